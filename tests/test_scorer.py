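"""Scorer: grade mapping, architecture contracts, training behavior,
inference, evaluation."""

from dataclasses import dataclass

import numpy as np
import pytest

from sift2d.formats_io import ClassAverageStack, ClassRecord
from sift2d.preprocess import CANVAS_SIDE
from sift2d.scorer import (
    EvaluationReport,
    MetadataFeatures,
    ScorerConfig,
    ScorerModel,
    build_scorer,
    desk_scorer_config,
    evaluate,
    grade_to_score,
    score_classes,
    train_scorer,
)
from sift2d.synthetic_data import make_labeled_corpus

TINY = dict(channel_widths=(2, 4), blocks_per_stage=1, stem_downsample=True,
            head_width=8, batch_size=8)


class TestGradeMapping:
    @pytest.mark.parametrize("grade,score", [("A", 1.0), ("B", 2.0), ("C", 3.0), ("D", 4.0), ("F", 5.0)])
    def test_rubric_anchors(self, grade, score):
        assert grade_to_score(grade) == score

    def test_unknown_grade_rejected(self):
        with pytest.raises(ValueError, match="unknown grade"):
            grade_to_score("E")


class TestArchitecture:
    def test_seeded_forward_is_deterministic(self):
        cfg = ScorerConfig(seed=3, **TINY)
        img = np.zeros((1, CANVAS_SIDE, CANVAS_SIDE), dtype=np.float32)
        meta = np.zeros((1, 6))
        a = build_scorer(cfg).net.forward(img, meta, train=False)
        b = build_scorer(cfg).net.forward(img, meta, train=False)
        assert a == b

    @pytest.mark.parametrize("widths,blocks", [((2, 4), 1), ((2, 3, 4), 2)])
    def test_pooled_map_is_6x6_regardless_of_trunk_depth(self, widths, blocks):
        cfg = ScorerConfig(channel_widths=widths, blocks_per_stage=blocks,
                           stem_downsample=True, head_width=8, seed=0)
        net = build_scorer(cfg).net
        x = np.random.default_rng(0).normal(size=(2, 1, CANVAS_SIDE, CANVAS_SIDE)).astype(np.float32)
        for layer in net.trunk:
            x = layer.forward(x, train=False)
        pooled = net.pool.forward(x, train=False)
        assert pooled.shape[2:] == (6, 6)

    def test_no_pooling_layers_in_trunk(self):
        net = build_scorer(ScorerConfig(seed=0, **TINY)).net
        assert all("Pool" not in name for name in net.trunk_layer_names())

    def test_batch_of_32_gives_32_scores(self):
        net = build_scorer(ScorerConfig(seed=0, **TINY)).net
        rng = np.random.default_rng(1)
        out = net.forward(
            rng.normal(size=(32, CANVAS_SIDE, CANVAS_SIDE)).astype(np.float32),
            rng.normal(size=(32, 6)).astype(np.float32),
            train=False,
        )
        assert out.shape == (32,)
        assert np.all(np.isfinite(out))


class TestTraining:
    def test_seeded_training_is_reproducible(self):
        corpus = make_labeled_corpus(n=48, seed=5)
        cfg = ScorerConfig(seed=5, epochs=2, **TINY)
        m1 = train_scorer(corpus, cfg)
        m2 = train_scorer(corpus, cfg)
        assert m1.history[-1]["val_mse"] == m2.history[-1]["val_mse"]

    def test_constant_labels_collapse_to_mean(self):
        corpus = make_labeled_corpus(n=100, seed=9)
        triples = [(corpus.canvases[i], corpus.metadata[i], 3.0) for i in range(100)]
        model = train_scorer(triples, ScorerConfig(seed=9, epochs=30, **TINY))
        assert model.history[-1]["val_mse"] < 0.05

    def test_corpus_smaller_than_batch_rejected(self):
        corpus = make_labeled_corpus(n=4, seed=1)
        with pytest.raises(ValueError, match="smaller than one batch"):
            train_scorer(corpus, ScorerConfig(seed=1, epochs=1, **TINY))

    def test_history_records_every_epoch(self):
        corpus = make_labeled_corpus(n=40, seed=2)
        model = train_scorer(corpus, ScorerConfig(seed=2, epochs=3, **TINY))
        assert [h["epoch"] for h in model.history] == [0, 1, 2]

    def test_checkpoint_round_trip(self, tmp_path):
        corpus = make_labeled_corpus(n=40, seed=4)
        model = train_scorer(corpus, ScorerConfig(seed=4, epochs=1, **TINY))
        model.save(tmp_path / "m.sift2d")
        back = ScorerModel.load(tmp_path / "m.sift2d")
        meta = np.stack([f.to_vector() for f in corpus.metadata])
        assert np.allclose(
            back.predict(corpus.canvases, meta), model.predict(corpus.canvases, meta)
        )


def _oracle_model(output: float) -> ScorerModel:
    """A trained-flagged model that always predicts ``output``."""
    model = build_scorer(ScorerConfig(seed=0, **TINY))
    model.net.fc2.weight.value[...] = 0.0
    model.net.fc1.weight.value[...] = 0.0
    model.net.fc2.bias.value[...] = output
    model.trained = True
    return model


class TestScoreClasses:
    def _stack_and_records(self, n=20):
        rng = np.random.default_rng(0)
        stack = ClassAverageStack(rng.normal(size=(n, 64, 64)).astype(np.float32), pixel_size=1.0)
        records = [
            ClassRecord(
                class_index=i, pixel_size=1.0, frc_resolution=5.0, class_distribution=1.0 / n,
                dev_mean_mass=0.0, dev_median_mass=0.0, dev_mode_mass=0.0,
            )
            for i in range(n)
        ]
        return stack, records

    def test_one_score_per_class_in_order(self):
        stack, records = self._stack_and_records(20)
        scores = score_classes(_oracle_model(2.5), stack, records)
        assert len(scores) == 20 and all(s == pytest.approx(2.5) for s in scores)

    def test_inference_is_deterministic(self):
        corpus = make_labeled_corpus(n=40, seed=6)
        model = train_scorer(corpus, ScorerConfig(seed=6, epochs=1, **TINY))
        stack, records = self._stack_and_records(6)
        assert score_classes(model, stack, records) == score_classes(model, stack, records)

    def test_scores_above_five_are_not_clipped(self):
        stack, records = self._stack_and_records(3)
        scores = score_classes(_oracle_model(5.3), stack, records)
        assert all(s == pytest.approx(5.3) for s in scores)

    def test_missing_metadata_names_class_and_field(self):
        stack, records = self._stack_and_records(4)
        records[2].dev_mode_mass = None
        with pytest.raises(ValueError, match="class 2.*dev_mode_mass"):
            score_classes(_oracle_model(1.0), stack, records)

    def test_untrained_model_rejected(self):
        stack, records = self._stack_and_records(2)
        with pytest.raises(ValueError, match="not trained"):
            score_classes(build_scorer(ScorerConfig(seed=0, **TINY)), stack, records)


class TestEvaluate:
    @dataclass
    class _Echo:
        offset: float = 0.0

        def predict(self, images, metadata):
            # labels are recoverable from the test corpus closure
            return self._labels + self.offset

    def _corpus(self, labels):
        rng = np.random.default_rng(0)
        canvases = rng.normal(size=(len(labels), CANVAS_SIDE, CANVAS_SIDE)).astype(np.float32)
        meta = [
            MetadataFeatures(1.0, 5.0, 0.1, 0.0, 0.0, 0.0) for _ in labels
        ]
        return [(canvases[i], meta[i], labels[i]) for i in range(len(labels))]

    def _eval(self, labels, offset):
        model = self._Echo(offset)
        model._labels = np.asarray(labels, dtype=float)
        return evaluate(model, self._corpus(labels))

    def test_perfect_predictions(self):
        report = self._eval([1.0, 2.0, 3.0, 4.0, 5.0], offset=0.0)
        assert report.mse == 0.0
        assert np.all(report.confusion == np.diag(np.diag(report.confusion)))

    def test_constant_offset_mse(self):
        report = self._eval([1.0, 2.0, 3.0, 4.0], offset=0.1)
        assert report.mse == pytest.approx(0.01)

    def test_confusion_rows_conserve_label_counts(self):
        labels = [1.0, 1.0, 2.0, 3.0, 3.0, 3.0, 5.0]
        report = self._eval(labels, offset=0.3)
        from sift2d.scorer import _to_bins

        counts = np.bincount(_to_bins(np.asarray(labels)), minlength=10)
        assert np.array_equal(report.confusion.sum(axis=1), counts)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate(self._Echo(), [])


def test_end_to_end_any_side_yields_one_score():
    """Original image sides from the minimum upward all map to one score."""
    from sift2d.preprocess import resample_to_canvas

    model = _oracle_model(1.7)
    for side in (31, 64, 210, 400):
        img = np.random.default_rng(side).normal(size=(side, side))
        canvas = resample_to_canvas(img)
        score = model.predict(canvas.pixels[None], np.zeros((1, 6)))
        assert score.shape == (1,) and np.isfinite(score[0])
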