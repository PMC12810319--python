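"""Iterative classify -> score -> route particle-curation policy.

Particles carry one of three mutually exclusive states: ``working`` (still
being classified), ``banked`` (good particles set aside from further
rounds) and ``discarded``.  Each round, every working particle inherits the
quality score of its 2D class; particles at or above the discard cutoff
(4.5) are discarded permanently, a seeded random 70% of particles at or
below the accept cutoff (2.5) are banked, and everything else keeps
working.  The number of rounds follows the extraction box side: fewer than
200 px -> 5 rounds, 200-300 px inclusive -> 3, above 300 px -> 2.  After
the scheduled rounds, banked and surviving working particles are pooled for
one final classification and scoring, then split into three nested batches
at final scores <= 2.5, <= 3.5 and <= 4.5; pooled particles scoring above
4.5 are discarded so the batches plus the discard set partition the input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd

from sift2d.formats_io import ClassAverageStack, ClassRecord
from sift2d.scorer import ScorerModel, score_classes

__all__ = [
    "PolicyConfig",
    "Classifier2DBackend",
    "SiftResult",
    "iteration_count",
    "recommend_class2d_params",
    "new_particle_table",
    "route",
    "final_batches",
    "run_sift",
]

WORKING, BANKED, DISCARDED = "working", "banked", "discarded"


@dataclass(frozen=True)
class PolicyConfig:
    accept_cutoff: float = 2.5
    discard_cutoff: float = 4.5
    bank_fraction: float = 0.70
    final_thresholds: tuple[float, float, float] = (2.5, 3.5, 4.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.accept_cutoff < self.discard_cutoff:
            raise ValueError("accept_cutoff must be below discard_cutoff")
        if not (0.0 < self.bank_fraction < 1.0):
            raise ValueError("bank_fraction must lie in (0, 1)")
        if list(self.final_thresholds) != sorted(set(self.final_thresholds)):
            raise ValueError("final_thresholds must be strictly increasing")


class Classifier2DBackend(Protocol):
    """Contract for a pluggable 2D-classification engine."""

    def classify(
        self, particle_ids: np.ndarray, round_index: int
    ) -> tuple[np.ndarray, ClassAverageStack, list[ClassRecord]]:
        """Assign every particle to exactly one class; return per-particle
        class indices, the class-average stack and per-class metadata with
        class distribution = member count / total."""
        ...


def iteration_count(box_side_px: int) -> int:
    """Scheduled classification rounds for an extraction box side (px):
    5 below 200, 3 for 200-300 inclusive, 2 above 300."""
    if box_side_px <= 0:
        raise ValueError(f"box side must be positive; got {box_side_px}")
    if box_side_px < 200:
        return 5
    if box_side_px <= 300:
        return 3
    return 2


def recommend_class2d_params(box_side_px: int) -> dict:
    """Box-size-dependent 2D classification settings.

    Small boxes (< 200 px) use the small-particle job settings (3 A maximum
    resolution, initial class uncertainty factor 3, force-max over
    poses/shifts off, 40 online-EM iterations, batch size 400); boxes of
    200-300 px keep defaults; large boxes (> 300 px) are Fourier-cropped to
    100 px with adaptive binning.
    """
    if box_side_px <= 0:
        raise ValueError(f"box side must be positive; got {box_side_px}")
    if box_side_px < 200:
        return {
            "tier": "small",
            "max_resolution_A": 3.0,
            "init_uncertainty_factor": 3,
            "force_max_over_poses_shifts": False,
            "online_em_iterations": 40,
            "batch_size": 400,
        }
    if box_side_px <= 300:
        return {"tier": "default"}
    return {"tier": "large", "fourier_crop_to_px": 100, "adaptive_binning": True}


def new_particle_table(particle_ids: Sequence[int]) -> pd.DataFrame:
    """Fresh table: every particle working, unscored, unassigned."""
    ids = np.asarray(particle_ids, dtype=int)
    if len(np.unique(ids)) != len(ids):
        raise ValueError("particle_ids must be unique")
    return pd.DataFrame(
        {
            "particle_id": ids,
            "state": WORKING,
            "score": np.nan,
            "class_id": -1,
        }
    )


def route(
    table: pd.DataFrame,
    config: PolicyConfig,
    round_index: int,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """One routing step over the working particles (returns a new table).

    Scores at or above the discard cutoff -> discarded; a seeded uniform
    random ``bank_fraction`` of scores at or below the accept cutoff ->
    banked (the rest keep working); mid-range scores keep working.  Banked
    and discarded states are never revisited.
    """
    table = table.copy()
    if len(table) == 0:
        return table
    working = table["state"] == WORKING
    if table.loc[working, "score"].isna().any():
        bad = table.loc[working & table["score"].isna(), "particle_id"].tolist()[:5]
        raise ValueError(f"working particles without a score, e.g. {bad}")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, round_index)))

    discard = working & (table["score"] >= config.discard_cutoff)
    table.loc[discard, "state"] = DISCARDED

    good_idx = table.index[working & ~discard & (table["score"] <= config.accept_cutoff)]
    n_bank = int(round(config.bank_fraction * len(good_idx)))
    if n_bank > 0:
        banked_idx = rng.choice(np.asarray(good_idx), size=n_bank, replace=False)
        table.loc[np.sort(banked_idx), "state"] = BANKED
    return table


def final_batches(
    scores: pd.Series, thresholds: Sequence[float] = (2.5, 3.5, 4.5)
) -> dict[float, np.ndarray]:
    """Cumulative particle batches at score <= threshold (nested by
    construction).  ``scores`` is indexed by particle id."""
    return {
        float(t): np.sort(scores.index[scores.to_numpy() <= t].to_numpy())
        for t in thresholds
    }


@dataclass
class SiftResult:
    """Outcome of the full iterative sift."""

    batches: dict[float, np.ndarray]
    discarded: np.ndarray
    final_scores: pd.Series
    audit: list[dict] = field(default_factory=list)
    n_input: int = 0

    def audit_json(self) -> str:
        """Line-oriented JSON audit log (deterministic byte-for-byte)."""
        return "\n".join(json.dumps(entry, sort_keys=True) for entry in self.audit)


def _state_counts(table: pd.DataFrame) -> dict[str, int]:
    counts = table["state"].value_counts()
    return {s: int(counts.get(s, 0)) for s in (WORKING, BANKED, DISCARDED)}


def run_sift(
    particles: pd.DataFrame | Sequence[int],
    backend: Classifier2DBackend,
    model: ScorerModel,
    box_side_px: int,
    config: PolicyConfig | None = None,
    score_fn: Callable[[ScorerModel, ClassAverageStack, list[ClassRecord]], list[float]] | None = None,
) -> SiftResult:
    """Run the full iterative classify -> score -> route policy.

    ``particles`` is a particle table (or a sequence of particle ids).
    After ``iteration_count(box_side_px)`` rounds, banked and surviving
    working particles are pooled, classified and scored once more, and
    split into the three nested final batches; final scores above the top
    threshold are discarded.  Stops early (and logs it) if the working set
    empties.
    """
    config = config or PolicyConfig()
    if score_fn is None:
        score_fn = score_classes
    if not isinstance(particles, pd.DataFrame):
        particles = new_particle_table(particles)
    table = particles.copy()
    if len(table) == 0:
        raise ValueError("particle table is empty")
    n_input = len(table)
    n_rounds = iteration_count(box_side_px)
    audit: list[dict] = []

    def classify_and_score(ids: np.ndarray, round_index: int):
        try:
            assignment, stack, records = backend.classify(ids, round_index)
        except Exception as exc:
            raise RuntimeError(f"classification backend failed in round {round_index}") from exc
        class_scores = score_fn(model, stack, records)
        return assignment, np.asarray(class_scores, dtype=float), records

    for round_index in range(1, n_rounds + 1):
        working_mask = table["state"] == WORKING
        ids = table.loc[working_mask, "particle_id"].to_numpy()
        if len(ids) == 0:
            audit.append({"round": round_index, "event": "early_stop_working_set_empty"})
            break
        assignment, class_scores, records = classify_and_score(ids, round_index)
        table.loc[working_mask, "class_id"] = assignment
        table.loc[working_mask, "score"] = class_scores[assignment]
        table = route(table, config, round_index)
        entry = _state_counts(table)
        audit.append(
            {
                "round": round_index,
                "event": "classified",
                "n_classes": int(len(class_scores)),
                "class_scores": [round(float(s), 6) for s in class_scores],
                "class_refs": [r.image_ref for r in records],
                **entry,
            }
        )
        assert sum(entry.values()) == n_input, "particle states must partition the input"

    pool_mask = table["state"].isin([WORKING, BANKED])
    pool_ids = table.loc[pool_mask, "particle_id"].to_numpy()
    if len(pool_ids) > 0:
        final_round = n_rounds + 1
        assignment, class_scores, records = classify_and_score(pool_ids, final_round)
        table.loc[pool_mask, "class_id"] = assignment
        table.loc[pool_mask, "score"] = class_scores[assignment]
        top = config.final_thresholds[-1]
        fail = pool_mask & (table["score"] > top)
        table.loc[fail, "state"] = DISCARDED
        audit.append(
            {
                "round": final_round,
                "event": "final_classification",
                "n_classes": int(len(class_scores)),
                "class_scores": [round(float(s), 6) for s in class_scores],
                "class_refs": [r.image_ref for r in records],
                **_state_counts(table),
            }
        )
        pooled = table.loc[table["state"].isin([WORKING, BANKED])]
        final_scores = pd.Series(pooled["score"].to_numpy(), index=pooled["particle_id"].to_numpy())
    else:
        final_scores = pd.Series(dtype=float)

    batches = final_batches(final_scores, config.final_thresholds)
    discarded = np.sort(table.loc[table["state"] == DISCARDED, "particle_id"].to_numpy())
    result = SiftResult(
        batches=batches,
        discarded=discarded,
        final_scores=final_scores,
        audit=audit,
        n_input=n_input,
    )
    top_batch = batches[float(config.final_thresholds[-1])]
    assert len(top_batch) + len(discarded) <= n_input
    return result
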