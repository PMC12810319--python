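"""Intensity-based particle-mass estimation for 2D class averages.

The particle signal of a class average is defined as every pixel more than
three standard deviations above the image mean; the rest is background.
Summing the background-subtracted particle intensities and multiplying by
the pixel area (A^2) gives a quantity proportional to molecular mass; a
linear calibration on particles of known mass converts it to kDa.  The
three mass-deviation features (from the stack mean, median and mode mass)
feed the quality scorer as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SIGMA_MULTIPLIER",
    "MassCalibration",
    "MassFeatures",
    "segment_particle",
    "summed_intensity",
    "estimate_mass",
    "fit_calibration",
    "mass_deviation_features",
    "save_calibration",
    "load_calibration",
]

#: Segmentation threshold: pixels above mean + SIGMA_MULTIPLIER * SD are signal.
SIGMA_MULTIPLIER = 3.0


@dataclass(frozen=True)
class MassCalibration:
    """Linear factor converting summed intensity x A^2 into kDa."""

    factor_c: float
    n_points: int
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.factor_c) and self.factor_c > 0):
            raise ValueError(f"factor_c must be positive and finite; got {self.factor_c}")
        if self.n_points < 1:
            raise ValueError("calibration needs at least one point")


#: Identity calibration (factor 1), used for synthetic data and testing.
UNIT_CALIBRATION = MassCalibration(factor_c=1.0, n_points=1, residual_rms=0.0)


@dataclass(frozen=True)
class MassFeatures:
    """Estimated mass and its signed deviations from stack statistics (kDa)."""

    est_mass: float
    dev_mean_mass: float
    dev_median_mass: float
    dev_mode_mass: float


def segment_particle(image: np.ndarray) -> np.ndarray:
    """Boolean mask of particle pixels: strictly above mean + 3 SD.

    Statistics are taken over the whole image (population SD); no
    morphological cleanup is applied.  An empty mask is a legal result
    (e.g. a constant image, where SD = 0 and nothing exceeds the mean).
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains NaN or Inf pixels")
    return image > image.mean() + SIGMA_MULTIPLIER * image.std()


def summed_intensity(image: np.ndarray, pixel_size: float) -> float:
    """Background-subtracted particle intensity times pixel area (A^2).

    Each particle pixel has the background mean subtracted before summation;
    an empty particle mask yields 0.
    """
    if not (np.isfinite(pixel_size) and pixel_size > 0):
        raise ValueError(f"pixel_size must be positive; got {pixel_size}")
    image = np.asarray(image, dtype=np.float64)
    mask = segment_particle(image)
    if not mask.any():
        return 0.0
    background_mean = image[~mask].mean() if (~mask).any() else 0.0
    return float((image[mask] - background_mean).sum() * pixel_size**2)


def estimate_mass(image: np.ndarray, pixel_size: float, cal: MassCalibration) -> float:
    """Estimated particle mass in kDa for one class average."""
    return cal.factor_c * summed_intensity(image, pixel_size)


def fit_calibration(pairs: Sequence[tuple[float, float]]) -> MassCalibration:
    """Fit the kDa-per-(intensity*A^2) factor on known-mass standards.

    Least-squares slope of mass on intensity through the origin:
    ``c = sum(I*M) / sum(I^2)``.
    """
    if len(pairs) < 1:
        raise ValueError("calibration needs at least one (intensity, mass) pair")
    intensity = np.asarray([p[0] for p in pairs], dtype=np.float64)
    mass = np.asarray([p[1] for p in pairs], dtype=np.float64)
    denom = float((intensity**2).sum())
    if denom == 0:
        raise ValueError("all calibration intensities are zero")
    factor = float((intensity * mass).sum() / denom)
    residual_rms = float(np.sqrt(np.mean((mass - factor * intensity) ** 2)))
    return MassCalibration(factor_c=factor, n_points=len(pairs), residual_rms=residual_rms)


def _histogram_mode(values: np.ndarray) -> float:
    """Mode of a continuous sample: center of the most populated
    Freedman-Diaconis bin (single bin when IQR = 0; ties go to the lowest bin)."""
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    vmin, vmax = float(values.min()), float(values.max())
    if iqr == 0 or vmax == vmin:
        return 0.5 * (vmin + vmax)
    width = 2.0 * iqr * len(values) ** (-1.0 / 3.0)
    n_bins = max(1, int(np.ceil((vmax - vmin) / width)))
    counts, edges = np.histogram(values, bins=n_bins, range=(vmin, vmax))
    k = int(np.argmax(counts))  # argmax takes the lowest bin on ties
    return float(0.5 * (edges[k] + edges[k + 1]))


def mass_deviation_features(masses: Sequence[float]) -> list[MassFeatures]:
    """Signed deviations (kDa) of each class mass from the stack mean,
    median and histogram mode."""
    masses_arr = np.asarray(masses, dtype=np.float64)
    if masses_arr.size < 1:
        raise ValueError("need at least one mass")
    if np.any(masses_arr < 0):
        raise ValueError("masses must be non-negative")
    mean = float(masses_arr.mean())
    median = float(np.median(masses_arr))
    mode = _histogram_mode(masses_arr)
    return [
        MassFeatures(
            est_mass=float(m),
            dev_mean_mass=float(m - mean),
            dev_median_mass=float(m - median),
            dev_mode_mass=float(m - mode),
        )
        for m in masses_arr
    ]


def save_calibration(cal: MassCalibration, path: str | Path) -> None:
    """Persist a calibration as a small key-value text file."""
    Path(path).write_text(
        f"factor_c {cal.factor_c!r}\nn_points {cal.n_points}\nresidual_rms {cal.residual_rms!r}\n"
    )


def load_calibration(path: str | Path) -> MassCalibration:
    kv = dict(line.split(None, 1) for line in Path(path).read_text().splitlines() if line.strip())
    return MassCalibration(
        factor_c=float(kv["factor_c"]),
        n_points=int(kv["n_points"]),
        residual_rms=float(kv["residual_rms"]),
    )
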