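"""Replication-gel densitometry.

Leading-strand products of an in vitro chromatin replication reaction are
separated on an alkaline agarose gel and imaged.  A lane's 1-D intensity
profile (position from the gel top, increasing downward; longer products
migrate less, i.e. sit at smaller positions) is obtained by summing image
columns across the lane, and the dominant leading-strand band is fit with a
single Gaussian over a flat baseline.  The fitted center is the mean
leading-strand migration; an optional log-linear ladder calibration converts
migration to fragment length.

Replication enhancement normalizes a test lane's metric between a
no-chaperone negative control (0%) and a full-length FACT positive control
(100%):

    enhancement % = 100 * (test - neg) / (pos - neg)

The normalization is affine-invariant, so it gives the same answer on
calibrated lengths or on raw centers (up to the migration-length
monotonicity, which the metric_kind flag declares).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import CalibrationError, NormalizationError

MIN_FIT_SAMPLES = 5


@dataclass
class LaneProfile:
    """1-D lane intensity profile; positions strictly increasing from gel top."""

    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.shape != self.intensities.shape or self.positions.ndim != 1:
            raise ValueError("positions and intensities must be equal-length 1-D arrays")
        if len(self.positions) >= 2 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"position": self.positions, "intensity": self.intensities}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "LaneProfile":
        df = pd.read_csv(path, comment="#")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())


@dataclass(frozen=True)
class GelFit:
    """Gaussian band fit: baseline + amplitude * exp(-(x - center)^2 / (2 sigma^2))."""

    center: float
    sigma: float
    amplitude: float
    baseline: float
    rss: float
    converged: bool
    message: str = ""


@dataclass(frozen=True)
class LadderCalibration:
    """Log-linear migration calibration: log10(length) = slope * position + intercept.

    Longer fragments migrate less, so slope < 0 in the top-down coordinate
    convention.
    """

    slope: float
    intercept: float
    r_squared: float

    def predict_length(self, position) -> np.ndarray | float:
        return 10.0 ** (self.slope * np.asarray(position, dtype=float) + self.intercept)


@dataclass(frozen=True)
class EnhancementResult:
    value: float
    test_metric: float
    neg_metric: float
    pos_metric: float
    metric_kind: str


def extract_lane_profile(image: np.ndarray, col_lo: int, col_hi: int) -> LaneProfile:
    """Per-row column sum of one lane's band [col_lo, col_hi)."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if not 0 <= col_lo < col_hi <= image.shape[1]:
        raise ValueError(f"empty or out-of-range column bounds [{col_lo}, {col_hi})")
    return LaneProfile(
        positions=np.arange(image.shape[0], dtype=float),
        intensities=image[:, col_lo:col_hi].sum(axis=1),
    )


def _gaussian(x, center, sigma, amplitude, baseline):
    return baseline + amplitude * np.exp(-((x - center) ** 2) / (2.0 * sigma**2))


def fit_lane_gaussian(profile: LaneProfile) -> GelFit:
    """Least-squares single-Gaussian fit of the dominant band.

    Initialization: center at the profile maximum, sigma from the half-max
    width, baseline at the minimum.  A flat profile or a non-converging fit
    returns ``converged=False`` with diagnostics — no fabricated center.
    """
    x, y = profile.positions, profile.intensities
    if len(x) < MIN_FIT_SAMPLES:
        raise ValueError(f"need >= {MIN_FIT_SAMPLES} samples, got {len(x)}")
    span = float(y.max() - y.min())
    if span == 0.0:
        return GelFit(np.nan, np.nan, np.nan, float(y.min()), np.nan, False, "flat profile")
    i_max = int(np.argmax(y))
    half = y.min() + span / 2.0
    above = np.flatnonzero(y >= half)
    width = x[above[-1]] - x[above[0]] if len(above) > 1 else x[1] - x[0]
    p0 = [x[i_max], max(width / 2.355, (x[1] - x[0]) / 2.0), span, float(y.min())]
    try:
        popt, _ = curve_fit(_gaussian, x, y, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        return GelFit(np.nan, np.nan, np.nan, np.nan, np.nan, False, f"fit failed: {exc}")
    center, sigma, amplitude, baseline = popt
    sigma = abs(float(sigma))
    rss = float(np.sum((y - _gaussian(x, *popt)) ** 2))
    if not x[0] <= center <= x[-1]:
        return GelFit(
            float(center), sigma, float(amplitude), float(baseline), rss, False,
            "fitted center outside the profile range",
        )
    return GelFit(float(center), sigma, float(amplitude), float(baseline), rss, True)


def ladder_calibrate(migrations, lengths) -> LadderCalibration:
    """Least-squares line of log10(fragment length) on migration position."""
    m = np.asarray(migrations, dtype=float)
    ln = np.asarray(lengths, dtype=float)
    if m.shape != ln.shape or m.ndim != 1 or len(m) < 2:
        raise ValueError("need >= 2 paired ladder points")
    if np.any(ln <= 0):
        raise ValueError("ladder lengths must be positive")
    if len(np.unique(m)) < 2:
        raise CalibrationError("duplicate migrations: singular calibration fit")
    logl = np.log10(ln)
    slope, intercept = np.polyfit(m, logl, 1)
    pred = slope * m + intercept
    ss_res = float(np.sum((logl - pred) ** 2))
    ss_tot = float(np.sum((logl - logl.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return LadderCalibration(float(slope), float(intercept), r2)


def replication_enhancement(
    test: float, neg: float, pos: float, metric_kind: str = "center"
) -> EnhancementResult:
    """Control-normalized enhancement: 100 * (test - neg) / (pos - neg).

    ``metric_kind`` declares what the three metrics are ("length" for
    ladder-calibrated fragment lengths, "center" for raw fitted centers in
    the top-down convention).  Values outside [0, 100] are permitted (a test
    reaction can exceed the full-length FACT control).
    """
    if pos == neg:
        raise NormalizationError("positive and negative controls coincide; normalization undefined")
    value = 100.0 * (test - neg) / (pos - neg)
    return EnhancementResult(float(value), float(test), float(neg), float(pos), metric_kind)


def write_fits_tsv(fits: dict[str, GelFit], path: str | Path, provenance: dict | None = None) -> None:
    rows = [
        (name, f.center, f.sigma, f.amplitude, f.baseline, f.rss, f.converged, f.message)
        for name, f in fits.items()
    ]
    df = pd.DataFrame(
        rows, columns=["lane", "center", "sigma", "amplitude", "baseline", "rss", "converged", "message"]
    )
    with open(path, "w") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False)
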