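"""Synthetic photon streams, burst tables and gel lanes.

The generator stands in for the instrument: freely diffusing, doubly labeled
molecules at ~50 pM produce sparse, non-overlapping photon bursts on top of a
low background.  Burst emission is modeled as piecewise-constant rates over an
exponentially distributed burst duration (default mean 1 ms) — no diffusion or
optics physics — because every downstream statistic depends only on per-burst
photon counts.  Each donor-excitation photon lands in the red channel with a
per-species probability ``p_da`` that folds together true FRET and donor
leakage: free DNA has p_da ~ 0.2 (leakage only), the intact nucleosome
p_da ~ 0.7.

Species carry a hidden ground-truth label through the pipeline so recovery
tests can compare estimates against the generating mixture; analysis
operations never see the labels.

Gel lanes are a dominant Gaussian leading-strand band over a flat baseline
with additive Gaussian noise, mirroring the densitometry model fitted
downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import SimulationError
from .streams import GREEN, RED, AlternationScheme, PhotonStream
from .bursts import BURST_COLUMNS

# ---------------------------------------------------------------------------
# photon-stream simulation
# ---------------------------------------------------------------------------

#: red-channel probability of a donor-excitation photon from free DNA: pure
#: donor leakage, no energy transfer at a 77 bp (~26 nm) dye separation
FREE_DNA_P_DA = 0.2
#: red-channel probability for the intact nucleosome (E* ~ 0.7)
NUCLEOSOME_P_DA = 0.7


@dataclass(frozen=True)
class SimSpecies:
    """One emitting species of the burst mixture.

    ``p_da`` is the probability that a donor-excitation photon is detected in
    the red channel (true FRET plus donor leakage).  ``dex_rate`` and
    ``aex_rate`` are detected photons per ms while the respective laser is on;
    ``aex_rate`` is 0 for acceptor-absent (donor-only) species.
    """

    name: str
    fraction: float
    p_da: float
    dex_rate: float = 100.0
    aex_rate: float = 100.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_da <= 1.0:
            raise ValueError(f"p_da must be in [0, 1], got {self.p_da}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction must be in [0, 1], got {self.fraction}")
        if self.dex_rate < 0 or self.aex_rate < 0:
            raise ValueError("rates must be >= 0")


def two_state_mixture(
    low_fret_weight: float,
    p_low: float = FREE_DNA_P_DA,
    p_high: float = NUCLEOSOME_P_DA,
    dex_rate: float = 100.0,
    aex_rate: float = 100.0,
) -> list[SimSpecies]:
    """Low-FRET / high-FRET two-species mixture at the given low-FRET weight."""
    return [
        SimSpecies("low_fret", low_fret_weight, p_low, dex_rate, aex_rate),
        SimSpecies("high_fret", 1.0 - low_fret_weight, p_high, dex_rate, aex_rate),
    ]


@dataclass(frozen=True)
class BackgroundRates:
    """Background photons per second per detector per excitation window."""

    donor_green: float = 1000.0
    donor_red: float = 600.0
    acceptor_green: float = 300.0
    acceptor_red: float = 900.0

    def __post_init__(self) -> None:
        if min(self.donor_green, self.donor_red, self.acceptor_green, self.acceptor_red) < 0:
            raise ValueError("background rates must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Photon-stream / burst-table simulation settings."""

    species: tuple[SimSpecies, ...]
    n_bursts: int = 1000
    mean_burst_duration_ms: float = 1.0
    burst_rate_per_s: float = 20.0
    background: BackgroundRates = field(default_factory=BackgroundRates)
    alternation: AlternationScheme = field(default_factory=AlternationScheme)
    seed: int = 0
    total_duration_s: float | None = None
    max_retries: int = 1000

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        if self.n_bursts < 0:
            raise ValueError("n_bursts must be >= 0")
        if self.mean_burst_duration_ms <= 0:
            raise ValueError("mean_burst_duration_ms must be positive")
        if self.burst_rate_per_s <= 0:
            raise ValueError("burst_rate_per_s must be positive")
        if self.n_bursts > 0:
            total = sum(sp.fraction for sp in self.species)
            if not self.species or abs(total - 1.0) > 1e-9:
                raise ValueError(f"species fractions must sum to 1, got {total}")


def _acceptor_segments(alt: AlternationScheme) -> list[tuple[int, int]]:
    """Phase intervals (within one period) with the acceptor laser on."""
    segs = []
    if alt.donor_start > 0:
        segs.append((0, alt.donor_start))
    if alt.donor_end < alt.period:
        segs.append((alt.donor_end, alt.period))
    return segs


def _window_photons(
    rng: np.random.Generator,
    t0: float,
    t1: float,
    seg: tuple[int, int],
    period: int,
    rate_per_tick: float,
) -> np.ndarray:
    """Poisson photon times within the overlap of [t0, t1) and one recurring
    phase segment; rate is constant while the segment is active."""
    if rate_per_tick <= 0 or t1 <= t0:
        return np.empty(0)
    p0 = int(math.floor(t0 / period))
    p1 = int(math.floor((t1 - 1e-9) / period))
    base = np.arange(p0, p1 + 1, dtype=np.float64) * period
    lo = np.maximum(base + seg[0], t0)
    hi = np.minimum(base + seg[1], t1)
    lens = np.clip(hi - lo, 0.0, None)
    counts = rng.poisson(lens * rate_per_tick)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    offsets = rng.random(total)
    return np.repeat(lo, counts) + offsets * np.repeat(lens, counts)


def simulate_photon_stream(
    config: SimConfig, return_truth: bool = False
) -> PhotonStream | tuple[PhotonStream, pd.DataFrame]:
    """Simulate a full ALEX photon stream.

    Bursts are placed at exponentially distributed inter-burst times; within a
    burst, photon counts per excitation window are Poisson with the species'
    rates, and each donor-excitation photon lands in the red detector with
    probability ``p_da``.  Background photons are Poisson throughout.
    Identical config (including seed) gives an identical stream.

    With ``return_truth=True`` also returns the per-burst ground truth
    (placement and generating species) used only by recovery tests.
    """
    alt = config.alternation
    period = alt.period
    tpms = alt.ticks_per_ms()
    ss = np.random.SeedSequence(config.seed)
    # child 0 drives placement/species/background; child i+1 the i-th burst
    children = ss.spawn(config.n_bursts + 1)
    root = np.random.default_rng(children[0])

    mean_dur = config.mean_burst_duration_ms * tpms
    mean_gap = alt.clock_rate_hz / config.burst_rate_per_s

    starts = np.empty(config.n_bursts)
    stops = np.empty(config.n_bursts)
    retries = 0
    prev_stop = 0.0
    prev_start = 0.0
    for i in range(config.n_bursts):
        dur = root.exponential(mean_dur)
        start = prev_start + root.exponential(mean_gap)
        while start < prev_stop:
            retries += 1
            if retries > config.max_retries:
                raise SimulationError(
                    "burst collisions exceeded the retry budget: burst density "
                    "too high for the sparse (non-overlapping) burst model"
                )
            start = prev_start + root.exponential(mean_gap)
        starts[i] = start
        stops[i] = start + dur
        prev_start, prev_stop = start, start + dur

    fractions = np.array([sp.fraction for sp in config.species]) if config.n_bursts else None
    species_idx = (
        root.choice(len(config.species), size=config.n_bursts, p=fractions)
        if config.n_bursts
        else np.empty(0, dtype=int)
    )

    times: list[np.ndarray] = []
    dets: list[np.ndarray] = []
    donor_seg = (alt.donor_start, alt.donor_end)
    acc_segs = _acceptor_segments(alt)
    for i in range(config.n_bursts):
        sp = config.species[species_idx[i]]
        rng = np.random.default_rng(children[i + 1])
        t_dex = _window_photons(rng, starts[i], stops[i], donor_seg, period, sp.dex_rate / tpms)
        det_dex = np.where(rng.random(len(t_dex)) < sp.p_da, RED, GREEN)
        times.append(t_dex)
        dets.append(det_dex.astype(np.int64))
        for seg in acc_segs:
            t_aa = _window_photons(rng, starts[i], stops[i], seg, period, sp.aex_rate / tpms)
            times.append(t_aa)
            dets.append(np.full(len(t_aa), RED, dtype=np.int64))

    if config.total_duration_s is not None:
        t_end = config.total_duration_s * alt.clock_rate_hz
    elif config.n_bursts:
        t_end = stops[-1] + mean_gap
    else:
        t_end = 1.0 * alt.clock_rate_hz  # 1 s of pure background
    bg = config.background
    per_s = 1.0 / alt.clock_rate_hz
    for seg, rate, det in (
        (donor_seg, bg.donor_green, GREEN),
        (donor_seg, bg.donor_red, RED),
    ):
        t_bg = _window_photons(root, 0.0, t_end, seg, period, rate * per_s)
        times.append(t_bg)
        dets.append(np.full(len(t_bg), det, dtype=np.int64))
    for seg in acc_segs:
        for rate, det in ((bg.acceptor_green, GREEN), (bg.acceptor_red, RED)):
            t_bg = _window_photons(root, 0.0, t_end, seg, period, rate * per_s)
            times.append(t_bg)
            dets.append(np.full(len(t_bg), det, dtype=np.int64))

    t_all = np.concatenate(times) if times else np.empty(0)
    d_all = np.concatenate(dets) if dets else np.empty(0, dtype=np.int64)
    t_ticks = np.floor(t_all).astype(np.int64)
    order = np.argsort(t_ticks, kind="stable")
    stream = PhotonStream(t_ticks[order], d_all[order], alt)
    if not return_truth:
        return stream
    truth = pd.DataFrame(
        {
            "burst_id": np.arange(config.n_bursts),
            "start_tick": starts.astype(np.int64),
            "stop_tick": stops.astype(np.int64),
            "species": [config.species[j].name for j in species_idx],
            "species_index": species_idx,
        }
    )
    return stream, truth


def simulate_burst_table(config: SimConfig) -> pd.DataFrame:
    """Fast path: draw per-burst DD/DA/AA counts directly, skipping timestamps.

    Per burst, the donor-excitation photon count is Poisson with the species'
    rate over the donor-on fraction of an exponential duration; DA is binomial
    with probability ``p_da`` out of it, and AA an independent Poisson.  The
    returned table carries the hidden ``species`` ground-truth column in
    addition to the standard burst columns; bursts with undefined E*/S
    (zero donor-excitation photons) are excluded.
    """
    alt = config.alternation
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_bursts
    fractions = np.array([sp.fraction for sp in config.species])
    idx = rng.choice(len(config.species), size=n, p=fractions)
    dur_ms = rng.exponential(config.mean_burst_duration_ms, size=n)
    dex_on = dur_ms * alt.donor_fraction
    aex_on = dur_ms - dex_on
    dex_rate = np.array([sp.dex_rate for sp in config.species])[idx]
    aex_rate = np.array([sp.aex_rate for sp in config.species])[idx]
    p_da = np.array([sp.p_da for sp in config.species])[idx]
    n_dex = rng.poisson(dex_rate * dex_on)
    n_da = rng.binomial(n_dex, p_da)
    n_dd = n_dex - n_da
    n_aa = rng.poisson(aex_rate * aex_on)

    # nominal non-overlapping placement for schema consistency
    tpms = alt.ticks_per_ms()
    gap = alt.clock_rate_hz / config.burst_rate_per_s
    stops = np.cumsum(dur_ms * tpms + gap)
    starts = stops - dur_ms * tpms

    size = n_dex + n_aa
    defined = n_dex > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        e_app = np.where(defined, n_da / np.maximum(n_dex, 1), np.nan)
        s = np.where(size > 0, n_dex / np.maximum(size, 1), np.nan)
    table = pd.DataFrame(
        {
            "burst_id": np.arange(n),
            "start_tick": starts.astype(np.int64),
            "stop_tick": stops.astype(np.int64),
            "n_dd": n_dd,
            "n_da": n_da,
            "n_aa": n_aa,
            "size": size,
            "e_app": e_app,
            "s": s,
            "species": [config.species[j].name for j in idx],
        }
    )
    return table.loc[defined, BURST_COLUMNS + ["species"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# gel simulation
# ---------------------------------------------------------------------------

UINT16_MAX = 65535


@dataclass(frozen=True)
class GelLane:
    """One simulated lane: a Gaussian leading-strand band over a baseline."""

    band_center: float
    band_sigma: float
    amplitude: float
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.band_sigma <= 0:
            raise ValueError("band_sigma must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class GelSimConfig:
    lanes: tuple[GelLane, ...]
    profile_length: int = 512
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "lanes", tuple(self.lanes))
        if self.profile_length < 2:
            raise ValueError("profile_length must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for lane in self.lanes:
            if not 0 <= lane.band_center < self.profile_length:
                raise ValueError(
                    f"band_center {lane.band_center} outside [0, {self.profile_length})"
                )


def simulate_lane_profile(config: GelSimConfig, lane_index: int):
    """Simulate the 1-D intensity profile of one lane (seeded per lane)."""
    from .gels import LaneProfile

    if not 0 <= lane_index < len(config.lanes):
        raise IndexError(f"lane_index {lane_index} out of range")
    lane = config.lanes[lane_index]
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, lane_index)))
    x = np.arange(config.profile_length, dtype=float)
    y = lane.baseline + lane.amplitude * np.exp(
        -((x - lane.band_center) ** 2) / (2.0 * lane.band_sigma**2)
    )
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, size=len(x))
    return LaneProfile(positions=x, intensities=y)


#: image-geometry defaults; a power-of-two lane width keeps the column split
#: and re-sum of each profile value exact in floating point
DEFAULT_LANE_WIDTH = 16
DEFAULT_LANE_GAP = 8
DEFAULT_MARGIN = 8


def lane_column_bounds(
    n_lanes: int,
    lane_width: int = DEFAULT_LANE_WIDTH,
    lane_gap: int = DEFAULT_LANE_GAP,
    margin: int = DEFAULT_MARGIN,
) -> list[tuple[int, int]]:
    """Column band [lo, hi) occupied by each lane in a simulated gel image."""
    bounds = []
    col = margin
    for _ in range(n_lanes):
        bounds.append((col, col + lane_width))
        col += lane_width + lane_gap
    return bounds


def simulate_gel_image(
    config: GelSimConfig,
    lane_width: int = DEFAULT_LANE_WIDTH,
    lane_gap: int = DEFAULT_LANE_GAP,
    margin: int = DEFAULT_MARGIN,
) -> np.ndarray:
    """2-D gel image: each lane's 1-D profile spread evenly over its column band.

    The column sum over a lane's band therefore reproduces the lane's 1-D
    simulated profile (exactly, including its noise draw).  Raises
    :class:`SimulationError` if any pixel exceeds the 16-bit intensity range.
    """
    n = len(config.lanes)
    bounds = lane_column_bounds(n, lane_width, lane_gap, margin)
    width = 2 * margin + n * lane_width + max(n - 1, 0) * lane_gap
    image = np.zeros((config.profile_length, max(width, 2 * margin)), dtype=float)
    for i, (lo, hi) in enumerate(bounds):
        profile = simulate_lane_profile(config, i)
        image[:, lo:hi] = (profile.intensities / lane_width)[:, None]
    if image.max(initial=0.0) > UINT16_MAX:
        raise SimulationError(
            f"pixel intensity {image.max():.1f} overflows the 16-bit range"
        )
    return image


def write_gel_tiff(image: np.ndarray, path) -> None:
    """Write an intensity matrix as 16-bit grayscale TIFF.

    Negative pixels (possible under additive noise) clip to 0; values above
    the 16-bit range are an error.
    """
    import tifffile

    if image.max(initial=0.0) > UINT16_MAX:
        raise SimulationError("image overflows the 16-bit range")
    tifffile.imwrite(path, np.clip(np.rint(image), 0, UINT16_MAX).astype(np.uint16))


def read_gel_tiff(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path).astype(float)
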