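"""Burst analysis: photon classification, dual-color burst search, E*/S.

A diffusing molecule crossing the confocal volume produces a burst of photons.
Each photon is classified by excitation window and detector into one of three
streams: DD (donor emission under donor excitation), DA (acceptor emission
under donor excitation) and AA (acceptor emission under direct acceptor
excitation); green photons during acceptor excitation carry no signal and are
discarded.  Per burst the apparent FRET efficiency and labeling stoichiometry
are

    E* = DA / (DA + DD)          S = (DA + DD) / (DA + DD + AA)

both uncorrected for leakage, direct excitation or detection gamma.  The
dual-color burst search (DCBS) requires simultaneous donor-excitation and
acceptor-excitation photon rates, which enriches doubly labeled molecules.

The "loss of FRET" statistic — the percentage of bursts below a universal
E* = 0.4 cutoff — quantifies nucleosome reorganization: intact nucleosomes sit
near E* = 0.7, reorganized/free DNA near E* = 0.2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import UndefinedStatisticError
from .streams import GREEN, RED, AlternationScheme, PhotonStream

logger = logging.getLogger(__name__)

# photon labels
DD = 0
DA = 1
AA = 2
DISCARD = 3

LABEL_NAMES = {DD: "DD", DA: "DA", AA: "AA", DISCARD: "discard"}

#: default E* cutoff separating the low-FRET (reorganized / free DNA) from the
#: high-FRET (intact nucleosome) population
DEFAULT_CUTOFF = 0.4

BURST_COLUMNS = ["burst_id", "start_tick", "stop_tick", "n_dd", "n_da", "n_aa", "size", "e_app", "s"]


@dataclass
class LabeledStream:
    """A photon stream plus a per-photon DD/DA/AA/discard label."""

    timestamps: np.ndarray
    detectors: np.ndarray
    labels: np.ndarray
    alternation: AlternationScheme

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass(frozen=True)
class BurstSearchParams:
    """Dual-color burst-search parameters.

    ``window`` is the full width (in clock ticks) of the sliding window
    centered on each photon; ``m_dex``/``m_aex`` are the minimum number of
    donor-excitation-window (DD+DA) and acceptor-excitation-window (AA)
    photons required inside it for the photon to count as "hot";
    ``min_size`` drops bursts with fewer total photons.
    """

    window: int = 500
    m_dex: int = 10
    m_aex: int = 10
    min_size: int = 30

    def __post_init__(self) -> None:
        for name in ("window", "m_dex", "m_aex", "min_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Burst:
    start_tick: int
    stop_tick: int
    n_dd: int
    n_da: int
    n_aa: int

    @property
    def size(self) -> int:
        return self.n_dd + self.n_da + self.n_aa


@dataclass
class ESHistogram:
    """2-D burst histogram of E* versus S plus its E* marginal."""

    e_edges: np.ndarray
    s_edges: np.ndarray
    counts_2d: np.ndarray
    counts_e: np.ndarray


def classify_photons(stream: PhotonStream) -> LabeledStream:
    """Label each photon DD/DA/AA/discard from its alternation phase and detector."""
    alt = stream.alternation
    phase = stream.timestamps % alt.period
    in_donor = (phase >= alt.donor_start) & (phase < alt.donor_end)
    labels = np.full(len(stream), DISCARD, dtype=np.int8)
    labels[in_donor & (stream.detectors == GREEN)] = DD
    labels[in_donor & (stream.detectors == RED)] = DA
    labels[~in_donor & (stream.detectors == RED)] = AA
    return LabeledStream(stream.timestamps, stream.detectors, labels, alt)


def _hot_photons(labeled: LabeledStream, params: BurstSearchParams) -> np.ndarray:
    """Boolean hot mask: photon i is hot iff the half-open centered window
    [t_i - w/2, t_i + w/2) contains >= m_dex DEX photons and >= m_aex AA photons."""
    t = labeled.timestamps.astype(np.float64)
    half = params.window / 2.0
    dex_t = t[(labeled.labels == DD) | (labeled.labels == DA)]
    aex_t = t[labeled.labels == AA]
    lo, hi = t - half, t + half
    n_dex = np.searchsorted(dex_t, hi, side="left") - np.searchsorted(dex_t, lo, side="left")
    n_aex = np.searchsorted(aex_t, hi, side="left") - np.searchsorted(aex_t, lo, side="left")
    return (n_dex >= params.m_dex) & (n_aex >= params.m_aex)


def dual_color_burst_search(
    labeled: LabeledStream, params: BurstSearchParams | None = None
) -> list[Burst]:
    """Find bursts as maximal runs of consecutive hot photons.

    Returns time-ordered, non-overlapping bursts with DD/DA/AA counts tallied
    over the run; runs with fewer than ``params.min_size`` total photons are
    dropped.  A run also breaks between consecutive hot photons farther apart
    than the search window (their windows share no photons, so they cannot
    belong to one molecule transit).  An empty stream yields an empty list.
    """
    params = params or BurstSearchParams()
    if len(labeled) == 0:
        return []
    hot = _hot_photons(labeled, params)
    if not hot.any():
        return []
    # run boundaries: hot-state changes, plus time gaps wider than the window
    t = labeled.timestamps
    gap_break = np.concatenate([[False], np.diff(t) > params.window])
    new_run = hot & (~np.concatenate([[False], hot[:-1]]) | gap_break)
    run_id = np.where(hot, np.cumsum(new_run), 0)
    bursts = []
    starts = np.flatnonzero(new_run)
    for rid, i0 in enumerate(starts, start=1):
        i1 = i0
        while i1 < len(t) and run_id[i1] == rid:
            i1 += 1
        if i1 - i0 < params.min_size:
            continue
        lab = labeled.labels[i0:i1]
        bursts.append(
            Burst(
                start_tick=int(labeled.timestamps[i0]),
                stop_tick=int(labeled.timestamps[i1 - 1]),
                n_dd=int(np.count_nonzero(lab == DD)),
                n_da=int(np.count_nonzero(lab == DA)),
                n_aa=int(np.count_nonzero(lab == AA)),
            )
        )
    return bursts


def compute_es(n_dd: int, n_da: int, n_aa: int) -> tuple[float, float]:
    """Apparent FRET efficiency and stoichiometry from raw burst counts.

    E* = DA/(DA+DD), S = (DA+DD)/(DA+DD+AA).  Raises
    :class:`UndefinedStatisticError` on a zero denominator.
    """
    dex = n_dd + n_da
    tot = dex + n_aa
    if dex <= 0 or tot <= 0:
        raise UndefinedStatisticError(
            f"E*/S undefined for counts DD={n_dd}, DA={n_da}, AA={n_aa}"
        )
    return n_da / dex, dex / tot


def burst_table(bursts: list[Burst]) -> pd.DataFrame:
    """Tabulate bursts with E* and S; bursts with undefined E*/S are excluded."""
    rows = []
    n_dropped = 0
    for i, b in enumerate(bursts):
        try:
            e, s = compute_es(b.n_dd, b.n_da, b.n_aa)
        except UndefinedStatisticError:
            n_dropped += 1
            continue
        rows.append((i, b.start_tick, b.stop_tick, b.n_dd, b.n_da, b.n_aa, b.size, e, s))
    if n_dropped:
        logger.info("excluded %d burst(s) with undefined E*/S", n_dropped)
    return pd.DataFrame(rows, columns=BURST_COLUMNS)


def select_bursts(
    table: pd.DataFrame,
    min_size: int = 0,
    s_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Filter a burst table on total photons and (optionally) stoichiometry.

    S-range filtering defaults off: the dual-color search already enriches
    doubly labeled molecules.
    """
    mask = table["size"] >= min_size
    if s_range is not None:
        lo, hi = s_range
        mask &= (table["s"] >= lo) & (table["s"] <= hi)
    out = table.loc[mask].reset_index(drop=True)
    logger.info("select_bursts: %d -> %d bursts", len(table), len(out))
    return out


def default_edges(n_bins: int = 48) -> np.ndarray:
    """Default histogram binning: 48 bins spanning [-0.1, 1.1]."""
    return np.linspace(-0.1, 1.1, n_bins + 1)


def es_histogram(
    table: pd.DataFrame,
    e_edges: np.ndarray | None = None,
    s_edges: np.ndarray | None = None,
) -> ESHistogram:
    """2-D histogram of per-burst (E*, S) plus the E* marginal."""
    e_edges = default_edges() if e_edges is None else np.asarray(e_edges, dtype=float)
    s_edges = default_edges() if s_edges is None else np.asarray(s_edges, dtype=float)
    for name, edges in (("e_edges", e_edges), ("s_edges", s_edges)):
        if len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError(f"{name} must be strictly increasing with >= 2 entries")
    counts_2d, _, _ = np.histogram2d(table["e_app"], table["s"], bins=(e_edges, s_edges))
    return ESHistogram(e_edges, s_edges, counts_2d, counts_2d.sum(axis=1))


def loss_of_fret(table: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF) -> float:
    """Percentage of bursts with E* strictly below ``cutoff``.

    Bursts exactly at the cutoff count as high-FRET.  This is the headline
    nucleosome-reorganization statistic: ~10% for intact nucleosomes, ~70%
    after reorganization by yFACT.
    """
    if len(table) == 0:
        raise UndefinedStatisticError("loss_of_fret is undefined on an empty burst table")
    return 100.0 * float(np.count_nonzero(table["e_app"] < cutoff)) / len(table)


def write_burst_table(table: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> None:
    """Write a burst table as TSV with ``# key=value`` provenance header comments."""
    with open(path, "w") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}={val}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_burst_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
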