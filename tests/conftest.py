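"""Shared fixtures and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from alexfret.bursts import AA, DA, DD, Burst, BurstSearchParams, LabeledStream
from alexfret.streams import AlternationScheme, PhotonStream


def brute_force_bursts(labeled: LabeledStream, params: BurstSearchParams) -> list[Burst]:
    """O(n^2) reference dual-color burst search.

    Independently re-derives hot photons by comparing every photon pair, then
    collects maximal consecutive hot runs.  Used only as an oracle.
    """
    t = labeled.timestamps.astype(float)
    labels = labeled.labels
    n = len(t)
    half = params.window / 2.0
    hot = np.zeros(n, dtype=bool)
    is_dex = (labels == DD) | (labels == DA)
    is_aex = labels == AA
    for i in range(n):
        in_win = (t >= t[i] - half) & (t < t[i] + half)
        hot[i] = (
            np.count_nonzero(in_win & is_dex) >= params.m_dex
            and np.count_nonzero(in_win & is_aex) >= params.m_aex
        )
    bursts: list[Burst] = []
    i = 0
    while i < n:
        if not hot[i]:
            i += 1
            continue
        j = i
        # a run continues through hot photons no farther apart than the window
        while j + 1 < n and hot[j + 1] and t[j + 1] - t[j] <= params.window:
            j += 1
        if j - i + 1 >= params.min_size:
            lab = labels[i : j + 1]
            bursts.append(
                Burst(
                    start_tick=int(labeled.timestamps[i]),
                    stop_tick=int(labeled.timestamps[j]),
                    n_dd=int(np.count_nonzero(lab == DD)),
                    n_da=int(np.count_nonzero(lab == DA)),
                    n_aa=int(np.count_nonzero(lab == AA)),
                )
            )
        i = j + 1
    return bursts


def random_labeled_stream(rng: np.random.Generator, n_photons: int) -> LabeledStream:
    """Random sorted photon stream with random DD/DA/AA/discard labels."""
    alt = AlternationScheme()
    # cluster timestamps so some windows actually reach the thresholds
    t = np.sort(rng.integers(0, rng.integers(2_000, 50_000), size=n_photons))
    labels = rng.choice([DD, DA, AA, 3], size=n_photons, p=[0.35, 0.25, 0.3, 0.1]).astype(np.int8)
    detectors = np.where((labels == DD) | (labels == 3), 0, 1).astype(np.int8)
    return LabeledStream(t.astype(np.int64), detectors, labels, alt)


@pytest.fixture
def alternation() -> AlternationScheme:
    return AlternationScheme()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


def make_stream(timestamps, detectors, alt=None) -> PhotonStream:
    return PhotonStream(
        np.asarray(timestamps, dtype=np.int64),
        np.asarray(detectors, dtype=np.int8),
        alt or AlternationScheme(),
    )
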