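"""Dual-color burst search, E*/S arithmetic and the loss-of-FRET statistic."""

import numpy as np
import pandas as pd
import pytest

from alexfret import (
    AA,
    DA,
    DD,
    AlternationScheme,
    BurstSearchParams,
    UndefinedStatisticError,
    burst_table,
    compute_es,
    dual_color_burst_search,
    es_histogram,
    loss_of_fret,
    read_burst_table,
    select_bursts,
    write_burst_table,
)
from alexfret.bursts import Burst, LabeledStream
from conftest import brute_force_bursts, random_labeled_stream


def labeled(timestamps, labels) -> LabeledStream:
    t = np.asarray(timestamps, dtype=np.int64)
    lab = np.asarray(labels, dtype=np.int8)
    det = np.where(lab == DD, 0, 1).astype(np.int8)
    return LabeledStream(t, det, lab, AlternationScheme())


def dense_cluster(t0: int, n_dex: int = 30, n_aex: int = 30, spacing: int = 3):
    """A photon cluster alternating DEX and AA labels, spanning < 200 us."""
    n = n_dex + n_aex
    t = t0 + np.arange(n) * spacing
    lab = np.empty(n, dtype=int)
    lab[0::2] = DD
    lab[1::2] = AA
    # make a third of the DEX photons DA so E* is nontrivial
    dex_idx = np.flatnonzero(lab == DD)
    lab[dex_idx[: n_dex // 3]] = DA
    return t, lab


class TestComputeES:
    @pytest.mark.parametrize(
        "dd, da, aa, e, s",
        [
            (30, 70, 100, 0.7, 0.5),   # intact-nucleosome regime
            (80, 20, 100, 0.2, 0.5),   # free-DNA regime (leakage only)
            (50, 0, 50, 0.0, 0.5),
            (0, 40, 0, 1.0, 1.0),
        ],
    )
    def test_known_count_combinations(self, dd, da, aa, e, s):
        assert compute_es(dd, da, aa) == pytest.approx((e, s))

    def test_zero_denominator_raises(self):
        with pytest.raises(UndefinedStatisticError):
            compute_es(0, 0, 100)
        with pytest.raises(UndefinedStatisticError):
            compute_es(0, 0, 0)

    def test_es_bounds_over_random_counts(self, rng):
        for _ in range(200):
            dd, da, aa = rng.integers(0, 200, size=3)
            if dd + da == 0:
                continue
            e, s = compute_es(int(dd), int(da), int(aa))
            assert 0.0 <= e <= 1.0 and 0.0 <= s <= 1.0


class TestDualColorBurstSearch:
    params = BurstSearchParams(window=500, m_dex=10, m_aex=10, min_size=30)

    def test_too_few_photons_yield_no_bursts(self):
        t, lab = [0, 10, 20, 30, 40], [DD, DA, AA, DD, AA]
        assert dual_color_burst_search(labeled(t, lab), self.params) == []

    def test_empty_stream_is_empty_list(self):
        assert dual_color_burst_search(labeled([], []), self.params) == []

    def test_single_dense_cluster_is_one_burst_with_all_photons(self):
        t, lab = dense_cluster(1000)
        result = dual_color_burst_search(labeled(t, lab), self.params)
        assert len(result) == 1
        b = result[0]
        assert b.size == 60
        assert (b.n_dd, b.n_da, b.n_aa) == (20, 10, 30)
        assert b.start_tick == t[0] and b.stop_tick == t[-1]
        assert result == brute_force_bursts(labeled(t, lab), self.params)

    def test_two_separated_clusters_are_two_bursts(self):
        t1, lab1 = dense_cluster(1000)
        t2, lab2 = dense_cluster(1000 + 1_000_000)  # 1 s of silence at 1 MHz
        stream = labeled(np.concatenate([t1, t2]), np.concatenate([lab1, lab2]))
        result = dual_color_burst_search(stream, self.params)
        assert len(result) == 2
        assert all((b.n_dd, b.n_da, b.n_aa) == (20, 10, 30) for b in result)
        assert result == brute_force_bursts(stream, self.params)

    def test_single_color_cluster_is_rejected(self):
        # plenty of DEX photons but no AA: the dual-color requirement fails
        t = 1000 + np.arange(60) * 3
        lab = np.full(60, DD)
        assert dual_color_burst_search(labeled(t, lab), self.params) == []

    def test_matches_brute_force_oracle_on_random_streams(self, rng):
        params = BurstSearchParams(window=400, m_dex=5, m_aex=5, min_size=12)
        for _ in range(40):
            stream = random_labeled_stream(rng, int(rng.integers(0, 300)))
            assert dual_color_burst_search(stream, params) == brute_force_bursts(stream, params)

    def test_bursts_are_ordered_and_non_overlapping(self, rng):
        params = BurstSearchParams(window=400, m_dex=5, m_aex=5, min_size=12)
        for _ in range(20):
            stream = random_labeled_stream(rng, 300)
            bursts = dual_color_burst_search(stream, params)
            for a, b in zip(bursts, bursts[1:]):
                assert a.stop_tick < b.start_tick


class TestSelection:
    def table(self):
        bursts = [
            Burst(0, 10, n_dd=30, n_da=70, n_aa=100),
            Burst(20, 30, n_dd=80, n_da=20, n_aa=100),
            Burst(40, 50, n_dd=10, n_da=10, n_aa=0),  # donor-only: S = 1
        ]
        return burst_table(bursts)

    def test_no_filters_is_identity(self):
        t = self.table()
        pd.testing.assert_frame_equal(select_bursts(t, min_size=0), t)

    def test_s_range_removes_donor_only_bursts(self):
        out = select_bursts(self.table(), s_range=(0.25, 0.75))
        assert len(out) == 2
        assert (out["s"] <= 0.75).all()

    def test_min_size_above_all_empties_table(self):
        assert len(select_bursts(self.table(), min_size=10_000)) == 0


class TestESHistogram:
    def test_single_burst_occupies_one_cell(self):
        t = burst_table([Burst(0, 1, 30, 70, 100)])  # E*=0.7, S=0.5
        h = es_histogram(t)
        assert h.counts_2d.sum() == 1
        assert np.count_nonzero(h.counts_2d) == 1

    def test_marginal_consistency_and_burst_conservation(self, rng):
        bursts = [
            Burst(i, i + 1, int(dd), int(da), int(aa))
            for i, (dd, da, aa) in enumerate(rng.integers(1, 100, size=(200, 3)))
        ]
        t = burst_table(bursts)
        h = es_histogram(t)
        assert h.counts_2d.sum() == len(t)
        np.testing.assert_array_equal(h.counts_e, h.counts_2d.sum(axis=1))

    def test_unsorted_edges_rejected(self):
        t = burst_table([Burst(0, 1, 30, 70, 100)])
        with pytest.raises(ValueError):
            es_histogram(t, e_edges=[0.5, 0.2, 1.0])


class TestLossOfFret:
    def test_counts_bursts_below_cutoff(self):
        e = [0.1] + [0.7] * 9
        t = pd.DataFrame({"e_app": e})
        assert loss_of_fret(t) == pytest.approx(10.0)

    def test_all_below_cutoff_gives_100(self):
        assert loss_of_fret(pd.DataFrame({"e_app": [0.1, 0.2, 0.3]})) == 100.0

    def test_burst_exactly_at_cutoff_counts_as_high_fret(self):
        t = pd.DataFrame({"e_app": [0.4, 0.8]})
        assert loss_of_fret(t, cutoff=0.4) == 0.0

    def test_empty_table_raises(self):
        with pytest.raises(UndefinedStatisticError):
            loss_of_fret(pd.DataFrame({"e_app": []}))

    def test_invariant_under_burst_order_permutation(self, rng):
        e = rng.random(500)
        t = pd.DataFrame({"e_app": e})
        shuffled = t.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert loss_of_fret(t) == loss_of_fret(shuffled)


def test_burst_table_tsv_round_trip(tmp_path, rng):
    bursts = [
        Burst(i * 100, i * 100 + 50, int(dd), int(da), int(aa))
        for i, (dd, da, aa) in enumerate(rng.integers(1, 100, size=(20, 3)))
    ]
    t = burst_table(bursts)
    path = tmp_path / "bursts.tsv"
    write_burst_table(t, path, provenance={"seed": 1})
    back = read_burst_table(path)
    pd.testing.assert_frame_equal(back, t)
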