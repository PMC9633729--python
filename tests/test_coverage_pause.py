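"""Tests for coverage profiles and the windowed pause statistic."""

import numpy as np
import pandas as pd
import pytest

from riborescue.coverage_pause import (
    CoverageProfile,
    ReadPositionTable,
    assign_position,
    coverage_profile,
    pause_test,
    scan_pauses,
    window_count,
)
from riborescue.synthetic_data import PauseSpec, SimSpec, generate_positions


def table_of(rows, library_sizes):
    frame = pd.DataFrame(rows, columns=["transcript_id", "start", "end",
                                        "read_id", "weight", "sample"])
    return ReadPositionTable(frame=frame, library_sizes=library_sizes)


class TestAssignPosition:
    @pytest.mark.parametrize("start,end,mode,expected", [
        (100, 130, "five_prime", 100),
        (100, 130, "p_site", 112),
        (100, 105, "p_site", 104),  # offset clipped to the last base
    ])
    def test_modes(self, start, end, mode, expected):
        assert assign_position(start, end, mode) == expected

    def test_vectorized(self):
        out = assign_position(np.array([0, 10]), np.array([30, 15]), "p_site")
        assert list(out) == [12, 14]


class TestCoverageProfile:
    def test_direct_count_and_scale(self):
        rows = [("tx", 5, 35, f"r{i}", 1, "s") for i in range(3)]
        rows.append(("tx", 7, 37, "r3", 1, "s"))
        t = table_of(rows, {"s": 1e6})
        prof = coverage_profile(t, "tx", "s", length=50)
        assert prof.values[5] == pytest.approx(3.0)
        assert prof.values[7] == pytest.approx(1.0)
        assert prof.values.sum() == pytest.approx(4.0)

    def test_weight_and_library_scale_invariance(self):
        rows = [("tx", 5, 35, "r0", 1, "s"), ("tx", 9, 39, "r1", 2, "s")]
        t1 = table_of(rows, {"s": 1e6})
        rows2 = [(tx, s, e, r, w * 2, smp) for tx, s, e, r, w, smp in rows]
        t2 = table_of(rows2, {"s": 2e6})
        p1 = coverage_profile(t1, "tx", "s", 50)
        p2 = coverage_profile(t2, "tx", "s", 50)
        assert np.allclose(p1.values, p2.values)

    def test_absent_transcript_zero_profile(self):
        t = table_of([("tx", 0, 30, "r", 1, "s")], {"s": 1e6})
        with pytest.warns(UserWarning, match="absent"):
            prof = coverage_profile(t, "other", "s", 20)
        assert not prof.values.any()

    def test_conservation_of_assigned_reads(self, rng):
        n = 500
        starts = rng.integers(0, 960, n)
        rows = [("tx", s, s + 30, f"r{i}", 1, "s")
                for i, s in enumerate(starts)]
        t = table_of(rows, {"s": 2e6})
        prof = coverage_profile(t, "tx", "s", 1000)
        assert prof.values.sum() * 2e6 / 1e6 == pytest.approx(n)


class TestWindowCount:
    def test_interval_membership(self):
        rows = [("tx", p, p + 30, f"r{i}", 1, "s")
                for i, p in enumerate([429, 441, 453, 454])]
        t = table_of(rows, {"s": 1e6})
        # 1-based positions 430, 442, 454, 455; window [430, 454]
        assert window_count(t, "tx", "s", 442, halfwidth=12) == 3

    def test_halfwidth_zero_single_nucleotide(self):
        rows = [("tx", 9, 39, "a", 1, "s"), ("tx", 9, 39, "b", 1, "s"),
                ("tx", 10, 40, "c", 1, "s")]
        t = table_of(rows, {"s": 1e6})
        assert window_count(t, "tx", "s", 10, halfwidth=0) == 2

    def test_truncated_window_warns(self):
        t = table_of([("tx", 0, 30, "r", 1, "s")], {"s": 1e6})
        with pytest.warns(UserWarning, match="truncated"):
            assert window_count(t, "tx", "s", 3, halfwidth=12) == 1

    def test_equals_per_position_sum_oracle(self, rng):
        """For unique reads, the window count is the sum of per-nt counts."""
        for trial in range(30):
            n = int(rng.integers(5, 80))
            starts = rng.integers(0, 170, n)
            rows = [("tx", s, s + 30, f"r{i}", 1, "s")
                    for i, s in enumerate(starts)]
            t = table_of(rows, {"s": 1e6})
            center = int(rng.integers(13, 180))
            per_nt = np.bincount(starts, minlength=220)
            lo, hi = center - 13, center + 12  # 0-based slice of the window
            assert window_count(t, "tx", "s", center) == per_nt[lo:hi].sum()


class TestPauseTest:
    def test_worked_example(self):
        counts = {"A": [(10, 1e6), (12, 1e6)], "B": [(30, 1e6), (28, 1e6)]}
        res = pause_test(counts, "A", "B")
        assert res.df == 2
        assert res.t == pytest.approx(18 / np.sqrt(2), rel=1e-6)
        # closed-form two-sided tail of the t distribution at df = 2
        x = 18 / np.sqrt(2)
        p_exact = 1 - x / np.sqrt(2 + x ** 2)
        assert res.p == pytest.approx(p_exact, rel=1e-9)
        assert res.window_width == 25

    def test_identical_groups(self):
        counts = {"A": [(10, 1e6), (10, 1e6)], "B": [(10, 1e6), (10, 1e6)]}
        res = pause_test(counts, "A", "B")
        assert res.t == 0 and res.p == 1.0 and not res.degenerate

    def test_swap_antisymmetry(self):
        counts = {"A": [(10, 1e6), (12, 1e6)], "B": [(30, 1e6), (28, 1e6)]}
        fwd = pause_test(counts, "A", "B")
        rev = pause_test(counts, "B", "A")
        assert fwd.t == pytest.approx(-rev.t)
        assert fwd.p == pytest.approx(rev.p)

    def test_library_normalization(self):
        # equal per-million rates at unequal library sizes: no signal
        counts = {"A": [(10, 1e6), (11, 1e6)], "B": [(20, 2e6), (22, 2e6)]}
        res = pause_test(counts, "A", "B")
        assert abs(res.t) < 1e-9

    def test_degenerate_zero_variance(self):
        counts = {"A": [(10, 1e6), (10, 1e6)], "B": [(30, 1e6), (30, 1e6)]}
        res = pause_test(counts, "A", "B")
        assert res.degenerate and res.p == 0.0

    def test_welch_variant(self):
        counts = {"A": [(10, 1e6), (12, 1e6)], "B": [(30, 1e6), (28, 1e6)]}
        pooled = pause_test(counts, "A", "B")
        welch = pause_test(counts, "A", "B", welch=True)
        # equal group sizes: same t statistic, Satterthwaite df
        assert welch.t == pytest.approx(pooled.t)
        assert welch.df <= pooled.df

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            pause_test({"A": [(10, 1e6)], "B": [(3, 1e6), (4, 1e6)]}, "A", "B")


def profiles_from(values_list, tx="tx"):
    return [CoverageProfile(transcript_id=tx, sample_id=f"s{i}",
                            values=np.asarray(v, float), library_size=1e6)
            for i, v in enumerate(values_list)]


class TestScanPauses:
    def test_identical_conditions_empty(self, rng):
        vals = rng.poisson(5.0, 300).astype(float)
        cands = scan_pauses(profiles_from([vals, vals]),
                            profiles_from([vals, vals]))
        assert cands == []

    def test_infinite_threshold_empty(self, rng):
        a = rng.poisson(5.0, 300).astype(float)
        b = a * 4
        assert scan_pauses(profiles_from([a, a]), profiles_from([b, b]),
                           min_ratio=np.inf) == []

    def test_planted_peak_is_reported(self):
        spec = SimSpec(seed=5, pause=PauseSpec(n_reads=20000))
        table, truth = generate_positions(spec)
        prof = {
            cond: [coverage_profile(table, "synthetic_tx", f"RPF_{cond}_r{r}",
                                    2400)
                   for r in (1, 2)]
            for cond in ("WT", "KO")
        }
        cands = scan_pauses(prof["WT"], prof["KO"])
        assert cands, "no candidates found"
        best = max(cands, key=lambda c: c.ratio)
        assert best.center == 442
        assert best.test.p < 0.05

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            scan_pauses(profiles_from([np.zeros(10), np.zeros(10)]),
                        profiles_from([np.zeros(12), np.zeros(12)]))
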