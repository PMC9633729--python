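"""Tests for normalization, dispersion, the NB Wald test and BH correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_counts, make_sheet
from riborescue.de_core import (
    CountMatrix,
    DispersionModel,
    SampleSheet,
    bh_adjust,
    estimate_dispersion,
    size_factors,
    wald_test,
)
from riborescue.synthetic_data import ClassSpec, SimSpec, generate_counts


def bh_oracle(p):
    """Literal step-up: sort ascending, q_i = min_{j>=i} p_j * m / j."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = float("inf")
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = min(running, 1.0)
    return q


class TestSizeFactors:
    def test_doubled_sample_gets_double_factor(self):
        a = np.array([10, 100, 50, 7], float)
        cm = make_counts(np.column_stack([a, 2 * a]), ["s1", "s2"])
        sf = size_factors(cm)
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)

    def test_identical_samples_unit_factors(self):
        a = np.array([10, 100, 50], float)
        cm = make_counts(np.column_stack([a, a, a]), ["s1", "s2", "s3"])
        assert np.allclose(size_factors(cm), 1.0)

    def test_invariant_to_gene_order(self, rng):
        vals = rng.integers(1, 500, (30, 3))
        cm = make_counts(vals, ["a", "b", "c"])
        perm = rng.permutation(30)
        cm2 = make_counts(vals[perm], ["a", "b", "c"],
                          gene_ids=[f"g{i}" for i in perm])
        assert np.allclose(size_factors(cm), size_factors(cm2))

    def test_scale_equivariance(self, rng):
        vals = rng.integers(1, 500, (50, 3)).astype(float)
        cm = make_counts(vals, ["a", "b", "c"])
        sf = size_factors(cm)
        scaled = vals.copy()
        scaled[:, 1] *= 5.0
        sf2 = size_factors(make_counts(scaled, ["a", "b", "c"]))
        assert sf2["b"] / sf2["a"] == pytest.approx(5 * sf["b"] / sf["a"])

    def test_no_all_positive_gene_errors(self):
        cm = make_counts([[0, 5], [3, 0]], ["a", "b"])
        with pytest.raises(ValueError, match="total-count fallback"):
            size_factors(cm)


class TestDispersion:
    def test_moment_estimator_recovers_truth(self, rng):
        # mu=100, alpha=0.1, 200 replicates per group, 2000 genes
        r = 1 / 0.1
        counts = rng.negative_binomial(r, r / (r + 100.0), size=(2000, 400))
        sheet = make_sheet(replicates=200)
        cm = make_counts(counts, sheet.samples(assay="RNA"))
        cm.size_factors = pd.Series(1.0, index=cm.sample_ids)
        model = estimate_dispersion(cm, sheet, method="moments")
        assert 0.08 <= model.dispersion.mean() <= 0.12

    def test_constant_counts_floored_to_zeroish(self):
        sheet = make_sheet(replicates=3)
        cm = make_counts(np.full((5, 6), 50), sheet.samples(assay="RNA"))
        model = estimate_dispersion(cm, sheet, method="moments")
        assert (model.dispersion <= 1e-8).all()

    def test_poisson_limit(self, rng):
        sheet = make_sheet(replicates=100)
        counts = rng.poisson(100.0, size=(500, 200))
        cm = make_counts(counts, sheet.samples(assay="RNA"))
        cm.size_factors = pd.Series(1.0, index=cm.sample_ids)
        model = estimate_dispersion(cm, sheet, method="moments")
        assert model.dispersion.mean() < 0.01

    def test_single_replicate_groups_error(self):
        sheet = make_sheet(replicates=1)
        cm = make_counts([[5, 5]], sheet.samples(assay="RNA"))
        with pytest.raises(ValueError, match=">= 2 replicates"):
            estimate_dispersion(cm, sheet)

    def test_pooled_is_common_value(self, rng):
        sheet = make_sheet(replicates=3)
        cm = make_counts(rng.poisson(100, (50, 6)), sheet.samples(assay="RNA"))
        model = estimate_dispersion(cm, sheet, method="pooled")
        assert model.dispersion.nunique() == 1


class TestBH:
    def test_worked_example(self):
        out = bh_adjust([0.005, 0.01, 0.03, 0.04])
        assert np.allclose(out, [0.02, 0.02, 0.04, 0.04])

    def test_single_and_tied_values(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60))
    @settings(derandomize=True, max_examples=200)
    def test_matches_step_up_oracle(self, p):
        out = bh_adjust(p)
        assert np.allclose(out, bh_oracle(p))
        assert (out >= np.asarray(p) - 1e-12).all()
        assert (out <= 1.0).all()


class TestWaldTest:
    def _null_pair(self, rng, n_genes=300, replicates=3):
        sheet = make_sheet(replicates=replicates)
        mu = rng.uniform(50, 500, n_genes)
        counts = rng.poisson(np.repeat(mu[:, None], 2 * replicates, axis=1))
        cm = make_counts(counts, sheet.samples(assay="RNA"))
        return cm, sheet

    def test_identical_groups_are_ns(self):
        sheet = make_sheet(replicates=2)
        vals = np.array([[100, 110, 100, 110], [5, 7, 5, 7], [30, 20, 30, 20]])
        cm = make_counts(vals, sheet.samples(assay="RNA"))
        de = wald_test(cm, sheet, "WT", "KO")
        assert np.allclose(de["lfc"], 0)
        assert (de["direction"] == "ns").all()

    def test_contrast_swap_antisymmetry(self, rng):
        cm, sheet = self._null_pair(rng)
        fwd = wald_test(cm, sheet, "WT", "KO")
        rev = wald_test(cm, sheet, "KO", "WT")
        assert np.allclose(fwd["lfc"], -rev["lfc"])
        assert np.allclose(fwd["wald"], -rev["wald"])
        assert np.allclose(fwd["p"], rev["p"])

    def test_p_is_two_sided_normal_tail(self, rng):
        from scipy.stats import norm

        cm, sheet = self._null_pair(rng)
        de = wald_test(cm, sheet, "WT", "KO")
        assert np.allclose(de["p"], 2 * norm.sf(np.abs(de["wald"])))
        assert (de["padj"] >= de["p"] - 1e-12).all()

    def test_direction_thresholds(self, rng):
        cm, sheet = self._null_pair(rng)
        de = wald_test(cm, sheet, "WT", "KO")
        up = (de["padj"] < 0.05) & (de["lfc"] >= 1.0)
        down = (de["padj"] < 0.05) & (de["lfc"] <= -1.0)
        assert ((de["direction"] == "up") == up).all()
        assert ((de["direction"] == "down") == down).all()

    def test_unknown_condition_errors(self, rng):
        cm, sheet = self._null_pair(rng)
        with pytest.raises(ValueError, match="unknown condition"):
            wald_test(cm, sheet, "WT", "XX")

    def test_all_zero_genes_dropped(self):
        sheet = make_sheet(replicates=2)
        vals = np.array([[50, 60, 55, 40], [0, 0, 0, 0], [9, 8, 7, 9]])
        cm = make_counts(vals, sheet.samples(assay="RNA"))
        de = wald_test(cm, sheet, "WT", "KO")
        assert list(de.index) == ["g0", "g2"]

    def test_lfc_recovery_of_planted_effects(self):
        classes = (ClassSpec("null", 0.5),
                   ClassSpec("nonrescued_responder", 0.5, lfc_rna=2.0,
                             lfc_rpf=2.0))
        spec = SimSpec(seed=21, n_genes=2000, replicates=2,
                       library_size=1e6, classes=classes)
        rna, _, sheet, truth = generate_counts(spec)
        de = wald_test(rna, sheet, "WT", "KO")
        hit = truth["class"] == "nonrescued_responder"
        err = de.loc[hit.index[hit], "lfc"] - truth.loc[hit, "lfc_rna_ko"]
        assert abs(np.median(err)) <= 0.2


def test_sample_sheet_validation():
    df = pd.DataFrame({
        "sample_id": ["a", "b"], "condition": ["WT", "WT"],
        "assay": ["RNA", "RNA"], "replicate": [1, 1],
    })
    with pytest.raises(ValueError, match="unique"):
        SampleSheet(df)
    with pytest.raises(ValueError, match="condition"):
        SampleSheet(df.assign(condition=["WT", "BAD"], replicate=[1, 2]))


def test_count_matrix_rejects_negative_and_bad_factors():
    with pytest.raises(ValueError, match="negative"):
        make_counts([[-1, 2]], ["a", "b"])
    cm = make_counts([[1, 2]], ["a", "b"])
    cm.size_factors = pd.Series([2.0, 2.0], index=cm.sample_ids)
    with pytest.raises(ValueError, match="geometric mean"):
        cm._check_size_factors()
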