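"""Reconstruction metrics: signatures, regulation calls, coverage,
Wilcoxon shift tests and Fisher enrichment."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from conftest import make_expression
from coretrn.metrics import (
    CellTypeSignature,
    classify_regulation,
    category_shift_test,
    coverage_fractions,
    define_specific_genes,
    enrichment_test,
    paired_target_shift_test,
)


def two_conditions(values_a, values_b):
    a = make_expression(values_a, {"T": 3})
    b = make_expression(values_b, {"M": 3})
    return a, b


class TestDefineSpecificGenes:
    def test_identical_matrices_give_empty_sets(self):
        vals = np.full((4, 3), 100.0)
        a, b = two_conditions(vals, vals)
        sig = define_specific_genes(a, b)
        assert not sig.target_specific_genes and not sig.source_specific_genes

    def test_threshold_enumeration(self):
        base = np.array([400.0, 401.0, 399.0])
        rows = [base * 4, base * 4.01, base, base * 1.01, base / 4, base / 3.99]
        a = make_expression(np.array(rows), {"T": 3})
        b = make_expression(np.tile(base, (6, 1)), {"M": 3})
        sig = define_specific_genes(a, b)
        assert sig.target_specific_genes == {"probe1", "probe2"}
        assert sig.source_specific_genes == {"probe5", "probe6"}

    def test_unreachable_threshold(self):
        rng = np.random.default_rng(1)
        a = make_expression(rng.uniform(50, 500, (5, 3)), {"T": 3})
        b = make_expression(rng.uniform(50, 500, (5, 3)), {"M": 3})
        sig = define_specific_genes(a, b, fold=np.inf)
        assert not sig.target_specific_genes and not sig.source_specific_genes

    def test_probe_mismatch_rejected(self):
        a = make_expression(np.ones((3, 3)), {"T": 3})
        b = make_expression(np.ones((4, 3)), {"M": 3})
        with pytest.raises(ValueError):
            define_specific_genes(a, b)

    def test_disjointness_enforced(self):
        with pytest.raises(ValueError):
            CellTypeSignature({"g1"}, {"g1"})


class TestClassifyRegulation:
    def test_identity_all_nc(self):
        vals = np.full((5, 3), 80.0)
        test, mock = two_conditions(vals, vals)
        calls = classify_regulation(test, mock)
        assert (calls["category"] == "NC").all()

    def test_strong_fold_with_significance_is_up(self):
        test = make_expression([[800.0, 810.0, 790.0]], {"T": 3})
        mock = make_expression([[100.0, 101.0, 99.0]], {"M": 3})
        calls = classify_regulation(test, mock)
        assert calls["category"].iloc[0] == "Up"

    def test_fold_without_significance_is_nc(self):
        test = make_expression([[800.0, 100.0, 50.0]], {"T": 3})
        mock = make_expression([[100.0, 101.0, 99.0]], {"M": 3})
        calls = classify_regulation(test, mock)
        assert calls["p_vs_mock"].iloc[0] > 0.05
        assert calls["category"].iloc[0] == "NC"

    def test_partition_property(self, rng):
        test = make_expression(rng.uniform(10, 1000, (50, 3)), {"T": 3})
        mock = make_expression(rng.uniform(10, 1000, (50, 3)), {"M": 3})
        calls = classify_regulation(test, mock)
        assert calls["category"].isin(["Up", "Down", "NC"]).all()
        assert len(calls) == 50


class TestCoverageFractions:
    def _calls(self, categories):
        return pd.DataFrame(
            {"category": categories},
            index=[f"g{i}" for i in range(len(categories))],
        )

    def test_no_up_calls_zero_percent(self):
        calls = self._calls(["NC"] * 10)
        sig = CellTypeSignature({f"g{i}" for i in range(10)}, {"other"})
        induced, _ = coverage_fractions(calls, sig)
        assert induced == 0.0

    def test_counting(self):
        calls = self._calls(["Up"] * 4 + ["NC"] * 6)
        sig = CellTypeSignature({f"g{i}" for i in range(10)}, {"other"})
        induced, _ = coverage_fractions(calls, sig)
        assert induced == pytest.approx(40.0)

    def test_saturation(self):
        calls = self._calls(["Up"] * 5)
        sig = CellTypeSignature({f"g{i}" for i in range(5)}, {"other"})
        induced, _ = coverage_fractions(calls, sig)
        assert induced == pytest.approx(100.0)

    def test_monotone_in_up_set(self):
        sig = CellTypeSignature({f"g{i}" for i in range(10)}, {"other"})
        base = ["Up"] * 3 + ["NC"] * 7
        more = ["Up"] * 4 + ["NC"] * 6
        assert coverage_fractions(self._calls(more), sig)[0] >= coverage_fractions(self._calls(base), sig)[0]

    def test_empty_signature_rejected(self):
        with pytest.raises(ValueError):
            coverage_fractions(self._calls(["Up"]), CellTypeSignature(set(), {"x"}))


class TestCategoryShiftTest:
    def _calls_and_ref(self, up_vals, nc_vals, down_vals=()):
        cats = ["Up"] * len(up_vals) + ["NC"] * len(nc_vals) + ["Down"] * len(down_vals)
        idx = [f"g{i}" for i in range(len(cats))]
        calls = pd.DataFrame({"category": cats}, index=idx)
        ref = pd.Series(list(up_vals) + list(nc_vals) + list(down_vals), index=idx)
        return calls, ref

    def test_complete_separation_tiny_p(self):
        up = np.arange(100, 120, dtype=float)
        nc = np.arange(0, 20, dtype=float)
        calls, ref = self._calls_and_ref(up, nc)
        p = category_shift_test(calls, ref)[("Up", "NC")]
        assert p < 1e-6

    def test_identical_samples_p_near_one(self):
        # same multiset in both categories: tied comparison, no evidence of
        # a shift (continuity correction keeps p marginally below 1)
        vals = np.arange(10, dtype=float)
        calls, ref = self._calls_and_ref(vals, vals + 0)
        p = category_shift_test(calls, ref)[("Up", "NC")]
        assert p > 0.9

    def test_empty_category_skipped_with_warning(self):
        calls, ref = self._calls_and_ref([1.0, 2.0], [3.0, 4.0])
        with pytest.warns(UserWarning):
            res = category_shift_test(calls, ref)
        assert ("Up", "Down") not in res

    def test_null_calibration(self):
        """Type-I error of the rank-sum comparison near nominal under the
        null (both categories drawn from one distribution)."""
        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            calls, ref = self._calls_and_ref(rng.normal(size=20), rng.normal(size=20))
            hits += category_shift_test(calls, ref)[("Up", "NC")] < 0.05
        assert 0.03 <= hits / n_rep <= 0.07


class TestPairedTargetShiftTest:
    def test_no_shift_p_one(self):
        probes = {f"g{i}" for i in range(10)}
        fc = pd.Series(np.arange(10.0), index=sorted(probes))
        assert paired_target_shift_test(fc, fc, probes) == pytest.approx(1.0)

    def test_uniform_positive_shift(self):
        probes = [f"g{i}" for i in range(20)]
        single = pd.Series(np.random.default_rng(0).normal(size=20), index=probes)
        multi = single + 1.0
        assert paired_target_shift_test(single, multi, set(probes)) < 1e-4

    def test_too_few_pairs_rejected(self):
        probes = [f"g{i}" for i in range(5)]
        fc = pd.Series(np.arange(5.0), index=probes)
        with pytest.raises(ValueError):
            paired_target_shift_test(fc, fc + 1, set(probes))

    def test_power_frozen_from_reference_run(self):
        """Empirical power at shift 0.5*sd, n=100 pairs, frozen from the
        first seeded run (1000 reps)."""
        rng = np.random.default_rng(99)
        probes = [f"g{i}" for i in range(100)]
        hits = 0
        for _ in range(1000):
            base = rng.normal(0, 1, 100)
            single = pd.Series(base, index=probes)
            multi = pd.Series(base + rng.normal(0.5, 1.0, 100), index=probes)
            hits += paired_target_shift_test(single, multi, set(probes)) < 0.05
        assert hits / 1000 == pytest.approx(0.999, abs=1e-12)


def fisher_two_sided_oracle(a, b, c, d):
    """Brute-force two-sided Fisher p: exact integer enumeration of all
    tables with the observed margins, summing the probability of tables no
    more probable than the observed one."""
    N, K, n = a + b + c + d, a + b, a + c
    total = comb(N, n)
    num_obs = comb(K, a) * comb(N - K, n - a)
    acc = 0
    for x in range(max(0, K + n - N), min(K, n) + 1):
        num_x = comb(K, x) * comb(N - K, n - x)
        if num_x <= num_obs:
            acc += num_x
    return acc / total


class TestEnrichmentTest:
    def test_study_equals_universe_all_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        annotation = {"term": [f"g{i}" for i in range(8)]}
        out = enrichment_test(universe, universe, annotation)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_against_enumeration_oracle(self):
        # the (8,2,2,8) table and neighbours, margins fixed
        universe = {f"g{i}" for i in range(20)}
        term = [f"g{i}" for i in range(10)]
        study = {f"g{i}" for i in range(8)} | {"g15", "g16"}
        out = enrichment_test(study, universe, {"term": term})
        assert out.loc["term", "study_in"] == 8
        expected = fisher_two_sided_oracle(8, 2, 2, 8)
        assert out.loc["term", "p_value"] == pytest.approx(expected, abs=1e-12)

    def test_zero_overlap_odds_ratio_zero(self):
        universe = {f"g{i}" for i in range(20)}
        out = enrichment_test({"g0", "g1"}, universe, {"term": ["g10", "g11", "g12"]})
        assert out["odds_ratio"].iloc[0] == 0.0

    def test_study_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test({"zzz"}, {"g1"}, {"t": ["g1"]})

    def test_exhaustive_small_margin_agreement(self):
        """scipy-backed p equals exact enumeration on every table with all
        cells <= 5."""
        from scipy.stats import fisher_exact

        for a, b, c, d in itertools.product(range(6), repeat=4):
            p_impl = fisher_exact([[a, b], [c, d]])[1]
            assert p_impl == pytest.approx(fisher_two_sided_oracle(a, b, c, d), abs=1e-10)
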