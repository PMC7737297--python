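import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omiconverge._stats import rank_sum_test
from omiconverge.data_model import CohortAnnotation, OmicsMatrix, ValidationError
from omiconverge.perturbation import (
    binarize_mutations,
    buffering_test,
    cis_correlations,
    compare_grade_groups,
    perturbation_scores,
    rank_top_proteins,
)


def _matrix(values, layer="cna", genes=None, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return OmicsMatrix(layer, pd.DataFrame(values, index=genes, columns=samples))


class TestBinarize:
    def test_definition(self):
        m = _matrix([[0, 2], [0.4, 0]], layer="mutation")
        out = binarize_mutations(m)
        np.testing.assert_array_equal(out.values, [[0, 1], [1, 0]])

    def test_all_zero_and_idempotent(self):
        m = _matrix(np.zeros((3, 2)), layer="mutation")
        assert binarize_mutations(m).values.sum() == 0
        m2 = _matrix([[0, 3], [1, 0]], layer="mutation")
        once = binarize_mutations(m2)
        np.testing.assert_array_equal(binarize_mutations(once).values, once.values)


class TestScores:
    def test_worked_example_cna(self):
        m = _matrix([[0.6], [-0.3], [1.2]], layer="cna")
        out = perturbation_scores(m, threshold=0.5)
        assert out.loc[0, "de_count"] == 2
        assert out.loc[0, "de_sum"] == pytest.approx(2.1)

    def test_same_values_mrna_threshold_one(self):
        m = _matrix([[0.6], [-0.3], [1.2]], layer="mrna")
        out = perturbation_scores(m)  # default threshold 1 for mRNA
        assert out.loc[0, "de_count"] == 1
        assert out.loc[0, "de_sum"] == pytest.approx(2.1)

    def test_mutation_layer_count_only(self):
        m = _matrix([[0, 1], [2, 0]], layer="mutation")
        out = perturbation_scores(m)
        assert list(out["de_count"]) == [1, 1]
        assert out["de_sum"].isna().all()

    def test_matches_brute_force(self, rng):
        vals = rng.standard_normal((100, 10))
        vals[rng.random((100, 10)) < 0.05] = np.nan
        m = _matrix(vals, layer="protein")
        out = perturbation_scores(m, threshold=0.8)
        for j, s in enumerate(m.samples):
            count = sum(1 for i in range(100)
                        if np.isfinite(vals[i, j]) and abs(vals[i, j]) > 0.8)
            total = sum(abs(vals[i, j]) for i in range(100) if np.isfinite(vals[i, j]))
            row = out[out["sample_id"] == s].iloc[0]
            assert row["de_count"] == count
            assert row["de_sum"] == pytest.approx(total)

    def test_sign_flip_invariance(self, rng):
        vals = rng.standard_normal((20, 5))
        a = perturbation_scores(_matrix(vals, "mrna"))
        b = perturbation_scores(_matrix(-vals, "mrna"))
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_threshold(self):
        with pytest.raises(ValidationError):
            perturbation_scores(_matrix([[1.0]], "cna"), threshold=0.0)

    @settings(max_examples=20, deadline=None)
    @given(st.floats(min_value=0.05, max_value=2.0), st.floats(min_value=0.05, max_value=2.0))
    def test_de_count_monotone_in_threshold(self, t1, t2):
        vals = np.linspace(-2, 2, 33).reshape(-1, 1)
        lo, hi = sorted([t1, t2])
        a = perturbation_scores(_matrix(vals, "cna"), threshold=lo)
        b = perturbation_scores(_matrix(vals, "cna"), threshold=hi)
        assert int(a["de_count"][0]) >= int(b["de_count"][0])

    def test_de_sum_additive_over_gene_partition(self, rng):
        vals = rng.standard_normal((40, 3))
        whole = perturbation_scores(_matrix(vals, "cna"), threshold=0.5)
        top = perturbation_scores(_matrix(vals[:25], "cna"), threshold=0.5)
        bottom = perturbation_scores(_matrix(vals[25:], "cna"), threshold=0.5)
        np.testing.assert_allclose(whole["de_sum"], top["de_sum"] + bottom["de_sum"])


def _annotation(grades):
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(len(grades))],
        "patient_id": [f"p{i}" for i in range(len(grades))],
        "area": ["TA"] * len(grades),
        "area_grade": grades,
        "overall_grade": ["low"] * len(grades),
    })
    return CohortAnnotation(samples=samples)


class TestGradeComparison:
    def test_exact_p_one_sixth(self):
        scores = pd.DataFrame({"sample_id": ["s0", "s1", "s2", "s3"],
                               "layer": "cna", "de_count": [1, 2, 3, 4],
                               "de_sum": np.nan, "threshold": 0.5})
        ann = _annotation(["G1", "G2", "G3", "G4_5"])
        res = compare_grade_groups(scores, ann, method="auto")
        # enumeration over C(4,2)=6 group assignments: only one puts both top
        # ranks in the high pool
        assert res.pvalue == pytest.approx(1 / 6)

    def test_constant_scores_p_one(self):
        scores = pd.DataFrame({"sample_id": [f"s{i}" for i in range(6)],
                               "layer": "cna", "de_count": [5] * 6,
                               "de_sum": np.nan, "threshold": 0.5})
        ann = _annotation(["G1", "G1", "G2", "G3", "G4_5", "G4_5"])
        assert compare_grade_groups(scores, ann, method="auto").pvalue == 1.0

    def test_anti_ordered_direction(self):
        scores = pd.DataFrame({"sample_id": [f"s{i}" for i in range(4)],
                               "layer": "cna", "de_count": [4, 3, 2, 1],
                               "de_sum": np.nan, "threshold": 0.5})
        ann = _annotation(["G1", "G2", "G3", "G4_5"])
        assert compare_grade_groups(scores, ann, method="auto").pvalue >= 0.5

    def test_empty_pool_errors(self):
        scores = pd.DataFrame({"sample_id": ["s0"], "layer": "cna",
                               "de_count": [1], "de_sum": np.nan, "threshold": 0.5})
        with pytest.raises(ValidationError):
            compare_grade_groups(scores, _annotation(["G1"]))


class TestExactRankSum:
    def test_exact_path_matches_enumeration(self, rng):
        """The exact one-sided rank-sum P equals full enumeration (no ties)."""
        for n1, n2 in itertools.product(range(2, 7), range(2, 7)):
            pooled = rng.permutation(np.arange(1, n1 + n2 + 1, dtype=float))
            x, y = pooled[:n1], pooled[n1:]
            res = rank_sum_test(x, y, method="exact")
            u_obs = sum(1 for a in x for b in y if a > b)
            count = 0
            total = 0
            for idx in itertools.combinations(range(n1 + n2), n1):
                hi = pooled[list(idx)]
                lo = np.delete(pooled, list(idx))
                u = sum(1 for a in hi for b in lo if a > b)
                count += u >= u_obs
                total += 1
            assert res.pvalue == pytest.approx(count / total)


class TestCisCorrelations:
    def test_monotone_transform_gives_one(self):
        cna = _matrix([np.arange(6, dtype=float)], "cna")
        mrna = _matrix([2.0 * np.arange(6)], "mrna")
        rho = cis_correlations(cna, mrna)
        assert rho.iloc[0] == pytest.approx(1.0)

    def test_null_mean_near_zero(self, rng):
        cna = _matrix(rng.standard_normal((1000, 10)), "cna")
        mrna = _matrix(rng.standard_normal((1000, 10)), "mrna")
        rho = cis_correlations(cna, mrna)
        assert abs(rho.mean()) < 0.02

    def test_constant_row_missing(self):
        cna = _matrix([np.ones(5), np.arange(5, dtype=float)], "cna")
        mrna = _matrix([np.arange(5, dtype=float), np.arange(5, dtype=float)], "mrna")
        rho = cis_correlations(cna, mrna)
        assert np.isnan(rho.iloc[0]) and rho.iloc[1] == pytest.approx(1.0)

    def test_no_shared_samples_errors(self):
        cna = _matrix([[1.0]], "cna", samples=["a"])
        mrna = _matrix([[1.0]], "mrna", samples=["b"])
        with pytest.raises(ValidationError):
            cis_correlations(cna, mrna)


class TestBufferingTest:
    def test_separated_groups_significant(self, rng):
        rho = pd.Series(np.concatenate([rng.normal(0.2, 0.1, 200),
                                        rng.normal(0.5, 0.1, 200)]))
        flag = pd.Series([True] * 200 + [False] * 200)
        assert buffering_test(rho, flag).pvalue < 1e-6

    def test_swapped_groups_not_significant(self, rng):
        rho = pd.Series(np.concatenate([rng.normal(0.5, 0.1, 100),
                                        rng.normal(0.2, 0.1, 100)]))
        flag = pd.Series([True] * 100 + [False] * 100)
        assert buffering_test(rho, flag).pvalue > 0.5

    def test_null_calibration_uniform(self):
        from scipy import stats

        rng = np.random.default_rng(42)
        pvals = []
        for _ in range(200):
            rho = pd.Series(rng.normal(0.3, 0.1, 120))
            flag = pd.Series(rng.random(120) < 0.4)
            pvals.append(buffering_test(rho, flag).pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_small_group_errors(self):
        with pytest.raises(ValidationError):
            buffering_test(pd.Series([0.1, 0.2, 0.3]), pd.Series([True, False, False]))


class TestTopProteins:
    def test_ordering_and_truncation(self):
        m = _matrix([[3, -3], [2, 2], [-1, 1]], "protein", genes=["a", "b", "c"])
        top = rank_top_proteins(m, 2)
        assert list(top["gene"]) == ["a", "b"]
        full = rank_top_proteins(m, 10)  # truncates with warning
        assert len(full) == 3

    def test_sign_flip_invariance(self, rng):
        vals = rng.standard_normal((30, 6))
        a = rank_top_proteins(_matrix(vals, "protein"), 10)
        b = rank_top_proteins(_matrix(-vals, "protein"), 10)
        pd.testing.assert_frame_equal(a, b)

    def test_matches_naive_sort(self, rng):
        vals = rng.standard_normal((50, 8))
        m = _matrix(vals, "protein")
        top = rank_top_proteins(m, 50)
        naive = sorted(m.genes, key=lambda g: (-np.abs(m.data.loc[g]).mean(), g))
        assert list(top["gene"]) == naive
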