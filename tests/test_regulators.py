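import networkx as nx
import numpy as np
import pandas as pd
import pytest

from omiconverge.data_model import GeneNetwork, OmicsMatrix, ValidationError
from omiconverge.regulators import (
    apply_event_filter,
    cna_event_filter,
    elastic_net_regulators,
    neighbor_correlation_test,
    sign_validation,
    split_neighborhood,
)


def _network(edges):
    g = nx.Graph()
    g.add_edges_from((u, v, {"confidence": c}) for u, v, c in edges)
    return GeneNetwork(graph=g)


def _cna(values, genes, samples=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return OmicsMatrix("cna", pd.DataFrame(values, index=genes, columns=samples))


class TestSplit:
    def test_star_threshold(self):
        net = _network([("t", "l1", 0.25), ("t", "l2", 0.15)])
        cna = _cna(np.ones((3, 4)), ["t", "l1", "l2"])
        split = split_neighborhood(net, "t", cna)
        assert split.group1 == ["l1", "t"]
        assert split.group2 == ["l2"]

    def test_threshold_one_leaves_target_alone(self):
        net = _network([("t", "l1", 0.99)])
        cna = _cna(np.ones((2, 3)), ["t", "l1"])
        split = split_neighborhood(net, "t", cna, conf_threshold=1.0)
        assert split.group1 == ["t"]

    def test_matches_naive_scan(self, rng):
        g = nx.gnp_random_graph(40, 0.15, seed=3)
        for u, v in g.edges:
            g.edges[u, v]["confidence"] = float(rng.random())
        net = GeneNetwork(graph=nx.relabel_nodes(g, {i: f"n{i}" for i in g}))
        measured = [f"n{i}" for i in range(40) if rng.random() < 0.8]
        cna = _cna(rng.standard_normal((len(measured), 5)), measured)
        split = split_neighborhood(net, measured[0], cna, conf_threshold=0.4)
        target = measured[0]
        naive1 = sorted({target} | {
            v for v in net.graph.neighbors(target)
            if net.graph.edges[target, v]["confidence"] > 0.4 and v in set(measured)})
        assert split.group1 == naive1
        assert sorted(set(split.group1) | set(split.group2)) == sorted(
            set(measured) & set(net.graph.nodes))
        assert not set(split.group1) & set(split.group2)

    def test_absent_target_errors(self):
        net = _network([("a", "b", 0.5)])
        cna = _cna(np.ones((2, 2)), ["a", "b"])
        with pytest.raises(ValidationError):
            split_neighborhood(net, "zzz", cna)


class TestEventFilter:
    def test_boundary_four_kept_three_dropped(self):
        vals = np.zeros((2, 10))
        vals[0, :4] = 0.6   # exactly 4 altered samples -> kept
        vals[1, :3] = -0.9  # 3 altered samples -> dropped
        cna = _cna(vals, ["keep", "drop"])
        assert cna_event_filter(["keep", "drop"], cna) == ["keep"]

    def test_magnitude_strictly_greater(self):
        vals = np.full((1, 6), 0.5)  # |0.5| is not > 0.5
        cna = _cna(vals, ["g"])
        assert cna_event_filter(["g"], cna) == []

    def test_matches_counting_oracle(self, rng):
        vals = rng.standard_normal((100, 20))
        genes = [f"g{i}" for i in range(100)]
        cna = _cna(vals, genes)
        got = cna_event_filter(genes, cna, min_samples=3, magnitude=0.8)
        expected = sorted(g for i, g in enumerate(genes)
                          if sum(abs(v) > 0.8 for v in vals[i]) >= 3)
        assert got == expected

    def test_split_and_filter_commute(self, rng):
        g = nx.gnp_random_graph(30, 0.2, seed=5)
        for u, v in g.edges:
            g.edges[u, v]["confidence"] = float(rng.random())
        net = GeneNetwork(graph=nx.relabel_nodes(g, {i: f"n{i}" for i in g}))
        genes = [f"n{i}" for i in range(30)]
        cna = _cna(rng.standard_normal((30, 15)) * 0.6, genes)
        split = apply_event_filter(split_neighborhood(net, "n0", cna), cna)
        kept = set(cna_event_filter(genes, cna))
        assert set(split.group1_filtered) == set(split.group1) & kept
        assert set(split.group2_filtered) == set(split.group2) & kept


class TestNeighborCorrelationTest:
    def _toy_split(self, n1, n2):
        from omiconverge.regulators import NeighborhoodSplit

        g1 = [f"a{i}" for i in range(n1)]
        g2 = [f"b{i}" for i in range(n2)]
        return NeighborhoodSplit(target="a0", group1=g1, group2=g2,
                                 conf_threshold=0.2), g1, g2

    def test_coupled_group_significant(self):
        rng = np.random.default_rng(0)
        split, g1, g2 = self._toy_split(30, 30)
        target_fc = pd.Series(rng.standard_normal(40),
                              index=[f"s{j}" for j in range(40)])
        vals = np.vstack([
            np.vstack([target_fc.to_numpy() + 0.5 * rng.standard_normal(40)
                       for _ in g1]),
            rng.standard_normal((30, 40)),
        ])
        cna = _cna(vals, g1 + g2, samples=list(target_fc.index))
        _, _, res = neighbor_correlation_test(split, cna, target_fc)
        assert res.pvalue < 0.01

    def test_null_uniform(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        pvals = []
        for _ in range(100):
            split, g1, g2 = self._toy_split(15, 15)
            target_fc = pd.Series(rng.standard_normal(25),
                                  index=[f"s{j}" for j in range(25)])
            cna = _cna(rng.standard_normal((30, 25)), g1 + g2,
                       samples=list(target_fc.index))
            _, _, res = neighbor_correlation_test(split, cna, target_fc)
            pvals.append(res.pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_degenerate_group_errors(self):
        split, g1, g2 = self._toy_split(1, 5)
        cna = _cna(np.random.default_rng(2).standard_normal((6, 10)), g1 + g2)
        target_fc = pd.Series(np.random.default_rng(2).standard_normal(10),
                              index=cna.samples)
        with pytest.raises(ValidationError):
            neighbor_correlation_test(split, cna, target_fc)


class TestElasticNet:
    def _planted_problem(self, seed, n=60, n_decoys=20):
        from omiconverge.regulators import NeighborhoodSplit

        rng = np.random.default_rng(seed)
        genes = ["x1", "x2"] + [f"d{i}" for i in range(n_decoys)]
        X = rng.standard_normal((len(genes), n))
        y = 2.0 * X[0] - 1.0 * X[1] + 0.1 * rng.standard_normal(n)
        samples = [f"s{j}" for j in range(n)]
        cna = _cna(X, genes, samples=samples)
        split = NeighborhoodSplit(target="x1", group1=genes, group2=[],
                                  conf_threshold=0.2,
                                  group1_filtered=genes, group2_filtered=[])
        return split, cna, pd.Series(y, index=samples)

    def test_recovers_planted_signs(self):
        successes = 0
        for seed in range(20):
            split, cna, y = self._planted_problem(seed)
            res = elastic_net_regulators(split, cna, y, seed=seed)
            ok = (res.selected.get("x1", 0) > 0) and (res.selected.get("x2", 0) < 0)
            successes += ok
        assert successes >= 18

    def test_pure_noise_near_empty_with_1se(self):
        rng = np.random.default_rng(7)
        split, cna, _ = self._planted_problem(7)
        y = pd.Series(rng.standard_normal(60), index=cna.samples)
        res = elastic_net_regulators(split, cna, y, seed=7, rule="1se")
        assert len(res.selected) <= 2

    def test_deterministic_given_seed(self):
        split, cna, y = self._planted_problem(3)
        a = elastic_net_regulators(split, cna, y, seed=5)
        b = elastic_net_regulators(split, cna, y, seed=5)
        pd.testing.assert_series_equal(a.selected, b.selected)
        assert a.penalty == b.penalty

    def test_duplicate_predictors_share_stable_sign(self):
        from omiconverge.regulators import NeighborhoodSplit

        rng = np.random.default_rng(11)
        x = rng.standard_normal(80)
        X = np.vstack([x, x, rng.standard_normal((5, 80))])
        genes = ["dup1", "dup2", "d0", "d1", "d2", "d3", "d4"]
        samples = [f"s{j}" for j in range(80)]
        cna = _cna(X, genes, samples=samples)
        y = pd.Series(3.0 * x + 0.1 * rng.standard_normal(80), index=samples)
        split = NeighborhoodSplit(target="dup1", group1=genes, group2=[],
                                  conf_threshold=0.2, group1_filtered=genes,
                                  group2_filtered=[])
        res = elastic_net_regulators(split, cna, y, seed=1)
        total = res.selected.get("dup1", 0.0) + res.selected.get("dup2", 0.0)
        assert total > 0

    def test_fold_reduction_on_small_samples(self):
        split, cna, y = self._planted_problem(2, n=8, n_decoys=3)
        res = elastic_net_regulators(split, cna, y, n_folds=10, seed=0)
        assert res.n_folds == 8


class TestSignValidation:
    def test_same_model_cohort_full_agreement(self, default_cohort):
        """Validation on a cohort from the same generative process agrees in sign."""
        from omiconverge._stats import spearman_rows
        from omiconverge.simulate import simulate_cohort
        from omiconverge.survival import zscore_genes

        cohort = default_cohort
        truth = cohort.truth
        cna = cohort.matrices["cna"]
        y = cohort.matrices["mrna"].data.loc[truth.target]
        genes = [g for g, _ in truth.regulators]
        disc_rho = pd.Series(
            spearman_rows(cna.data.loc[genes].to_numpy(),
                          np.tile(y.to_numpy(), (len(genes), 1))), index=genes)
        val_cohort = simulate_cohort(
            truth.config, cohort.network, truth.component, seed=999,
            planted=(truth.target, truth.regulators))
        target_z = zscore_genes(val_cohort.matrices["mrna"]).data.loc[truth.target]
        coef = pd.Series([s for _, s in truth.regulators], index=genes, dtype=float)
        table = sign_validation(coef, disc_rho,
                                {"val": (val_cohort.matrices["cna"], target_z)})
        strong = table[table["reference_rho"].abs() > 0.15]
        assert strong["sign_match"].all() and len(strong) >= 3

    def test_sign_flip_and_missing_gene(self, rng):
        cna = _cna(rng.standard_normal((2, 30)), ["r1", "r2"])
        y = pd.Series(cna.data.loc["r1"] + 0.1 * rng.standard_normal(30),
                      index=cna.samples)
        disc_rho = pd.Series({"r1": 0.8, "absent": 0.5})
        coef = pd.Series({"r1": 1.0, "absent": 1.0})
        table = sign_validation(coef, disc_rho, {"flip": (cna, -y), "ok": (cna, y)})
        flip = table[(table["cohort"] == "flip") & (table["regulator"] == "r1")]
        ok = table[(table["cohort"] == "ok") & (table["regulator"] == "r1")]
        assert not flip["sign_match"].iloc[0] and ok["sign_match"].iloc[0]
        absent = table[table["regulator"] == "absent"]
        assert (~absent["evaluable"]).all()
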