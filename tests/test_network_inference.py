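import numpy as np
import pandas as pd
import pytest

from phyllodyn.network_inference import (CorrelationMatrix,
                                         build_month_networks, fisher_z_p,
                                         network_from_correlations,
                                         sparcc_correlations, sparcc_pseudo_p,
                                         spearman_network, variation_matrix)
from phyllodyn.synth_data import SimConfig, generate_dataset

from conftest import make_table


def iid_counts(D, n, seed, depth=10_000):
    rng = np.random.default_rng(seed)
    ab = np.exp(rng.normal(0, 1.2, (D, 1)) + rng.normal(0, 1.2, (D, n)))
    p = ab / ab.sum(axis=0)
    counts = np.vstack([rng.multinomial(depth, p[:, j]) for j in range(n)]).T
    return pd.DataFrame(counts, index=[f"t{i}" for i in range(D)],
                        columns=[f"s{j}" for j in range(n)])


class TestVariationMatrix:
    def test_zero_diagonal_and_symmetry(self):
        rng = np.random.default_rng(0)
        logf = rng.normal(size=(6, 40))
        t = variation_matrix(logf)
        assert np.allclose(np.diag(t), 0.0)
        assert np.allclose(t, t.T)

    def test_equals_direct_log_ratio_variance(self):
        rng = np.random.default_rng(1)
        logf = rng.normal(size=(4, 50))
        t = variation_matrix(logf)
        direct = np.var(logf[0] - logf[2], ddof=1)
        assert t[0, 2] == pytest.approx(direct)


class TestSparcc:
    def test_null_data_has_no_strong_correlations(self):
        corr = sparcc_correlations(iid_counts(40, 150, seed=0), seed=0)
        off = corr.rho.to_numpy()[np.triu_indices(40, 1)]
        assert (np.abs(off) > 0.3).mean() < 0.01

    def test_planted_pair_recovered(self):
        ids = [f"Otub{i+1:04d}" for i in range(30)]
        pairs = [((ids[0], ids[1]), 0.7)]
        cfg = SimConfig(n_bacteria=30, n_fungi=0, n_oomycetes=0,
                        n_experiments=2, n_ecotypes=4, plants_per_cell=5,
                        sparsity_target=None, seed=1,
                        corr_spec={m: pairs for m in SimConfig().months})
        table, _ = generate_dataset(cfg)
        corr = sparcc_correlations(table, seed=1)
        assert corr.rho.loc[ids[0], ids[1]] == pytest.approx(0.7, abs=0.2)

    def test_deterministic_given_seed(self):
        c1 = sparcc_correlations(iid_counts(10, 40, seed=3), seed=7)
        c2 = sparcc_correlations(iid_counts(10, 40, seed=3), seed=7)
        assert c1.rho.equals(c2.rho)

    def test_compositional_invariance_under_depth_rescaling(self):
        """Same underlying proportions sampled at 4x depth give nearly
        identical estimates (counts carry only relative information)."""
        rng = np.random.default_rng(5)
        D, n = 20, 120
        ab = np.exp(rng.normal(0, 1.2, (D, 1)) + rng.normal(0, 1.2, (D, n)))
        p = ab / ab.sum(axis=0)
        est = []
        for depth in (5_000, 20_000):
            counts = np.vstack([rng.multinomial(depth, p[:, j])
                                for j in range(n)]).T
            df = pd.DataFrame(counts, index=[f"t{i}" for i in range(D)],
                              columns=[f"s{j}" for j in range(n)])
            est.append(sparcc_correlations(df, seed=1).rho.to_numpy())
        diff = np.abs(est[0] - est[1])[np.triu_indices(D, 1)]
        assert diff.max() < 0.15

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            sparcc_correlations(iid_counts(3, 50, seed=0))


class TestPseudoP:
    def test_minimum_attainable_p(self):
        ids = [f"Otub{i+1:04d}" for i in range(20)]
        pairs = [((ids[0], ids[1]), 0.8)]
        cfg = SimConfig(n_bacteria=20, n_fungi=0, n_oomycetes=0,
                        n_experiments=2, n_ecotypes=4, plants_per_cell=5,
                        sparsity_target=None, seed=2,
                        corr_spec={m: pairs for m in SimConfig().months})
        table, _ = generate_dataset(cfg)
        corr = sparcc_correlations(table, seed=2)
        p = sparcc_pseudo_p(table, corr, n_boot=49, seed=2)
        assert p.loc[ids[0], ids[1]] == pytest.approx(1 / 50)

    def test_null_pair_p_large(self):
        counts = iid_counts(10, 80, seed=4)
        corr = sparcc_correlations(counts, seed=4)
        # weakest observed pair should not look significant
        p = sparcc_pseudo_p(counts, corr, n_boot=49, seed=4)
        i, j = np.unravel_index(np.argmin(np.abs(corr.rho.to_numpy()
                                                 - np.eye(10) * 2)),
                                (10, 10))
        assert p.iloc[i, j] > 0.2


class TestSpearman:
    def test_monotone_pair_is_one(self):
        # pre-transformed abundances passed straight through
        X = pd.DataFrame({
            "a": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6],
            "b": [0.2, 0.4, 0.8, 1.6, 3.2, 6.4],
            "c": [0.5, 0.3, 0.6, 0.1, 0.2, 0.4],
            "d": [0.9, 0.1, 0.4, 0.7, 0.2, 0.8],
        }).T
        corr = spearman_network(X, quantile=0.25, alpha=1.0)
        assert corr.rho.loc["a", "b"] == pytest.approx(1.0)

    def test_candidate_count_from_quantile(self):
        rng = np.random.default_rng(0)
        t = make_table({f"o{i}": rng.integers(1, 100, 30).tolist()
                        for i in range(16)})  # 120 pairs
        corr = spearman_network(t, quantile=0.05, alpha=1.0)
        # 6 top + 6 bottom candidates (distinct pairs)
        assert len(corr.candidates) == 12

    def test_fisher_z_formula(self):
        # z = atanh(0.6)*sqrt(27) = 3.6019 -> two-sided p = 3.161e-4
        assert fisher_z_p(0.6, 30) == pytest.approx(3.1614e-4, rel=1e-3)

    def test_constant_taxon_skipped(self):
        t = make_table({
            "const": [5, 5, 5, 5, 5],
            "a": [1, 2, 3, 4, 5],
            "b": [5, 4, 3, 2, 1],
        })
        corr = spearman_network(t, quantile=0.5, alpha=1.0)
        assert not any("const" in pair for pair in corr.candidates)


class TestGraphAssembly:
    def _corr(self, p_ab):
        ids = ["a", "b", "c"]
        rho = pd.DataFrame(np.eye(3), index=ids, columns=ids)
        rho.loc["a", "b"] = rho.loc["b", "a"] = 0.9
        p = pd.DataFrame(1.0, index=ids, columns=ids)
        p.loc["a", "b"] = p.loc["b", "a"] = p_ab
        return CorrelationMatrix(rho=rho, method="sparcc", p=p)

    def test_sparcc_gate_is_strict(self):
        net = network_from_correlations(self._corr(0.001), "Nov", alpha=0.001)
        assert net.n_edges == 0
        net = network_from_correlations(self._corr(0.0005), "Nov", alpha=0.001)
        assert net.edges == {frozenset(("a", "b"))}

    def test_isolated_nodes_excluded(self):
        net = network_from_correlations(self._corr(0.0005), "Nov", alpha=0.001)
        assert net.nodes == {"a", "b"}

    def test_edge_set_shrinks_with_alpha(self):
        rng = np.random.default_rng(1)
        ids = [f"t{i}" for i in range(8)]
        rho = pd.DataFrame(np.eye(8), index=ids, columns=ids)
        pm = pd.DataFrame(rng.uniform(0, 0.1, (8, 8)), index=ids, columns=ids)
        pm = (pm + pm.T) / 2
        corr = CorrelationMatrix(rho=rho, method="sparcc", p=pm)
        e_loose = network_from_correlations(corr, "m", alpha=0.05).edges
        e_tight = network_from_correlations(corr, "m", alpha=0.01).edges
        assert e_tight <= e_loose


class TestMonthNetworks:
    @pytest.fixture(scope="class")
    def small_study(self):
        cfg = SimConfig(n_bacteria=25, n_fungi=10, n_oomycetes=5,
                        n_experiments=2, n_ecotypes=3, plants_per_cell=2,
                        sparsity_target=0.3, seed=6)
        return generate_dataset(cfg)[0]

    def test_one_network_per_month(self, small_study):
        series = build_month_networks(small_study, method="spearman",
                                      alpha=0.05)
        assert len(series) == 5
        assert series.months == list(small_study.month_order)

    def test_spearman_identical_data_identical_networks(self, small_study):
        nov = small_study.subset_samples(small_study.samples_of_month("Nov"))
        # feed the same samples relabelled as two months
        dup = nov.counts.copy()
        dup.columns = [f"{c}.x" for c in dup.columns]
        meta = nov.samples.copy()
        meta.index = dup.columns
        meta["month"] = "Dec"
        import pandas as pd
        from phyllodyn.otu_io import OtuTable
        merged = OtuTable(
            counts=pd.concat([nov.counts, dup], axis=1),
            taxonomy=nov.taxonomy,
            samples=pd.concat([nov.samples, meta]),
            month_order=("Nov", "Dec"),
        )
        series = build_month_networks(merged, method="spearman", alpha=0.05)
        e0 = {frozenset(e) for e in series[0].graph.edges}
        e1 = {frozenset((a.replace(".x", ""), b.replace(".x", "")))
              for a, b in series[1].graph.edges}
        assert e0 == e1

    def test_sparcc_series_reproducible(self, small_study):
        kw = dict(method="sparcc", seed=3, n_boot=20, alpha=0.1, n_inner=5)
        s1 = build_month_networks(small_study, **kw)
        s2 = build_month_networks(small_study, **kw)
        for a, b in zip(s1, s2):
            assert a.edges == b.edges
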