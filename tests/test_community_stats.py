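import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from phyllodyn.community_stats import (aggregate_by_rank, beta_dispersion,
                                       between_month_distances, bray_curtis,
                                       dunn_test, permanova, shannon_index)
from phyllodyn.otu_io import RANKS, to_relative

from conftest import make_table


class TestShannon:
    def test_uniform_counts(self):
        assert shannon_index([10, 10, 10, 10]) == pytest.approx(np.log(4))

    def test_single_taxon_is_zero(self):
        assert shannon_index([42]) == 0.0

    def test_direct_formula(self):
        # p = 1/6, 2/6, 3/6 -> H = 1.011404
        assert shannon_index([1, 2, 3]) == pytest.approx(1.011404, abs=1e-5)

    def test_invariant_to_rescaling(self):
        assert shannon_index([1, 2, 3]) == pytest.approx(
            shannon_index([10, 20, 30]))

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            shannon_index([0, 0])


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        t = make_table({"a": [3, 3], "b": [1, 1]})
        dm = bray_curtis(to_relative(t))
        assert dm["s1", "s2"] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        t = make_table({"a": [5, 0], "b": [0, 7]})
        dm = bray_curtis(to_relative(t))
        assert dm["s1", "s2"] == pytest.approx(1.0)

    def test_formula_evaluation(self):
        # x=(1,0,3), y=(0,2,1): BC = 1 - 2*1/7 = 5/7 on raw profiles;
        # evaluated on closed profiles via an explicitly built table
        from phyllodyn.otu_io import RelAbundTable
        vals = pd.DataFrame({"s1": [1, 0, 3], "s2": [0, 2, 1]},
                            index=["a", "b", "c"], dtype=float)
        meta = pd.DataFrame({"experiment": ["E1"] * 2, "month": ["Nov"] * 2},
                            index=["s1", "s2"])
        rel = RelAbundTable(values=vals, samples=meta)
        dm = bray_curtis(rel)
        assert dm["s1", "s2"] == pytest.approx(5 / 7)

    def test_bounded_and_symmetric(self, random_table):
        dm = bray_curtis(to_relative(random_table))
        assert (dm.data >= 0).all() and (dm.data <= 1 + 1e-12).all()
        assert np.allclose(dm.data, dm.data.T)


def _euclid_dm(X, ids):
    return DistanceMatrix(squareform(pdist(X)), ids=ids)


class TestPermanova:
    def test_perfect_separation_r2_one(self):
        # two groups, zero within-group variance
        X = np.array([[0.0, 0.0]] * 3 + [[1.0, 1.0]] * 3)
        ids = [f"s{i}" for i in range(6)]
        fac = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3}, index=ids)
        res = permanova(_euclid_dm(X, ids), fac, ["g"], n_perm=99, seed=0)
        assert res.r2("g") == pytest.approx(1.0)

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(0)
        X = rng.random((12, 4))
        ids = [f"s{i}" for i in range(12)]
        fac = pd.DataFrame({"g": [f"g{i%3}" for i in range(12)]}, index=ids)
        dm = _euclid_dm(X, ids)
        res1 = permanova(dm, fac, ["g"], n_perm=49, seed=1)
        perm = rng.permutation(12)
        dm2 = DistanceMatrix(dm.data[np.ix_(perm, perm)],
                             ids=[ids[i] for i in perm])
        res2 = permanova(dm2, fac, ["g"], n_perm=49, seed=1)
        assert res1.r2("g") == pytest.approx(res2.r2("g"))

    def test_single_level_factor_skipped(self):
        rng = np.random.default_rng(1)
        X = rng.random((8, 3))
        ids = [f"s{i}" for i in range(8)]
        fac = pd.DataFrame({"g": ["a"] * 8, "h": ["x", "y"] * 4}, index=ids)
        res = permanova(_euclid_dm(X, ids), fac, ["g", "h"], n_perm=49, seed=0)
        assert "g" not in res.table.index
        assert "h" in res.table.index

    def test_matches_vegan_adonis2(self):
        """Sequential SS, R2 and F must agree with vegan's adonis2."""
        rng = np.random.default_rng(42)
        n = 18
        X = rng.random((n, 5))
        ids = [f"s{i}" for i in range(n)]
        fac = pd.DataFrame({
            "a": [f"a{i % 3}" for i in range(n)],
            "b": [f"b{(i // 3) % 2}" for i in range(n)],
        }, index=ids)
        D = squareform(pdist(X, "braycurtis"))
        res = permanova(DistanceMatrix(D, ids=ids), fac, ["a", "b"],
                        n_perm=9, seed=0)
        script = """
suppressMessages(library(vegan))
D <- as.dist(matrix(scan('{d}', quiet=TRUE), nrow={n}, byrow=TRUE))
fac <- read.csv('{f}', row.names=1)
a <- adonis2(D ~ a + b, data=fac, permutations=9, by='terms')
cat(a$R2[1], a$R2[2], a$F[1], a$F[2])
"""
        import tempfile, os
        with tempfile.TemporaryDirectory() as td:
            dpath = os.path.join(td, "D.txt")
            fpath = os.path.join(td, "fac.csv")
            np.savetxt(dpath, D)
            fac.to_csv(fpath)
            out = subprocess.run(
                ["Rscript", "-e", script.format(d=dpath, n=n, f=fpath)],
                capture_output=True, text=True, check=True)
        r2a, r2b, fa, fb = map(float, out.stdout.split())
        assert res.r2("a") == pytest.approx(r2a, rel=1e-5)
        assert res.r2("b") == pytest.approx(r2b, rel=1e-5)
        assert res.table.loc["a", "F"] == pytest.approx(fa, rel=1e-5)
        assert res.table.loc["b", "F"] == pytest.approx(fb, rel=1e-5)


class TestBetaDispersion:
    def test_identical_members_zero(self):
        X = np.array([[1.0, 2.0]] * 4)
        ids = [f"s{i}" for i in range(4)]
        res = beta_dispersion(_euclid_dm(X, ids), ["g"] * 4)
        assert np.allclose(res.distances, 0.0)

    def test_euclidean_equals_distance_to_mean(self):
        rng = np.random.default_rng(5)
        X = rng.random((10, 3))
        ids = [f"s{i}" for i in range(10)]
        groups = ["a"] * 5 + ["b"] * 5
        res = beta_dispersion(_euclid_dm(X, ids), groups)
        for g in ("a", "b"):
            mask = np.array(groups) == g
            direct = np.linalg.norm(X[mask] - X[mask].mean(axis=0), axis=1)
            assert np.allclose(res.distances.to_numpy()[mask], direct,
                               atol=1e-8)

    def test_noisier_group_has_larger_dispersion(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = np.vstack([rng.normal(0, 1, (8, 4)),
                           rng.normal(0, 2, (8, 4))])
            ids = [f"s{i}" for i in range(16)]
            groups = ["quiet"] * 8 + ["noisy"] * 8
            med = beta_dispersion(_euclid_dm(X, ids), groups).median_by_group()
            hits += med["noisy"] > med["quiet"]
        assert hits >= 9

    def test_negative_eigenvalue_correction_matches_vegan_geometry(self):
        """Bray-Curtis matrices are non-Euclidean; distances must stay
        real and non-negative."""
        rng = np.random.default_rng(8)
        t = make_table({f"o{i}": rng.integers(0, 20, 12).tolist()
                        for i in range(6)})
        dm = bray_curtis(to_relative(t))
        res = beta_dispersion(dm, ["g1"] * 6 + ["g2"] * 6)
        assert (res.distances >= 0).all()
        assert np.isfinite(res.distances).all()


class TestBetweenMonthDistances:
    def test_cross_pair_count(self):
        t = make_table({"a": [1, 2, 3, 4], "b": [4, 3, 2, 1]},
                       months=["Nov", "Nov", "Dec", "Dec"])
        dm = bray_curtis(to_relative(t))
        out = between_month_distances(dm, t.samples["month"].astype(str),
                                      t.month_order)
        assert len(out[("Nov", "Dec")]) == 4

    def test_identical_composition_near_zero(self):
        t = make_table({"a": [5, 5, 5, 5], "b": [5, 5, 5, 5]},
                       months=["Nov", "Nov", "Dec", "Dec"])
        dm = bray_curtis(to_relative(t))
        out = between_month_distances(dm, t.samples["month"].astype(str),
                                      t.month_order)
        assert np.allclose(out[("Nov", "Dec")], 0.0)

    def test_matches_double_loop(self, random_table):
        dm = bray_curtis(to_relative(random_table))
        months = random_table.samples["month"].astype(str)
        out = between_month_distances(dm, months, random_table.month_order)
        for (m1, m2), dists in out.items():
            expected = sorted(
                dm[s1, s2]
                for s1 in dm.ids if months[s1] == m1
                for s2 in dm.ids if months[s2] == m2
            )
            assert np.allclose(sorted(dists), expected)


class TestDunn:
    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=30)
        res = dunn_test(vals, np.repeat(["a", "b", "c"], 10))
        assert not res.comparisons["significant"].any()
        # all groups share a letter
        assert len(set(res.letters.values())) == 1

    def test_hand_computed_z(self):
        # A=(1,2), B=(3,4): mean ranks 1.5 vs 3.5, no ties,
        # se = sqrt(N(N+1)/12 * (1/2+1/2)) = sqrt(5/3)
        res = dunn_test([1, 2, 3, 4], ["A", "A", "B", "B"])
        z = res.comparisons["z"].iloc[0]
        assert abs(z) == pytest.approx(2.0 / np.sqrt(5 / 3), abs=1e-10)

    def test_tie_correction(self):
        # all values tied -> z = 0, p = 1... variance collapses to 0
        res = dunn_test([1, 1, 1, 1], ["A", "A", "B", "B"])
        assert (res.comparisons["p"] == 1.0).all()

    def test_separation_ordering_and_letters(self):
        vals = [1, 2, 3, 101, 102, 103, 201, 202, 203]
        groups = ["g1"] * 3 + ["g2"] * 3 + ["g3"] * 3
        res = dunn_test(vals, groups)
        comp = res.comparisons.set_index(["group1", "group2"])
        z13 = abs(comp.loc[("g1", "g3"), "z"])
        z12 = abs(comp.loc[("g1", "g2"), "z"])
        assert z13 > z12
        # extreme groups differ, middle shares with both
        assert set(res.letters["g1"]) & set(res.letters["g3"]) == set()
        assert set(res.letters["g2"]) & set(res.letters["g1"])
        assert set(res.letters["g2"]) & set(res.letters["g3"])


class TestAggregateByRank:
    def _tax(self, orders, n):
        import pandas as pd
        tax = pd.DataFrame({r: ["x"] * n for r in RANKS},
                           index=[f"o{i}" for i in range(n)])
        tax["kingdom"] = "bacteria"
        tax["order"] = orders
        return tax

    def test_single_order_is_total(self):
        t = make_table({"o0": [3, 1], "o1": [1, 3]},
                       taxonomy=self._tax(["OrdA", "OrdA"], 2))
        out = aggregate_by_rank(t, "order")
        assert np.allclose(out.loc[("bacteria", "OrdA")], 1.0)

    def test_constant_ratio(self):
        t = make_table({"o0": [10, 20], "o1": [30, 60]},
                       taxonomy=self._tax(["OrdA", "OrdB"], 2))
        out = aggregate_by_rank(t, "order")
        assert np.allclose(out.loc[("bacteria", "OrdA")], 0.25)
        assert np.allclose(out.loc[("bacteria", "OrdB")], 0.75)

    def test_matches_manual_aggregation(self, random_table):
        tax = random_table.taxonomy.copy()
        tax["order"] = [f"Ord{i % 3}" for i in range(len(tax))]
        t = make_table(
            {k: random_table.counts.loc[k].tolist()
             for k in random_table.taxa},
            months=list(random_table.samples["month"].astype(str)),
            taxonomy=tax)
        out = aggregate_by_rank(t, "order")
        # manual: closure per sample, sum per order, mean per month
        rel = t.counts / t.counts.sum(axis=0)
        manual = rel.groupby(tax["order"]).sum()
        for m in t.month_order:
            cols = t.samples_of_month(m)
            for o in manual.index:
                assert out.loc[("bacteria", o), m] == pytest.approx(
                    manual.loc[o, cols].mean())

    def test_unknown_rank_raises(self, toy_table):
        with pytest.raises(ValueError):
            aggregate_by_rank(toy_table, "species")
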