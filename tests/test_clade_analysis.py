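import numpy as np
import pandas as pd
import pytest

from conftest import expression_from_array
from oracles import bh_qvalues, hypergeom_upper_tail

from exprphylo.clade_analysis import (
    CladeSplit,
    differential_genes,
    enrichment,
    hypergeometric_p,
    split_major_clades,
)
from exprphylo.discretize import CharacterMatrix
from exprphylo.io_formats import GeneSetCollection, parse_newick


class TestSplitMajorClades:
    def test_balanced_quartet_gives_cherries(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);", rooted=True)
        split = split_major_clades(t, exclude_outgroup=False)
        assert {split.clade_a, split.clade_b} == {
            frozenset({"A", "B"}),
            frozenset({"C", "D"}),
        }

    def test_caterpillar_rooted_at_outgroup(self):
        t = parse_newick(
            "(og:1,(t1:1,(t2:1,(t3:1,(t4:1,t5:1):1):1):1):1);", rooted=True
        )
        split = split_major_clades(t, exclude_outgroup=True, outgroup={"og"})
        assert {split.clade_a, split.clade_b} == {
            frozenset({"t1"}),
            frozenset({"t2", "t3", "t4", "t5"}),
        }

    def test_support_picked_from_edge_label(self):
        t = parse_newick("((A:1,B:1)91:1,(C:1,D:1):1);", rooted=True)
        split = split_major_clades(t, exclude_outgroup=False)
        assert split.support == 91

    def test_unrooted_rejected(self):
        t = parse_newick("(A:1,B:1,(C:1,D:1):1);")
        with pytest.raises(ValueError, match="rooted"):
            split_major_clades(t)


class TestDifferentialGenes:
    def _expr_split(self, rng, n_genes=30, shift_first=5):
        arr = rng.normal(8, 0.2, size=(n_genes, 8))
        arr[:shift_first, 4:] += 3.0
        expr = expression_from_array(arr)
        split = CladeSplit(
            clade_a=frozenset(expr.sample_ids[:4]),
            clade_b=frozenset(expr.sample_ids[4:]),
        )
        return expr, split

    def test_shifted_genes_significant(self, rng):
        expr, split = self._expr_split(rng)
        table = differential_genes(expr, split)
        assert set(table.index[table["significant"]]) >= {f"g{i}" for i in range(5)}

    def test_constant_gene_p_one(self, rng):
        arr = np.vstack([np.full((1, 8), 5.0), rng.normal(0, 1, size=(3, 8))])
        expr = expression_from_array(arr)
        split = CladeSplit(
            clade_a=frozenset(expr.sample_ids[:4]),
            clade_b=frozenset(expr.sample_ids[4:]),
        )
        table = differential_genes(expr, split)
        assert table.loc["g0", "p"] == 1.0
        assert table.loc["g0", "statistic"] == 0.0

    def test_q_values_match_bh_oracle(self, rng):
        expr, split = self._expr_split(rng, n_genes=50, shift_first=8)
        table = differential_genes(expr, split)
        assert np.allclose(table["q"], bh_qvalues(table["p"].to_numpy()), atol=1e-12)
        assert (table["q"] >= table["p"] - 1e-15).all()

    def test_small_clade_suggests_synapomorphy(self, rng):
        expr, _ = self._expr_split(rng)
        split = CladeSplit(
            clade_a=frozenset(expr.sample_ids[:1]),
            clade_b=frozenset(expr.sample_ids[1:]),
        )
        with pytest.raises(ValueError, match="synapomorphy"):
            differential_genes(expr, split)

    def test_synapomorphy_mode(self, rng):
        expr, split = self._expr_split(rng, n_genes=4)
        states = np.array(
            [
                [2, 2, 2, 2, 0, 0, 0, 0],  # clean synapomorphy
                [1, 1, 1, 1, 1, 1, 1, 1],  # constant: excluded
                [2, 1, 2, 2, 0, 0, 0, 0],  # not uniform in clade A
                [0, 0, 0, 0, 0, 0, 0, 0],  # uniform but equal: excluded
            ],
            dtype=np.int8,
        ).T
        cm = CharacterMatrix(
            taxa=expr.sample_ids, states=states, characters=[f"g{i}" for i in range(4)]
        )
        table = differential_genes(expr, split, mode="synapomorphy", cm=cm)
        assert table["significant"].tolist() == [True, False, False, False]

    def test_label_permutation_false_positive_rate(self, rng):
        """Permuted clade labels produce few q<0.05 calls."""
        arr = rng.normal(8, 0.5, size=(200, 10))
        expr = expression_from_array(arr)
        rates = []
        for _ in range(20):
            perm = rng.permutation(expr.sample_ids)
            split = CladeSplit(
                clade_a=frozenset(perm[:5]), clade_b=frozenset(perm[5:])
            )
            table = differential_genes(expr, split)
            rates.append(table["significant"].mean())
        assert np.mean(rates) <= 0.05


class TestHypergeometric:
    def test_worked_example_exact(self):
        assert hypergeometric_p(3, 5, 3, 10) == pytest.approx(10 / 120, abs=1e-12)

    def test_zero_overlap_is_one(self):
        assert hypergeometric_p(0, 5, 3, 10) == pytest.approx(1.0)

    def test_query_equals_universe(self):
        assert hypergeometric_p(4, 4, 10, 10) == pytest.approx(1.0)

    def test_matches_combinatorial_oracle(self, rng):
        for _ in range(25):
            u = int(rng.integers(8, 40))
            m = int(rng.integers(1, u))
            q = int(rng.integers(1, u))
            k = int(rng.integers(0, min(m, q) + 1))
            assert hypergeometric_p(k, m, q, u) == pytest.approx(
                hypergeom_upper_tail(k, m, q, u), rel=1e-10
            )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_p(6, 5, 3, 10)


class TestEnrichment:
    def _toy(self, rng, n_sets=8, universe_size=50):
        universe = [f"G{i:02d}" for i in range(universe_size)]
        sets = {}
        for s in range(n_sets):
            size = int(rng.integers(4, 12))
            sets[f"S{s}"] = frozenset(rng.choice(universe, size=size, replace=False))
        return universe, GeneSetCollection(sets=sets)

    def test_trivial_collection_all_ones(self):
        universe = [f"G{i}" for i in range(10)]
        coll = GeneSetCollection(sets={"ALL": frozenset(universe)})
        res = enrichment(universe, coll, universe=universe, n_perm=50, seed=0)
        assert res.table.loc["ALL", "p"] == pytest.approx(1.0)
        assert res.table.loc["ALL", "adjusted_p"] == pytest.approx(1.0)

    def test_empty_query_rejected(self, rng):
        universe, coll = self._toy(rng)
        with pytest.raises(ValueError, match="empty"):
            enrichment([], coll, universe=universe)

    def test_adjusted_p_close_to_large_mc_oracle(self, rng):
        from scipy import stats as sps

        universe, coll = self._toy(rng)
        query = sorted(coll.sets["S0"])[:6] + ["G00", "G01"]
        query = list(dict.fromkeys(query))
        res = enrichment(query, coll, universe=universe, n_perm=1000, seed=3)
        # independent 10,000-rep Monte-Carlo estimate of the min-p null
        oracle_rng = np.random.default_rng(12345)
        uidx = {g: i for i, g in enumerate(sorted(set(universe)))}
        names = coll.names
        member = np.zeros((len(names), len(uidx)))
        for si, nm in enumerate(names):
            for g in coll.sets[nm]:
                member[si, uidx[g]] = 1.0
        sizes = member.sum(axis=1).astype(int)
        mins = np.empty(10000)
        for r in range(10000):
            pick = oracle_rng.choice(len(uidx), size=len(query), replace=False)
            v = np.zeros(len(uidx))
            v[pick] = 1.0
            ov = (member @ v).astype(int)
            mins[r] = min(
                sps.hypergeom.sf(ov[i] - 1, len(uidx), sizes[i], len(query))
                for i in range(len(names))
            )
        for nm in names:
            expected = (mins <= res.table.loc[nm, "p"] + 1e-15).mean()
            assert res.table.loc[nm, "adjusted_p"] == pytest.approx(
                expected, abs=0.03
            )

    def test_adjusted_p_monotone_in_raw_p(self, rng):
        universe, coll = self._toy(rng)
        query = list(np.random.default_rng(5).choice(universe, size=8, replace=False))
        res = enrichment(query, coll, universe=universe, n_perm=500, seed=9)
        t = res.table.sort_values("p")
        assert (np.diff(t["adjusted_p"].to_numpy()) >= -1e-12).all()

    def test_null_super_uniformity(self, rng):
        """Min adjusted p over the collection is super-uniform under the null."""
        universe, coll = self._toy(rng, n_sets=6, universe_size=40)
        hits = 0
        n_trials = 150
        for trial in range(n_trials):
            query = list(rng.choice(universe, size=6, replace=False))
            res = enrichment(query, coll, universe=universe, n_perm=200, seed=trial)
            hits += res.table["adjusted_p"].min() <= 0.05
        assert hits / n_trials <= 0.09
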