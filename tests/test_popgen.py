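"""Population statistics: presence/frequency, matching, co-occurrence, tree stats."""

import itertools
import random

import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popfit import (
    GenotypeMatrix,
    cooccurrence_test,
    fitch_parsimony,
    jaccard,
    match_controls,
    presence_stats,
    retention_index,
    singletons_per_strain,
    strain_age_comparison,
)
from popfit.popgen import mean_pairwise_jaccard

from conftest import random_genotype_frame


class TestPresenceStats:
    def test_singleton_detection(self):
        df = pd.DataFrame(0, index=["v1", "v2"], columns=[f"s{i}" for i in range(100)], dtype=np.int8)
        df.loc["v1", "s0"] = 2
        df.loc["v2", ["s0", "s1", "s2"]] = 1
        out = presence_stats(GenotypeMatrix(df)).set_index("variant")
        assert out.loc["v1", "n_strains"] == 1 and bool(out.loc["v1", "is_singleton"])
        assert out.loc["v2", "het_fraction"] == 1.0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(5)
        df = random_genotype_frame(rng)
        out = presence_stats(GenotypeMatrix(df)).set_index("variant")
        for v in df.index:
            row = df.loc[v]
            carriers = (row > 0).sum()
            het = (row == 1).sum()
            assert out.loc[v, "n_strains"] == carriers
            assert out.loc[v, "allele_frequency"] == carriers / df.shape[1]
            assert out.loc[v, "het_fraction"] == het / carriers

    def test_absent_variant_excluded(self):
        df = pd.DataFrame([[0, 0], [2, 0]], index=["dead", "ok"], columns=["s1", "s2"], dtype=np.int8)
        out = presence_stats(GenotypeMatrix(df))
        assert out.variant.tolist() == ["ok"]

    def test_dosage_mode(self):
        df = pd.DataFrame([[1, 2, 0, 0]], index=["v"], columns=list("abcd"), dtype=np.int8)
        carrier = presence_stats(GenotypeMatrix(df), mode="carrier")
        dosage = presence_stats(GenotypeMatrix(df), mode="dosage")
        assert carrier.allele_frequency.iloc[0] == 0.5
        assert dosage.allele_frequency.iloc[0] == 3 / 8


class TestJaccard:
    def test_examples(self):
        assert jaccard({"s1", "s2"}, {"s1", "s2"}) == 1.0
        assert jaccard({"s1"}, {"s2"}) == 0.0
        assert jaccard({"s1", "s2"}, {"s2", "s3"}) == pytest.approx(1 / 3)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            jaccard(set(), {"s1"})

    @given(
        a=st.sets(st.integers(0, 15), min_size=1),
        b=st.sets(st.integers(0, 15), min_size=1),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_symmetry_and_identity(self, a, b):
        assert jaccard(a, b) == jaccard(b, a)
        assert 0.0 <= jaccard(a, b) <= 1.0
        assert (jaccard(a, b) == 1.0) == (a == b)

    def test_matrix_mean_equals_set_arithmetic(self):
        rng = np.random.default_rng(3)
        df = random_genotype_frame(rng, n_variants=12)
        G = GenotypeMatrix(df)
        X = G.presence_matrix()
        sets = [G.presence_set(v) for v in G.variants]
        manual = np.mean([
            jaccard(sets[i], sets[j]) for i in range(12) for j in range(i + 1, 12)
        ])
        assert mean_pairwise_jaccard(X) == pytest.approx(manual)


class TestMatchControls:
    def test_exact_matches_when_available(self):
        rng = np.random.default_rng(0)
        # candidate pool contains a same-frequency, disjoint control per focal
        n = 40
        rows = []
        ids = []
        for i in range(5):
            v = np.zeros(n, np.int8); v[2 * i] = 2
            c = np.zeros(n, np.int8); c[20 + 2 * i] = 2
            rows += [v, c]; ids += [f"f{i}", f"c{i}"]
        G = GenotypeMatrix(pd.DataFrame(rows, index=ids, columns=[f"s{j}" for j in range(n)]))
        pairs = match_controls([f"f{i}" for i in range(5)], [f"c{i}" for i in range(5)], G, seed=0)
        assert (pairs.pairs.abs_af_diff == 0).all()
        assert not pairs.unmatched

    def test_jaccard_tie_break(self):
        n = 10
        focal = np.zeros(n, np.int8); focal[[0, 1]] = 2
        linked = np.zeros(n, np.int8); linked[[0, 2]] = 2   # Jaccard 1/3 with focal
        unlinked = np.zeros(n, np.int8); unlinked[[5, 6]] = 2  # Jaccard 0
        G = GenotypeMatrix(pd.DataFrame([focal, linked, unlinked], index=["f", "cl", "cu"],
                                        columns=[f"s{j}" for j in range(n)]))
        pairs = match_controls(["f"], ["cl", "cu"], G, seed=0)
        assert pairs.pairs.control.iloc[0] == "cu"

    def test_overlap_rejected(self):
        rng = np.random.default_rng(1)
        G = GenotypeMatrix(random_genotype_frame(rng))
        with pytest.raises(ValueError, match="disjoint"):
            match_controls(["v000"], ["v000", "v001"], G)

    def test_exhausted_pool_reports_unmatched(self):
        rng = np.random.default_rng(2)
        G = GenotypeMatrix(random_genotype_frame(rng, n_variants=10))
        pairs = match_controls([f"v00{i}" for i in range(5)], ["v009"], G, seed=0)
        assert len(pairs.pairs) == 1 and len(pairs.unmatched) == 4

    def test_stepwise_greedy_optimality(self):
        # replay the greedy order and verify each chosen control is optimal
        # among the still-unmatched candidates by exhaustive scan
        rng = np.random.default_rng(7)
        df = random_genotype_frame(rng, n_variants=120, n_strains=40)
        G = GenotypeMatrix(df)
        focal = list(df.index[:20])
        candidates = list(df.index[20:])
        pairs = match_controls(focal, candidates, G, seed=11)
        af = dict(zip(df.index, G.allele_frequency(list(df.index))))
        sets = {v: G.presence_set(v) for v in df.index}
        order = sorted(focal, key=lambda v: (-af[v], str(v)))
        chosen = pairs.pairs.set_index("focal")["control"]
        assert chosen.is_unique
        used = set()
        for f in order:
            c = chosen[f]
            remaining = [x for x in candidates if x not in used]
            best_d = min(abs(af[x] - af[f]) for x in remaining)
            tied = [x for x in remaining if abs(af[x] - af[f]) == best_d]
            best_j = min(jaccard(sets[x], sets[f]) for x in tied)
            assert abs(af[c] - af[f]) == pytest.approx(best_d)
            assert jaccard(sets[c], sets[f]) == pytest.approx(best_j)
            used.add(c)


class TestCooccurrence:
    def test_identical_sets_null(self):
        rng = np.random.default_rng(4)
        df = random_genotype_frame(rng, n_variants=24)
        G = GenotypeMatrix(df)
        ids = list(df.index[:12])
        res = cooccurrence_test(ids, ids, G, n_boot=200, seed=0)
        assert res.difference == 0.0
        assert res.p_value > 0.5

    def test_singleton_reduction_to_cooccurrence_frequency(self):
        # for singletons, a pair shares a strain (J = 1) or not (J = 0), so the
        # mean pairwise Jaccard equals the fraction of co-occurring pairs
        n = 6
        M = np.zeros((4, n), np.int8)
        M[0, 0] = M[1, 0] = 2  # same strain
        M[2, 1] = 2
        M[3, 2] = 2
        G = GenotypeMatrix(pd.DataFrame(M, index=list("abcd"), columns=[f"s{j}" for j in range(n)]))
        X = G.presence_matrix(list("abcd"))
        assert mean_pairwise_jaccard(X) == pytest.approx(1 / 6)

    def test_min_set_size_enforced(self):
        rng = np.random.default_rng(9)
        G = GenotypeMatrix(random_genotype_frame(rng))
        with pytest.raises(ValueError):
            cooccurrence_test(["v000"], ["v001", "v002"], G)

    def test_detects_planted_cooccurrence(self):
        # focal variants all private to one tight strain group; controls scattered
        n = 40
        rng = np.random.default_rng(8)
        rows, ids = [], []
        for i in range(10):
            v = np.zeros(n, np.int8)
            v[rng.choice(5, size=2, replace=False)] = 2  # clustered in strains 0-4
            rows.append(v); ids.append(f"x{i}")
        for i in range(10):
            v = np.zeros(n, np.int8)
            v[rng.choice(n, size=2, replace=False)] = 2
            rows.append(v); ids.append(f"y{i}")
        G = GenotypeMatrix(pd.DataFrame(rows, index=ids, columns=[f"s{j}" for j in range(n)]))
        res = cooccurrence_test([f"x{i}" for i in range(10)], [f"y{i}" for i in range(10)], G,
                                n_boot=500, seed=1)
        assert res.difference > 0 and res.p_value < 0.05
        assert res.ratio > 1.5


class TestSingletonsAndStrainAge:
    def test_counts_match_double_loop(self):
        rng = np.random.default_rng(6)
        df = random_genotype_frame(rng)
        G = GenotypeMatrix(df)
        counts = singletons_per_strain(G)
        for s in df.columns:
            manual = sum(
                1 for v in df.index
                if df.loc[v, s] > 0 and (df.loc[v] > 0).sum() == 1
            )
            assert counts[s] == manual

    def test_one_singleton_per_strain(self):
        df = pd.DataFrame(np.diag([2] * 8), index=[f"v{i}" for i in range(8)],
                          columns=[f"s{i}" for i in range(8)]).astype(np.int8)
        assert (singletons_per_strain(GenotypeMatrix(df)) == 1).all()

    def test_identical_sets_give_p_one(self):
        df = pd.DataFrame(np.diag([2] * 10), index=[f"v{i}" for i in range(10)],
                          columns=[f"s{i}" for i in range(10)]).astype(np.int8)
        G = GenotypeMatrix(df)
        ids = [f"v{i}" for i in range(6)]
        res = strain_age_comparison(ids, ids, G)
        assert res["p_value"] > 0.99

    def test_rank_statistic_matches_textbook_formula(self):
        # U = (sum of ranks of sample A) - n_a(n_a+1)/2, computed by hand on
        # 20 carrier ages derived from a diagonal singleton matrix plus
        # extra private variants that diversify per-strain counts
        rng = np.random.default_rng(2)
        n = 20
        rows = [np.eye(n, dtype=np.int8)[i] * 2 for i in range(n)]
        ids = [f"v{i}" for i in range(n)]
        k = n
        for _ in range(25):
            v = np.zeros(n, np.int8)
            v[rng.integers(0, n)] = 2
            rows.append(v)
            ids.append(f"x{k}")
            k += 1
        G = GenotypeMatrix(pd.DataFrame(rows, index=ids, columns=[f"s{i}" for i in range(n)]))
        A = [f"v{i}" for i in range(8)]
        B = [f"v{i}" for i in range(8, 20)]
        res = strain_age_comparison(A, B, G)
        ages = singletons_per_strain(G)
        values = np.concatenate([
            ages[[f"s{i}" for i in range(8)]].to_numpy(),
            ages[[f"s{i}" for i in range(8, 20)]].to_numpy(),
        ]).astype(float)
        from scipy.stats import rankdata

        U = rankdata(values)[:8].sum() - 8 * 9 / 2
        assert res["statistic"] == pytest.approx(U)

    def test_requires_singletons(self):
        df = pd.DataFrame([[2, 2, 0], [2, 0, 0]], index=["v0", "v1"], columns=list("abc"), dtype=np.int8)
        with pytest.raises(ValueError, match="singleton"):
            strain_age_comparison(["v0"], ["v1"], GenotypeMatrix(df))

    def test_planted_young_strain_placement_detected(self):
        # set A placed in "young" strains (many singletons) -> its carrier
        # median singleton count is strictly higher in nearly every run
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 30
            young = rng.choice(n, size=10, replace=False)
            rows = []
            ids = []
            k = 0
            # young strains carry extra private variants
            for s in young:
                for _ in range(rng.integers(3, 7)):
                    v = np.zeros(n, np.int8); v[s] = 2
                    rows.append(v); ids.append(f"bg{k}"); k += 1
            for s in range(n):
                v = np.zeros(n, np.int8); v[s] = 2
                rows.append(v); ids.append(f"bg{k}"); k += 1
            # set A: singletons in young strains; set B: in random strains
            A, B = [], []
            for i in range(8):
                v = np.zeros(n, np.int8); v[rng.choice(young)] = 2
                rows.append(v); ids.append(f"a{i}"); A.append(f"a{i}")
                w = np.zeros(n, np.int8); w[rng.integers(0, n)] = 2
                rows.append(w); ids.append(f"b{i}"); B.append(f"b{i}")
            G = GenotypeMatrix(pd.DataFrame(rows, index=ids, columns=[f"s{j}" for j in range(n)]))
            res = strain_age_comparison(A, B, G)
            wins += res["median_a"] > res["median_b"]
        assert wins >= 90


def _random_tree(n_tips, seed):
    tns = dendropy.TaxonNamespace([f"t{i}" for i in range(n_tips)])
    return dendropy.simulate.treesim.pure_kingman_tree(
        taxon_namespace=tns, pop_size=1, rng=random.Random(seed)
    )


def _brute_force_parsimony(tree, trait):
    internals = [nd for nd in tree.postorder_node_iter() if not nd.is_leaf()]
    best = np.inf
    for labels in itertools.product((0, 1), repeat=len(internals)):
        lab = {id(nd): s for nd, s in zip(internals, labels)}
        for lf in tree.leaf_node_iter():
            lab[id(lf)] = trait[lf.taxon.label]
        changes = sum(
            1
            for nd in tree.preorder_node_iter()
            if nd.parent_node is not None and lab[id(nd)] != lab[id(nd.parent_node)]
        )
        best = min(best, changes)
    return best


class TestTreeStatistics:
    def test_uniform_trait_zero_changes(self):
        tree = _random_tree(6, 0)
        assert fitch_parsimony(tree, {f"t{i}": 1 for i in range(6)}) == 0

    def test_single_derived_tip_one_change(self):
        tree = _random_tree(6, 1)
        trait = {f"t{i}": int(i == 3) for i in range(6)}
        assert fitch_parsimony(tree, trait) == 1

    def test_matches_brute_force_on_random_trees(self):
        for seed in range(5):
            tree = _random_tree(6, seed)
            for bits in itertools.product((0, 1), repeat=6):
                trait = {f"t{i}": bits[i] for i in range(6)}
                assert fitch_parsimony(tree, trait) == _brute_force_parsimony(tree, trait)

    def test_never_exceeds_minority_count(self):
        rng = np.random.default_rng(0)
        for seed in range(10):
            tree = _random_tree(8, seed)
            bits = rng.integers(0, 2, size=8)
            if bits.sum() in (0, 8):
                continue
            trait = {f"t{i}": int(bits[i]) for i in range(8)}
            assert fitch_parsimony(tree, trait) <= min(bits.sum(), 8 - bits.sum())

    def test_missing_tip_trait_rejected(self):
        tree = _random_tree(4, 0)
        with pytest.raises(ValueError, match="no trait"):
            fitch_parsimony(tree, {"t0": 1, "t1": 0, "t2": 1})

    def test_retention_index_extremes(self):
        tree = dendropy.Tree.get(
            data="((a:1,b:1):1,((c:1,d:1):1,(e:1,f:1):1):1):0;", schema="newick"
        )
        assert retention_index(tree, {"a": 1, "b": 1, "c": 0, "d": 0, "e": 0, "f": 0}) == 1.0
        assert retention_index(tree, {"a": 1, "b": 0, "c": 1, "d": 0, "e": 1, "f": 0}) == 0.0

    def test_retention_index_formula_from_oracle(self):
        rng = np.random.default_rng(1)
        for seed in range(5):
            tree = _random_tree(7, seed)
            bits = rng.integers(0, 2, size=7)
            if min(bits.sum(), 7 - bits.sum()) < 2:
                continue
            trait = {f"t{i}": int(bits[i]) for i in range(7)}
            obs = _brute_force_parsimony(tree, trait)
            max_steps = min(bits.sum(), 7 - bits.sum())
            expect = (max_steps - obs) / (max_steps - 1)
            assert retention_index(tree, trait) == pytest.approx(expect)

    def test_invariant_trait_rejected(self):
        tree = _random_tree(5, 2)
        with pytest.raises(ValueError, match="invariant"):
            retention_index(tree, {f"t{i}": 0 for i in range(5)})

    def test_singleton_minority_flagged_nan(self):
        tree = _random_tree(5, 3)
        trait = {f"t{i}": int(i == 0) for i in range(5)}
        assert np.isnan(retention_index(tree, trait))
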