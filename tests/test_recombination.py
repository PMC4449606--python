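"""Incompatibility scoring (vs a brute-force parsimony oracle), the three
recombination statistics, and the permutation machinery."""

import itertools

import numpy as np
import pytest

from beepan.phylo import Alignment
from beepan.recombination import (
    InformativeSiteMatrix,
    RecombinationParams,
    incompatibility_matrix,
    informative_sites,
    maxchi_statistic,
    nss_statistic,
    pair_incompatibility,
    permutation_pvalue,
    phi_statistic,
    scan_genes,
    evaluate_gene,
)

# ---------------------------------------------------------------------------
# brute-force parsimony oracle: minimum extra steps over all small trees
# ---------------------------------------------------------------------------


def all_topologies(n):
    base = [(0, "i0"), (1, "i0"), (2, "i0")]
    tops = [base]
    for leaf in range(3, n):
        nxt = []
        for edges in tops:
            for k, (u, v) in enumerate(edges):
                mid = f"m{leaf}_{k}"
                nxt.append(edges[:k] + edges[k + 1 :] + [(u, mid), (v, mid), (leaf, mid)])
        tops = nxt
    return tops


def fitch_steps(edges, column):
    """Fitch parsimony steps of one multistate character on one topology."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    root = next(x for x in adj if isinstance(x, str))
    steps = 0

    def down(x, parent):
        nonlocal steps
        if isinstance(x, int):
            return {column[x]}
        sets = [down(y, x) for y in adj[x] if y != parent]
        inter = set.intersection(*sets)
        if inter:
            return inter
        steps += len(sets) - 1 if len(sets) > 2 else 1
        # standard Fitch on binary internals; the root may be ternary, where
        # pairwise unions still count one step per missing intersection
        if len(sets) == 2:
            return sets[0] | sets[1]
        # ternary root: count via sequential Fitch
        steps -= len(sets) - 1 if len(sets) > 2 else 1
        acc = sets[0]
        for s in sets[1:]:
            if acc & s:
                acc = acc & s
            else:
                steps += 1
                acc = acc | s
        return acc

    down(root, None)
    return steps


def min_joint_extra_steps(col_i, col_j):
    n = len(col_i)
    best = None
    for edges in all_topologies(n):
        joint = fitch_steps(edges, col_i) + fitch_steps(edges, col_j)
        best = joint if best is None else min(best, joint)
    base = (len(set(col_i)) - 1) + (len(set(col_j)) - 1)
    return best - base


class TestPairIncompatibility:
    def test_four_gamete_binary_pair(self):
        assert pair_incompatibility([0, 0, 1, 1], [0, 1, 0, 1]) == 1

    def test_identical_partition_compatible(self):
        assert pair_incompatibility("AACC", "GGTT") == 0

    def test_symmetric_and_zero_on_identical(self):
        a, b = [0, 1, 0, 2, 1], [1, 1, 0, 0, 2]
        assert pair_incompatibility(a, b) == pair_incompatibility(b, a)
        assert pair_incompatibility(a, a) == 0

    def test_column_with_single_state_scores_zero(self):
        assert pair_incompatibility([0, 0, 0, 0], [0, 1, 0, 1]) == 0

    def test_missing_taxa_excluded(self):
        # with the missing taxon dropped only three gametes remain
        assert pair_incompatibility([0, 0, 1, -1], [0, 1, 0, 1]) == 0

    @pytest.mark.parametrize("seed", range(15))
    def test_equals_minimum_extra_parsimony_steps(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        col_i = rng.integers(0, 3, size=n).tolist()
        col_j = rng.integers(0, 3, size=n).tolist()
        assert pair_incompatibility(col_i, col_j) == min_joint_extra_steps(
            col_i, col_j
        )

    def test_state_relabeling_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = rng.integers(0, 4, size=6)
            b = rng.integers(0, 4, size=6)
            perm = rng.permutation(4)
            assert pair_incompatibility(a, b) == pair_incompatibility(perm[a], b)


class TestInformativeSites:
    def test_two_by_two_column_retained(self):
        m = informative_sites({"a": "A", "b": "A", "c": "C", "d": "C"})
        assert m.m == 1

    def test_singleton_state_dropped(self):
        m = informative_sites({"a": "A", "b": "A", "c": "A", "d": "C"})
        assert m.m == 0

    def test_majority_missing_column_dropped(self):
        m = informative_sites({"a": "A", "b": "-", "c": "-", "d": "C"})
        assert m.m == 0

    def test_positions_are_original_coordinates(self):
        aln = {"a": "GAG", "b": "GAG", "c": "GCT", "d": "GCT"}
        m = informative_sites(aln)
        assert m.positions.tolist() == [2, 3]


def matrix_from_columns(columns, positions=None):
    codes = np.array(columns, dtype=np.int8).T
    n = codes.shape[0]
    return InformativeSiteMatrix(
        taxa=[f"t{i}" for i in range(n)],
        codes=codes,
        positions=np.asarray(positions if positions is not None else range(1, codes.shape[1] + 1)),
    )


class TestStatistics:
    def test_phi_zero_when_all_compatible(self):
        m = matrix_from_columns([[0, 0, 1, 1]] * 5)
        assert phi_statistic(m, 100) == 0.0

    def test_phi_mean_of_nearby_pair_scores(self):
        # three sites; pairs (1,2) and (2,3) incompatible, (1,3) compatible
        cols = [[0, 0, 1, 1], [0, 1, 0, 1], [0, 0, 1, 1]]
        m = matrix_from_columns(cols)
        assert phi_statistic(m, 100) == pytest.approx(2 / 3)

    def test_phi_not_evaluable_when_window_too_small(self):
        m = matrix_from_columns([[0, 0, 1, 1], [0, 1, 0, 1]], positions=[1, 500])
        assert phi_statistic(m, 100) is None

    def test_nss_adjacent_compatibility_fraction(self):
        a, b = [0, 0, 1, 1], [0, 1, 0, 1]
        m = matrix_from_columns([a, b, a, b, a])
        # neighbours all incompatible
        assert nss_statistic(m) == 0.0
        m2 = matrix_from_columns([a, a, b, b, a])
        # compatible neighbours: (1,2), (3,4); incompatible: (2,3), (4,5)
        assert nss_statistic(m2) == 0.5

    def test_nss_two_incompatible_sites(self):
        m = matrix_from_columns([[0, 0, 1, 1], [0, 1, 0, 1]])
        assert nss_statistic(m) == 0.0

    def test_maxchi_identical_sequences_zero(self):
        m = matrix_from_columns([[0, 0, 1, 1]] * 20)
        stat, _, _ = maxchi_statistic(m, 5)
        assert stat == 0.0

    def test_maxchi_planted_mosaic_equals_2k(self):
        k = 5
        left = [0, 0, 1, 1]  # t0,t1 match
        right = [0, 1, 0, 1]  # t0,t1 mismatch
        m = matrix_from_columns([left] * k + [right] * k)
        stat, _, breakpoint = maxchi_statistic(m, k)
        assert stat == pytest.approx(2 * k)
        assert breakpoint == k

    def test_maxchi_permuted_mosaic_scores_below_2k(self):
        k = 5
        left = [0, 0, 1, 1]
        right = [0, 1, 0, 1]
        cols = [left] * k + [right] * k
        rng = np.random.default_rng(0)
        permuted_max = []
        for _ in range(40):
            order = rng.permutation(2 * k)
            m = matrix_from_columns([cols[i] for i in order])
            permuted_max.append(maxchi_statistic(m, k)[0])
        assert np.mean(permuted_max) < 0.8 * 2 * k

    def test_maxchi_not_evaluable_on_short_matrix(self):
        m = matrix_from_columns([[0, 0, 1, 1]] * 5)
        assert maxchi_statistic(m, 10) is None

    def test_taxon_reordering_invariance(self):
        rng = np.random.default_rng(2)
        seqs = {t: "".join(rng.choice(list("ACGT"), 120)) for t in "abcdef"}
        m1 = informative_sites(seqs)
        order = rng.permutation(6)
        shuffled = {t: seqs[t] for t in np.array(sorted(seqs))[order]}
        m2 = informative_sites(dict(sorted(shuffled.items())))
        s1, s2 = incompatibility_matrix(m1), incompatibility_matrix(m2)
        assert phi_statistic(m1, 100, s=s1) == phi_statistic(m2, 100, s=s2)
        assert nss_statistic(m1, s=s1) == nss_statistic(m2, s=s2)


class TestPermutationPvalue:
    def test_add_one_estimator(self):
        perms = np.array([1.0, 2.0, 3.0, 4.0])
        assert permutation_pvalue(2.5, perms, "ge") == (1 + 2) / 5
        assert permutation_pvalue(2.5, perms, "le") == (1 + 2) / 5

    def test_constant_statistic_gives_p_one(self):
        # identical informative columns: every permutation leaves all three
        # statistics unchanged
        col = "A" * 15 + "C" * 15
        aln = {"a": col, "b": col, "c": col.replace("A", "C"), "d": col.replace("A", "C")}
        # columns all share one pattern -> statistics constant
        rec = evaluate_gene(
            {"a": "AC" * 30, "b": "AC" * 30, "c": "CA" * 30, "d": "CA" * 30},
            RecombinationParams(permutations=100, seed=0),
        )
        assert rec["p_phi"] == 1.0 and rec["p_nss"] == 1.0 and rec["p_maxchi"] == 1.0

    def test_same_seed_reproduces_pvalues(self):
        rng = np.random.default_rng(3)
        seqs = {t: "".join(rng.choice(list("ACGT"), 300)) for t in "abcdef"}
        r1 = evaluate_gene(seqs, RecombinationParams(permutations=200, seed=11))
        r2 = evaluate_gene(seqs, RecombinationParams(permutations=200, seed=11))
        assert (r1["p_phi"], r1["p_nss"], r1["p_maxchi"]) == (
            r2["p_phi"],
            r2["p_nss"],
            r2["p_maxchi"],
        )


class TestScanGenes:
    def test_invariant_sites_not_evaluable(self):
        alns = {f"g{i}": {"a": "AAAA", "b": "AAAA", "c": "AAAA", "d": "AAAA"} for i in range(3)}
        table, summary = scan_genes(alns, RecombinationParams(permutations=50))
        assert (table["verdict"] == "not-evaluable").all()
        assert summary["recombinant"] == 0 and summary["evaluable"] == 0

    def test_verdict_requires_all_three_pvalues(self):
        from beepan.sim import recombinant_gene_set

        genes = {f"g{i}": a for i, a in enumerate(recombinant_gene_set(4, seed=5))}
        table, _ = scan_genes(genes, RecombinationParams(seed=5))
        for _, row in table.iterrows():
            if row["verdict"] == "recombinant":
                assert (
                    row["p_phi"] < 0.01
                    and row["p_nss"] < 0.01
                    and row["p_maxchi"] < 0.01
                )

    def test_scan_independent_of_dict_order(self):
        from beepan.sim import clonal_gene_set

        genes = {f"g{i}": a for i, a in enumerate(clonal_gene_set(4, seed=9, gene_length=300))}
        rev = dict(reversed(list(genes.items())))
        p = RecombinationParams(permutations=100, seed=2)
        t1, _ = scan_genes(genes, p)
        t2, _ = scan_genes(rev, p)
        assert t1.equals(t2)
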