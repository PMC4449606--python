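"""Alignment pruning/back-translation, JC distances, neighbor-joining against
an exhaustive least-squares oracle, rooting, and monophyly tests."""

import itertools

import dendropy
import numpy as np
import pytest

from beepan.phylo import (
    Alignment,
    DistanceMatrix,
    backtranslate,
    bipartitions,
    bootstrap_support,
    concatenate,
    is_monophyletic,
    jc_distance,
    monophyly_report,
    nj_tree,
    prune_gap_columns,
    root_with_outgroup,
)

# ---------------------------------------------------------------------------
# unrooted-topology enumeration + least-squares fit (independent NJ oracle)
# ---------------------------------------------------------------------------


def enumerate_topologies(n):
    """All unrooted binary topologies on taxa 0..n-1 as edge lists."""
    base = [(0, "i0"), (1, "i0"), (2, "i0")]
    tops = [base]
    next_internal = 1
    for leaf in range(3, n):
        new_tops = []
        for edges in tops:
            for k, (u, v) in enumerate(edges):
                mid = f"i{next_internal}_{leaf}_{k}"
                new = edges[:k] + edges[k + 1 :]
                new += [(u, mid), (v, mid), (leaf, mid)]
                new_tops.append(new)
        tops = new_tops
        next_internal += 1
    return tops


def topology_bipartitions(edges, n):
    """Leaf bipartitions (canonical side without leaf 0) of an edge list."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def leaves_beyond(u, v):
        # leaves reachable from v without passing u
        seen, stack, out = {u, v}, [v], set()
        while stack:
            x = stack.pop()
            if isinstance(x, int):
                out.add(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return out

    bps = set()
    for u, v in edges:
        side = frozenset(leaves_beyond(u, v))
        if 0 in side:
            side = frozenset(set(range(n)) - side)
        if 2 <= len(side) <= n - 2:
            bps.add(side)
    return bps


def least_squares_sse(edges, dist):
    """Ordinary least-squares edge fit of a topology to a distance matrix."""
    n = dist.shape[0]
    edge_index = {e: i for i, e in enumerate(edges)}
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append((v, edge_index[(u, v)]))
        adj.setdefault(v, []).append((u, edge_index[(u, v)]))
    rows, targets = [], []
    for a, b in itertools.combinations(range(n), 2):
        # path from a to b by DFS
        stack = [(a, [])]
        seen = {a}
        path = None
        while stack:
            x, used = stack.pop()
            if x == b:
                path = used
                break
            for y, ei in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append((y, used + [ei]))
        row = np.zeros(len(edges))
        row[path] = 1.0
        rows.append(row)
        targets.append(dist[a, b])
    a_mat = np.array(rows)
    x, *_ = np.linalg.lstsq(a_mat, np.array(targets), rcond=None)
    resid = a_mat @ x - np.array(targets)
    return float(resid @ resid)


def random_additive(rng, n):
    """Random binary topology with positive branch lengths -> (bps, matrix)."""
    tops = enumerate_topologies(n)
    edges = tops[rng.integers(0, len(tops))]
    lengths = {e: float(rng.uniform(0.1, 1.0)) for e in edges}
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append((v, lengths[(u, v)]))
        adj.setdefault(v, []).append((u, lengths[(u, v)]))
    dist = np.zeros((n, n))
    for a, b in itertools.combinations(range(n), 2):
        stack = [(a, 0.0)]
        seen = {a}
        while stack:
            x, acc = stack.pop()
            if x == b:
                dist[a, b] = dist[b, a] = acc
                break
            for y, w in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append((y, acc + w))
    return topology_bipartitions(edges, n), dist


def tree_bipartitions_as_indices(tree, taxa):
    index = {t: i for i, t in enumerate(taxa)}
    out = set()
    for side in bipartitions(tree):
        ids = frozenset(index[x] for x in side)
        if 0 in ids:
            ids = frozenset(set(range(len(taxa))) - ids)
        out.add(ids)
    return out


# ---------------------------------------------------------------------------
# alignment operations
# ---------------------------------------------------------------------------


class TestPruneGapColumns:
    def test_half_gapped_column_dropped(self):
        aln = Alignment(taxa=list("wxyz"), rows=["A-C", "A-C", "AAC", "AAC"])
        out = prune_gap_columns(aln)
        assert out.rows == ["AC", "AC", "AC", "AC"]
        assert out.columns.tolist() == [1, 3]

    def test_quarter_gapped_column_kept(self):
        aln = Alignment(taxa=list("wxyz"), rows=["A-", "AA", "AA", "AA"])
        assert prune_gap_columns(aln).width == 2

    def test_gap_free_identity_and_idempotence(self):
        aln = Alignment(taxa=["a", "b"], rows=["ACGT", "ACGT"])
        once = prune_gap_columns(aln)
        assert once.rows == aln.rows
        twice = prune_gap_columns(once)
        assert twice.rows == once.rows and twice.columns.tolist() == once.columns.tolist()

    def test_all_columns_dropped_is_error(self):
        aln = Alignment(taxa=["a", "b"], rows=["--", "AA"])
        with pytest.raises(ValueError, match="empty"):
            prune_gap_columns(aln)


class TestBacktranslate:
    def test_gap_expands_to_triplet(self):
        aln = Alignment(taxa=["t"], rows=["M-A"])
        out = backtranslate(aln, {"t": "ATGGCT"})
        assert out.rows == ["ATG---GCT"]

    def test_length_mismatch_names_taxon(self):
        aln = Alignment(taxa=["t"], rows=["MA"])
        with pytest.raises(ValueError, match="t"):
            backtranslate(aln, {"t": "ATGGC"})

    def test_wrong_translation_rejected(self):
        aln = Alignment(taxa=["t"], rows=["MM"])
        with pytest.raises(ValueError, match="translate"):
            backtranslate(aln, {"t": "ATGGCT"})

    def test_gap_free_width_triples(self):
        aln = Alignment(taxa=["t"], rows=["MA"])
        assert backtranslate(aln, {"t": "ATGGCT"}).width == 6


class TestConcatenate:
    def test_spans_recorded(self):
        a = Alignment(taxa=["x", "y"], rows=["AAACCCGGG", "AAACCCGGG"])
        b = Alignment(taxa=["x", "y"], rows=["ACGTACGTACGT", "ACGTACGTACGT"])
        cat, spans = concatenate({"fam1": a, "fam2": b}, ["x", "y"])
        assert cat.width == 21
        assert spans == {"fam1": (1, 9), "fam2": (10, 21)}

    def test_single_family_identity(self):
        a = Alignment(taxa=["x", "y"], rows=["ACG", "ACG"])
        cat, spans = concatenate({"f": a}, ["x", "y"])
        assert cat.rows == a.rows and spans == {"f": (1, 3)}

    def test_missing_taxon_is_error(self):
        a = Alignment(taxa=["x"], rows=["ACG"])
        with pytest.raises(ValueError, match="y"):
            concatenate({"f": a}, ["x", "y"])


class TestJcDistance:
    def test_identical_rows_zero(self):
        aln = Alignment(taxa=["a", "b"], rows=["ACGT" * 10, "ACGT" * 10])
        assert jc_distance(aln).values[0, 1] == 0.0

    def test_closed_form_at_p_ten_percent(self):
        row_a = "A" * 100
        row_b = "C" * 10 + "A" * 90
        aln = Alignment(taxa=["a", "b"], rows=[row_a, row_b])
        d = jc_distance(aln).values[0, 1]
        assert d == pytest.approx(-0.75 * np.log(1 - 0.4 / 3), abs=1e-5)
        assert d == pytest.approx(0.10732, abs=1e-5)

    def test_saturation_capped_at_five(self):
        row_a = "A" * 100
        row_b = "C" * 80 + "A" * 20
        aln = Alignment(taxa=["a", "b"], rows=[row_a, row_b])
        assert jc_distance(aln).values[0, 1] == 5.0

    def test_no_shared_columns_is_error(self):
        aln = Alignment(taxa=["a", "b"], rows=["A-", "-A"])
        with pytest.raises(ValueError, match="shared"):
            jc_distance(aln)

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(0)
        rows = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(5)]
        dm = jc_distance(Alignment(taxa=list("abcde"), rows=rows))
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0)


class TestNjTree:
    def test_three_taxa_three_point_formula(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(taxa=["a", "b", "c"], values=d))
        lengths = {
            l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(taxa=["a", "b"], values=np.zeros((2, 2))))

    def test_four_taxon_additive_topology_recovered(self):
        # ((A,B),(C,D)) with internal edge 2
        d = np.array(
            [
                [0, 2, 5, 5],
                [2, 0, 5, 5],
                [5, 5, 0, 2],
                [5, 5, 2, 0],
            ],
            dtype=float,
        )
        taxa = ["A", "B", "C", "D"]
        tree = nj_tree(DistanceMatrix(taxa=taxa, values=d))
        bps = tree_bipartitions_as_indices(tree, taxa)
        assert bps == {frozenset({2, 3})}

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_least_squares_oracle_on_additive_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        true_bps, dist = random_additive(rng, n)
        taxa = [f"t{i}" for i in range(n)]
        tree = nj_tree(DistanceMatrix(taxa=taxa, values=dist))
        assert tree_bipartitions_as_indices(tree, taxa) == true_bps
        # oracle: exhaustive enumeration, least-squares edge fit
        best = min(
            enumerate_topologies(n), key=lambda e: least_squares_sse(e, dist)
        )
        assert topology_bipartitions(best, n) == true_bps

    def test_agrees_with_skbio_on_random_additive_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(3)
        _, dist = random_additive(rng, 6)
        taxa = [f"t{i}" for i in range(6)]
        mine = nj_tree(DistanceMatrix(taxa=taxa, values=dist))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(dist, ids=taxa))
        theirs_dnd = dendropy.Tree.get(data=str(theirs), schema="newick")
        mine_bps = tree_bipartitions_as_indices(mine, taxa)
        their_sides = set()
        for node in theirs_dnd.preorder_node_iter():
            if node.is_leaf() or node is theirs_dnd.seed_node:
                continue
            side = frozenset(
                int(l.taxon.label[1:]) for l in node.leaf_iter()
            )
            if 0 in side:
                side = frozenset(set(range(6)) - side)
            if 2 <= len(side) <= 4:
                their_sides.add(side)
        assert mine_bps == their_sides


class TestBootstrap:
    def test_congruent_signal_gives_full_support(self):
        rng = np.random.default_rng(1)
        block = {"a": "", "b": "", "c": "", "d": ""}
        # strong ((a,b),(c,d)) signal repeated in two long blocks
        for _ in range(2):
            for t in block:
                block[t] += ("A" if t in "ab" else "C") * 50
                block[t] += "".join(rng.choice(list("ACGT"), 1).tolist() * 4)
        aln = Alignment(taxa=sorted(block), rows=[block[t] for t in sorted(block)])
        tree = bootstrap_support(aln, n=50, seed=2)
        supports = [
            n.support
            for n in tree.preorder_node_iter()
            if not n.is_leaf() and getattr(n, "support", None) is not None
        ]
        assert supports and all(s == 100.0 for s in supports)

    def test_same_seed_reproduces_supports(self):
        rng = np.random.default_rng(5)
        rows = ["".join(rng.choice(list("ACGT"), 120)) for _ in range(5)]
        aln = Alignment(taxa=list("abcde"), rows=rows)
        t1 = bootstrap_support(aln, n=30, seed=9)
        t2 = bootstrap_support(aln, n=30, seed=9)
        s1 = sorted(
            n.support for n in t1.preorder_node_iter() if getattr(n, "support", None) is not None
        )
        s2 = sorted(
            n.support for n in t2.preorder_node_iter() if getattr(n, "support", None) is not None
        )
        assert s1 == s2

    def test_single_replicate_supports_are_binary(self):
        rng = np.random.default_rng(6)
        rows = ["".join(rng.choice(list("ACGT"), 90)) for _ in range(5)]
        aln = Alignment(taxa=list("abcde"), rows=rows)
        tree = bootstrap_support(aln, n=1, seed=0)
        for node in tree.preorder_node_iter():
            s = getattr(node, "support", None)
            if s is not None:
                assert s in (0.0, 100.0)


class TestRooting:
    def tree(self, newick):
        return dendropy.Tree.get(data=newick, schema="newick")

    def test_outgroup_clade_roots_tree(self):
        t = self.tree("((A:1,B:1):1,(C:1,D:1):1);")
        rooted = root_with_outgroup(t, {"C", "D"})
        assert rooted is not None
        assert is_monophyletic(rooted, {"A", "B"})

    def test_interleaved_outgroup_fails_without_guessing(self):
        t = self.tree("((A:1,C:1):1,(B:1,D:1):1);")
        assert root_with_outgroup(t, {"A", "B"}) is None

    def test_single_leaf_outgroup_always_roots(self):
        t = self.tree("((A:1,B:1):1,(C:1,D:1):1);")
        assert root_with_outgroup(t, {"A"}) is not None

    def test_absent_outgroup_leaf_is_error(self):
        t = self.tree("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError):
            root_with_outgroup(t, {"Z"})


class TestMonophyly:
    def test_examples(self):
        t = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        t.is_rooted = True
        assert is_monophyletic(t, {"A", "B"})
        assert not is_monophyletic(t, {"A", "C"})
        assert is_monophyletic(t, {"A", "B", "C", "D"})  # the root

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dendropy_mrca_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        tops = enumerate_topologies(n)
        edges = tops[rng.integers(0, len(tops))]
        # build newick from the edge list by rooting at internal node i0
        adj = {}
        for u, v in edges:
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)

        def subtree(x, parent):
            kids = [y for y in adj[x] if y != parent]
            if not kids:
                return f"t{x}"
            return "(" + ",".join(subtree(y, x) for y in kids) + ")"

        newick = subtree("i0", None) + ";"
        tree = dendropy.Tree.get(data=newick, schema="newick")
        tree.is_rooted = True
        labels = [f"t{i}" for i in range(n)]
        for _ in range(8):
            k = int(rng.integers(1, n))
            query = set(rng.choice(labels, size=k, replace=False).tolist())
            taxa = [tree.taxon_namespace.get_taxon(x) for x in sorted(query)]
            mrca = tree.mrca(taxa=taxa)
            oracle = {l.taxon.label for l in mrca.leaf_iter()} == query
            assert is_monophyletic(tree, query) == oracle


class TestMonophylyReport:
    def test_clonal_genes_all_congruent(self, small_sim):
        from beepan.pangenome import extract_pan_orthologs
        from beepan.pipeline import family_alignment
        from beepan.sim import true_clusters

        cs = true_clusters(small_sim.truth)
        genomes = set(small_sim.truth.group_of_genome)
        pan = extract_pan_orthologs(cs, genomes)[:15]
        clonal = [
            f
            for f in pan
            if f not in {r["family"] for r in small_sim.truth.recombinants}
        ]
        trees = {
            fam: nj_tree(jc_distance(family_alignment(small_sim, cs.families[fam])))
            for fam in clonal
        }
        groups = {
            gid: {g for g, gr in small_sim.truth.group_of_genome.items() if gr == gid}
            for gid in ("A", "B")
        }
        report = monophyly_report(trees, groups, outgroup=groups["B"])
        assert int(report["incongruent"].sum()) == 0

    def test_whole_gene_intergroup_transfer_flagged(self, small_sim):
        from beepan.pangenome import extract_pan_orthologs
        from beepan.pipeline import family_alignment
        from beepan.sim import plant_recombination, true_clusters

        cs = true_clusters(small_sim.truth)
        genomes = set(small_sim.truth.group_of_genome)
        fam = extract_pan_orthologs(cs, genomes)[0]
        aln = family_alignment(small_sim, cs.families[fam])
        seqs = dict(zip(aln.taxa, aln.rows))
        # replace one group-A gene wholesale with a group-B donor copy
        seqs, _ = plant_recombination(seqs, "A1", "B1", (1, len(seqs["A1"])))
        tree = nj_tree(jc_distance(Alignment.from_dict(seqs)))
        groups = {
            gid: {g for g, gr in small_sim.truth.group_of_genome.items() if gr == gid}
            for gid in ("A", "B")
        }
        report = monophyly_report({fam: tree}, groups, outgroup={"B3"})
        row = report.iloc[0]
        assert row["status"] == "tested" and bool(row["incongruent"])

    def test_unrootable_gene_reported_untested(self):
        t = dendropy.Tree.get(data="((A:1,C:1):1,(B:1,D:1):1);", schema="newick")
        report = monophyly_report(
            {"g": t}, {"grp": {"A", "B"}}, outgroup={"A", "B"}
        )
        assert report.iloc[0]["status"] == "untested"
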