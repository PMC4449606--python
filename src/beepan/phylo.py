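"""Alignment handling, distance/NJ tree inference, rooting and monophyly tests.

Built-in tree inference is Jukes-Cantor distance + neighbor-joining with
column-bootstrap supports; externally built trees (Newick) can be substituted
at every consumer since the rooting/monophyly logic is engine-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .sim import translate_cds

GAP_CHARS = set("-")
MISSING_CHARS = set("NX?")


@dataclass
class Alignment:
    """Equal-length gapped rows with retained original column coordinates."""

    taxa: list[str]
    rows: list[str]
    columns: np.ndarray | None = None  # original 1-based positions

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon ids")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("rows have unequal lengths")
        if self.columns is None:
            self.columns = np.arange(1, self.width + 1)
        elif len(self.columns) != self.width:
            raise ValueError("column coordinates do not match width")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def matrix(self) -> np.ndarray:
        return np.frombuffer("".join(self.rows).encode(), dtype="S1").reshape(
            len(self.rows), self.width
        )

    @classmethod
    def from_dict(cls, seqs: dict[str, str]) -> "Alignment":
        taxa = sorted(seqs)
        return cls(taxa=taxa, rows=[seqs[t].upper() for t in taxa])

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(v, v.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("nonzero diagonal")
        if (v < 0).any() or not np.isfinite(v).all():
            raise ValueError("distances must be finite and >= 0")
        self.values = v


# ---------------------------------------------------------------------------
# alignment operations
# ---------------------------------------------------------------------------


def prune_gap_columns(aln: Alignment, threshold: float = 0.5) -> Alignment:
    """Drop columns whose gap fraction is >= threshold (default: 50% or more).

    Idempotent; survivor coordinates are retained.
    """
    mat = aln.matrix()
    gap = mat == b"-"
    frac = gap.mean(axis=0)
    keep = frac < threshold
    if not keep.any():
        raise ValueError("empty alignment after gap pruning")
    kept = mat[:, keep]
    return Alignment(
        taxa=list(aln.taxa),
        rows=[r.tobytes().decode() for r in kept],
        columns=aln.columns[keep],
    )


def backtranslate(protein_aln: Alignment, cds: dict[str, str]) -> Alignment:
    """Expand each protein column to its codon; protein gap -> '---'.

    Each CDS must be 3x the ungapped protein length (stop excluded) and
    translate to the protein under the bacterial code.
    """
    rows: list[str] = []
    for taxon, row in zip(protein_aln.taxa, protein_aln.rows):
        if taxon not in cds:
            raise ValueError(f"no CDS for taxon {taxon}")
        nt = cds[taxon].upper()
        prot = row.replace("-", "")
        if len(nt) != 3 * len(prot):
            raise ValueError(
                f"taxon {taxon}: CDS length {len(nt)} != 3 x {len(prot)} residues"
            )
        if translate_cds(nt) != prot:
            raise ValueError(f"taxon {taxon}: CDS does not translate to the protein")
        out = []
        k = 0
        for aa in row:
            if aa == "-":
                out.append("---")
            else:
                out.append(nt[3 * k : 3 * k + 3])
                k += 1
        rows.append("".join(out))
    cols = np.repeat(protein_aln.columns, 3) * 3 - np.tile(
        np.array([2, 1, 0]), protein_aln.width
    )
    return Alignment(taxa=list(protein_aln.taxa), rows=rows, columns=cols)


def concatenate(
    alignments: dict[str, Alignment], taxa: list[str]
) -> tuple[Alignment, dict[str, tuple[int, int]]]:
    """Concatenate family alignments in ascending family-id order.

    Returns the superalignment and a partition map of 1-based column spans.
    """
    rows = {t: [] for t in taxa}
    spans: dict[str, tuple[int, int]] = {}
    cursor = 0
    for fam in sorted(alignments):
        aln = alignments[fam]
        missing = set(taxa) - set(aln.taxa)
        if missing:
            raise ValueError(f"family {fam} missing taxa {sorted(missing)}")
        for t in taxa:
            rows[t].append(aln.row(t))
        spans[fam] = (cursor + 1, cursor + aln.width)
        cursor += aln.width
    return (
        Alignment(taxa=list(taxa), rows=["".join(rows[t]) for t in taxa]),
        spans,
    )


# ---------------------------------------------------------------------------
# distances and neighbor-joining
# ---------------------------------------------------------------------------

_JC_CAP = 5.0
_P_CAP = 0.749


def jc_distance(aln: Alignment) -> DistanceMatrix:
    """Jukes-Cantor distances: d = -(3/4) ln(1 - 4p/3) over shared columns.

    Gap and missing characters are excluded pairwise; p >= 0.749 caps the
    distance at 5.0; a pair with no shared columns is an error.
    """
    mat = aln.matrix()
    bad = np.isin(mat, [c.encode() for c in (GAP_CHARS | MISSING_CHARS)])
    n = len(aln.taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(bad[i] | bad[j])
            total = int(ok.sum())
            if total == 0:
                raise ValueError(
                    f"no shared columns between {aln.taxa[i]} and {aln.taxa[j]}"
                )
            p = float((mat[i, ok] != mat[j, ok]).sum()) / total
            if p >= _P_CAP:
                dist = _JC_CAP
            elif p == 0:
                dist = 0.0
            else:
                dist = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            d[i, j] = d[j, i] = min(dist, _JC_CAP)
    return DistanceMatrix(taxa=list(aln.taxa), values=d)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining by the standard Q-criterion.

    Ties in Q are broken by the smallest (row, column) index pair in the
    current matrix order; negative branch lengths are clamped to zero. The
    returned tree is unrooted.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor-joining requires >= 3 taxa")
    ns = dendropy.TaxonNamespace(dm.taxa)
    nodes: list[dendropy.Node] = []
    for t in dm.taxa:
        nd = dendropy.Node()
        nd.taxon = ns.get_taxon(t)
        nodes.append(nd)
    d = dm.values.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        parent = dendropy.Node()
        nodes[i].edge.length = max(0.0, li)
        nodes[j].edge.length = max(0.0, lj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        newd = np.zeros((m - 1, m - 1))
        keep = [k for k in range(m) if k not in (i, j)]
        for a, ka in enumerate(keep):
            for b, kb in enumerate(keep):
                newd[a, b] = d[ka, kb]
        for a, ka in enumerate(keep):
            nd_ = 0.5 * (d[i, ka] + d[j, ka] - d[i, j])
            newd[a, m - 2] = newd[m - 2, a] = max(0.0, nd_)
        nodes = [nodes[k] for k in keep] + [parent]
        d = newd

    # final three-point join
    center = dendropy.Node()
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    for node, length in zip(nodes, (la, lb, lc)):
        node.edge.length = max(0.0, length)
        center.add_child(node)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=center)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bipartitions, bootstrap, rooting, monophyly
# ---------------------------------------------------------------------------


def _leafsets(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    ls: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ls[node] = frozenset([node.taxon.label])
        else:
            acc: set[str] = set()
            for c in node.child_nodes():
                acc |= ls[c]
            ls[node] = frozenset(acc)
    return ls


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial bipartitions as canonical leaf sets (side without the
    lexicographically smallest leaf)."""
    ls = _leafsets(tree)
    all_leaves = ls[tree.seed_node]
    ref = min(all_leaves)
    out: set[frozenset[str]] = set()
    for node, leaves in ls.items():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = leaves if ref not in leaves else all_leaves - leaves
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(frozenset(side))
    return out


def bootstrap_support(
    aln: Alignment,
    n: int = 100,
    seed: int = 0,
    tree_builder=None,
) -> dendropy.Tree:
    """NJ tree with column-bootstrap supports (percent of replicates
    containing each internal bipartition of the full-data tree)."""
    if n < 1:
        raise ValueError("need at least one bootstrap replicate")
    build = tree_builder or (lambda a: nj_tree(jc_distance(a)))
    tree = build(aln)
    target = bipartitions(tree)
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    mat = aln.matrix()
    for _ in range(n):
        cols = rng.integers(0, aln.width, size=aln.width)
        rep_rows = [mat[i, cols].tobytes().decode() for i in range(len(aln.taxa))]
        rep = Alignment(taxa=list(aln.taxa), rows=rep_rows)
        for bp in bipartitions(build(rep)):
            if bp in counts:
                counts[bp] += 1
    ls = _leafsets(tree)
    all_leaves = ls[tree.seed_node]
    ref = min(all_leaves)
    for node, leaves in ls.items():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = leaves if ref not in leaves else all_leaves - leaves
        if frozenset(side) in counts:
            node.support = 100.0 * counts[frozenset(side)] / n
    return tree


def root_with_outgroup(
    tree: dendropy.Tree, outgroup: set[str]
) -> dendropy.Tree | None:
    """Root on the edge separating the outgroup from the rest, at its midpoint.

    Returns None when no single edge separates the outgroup (rooting not
    possible); raises if an outgroup leaf is absent from the tree.
    """
    work = tree.clone(depth=1)
    leaves = {l.taxon.label for l in work.leaf_node_iter()}
    missing = set(outgroup) - leaves
    if missing:
        raise ValueError(f"outgroup leaves not in tree: {sorted(missing)}")
    if not outgroup or set(outgroup) == leaves:
        return None
    og = frozenset(outgroup)
    ls = _leafsets(work)
    for node, below in ls.items():
        if node is work.seed_node:
            continue
        if below == og or leaves - below == og:
            length = node.edge.length or 0.0
            work.reroot_at_edge(node.edge, length1=length / 2, length2=length / 2)
            work.is_rooted = True
            return work
    return None


def is_monophyletic(tree: dendropy.Tree, leaf_set: set[str]) -> bool:
    """True iff some node's descendant-leaf set equals the query exactly."""
    if not leaf_set:
        raise ValueError("empty leaf set")
    ls = _leafsets(tree)
    present = ls[tree.seed_node]
    missing = set(leaf_set) - present
    if missing:
        raise ValueError(f"leaves not in tree: {sorted(missing)}")
    query = frozenset(leaf_set)
    return any(below == query for below in ls.values())


def monophyly_report(
    gene_trees: dict[str, dendropy.Tree],
    groups: dict[str, set[str]],
    outgroup: set[str],
) -> pd.DataFrame:
    """Test each group's monophyly on each rooted gene tree.

    Genes whose tree cannot be rooted with the outgroup are reported
    "untested"; incongruent = rooted and at least one group non-monophyletic.
    """
    rows = []
    for gene in sorted(gene_trees):
        tree = gene_trees[gene]
        leaves = {l.taxon.label for l in tree.leaf_node_iter()}
        og = set(outgroup) & leaves
        rooted = root_with_outgroup(tree, og) if og else None
        row: dict[str, object] = {"gene": gene}
        if rooted is None:
            row["status"] = "untested"
            for gid in groups:
                row[f"monophyletic_{gid}"] = None
            row["incongruent"] = False
        else:
            ok_all = True
            for gid, members in groups.items():
                present = set(members) & leaves
                mono = is_monophyletic(rooted, present) if present else None
                row[f"monophyletic_{gid}"] = mono
                if mono is False:
                    ok_all = False
            row["status"] = "tested"
            row["incongruent"] = not ok_all
        rows.append(row)
    return pd.DataFrame(rows)
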