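"""Protein-family inference: similarity graph construction and Markov clustering.

The built-in pairwise scorer lets synthetic runs proceed without an external
search engine; real-data runs supply a precomputed 12-column hits table
instead. Clustering is Markov clustering (expansion/inflation on a
column-stochastic matrix) at inflation 1.5, with the mean inter-genome edge
normalization that keeps between-species edge weights comparable to
within-species ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .io_formats import ClusterSet, SimilarityHit


@dataclass
class ClusteringParams:
    inflation: float = 1.5
    max_iterations: int = 100
    prune_threshold: float = 1e-6
    convergence_tol: float = 1e-8
    evalue_cap: float = 1e-200

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")


# ---------------------------------------------------------------------------
# pairwise scoring
# ---------------------------------------------------------------------------


def score_pairs(
    proteins: dict[str, str],
    min_identity: float = 50.0,
    min_coverage: float = 0.5,
) -> list[SimilarityHit]:
    """All-vs-all ungapped identity scoring of protein sequences.

    For a pair the identity is percent matching positions over the shorter
    sequence and coverage is shorter/longer length. A hit is emitted (in both
    directions) iff identity >= min_identity and coverage >= min_coverage,
    with e-value surrogate 10**(-identity) used downstream for edge weights.
    """
    ids = sorted(proteins)
    if any(len(proteins[g]) == 0 for g in ids):
        raise ValueError("empty protein sequence")
    by_len: dict[int, list[str]] = {}
    for g in ids:
        by_len.setdefault(len(proteins[g]), []).append(g)

    hits: list[SimilarityHit] = []

    def emit(q: str, s: str, ident: float, aln_len: int) -> None:
        ev = 10.0 ** (-ident)
        bs = ident * aln_len / 100.0
        hits.append(SimilarityHit(q, s, ident, aln_len, ev, bs))
        hits.append(SimilarityHit(s, q, ident, aln_len, ev, bs))

    lengths = sorted(by_len)
    for li, la in enumerate(lengths):
        ga = by_len[la]
        mat_a = np.frombuffer(
            "".join(proteins[g] for g in ga).encode(), dtype=np.uint8
        ).reshape(len(ga), la)
        for lb in lengths[li:]:
            if la / lb < min_coverage:
                continue
            gb = by_len[lb]
            mat_b = np.frombuffer(
                "".join(proteins[g][:la] for g in gb).encode(), dtype=np.uint8
            ).reshape(len(gb), la)
            coverage = la / lb
            # chunked identity over the shared prefix of length la
            chunk = max(1, 2_000_000 // max(1, la * len(gb)))
            for start in range(0, len(ga), chunk):
                blk = mat_a[start : start + chunk]
                matches = (blk[:, None, :] == mat_b[None, :, :]).sum(axis=2)
                ident = matches * (100.0 / la)
                qi, si = np.nonzero(ident >= min_identity)
                for q, s in zip(qi.tolist(), si.tolist()):
                    qg, sg = ga[start + q], gb[s]
                    if la == lb and (qg >= sg):
                        continue  # same bucket: count each unordered pair once
                    if coverage >= min_coverage:
                        emit(qg, sg, float(ident[q, s]), la)
    return hits


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------


def build_graph(
    hits: list[SimilarityHit],
    gene_genome: dict[str, str],
    params: ClusteringParams | None = None,
) -> nx.Graph:
    """Weighted similarity graph from a hits table.

    Edge weight starts as -log10(max(evalue, cap)), reciprocal hits averaged;
    each edge between genomes X and Y is then divided by the mean weight of
    all X-Y edges (when positive), equalizing scales across genome pairs.
    Self-hits never become edges.
    """
    params = params or ClusteringParams()
    raw: dict[tuple[str, str], list[float]] = {}
    for h in hits:
        if h.is_self:
            continue
        key = (h.query_gene, h.subject_gene) if h.query_gene < h.subject_gene else (
            h.subject_gene,
            h.query_gene,
        )
        w = -np.log10(max(h.evalue, params.evalue_cap))
        raw.setdefault(key, []).append(float(w))

    graph = nx.Graph()
    for gene, genome in gene_genome.items():
        graph.add_node(gene, genome=genome)
    pair_sums: dict[tuple[str, str], list[float]] = {}
    edges: list[tuple[str, str, float]] = []
    for (a, b), ws in raw.items():
        w = float(np.mean(ws))
        ga, gb = gene_genome.get(a, "?"), gene_genome.get(b, "?")
        pkey = (ga, gb) if ga < gb else (gb, ga)
        pair_sums.setdefault(pkey, []).append(w)
        edges.append((a, b, w))
    pair_mean = {k: float(np.mean(v)) for k, v in pair_sums.items()}
    for a, b, w in edges:
        ga, gb = gene_genome.get(a, "?"), gene_genome.get(b, "?")
        pkey = (ga, gb) if ga < gb else (gb, ga)
        mean = pair_mean.get(pkey, 0.0)
        if mean > 0:
            w = w / mean
        if w > 0:
            graph.add_edge(a, b, weight=w)
    return graph


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------


def _normalize_columns(m: sp.csc_matrix) -> sp.csc_matrix:
    sums = np.asarray(m.sum(axis=0)).ravel()
    sums[sums == 0] = 1.0
    d = sp.diags(1.0 / sums)
    return (m @ d).tocsc()


def mcl_cluster(graph: nx.Graph, params: ClusteringParams | None = None) -> ClusterSet:
    """Markov clustering of the similarity graph into protein families.

    Self-loops are set to each node's maximum incident edge weight (1 for
    isolated nodes); the column-stochastic matrix is iterated through
    expansion (matrix squaring) and inflation (element-wise power, renormalize,
    prune) until the maximum element change drops below the tolerance.
    Clusters are the connected components of the attractor support; nodes
    claimed by several clusters go to the largest (ties to the cluster with
    the lexicographically smallest member), and unclaimed nodes become
    singletons.
    """
    params = params or ClusteringParams()
    nodes = sorted(graph.nodes)
    if not nodes:
        raise ValueError("empty graph")
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    rows, cols, vals = [], [], []
    loop = np.zeros(n)  # max incident edge weight; isolated nodes get 1
    for a, b, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        ia, ib = index[a], index[b]
        rows += [ia, ib]
        cols += [ib, ia]
        vals += [w, w]
        loop[ia] = max(loop[ia], w)
        loop[ib] = max(loop[ib], w)
    loop[loop == 0] = 1.0
    rows += list(range(n))
    cols += list(range(n))
    vals += loop.tolist()
    m = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    m = _normalize_columns(m)

    converged = False
    for _ in range(params.max_iterations):
        expanded = (m @ m).tocsc()
        expanded.data = np.power(expanded.data, params.inflation)
        expanded.data[expanded.data < params.prune_threshold] = 0.0
        expanded.eliminate_zeros()
        expanded = _normalize_columns(expanded)
        delta = abs(expanded - m)
        change = delta.max() if delta.nnz else 0.0
        m = expanded
        if change < params.convergence_tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge in {params.max_iterations} iterations; "
            "clustering the last iterate",
            stacklevel=2,
        )

    clusters = _extract_clusters(m, n)
    genome_of = nx.get_node_attributes(graph, "genome")
    families: dict[str, list[tuple[str, str]]] = {}
    named = sorted(clusters, key=lambda c: min(nodes[i] for i in c))
    for k, cluster in enumerate(named):
        fam = f"fam{k + 1:05d}"
        families[fam] = sorted(
            (genome_of.get(nodes[i], "?"), nodes[i]) for i in cluster
        )
    return ClusterSet(families=families, genomes=set(genome_of.values()))


def _extract_clusters(m: sp.csc_matrix, n: int) -> list[set[int]]:
    """Attractor-support interpretation of a (near-)idempotent MCL matrix."""
    csr = m.tocsr()
    diag = csr.diagonal()
    attractors = np.nonzero(diag > 0)[0]
    supports = {int(i): set(csr.getrow(i).nonzero()[1].tolist()) for i in attractors}
    # union attractors whose supports overlap (connected components)
    parent = {int(i): int(i) for i in attractors}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    owner: dict[int, int] = {}
    for i in attractors:
        for j in supports[int(i)]:
            if j in supports:  # j is itself an attractor
                union(int(i), int(j))
    merged: dict[int, set[int]] = {}
    for i in attractors:
        merged.setdefault(find(int(i)), set()).update(supports[int(i)])
    candidates = list(merged.values())

    # resolve overlaps: largest cluster wins, ties by smallest member index
    assigned: dict[int, int] = {}
    order = sorted(
        range(len(candidates)), key=lambda c: (-len(candidates[c]), min(candidates[c]))
    )
    for ci in order:
        for node in candidates[ci]:
            if node not in assigned:
                assigned[node] = ci
    clusters: dict[int, set[int]] = {}
    for node, ci in assigned.items():
        clusters.setdefault(ci, set()).add(node)
    out = list(clusters.values())
    claimed = set(assigned)
    for i in range(n):
        if i not in claimed:
            out.append({i})
    return out
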