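"""Pairwise-comparison filtering, tree-ordered genome pairs, genome summary
statistics and low-GC island flagging.

Filter semantics are literal: "below X" excludes strictly smaller values
only, so identity exactly 80% and length exactly 200 bp pass the default
filter (the Firm-4 dialect lowers the length cutoff to 50 bp for more
distantly related strains).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import pandas as pd

from .io_formats import GeneAnnotation, GenomeRecord, SimilarityHit


@dataclass
class SyntenyFilter:
    min_identity: float = 80.0
    min_length: int = 200

    def __post_init__(self) -> None:
        if not 0 <= self.min_identity <= 100 or self.min_length < 1:
            raise ValueError("invalid filter bounds")


FIRM4_FILTER = SyntenyFilter(min_identity=80.0, min_length=50)


def filter_comparisons(
    hits: list[SimilarityHit], filt: SyntenyFilter | None = None
) -> list[SimilarityHit]:
    """Keep hits with identity >= min_identity and length >= min_length."""
    filt = filt or SyntenyFilter()
    return [
        h
        for h in hits
        if h.pct_identity >= filt.min_identity and h.aln_length >= filt.min_length
    ]


def ladderized_leaf_order(tree: dendropy.Tree) -> list[str]:
    """Deterministic leaf order: children sorted by subtree size, ties by the
    lexicographically smallest descendant leaf."""
    sizes: dict[dendropy.Node, int] = {}
    smallest: dict[dendropy.Node, str] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sizes[node] = 1
            smallest[node] = node.taxon.label
        else:
            sizes[node] = sum(sizes[c] for c in node.child_nodes())
            smallest[node] = min(smallest[c] for c in node.child_nodes())

    order: list[str] = []

    def walk(node: dendropy.Node) -> None:
        if node.is_leaf():
            order.append(node.taxon.label)
            return
        for c in sorted(node.child_nodes(), key=lambda c: (sizes[c], smallest[c])):
            walk(c)

    walk(tree.seed_node)
    return order


def order_pairs_by_tree(
    strains: list[str], tree: dendropy.Tree
) -> list[tuple[str, str]]:
    """Adjacent comparison pairs in the ladderized leaf order of the tree."""
    order = ladderized_leaf_order(tree)
    missing = set(strains) - set(order)
    if missing:
        raise ValueError(f"strains not in tree: {sorted(missing)}")
    kept = [s for s in order if s in set(strains)]
    return list(zip(kept, kept[1:]))


def _gc(seq: str) -> float:
    acgt = sum(1 for b in seq if b in "ACGT")
    if acgt == 0:
        return float("nan")
    return sum(1 for b in seq if b in "GC") / acgt


def gc_island_scan(
    genome: GenomeRecord,
    annotations: list[GeneAnnotation],
    window_genes: int = 5,
    delta: float = 0.04,
) -> pd.DataFrame:
    """Flag runs of consecutive genes whose pooled GC deviates from the
    genomic GC by >= delta; overlapping flagged windows are merged and
    reported with the pooled GC of the merged region."""
    genome_gc = _gc("".join(seq for _, seq in genome.contigs))
    rows = []
    for contig_id, seq in genome.contigs:
        genes = sorted(
            (g for g in annotations if g.genome_id == genome.genome_id and g.contig_id == contig_id),
            key=lambda g: g.start,
        )
        flagged: list[tuple[int, int]] = []  # gene index spans
        for i in range(0, max(0, len(genes) - window_genes + 1)):
            window = genes[i : i + window_genes]
            pooled = _gc("".join(seq[g.start - 1 : g.end] for g in window))
            if abs(pooled - genome_gc) >= delta:
                flagged.append((i, i + window_genes - 1))
        # merge overlapping windows
        merged: list[list[int]] = []
        for a, b in flagged:
            if merged and a <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        for a, b in merged:
            # windows straddling the island edge drag in unremarkable flank
            # genes; trim boundary genes that do not themselves deviate
            while a < b and abs(
                _gc(seq[genes[a].start - 1 : genes[a].end]) - genome_gc
            ) < delta:
                a += 1
            while b > a and abs(
                _gc(seq[genes[b].start - 1 : genes[b].end]) - genome_gc
            ) < delta:
                b -= 1
            region = genes[a : b + 1]
            pooled = _gc("".join(seq[g.start - 1 : g.end] for g in region))
            rows.append(
                {
                    "genome": genome.genome_id,
                    "contig": contig_id,
                    "start": region[0].start,
                    "end": region[-1].end,
                    "n_genes": len(region),
                    "region_gc": pooled,
                    "genome_gc": genome_gc,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["genome", "contig", "start", "end", "n_genes", "region_gc", "genome_gc"],
    )


def genome_summary(
    genome: GenomeRecord, annotations: list[GeneAnnotation], min_contig: int = 500
) -> dict:
    """Per-genome descriptive statistics.

    Size and GC are computed over contigs larger than `min_contig` bp; the
    CDS count excludes genes flagged partial or pseudogene; mean gene size is
    total included-CDS length / included-CDS count (None when no CDS
    qualifies).
    """
    included = [(cid, seq) for cid, seq in genome.contigs if len(seq) > min_contig]
    size = sum(len(seq) for _, seq in included)
    gc = _gc("".join(seq for _, seq in included)) if included else float("nan")
    cds = [
        g
        for g in annotations
        if g.genome_id == genome.genome_id
        and g.kind == "CDS"
        and not ({"partial", "pseudogene"} & set(g.flags))
    ]
    n_cds = len(cds)
    total_len = sum(g.length for g in cds)
    return {
        "genome": genome.genome_id,
        "size": size,
        "n_contigs": len(included),
        "gc": gc,
        "n_cds": n_cds,
        "mean_gene_size": (total_len / n_cds) if n_cds else None,
    }
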