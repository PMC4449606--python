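"""Readers and writers for every external representation the pipeline touches.

Conventions
-----------
* Coordinates are 1-based and inclusive throughout (GFF convention); code that
  needs 0-based half-open slices converts at the computation boundary.
* FASTA record ids are the first whitespace token of the header; the full
  header is kept as the description.
* ``N`` is a legal genome character and is treated as missing downstream.

Formats: FASTA (sequences), 12-column tab-separated similarity hits (the
common tabular dialect of sequence-search output), Newick (trees), a
groups-file cluster dialect (``famID: genome|gene genome|gene ...``) and a
tab-separated gene table.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import dendropy
from Bio import SeqIO

GENOME_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """Malformed input; the message names the offending line or token."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeRecord:
    """A (draft) genome: ordered contigs of upper-case nucleotide sequence."""

    genome_id: str
    contigs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cid, seq in self.contigs:
            if cid in seen:
                raise FormatError(f"duplicate contig id {cid} in genome {self.genome_id}")
            seen.add(cid)
            if not seq:
                raise FormatError(f"empty contig {cid} in genome {self.genome_id}")
            extra = set(seq) - GENOME_ALPHABET
            if extra:
                raise FormatError(
                    f"contig {cid}: illegal characters {sorted(extra)} (alphabet is A,C,G,T,N)"
                )

    def contig_seq(self, contig_id: str) -> str:
        for cid, seq in self.contigs:
            if cid == contig_id:
                return seq
        raise KeyError(contig_id)

    @property
    def length(self) -> int:
        return sum(len(s) for _, s in self.contigs)


@dataclass
class GeneAnnotation:
    """One gene on one contig; start/end are 1-based inclusive, end >= start."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    kind: str = "CDS"
    product: str = ""
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise FormatError(f"gene {self.gene_id}: end {self.end} < start {self.start}")
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: strand must be '+' or '-'")
        bad = set(self.flags) - {"partial", "pseudogene"}
        if bad:
            raise FormatError(f"gene {self.gene_id}: unknown flags {sorted(bad)}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SimilarityHit:
    query_gene: str
    subject_gene: str
    pct_identity: float
    aln_length: int
    evalue: float
    bitscore: float

    @property
    def is_self(self) -> bool:
        return self.query_gene == self.subject_gene


@dataclass
class ClusterSet:
    """family_id -> members as (genome_id, gene_id); the clustering pivot.

    A gene belongs to at most one family.
    """

    families: dict[str, list[tuple[str, str]]]
    genomes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for fam, members in self.families.items():
            for m in members:
                if m in seen:
                    raise FormatError(f"gene {m[1]} of {m[0]} appears in more than one family")
                seen.add(m)
        if not self.genomes:
            self.genomes = {g for mem in self.families.values() for g, _ in mem}

    def copy_numbers(self, family_id: str) -> dict[str, int]:
        counts: dict[str, int] = {}
        for genome, _ in self.families[family_id]:
            counts[genome] = counts.get(genome, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.families)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClusterSet):
            return NotImplemented
        a = {f: sorted(m) for f, m in self.families.items()}
        b = {f: sorted(m) for f, m in other.families.items()}
        return a == b and self.genomes == other.genomes


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, upper-case sequence)`` pairs.

    The id is the first whitespace token of the header. Raises
    :class:`FormatError` on an empty file or a duplicate id.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate id {rec.id}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records, path, width: int = 70) -> None:
    """Write ``(id, sequence)`` pairs, wrapping sequence lines at `width`."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# similarity hits (12-column tabular dialect)
# ---------------------------------------------------------------------------

_HIT_COLUMNS = 12


def read_hits_table(path) -> list[SimilarityHit]:
    """Parse a tab-separated >=12-column hits table.

    Columns: query, subject, identity, length, mismatches, gapopens, qstart,
    qend, sstart, send, evalue, bitscore. Extra columns are ignored.
    """
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < _HIT_COLUMNS:
                raise FormatError(
                    f"line {lineno}: expected >= {_HIT_COLUMNS} tab-separated columns, got {len(parts)}"
                )
            try:
                identity = float(parts[2])
                length = int(float(parts[3]))
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-numeric field ({exc})") from None
            if not (evalue == evalue and abs(evalue) != float("inf")):
                raise FormatError(f"line {lineno}: non-finite evalue")
            hits.append(
                SimilarityHit(
                    query_gene=parts[0],
                    subject_gene=parts[1],
                    pct_identity=identity,
                    aln_length=length,
                    evalue=evalue,
                    bitscore=bitscore,
                )
            )
    return hits


def write_hits_table(hits, path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_gene}\t{h.subject_gene}\t{h.pct_identity:.2f}\t{h.aln_length}"
                f"\t0\t0\t1\t{h.aln_length}\t1\t{h.aln_length}\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


# ---------------------------------------------------------------------------
# groups file (cluster dialect)
# ---------------------------------------------------------------------------


def read_clusters(path) -> ClusterSet:
    """Read a groups file: one family per line, ``famID: genome|gene ...``."""
    families: dict[str, list[tuple[str, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if ":" not in line:
                raise FormatError(f"line {lineno}: missing ':' after family id")
            fam, rest = line.split(":", 1)
            fam = fam.strip()
            if fam in families:
                raise FormatError(f"line {lineno}: duplicate family id {fam}")
            members: list[tuple[str, str]] = []
            for tok in rest.split():
                if "|" not in tok:
                    raise FormatError(f"line {lineno}: token '{tok}' lacks 'genome|gene' separator")
                genome, gene = tok.split("|", 1)
                members.append((genome, gene))
            families[fam] = members
    return ClusterSet(families=families)


def write_clusters(clusters: ClusterSet, path) -> None:
    with open(path, "w") as fh:
        for fam in sorted(clusters.families):
            toks = " ".join(f"{g}|{gene}" for g, gene in sorted(clusters.families[fam]))
            fh.write(f"{fam}: {toks}\n")


# ---------------------------------------------------------------------------
# gene table
# ---------------------------------------------------------------------------

_GENE_HEADER = ["genome", "contig", "gene", "start", "end", "strand", "kind", "flags"]


def read_gene_table(path) -> list[GeneAnnotation]:
    """Read the tab-separated gene table (header optional)."""
    genes: list[GeneAnnotation] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[:3] == _GENE_HEADER[:3]:
                continue
            if len(parts) < 8:
                raise FormatError(f"line {lineno}: expected 8 columns, got {len(parts)}")
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError:
                raise FormatError(f"line {lineno}: non-integer coordinates") from None
            flags = frozenset(f for f in parts[7].split(",") if f)
            key = (parts[0], parts[2])
            if key in seen:
                raise FormatError(f"line {lineno}: duplicate gene id {parts[2]} in genome {parts[0]}")
            seen.add(key)
            genes.append(
                GeneAnnotation(
                    gene_id=parts[2],
                    genome_id=parts[0],
                    contig_id=parts[1],
                    start=start,
                    end=end,
                    strand=parts[5],
                    kind=parts[6],
                    flags=flags,
                    product=parts[8] if len(parts) > 8 else "",
                )
            )
    return genes


def write_gene_table(genes, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_HEADER + ["product"]) + "\n")
        for g in genes:
            fh.write(
                f"{g.genome_id}\t{g.contig_id}\t{g.gene_id}\t{g.start}\t{g.end}"
                f"\t{g.strand}\t{g.kind}\t{','.join(sorted(g.flags))}\t{g.product}\n"
            )


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def read_newick(text: str) -> dendropy.Tree:
    """Parse one Newick tree; internal node labels are read as supports."""
    if text.count("(") != text.count(")"):
        raise FormatError("unbalanced parentheses in Newick string")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"Newick parse error: {exc}") from None
    # internal labels -> supports in [0, 100]
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and node.label is not None:
            try:
                node.support = float(node.label)
            except ValueError:
                node.support = None
    return tree


def read_newick_file(path) -> dendropy.Tree:
    with open(path) as fh:
        return read_newick(fh.read())


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize with branch lengths to 10 significant digits and supports."""
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            sup = getattr(node, "support", None)
            if sup is not None:
                node.label = f"{sup:g}"
    out = io.StringIO()
    tree.write(
        file=out,
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".10g",
    )
    text = out.getvalue().strip()
    # dendropy quotes labels containing spaces; the dialect forbids them anyway
    return re.sub(r"\s+", "", text)


def write_newick_file(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(tree) + "\n")
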