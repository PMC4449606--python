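"""Rule chain for phosphotransferase-system (PTS) transporter annotation.

A gene is positively called as a PTS transporter when it (1) has a hit to the
phosphotransfer-driven group translocators (TC family 4.A) at e-value <= 0.01,
(2) carries a PTS EII domain prediction, and (3) sits in an operon (maximal
same-strand run with intergenic gaps <= 200 bp) of at least two genes of
which at least two carry PTS domains. Called genes are assigned to one of the
seven PTS families 4.A.1-4.A.7 by their best (lowest e-value) hit. A Man
(4.A.6) operon is complete when its calls cover all four subunit roles
IIA/IIB/IIC/IID; a fused IIA-IIB gene counts for both roles.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

from .io_formats import GeneAnnotation

_TC_PATTERN = re.compile(r"^\d+\.[A-Za-z]+\.\d+")
PTS_CLASSES = ("PTS_EIIA", "PTS_EIIB", "PTS_EIIC", "PTS_EIID")
_ROLE_OF_CLASS = {
    "PTS_EIIA": "IIA",
    "PTS_EIIB": "IIB",
    "PTS_EIIC": "IIC",
    "PTS_EIID": "IID",
}


@dataclass
class TransporterHit:
    gene_id: str
    tc_id: str
    evalue: float

    def __post_init__(self) -> None:
        if not _TC_PATTERN.match(self.tc_id):
            raise ValueError(f"malformed TC id {self.tc_id}")

    @property
    def tc_family(self) -> str:
        return ".".join(self.tc_id.split(".")[:3])


@dataclass
class DomainCall:
    gene_id: str
    domain_id: str
    domain_class: str  # PTS_EIIA/B/C/D or "other"


@dataclass
class OperonModel:
    operon_id: str
    genome: str
    contig: str
    strand: str
    genes: list[str]
    max_gap: int


@dataclass
class PtsCall:
    gene_id: str
    genome: str
    family: str
    operon_id: str
    roles: frozenset[str]  # subunit roles; >1 entry for fused genes

    @property
    def role(self) -> str:
        if len(self.roles) == 1:
            return next(iter(self.roles))
        if self.roles:
            return "fused"
        return "unknown"


def load_domain_class_map() -> dict[str, str]:
    """Shipped editable map of domain accessions to PTS EII classes."""
    text = (
        resources.files("beepan").joinpath("data/pts_domains.tsv").read_text()
    )
    out: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        dom, cls = line.split("\t")[:2]
        out[dom] = cls
    return out


def filter_tc_hits(
    hits: list[TransporterHit], evalue_threshold: float = 0.01
) -> list[TransporterHit]:
    """Keep hits to family 4.A at e-value <= threshold (boundary retained)."""
    return [
        h
        for h in hits
        if (h.tc_id == "4.A" or h.tc_id.startswith("4.A.")) and h.evalue <= evalue_threshold
    ]


def infer_operons(
    annotations: list[GeneAnnotation], max_gap: int = 200
) -> list[OperonModel]:
    """Maximal same-strand CDS runs with intergenic gaps <= max_gap.

    Singleton runs are operons of size 1. Annotations are grouped per
    genome/contig and sorted by start coordinate.
    """
    by_contig: dict[tuple[str, str], list[GeneAnnotation]] = {}
    for g in annotations:
        if g.kind != "CDS":
            continue
        by_contig.setdefault((g.genome_id, g.contig_id), []).append(g)
    operons: list[OperonModel] = []
    serial = 0
    for (genome, contig) in sorted(by_contig):
        genes = sorted(by_contig[(genome, contig)], key=lambda g: (g.start, g.gene_id))
        run: list[GeneAnnotation] = []
        for g in genes:
            if run and (
                g.strand != run[-1].strand or g.start - run[-1].end - 1 > max_gap
            ):
                serial += 1
                operons.append(
                    OperonModel(
                        operon_id=f"op{serial:05d}",
                        genome=genome,
                        contig=contig,
                        strand=run[0].strand,
                        genes=[x.gene_id for x in run],
                        max_gap=max_gap,
                    )
                )
                run = []
            run.append(g)
        if run:
            serial += 1
            operons.append(
                OperonModel(
                    operon_id=f"op{serial:05d}",
                    genome=genome,
                    contig=contig,
                    strand=run[0].strand,
                    genes=[x.gene_id for x in run],
                    max_gap=max_gap,
                )
            )
    return operons


def call_pts(
    filtered_hits: list[TransporterHit],
    domain_calls: list[DomainCall],
    operons: list[OperonModel],
) -> list[PtsCall]:
    """Positive PTS calls under the operon + consistent-domain rule.

    A gene is called iff it has a filtered 4.A hit, a PTS EII domain class,
    and lies in an operon of >= 2 genes containing >= 2 PTS-domain genes.
    Family is that of the lowest-evalue hit (ties: numerically smallest
    family).
    """
    hits_by_gene: dict[str, list[TransporterHit]] = {}
    for h in filtered_hits:
        hits_by_gene.setdefault(h.gene_id, []).append(h)
    roles_by_gene: dict[str, set[str]] = {}
    for d in domain_calls:
        role = _ROLE_OF_CLASS.get(d.domain_class)
        if role is not None:
            roles_by_gene.setdefault(d.gene_id, set()).add(role)

    calls: list[PtsCall] = []
    for op in operons:
        if len(op.genes) < 2:
            continue
        pts_domain_genes = [g for g in op.genes if g in roles_by_gene]
        if len(pts_domain_genes) < 2:
            continue
        for gene in op.genes:
            if gene not in hits_by_gene or gene not in roles_by_gene:
                continue
            best = min(
                hits_by_gene[gene],
                key=lambda h: (h.evalue, _family_sort_key(h.tc_family)),
            )
            calls.append(
                PtsCall(
                    gene_id=gene,
                    genome=op.genome,
                    family=best.tc_family,
                    operon_id=op.operon_id,
                    roles=frozenset(roles_by_gene[gene]),
                )
            )
    return calls


def _family_sort_key(family: str) -> tuple:
    parts = family.split(".")
    return tuple(int(p) if p.isdigit() else p for p in parts)


def count_complete_man_operons(calls: list[PtsCall]) -> dict[str, int]:
    """Per-genome count of complete Man-family (4.A.6) operons.

    An operon is complete when its 4.A.6 calls cover all four roles; a fused
    IIA-IIB gene counts for both roles.
    """
    roles_by_operon: dict[tuple[str, str], set[str]] = {}
    for c in calls:
        if c.family != "4.A.6":
            continue
        roles_by_operon.setdefault((c.genome, c.operon_id), set()).update(c.roles)
    counts: dict[str, int] = {}
    for (genome, _), roles in roles_by_operon.items():
        if roles >= {"IIA", "IIB", "IIC", "IID"}:
            counts[genome] = counts.get(genome, 0) + 1
    return counts


def man_gene_counts(calls: list[PtsCall]) -> dict[str, int]:
    """Per-genome number of genes assigned to the Man family (4.A.6)."""
    out: dict[str, int] = {}
    for c in calls:
        if c.family == "4.A.6":
            out[c.genome] = out.get(c.genome, 0) + 1
    return out
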