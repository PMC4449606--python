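"""Core/accessory partitioning of protein families and functional tallies.

Definitions (all computed purely from cluster membership counts):

* pan-ortholog: exactly one member in every genome of the analyzed set; these
  families feed the concatenated core phylogeny.
* group core: exactly one copy in every strain of the group, with any number
  of additional members outside the group.
* group accessory: present in >= 1 but not all group strains, in any copy
  number (outside membership ignored); group-member singletons count as
  one-member accessory families.
* group-specific core: present in every group strain (any copy number) and
  absent from every non-group genome.

The functional-category rule: a gene is assigned a category iff exactly one
category collects >= 2 hits with e-value < 0.01; genes with several qualifying
categories stay unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .io_formats import ClusterSet


@dataclass
class GroupDefinition:
    groups: dict[str, set[str]]
    outgroups: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for gid, members in self.groups.items():
            if seen & members:
                raise ValueError(f"group {gid} overlaps another group")
            seen |= members

    def other_genomes(self, group_id: str, all_genomes: set[str]) -> set[str]:
        return all_genomes - self.groups[group_id]


def extract_pan_orthologs(clusters: ClusterSet, genome_set: set[str]) -> list[str]:
    """Families with exactly one member in every genome of the set."""
    if not genome_set:
        raise ValueError("empty genome set")
    out = []
    for fam in clusters.families:
        counts = clusters.copy_numbers(fam)
        if all(counts.get(g, 0) == 1 for g in genome_set):
            out.append(fam)
    return sorted(out)


def group_core(clusters: ClusterSet, group: set[str]) -> list[str]:
    """Single copy in every group strain; outside membership ignored."""
    out = []
    for fam in clusters.families:
        counts = clusters.copy_numbers(fam)
        if all(counts.get(g, 0) == 1 for g in group):
            out.append(fam)
    return sorted(out)


def group_accessory(clusters: ClusterSet, group: set[str]) -> list[str]:
    """Families with a proper nonempty subset of group strains, any copy number.

    A family single-copy in all group strains is core, not accessory; a family
    present in all group strains with a duplication in one of them is
    accessory (not "a single gene copy for each").
    """
    out = []
    for fam in clusters.families:
        counts = clusters.copy_numbers(fam)
        present = {g for g in group if counts.get(g, 0) > 0}
        if not present:
            continue
        if present == group and all(counts.get(g, 0) == 1 for g in group):
            continue  # group core
        out.append(fam)
    return sorted(out)


def group_specific_core(
    clusters: ClusterSet, group: set[str], other_genomes: set[str]
) -> list[str]:
    """Present in every group strain and absent from all non-group genomes."""
    out = []
    for fam in clusters.families:
        counts = clusters.copy_numbers(fam)
        if all(counts.get(g, 0) >= 1 for g in group) and not any(
            counts.get(g, 0) for g in other_genomes
        ):
            out.append(fam)
    return sorted(out)


def venn_partition(
    clusters: ClusterSet, accessory_families: list[str], group: set[str]
) -> dict[frozenset[str], int]:
    """Count accessory families per exact strain-subset region.

    Every family is counted exactly once, in the region equal to the set of
    group strains it touches; counts over all regions sum to the accessory
    family total.
    """
    if len(group) > 6:
        raise ValueError(
            "venn_partition supports at most 6 strains; use pairwise summaries"
        )
    regions: dict[frozenset[str], int] = {}
    for r in range(1, len(group) + 1):
        for combo in combinations(sorted(group), r):
            regions[frozenset(combo)] = 0
    for fam in accessory_families:
        counts = clusters.copy_numbers(fam)
        present = frozenset(g for g in group if counts.get(g, 0) > 0)
        if present:
            regions[present] += 1
    return regions


def assign_category(
    hits: list[tuple[str, float]],
    evalue_threshold: float = 0.01,
    min_proteins: int = 2,
) -> str | None:
    """COG-style assignment from (category, evalue) hits for one gene.

    Assign iff exactly one category has >= min_proteins hits below the
    threshold; several qualifying categories -> unassigned (None).
    """
    per_cat: dict[str, int] = {}
    for cat, ev in hits:
        if ev < evalue_threshold:
            per_cat[cat] = per_cat.get(cat, 0) + 1
    qualifying = [c for c, n in per_cat.items() if n >= min_proteins]
    if len(qualifying) == 1:
        return qualifying[0]
    return None


def accessory_function_fraction(
    clusters: ClusterSet,
    accessory_families: list[str],
    family_category: dict[str, str | None],
    category: str,
    strain: str,
) -> float | None:
    """Fraction of the strain's category-annotated accessory families that
    belong to `category`; None when no annotated accessory family is present
    (undefined)."""
    annotated = 0
    in_cat = 0
    for fam in accessory_families:
        if clusters.copy_numbers(fam).get(strain, 0) == 0:
            continue
        cat = family_category.get(fam)
        if cat is None:
            continue
        annotated += 1
        if cat == category:
            in_cat += 1
    if annotated == 0:
        return None
    return in_cat / annotated


def proteome_function_fraction(
    clusters: ClusterSet,
    family_category: dict[str, str | None],
    category: str,
    strain: str,
) -> float | None:
    """Whole-proteome contrast for :func:`accessory_function_fraction`."""
    return accessory_function_fraction(
        clusters, sorted(clusters.families), family_category, category, strain
    )
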