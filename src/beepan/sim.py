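"""Synthetic multi-group pangenome generator with exact ground truth.

Emulates the statistical structure of a honeybee-gut bacterial community:
several phylotype-like strain groups related by a clonal tree, a shared
single-copy core genome, gained/lost accessory families and occasional
paralogs, within-gene recombination tracts imported from distant donors,
CRISPR repeat-spacer arrays whose protospacers land preferentially within the
same group, and Man-family PTS transporter operons with accompanying hit and
domain tables.

Design notes
------------
* Substitution model is Jukes-Cantor; homologs never gain indels, so the
  "alignment" of a family is column-wise identity and ground truth is exact.
* Each genome is the concatenation of its gene sequences (reverse-complemented
  for minus-strand genes) with 100-bp random intergenic spacers; CRISPR arrays
  and protospacers live inside intergenic segments only, so they never disturb
  the gene-family ground truth.
* Every source of randomness flows through one ``numpy.random.Generator``
  seeded from the config, so an identical config yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .io_formats import GeneAnnotation, GenomeRecord

BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
STOP_CODONS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = [
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
]


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_TO_CODE[b] for b in seq], dtype=np.uint8)


def _decode(arr: np.ndarray) -> str:
    return "".join(BASES[i] for i in arr)


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_cds(cds: str) -> str:
    """Translate a stop-free CDS under the bacterial code."""
    return str(Seq(cds).translate(table=11))


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Minimal rooted tree used only inside the simulator."""

    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def edges(self) -> list["TreeNode"]:
        """All non-root nodes, i.e. the edges (node + its parent branch)."""
        out: list[TreeNode] = []
        for c in self.children:
            out.append(c)
            out.extend(c.edges())
        return out

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{node.length:.6f}"

        inner = ",".join(fmt(c) for c in self.children)
        return f"({inner});"


def pure_birth_tree(rng: np.random.Generator, names: list[str], mean_branch: float) -> TreeNode:
    """Yule-style tree: split a random leaf until all names placed;
    every branch length drawn Exponential(mean_branch)."""
    if not names:
        raise ValueError("at least one strain required per group")
    root = TreeNode(name=names[0])
    for name in names[1:]:
        leaves = root.leaves()
        target = leaves[rng.integers(0, len(leaves))]
        left = TreeNode(
            name=target.name, length=float(rng.exponential(mean_branch))
        )
        right = TreeNode(name=name, length=float(rng.exponential(mean_branch)))
        target.name = None
        target.children = [left, right]
    for edge in root.edges():
        if edge.length == 0.0:
            edge.length = float(rng.exponential(mean_branch))
    return root


def build_group_tree(
    rng: np.random.Generator,
    groups: list[tuple[str, int]],
    subs_within: float,
    subs_between: float,
) -> TreeNode:
    """Clonal strain tree: one pure-birth subtree per group hung on a root,
    with deep group-root branches so inter-group distances ~ subs_between."""
    root = TreeNode()
    for group_id, n in groups:
        if n < 1:
            raise ValueError(f"group {group_id} has no strains")
        names = [f"{group_id}{i + 1}" for i in range(n)]
        sub = pure_birth_tree(rng, names, subs_within)
        sub.length = subs_between / 2.0
        root.children.append(sub)
    if len(root.children) == 1:
        root = root.children[0]
        root.length = 0.0
    return root


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------


def _jc_branch(arr: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """One Jukes-Cantor branch: each site substitutes with probability
    (3/4)(1 - exp(-4t/3)), landing uniformly on one of the 3 other bases."""
    if t <= 0:
        return arr.copy()
    p = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
    out = arr.copy()
    hit = rng.random(arr.shape[0]) < p
    n_hit = int(hit.sum())
    if n_hit:
        out[hit] = (out[hit] + rng.integers(1, 4, size=n_hit).astype(np.uint8)) % 4
    return out


def evolve_gene(
    root_sequence: str,
    tree: TreeNode,
    rate: float = 1.0,
    rng: np.random.Generator | int = 0,
) -> dict[str, str]:
    """Evolve a sequence down a tree under Jukes-Cantor; returns leaf -> seq.

    Branch lengths are multiplied by `rate` (expected substitutions/site).
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out: dict[str, str] = {}

    def walk(node: TreeNode, arr: np.ndarray) -> None:
        arr = _jc_branch(arr, node.length * rate, rng)
        if node.is_leaf():
            out[node.name] = _decode(arr)
        else:
            for c in node.children:
                walk(c, arr)

    root_arr = _encode(root_sequence)
    if tree.is_leaf():
        walk(tree, root_arr)
    else:
        for c in tree.children:
            walk(c, _jc_branch(root_arr, tree.length * rate, rng))
    return out


def random_coding_sequence(rng: np.random.Generator, length: int) -> str:
    """Random CDS of sense codons (no start/stop handling; length % 3 == 0)."""
    if length % 3:
        raise ValueError("coding length must be a multiple of 3")
    idx = rng.integers(0, len(SENSE_CODONS), size=length // 3)
    return "".join(SENSE_CODONS[i] for i in idx)


def repair_stops(seq: str, reference: str) -> str:
    """Revert any in-frame stop codon to the reference codon (which is sense)."""
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for i, c in enumerate(codons):
        if c in STOP_CODONS:
            codons[i] = reference[3 * i : 3 * i + 3]
    return "".join(codons)


def plant_recombination(
    alignment: dict[str, str],
    recipient: str,
    donor: str,
    tract: tuple[int, int],
) -> tuple[dict[str, str], dict]:
    """Overwrite the recipient's sequence with the donor's over a tract.

    `tract` is 1-based inclusive within the gene. Returns the mosaic
    alignment and an event record.
    """
    if donor == recipient:
        raise ValueError("donor and recipient must differ")
    start, end = tract
    gene_len = len(alignment[recipient])
    if end < start - 1 or start < 1 or end > gene_len:
        raise ValueError(f"tract {tract} outside gene of length {gene_len}")
    mosaic = dict(alignment)
    rec = mosaic[recipient]
    mosaic[recipient] = rec[: start - 1] + alignment[donor][start - 1 : end] + rec[end:]
    event = {"recipient": recipient, "donor": donor, "start": start, "end": end}
    return mosaic, event


# ---------------------------------------------------------------------------
# CRISPR planting
# ---------------------------------------------------------------------------


def make_crispr_array(
    rng: np.random.Generator,
    n_repeats: int,
    repeat_length: int = 32,
    spacer_length: int = 33,
) -> dict:
    """Build an exact repeat-spacer array (r repeats, r-1 distinct spacers).

    Returns the array sequence plus 0-based repeat/spacer offsets within it.
    """
    repeat = _decode(rng.integers(0, 4, size=repeat_length).astype(np.uint8))
    spacers: list[str] = []
    while len(spacers) < n_repeats - 1:
        sp = _decode(rng.integers(0, 4, size=spacer_length).astype(np.uint8))
        if sp not in spacers:
            spacers.append(sp)
    parts: list[str] = []
    repeat_offsets: list[int] = []
    spacer_offsets: list[int] = []
    pos = 0
    for i in range(n_repeats):
        repeat_offsets.append(pos)
        parts.append(repeat)
        pos += repeat_length
        if i < n_repeats - 1:
            spacer_offsets.append(pos)
            parts.append(spacers[i])
            pos += spacer_length
    return {
        "seq": "".join(parts),
        "repeat": repeat,
        "spacers": spacers,
        "repeat_offsets": repeat_offsets,
        "spacer_offsets": spacer_offsets,
        "repeat_length": repeat_length,
        "spacer_length": spacer_length,
    }


def _deunanimize(bases: list[str], rng: np.random.Generator) -> str | None:
    """If every base in the boundary column agrees, return a different base."""
    if len(set(bases)) == 1:
        choices = [b for b in BASES if b != bases[0]]
        return choices[rng.integers(0, len(choices))]
    return None


def embed_array_in_flanks(
    array: dict, left: str, right: str, rng: np.random.Generator
) -> tuple[str, str, str, dict]:
    """Make the columns immediately flanking the repeat copies non-unanimous
    so planted array boundaries are locally unambiguous for any detector that
    extends repeats through conserved columns.

    Returns possibly adjusted (left, right, array_seq, array).
    """
    spacers = list(array["spacers"])
    # left-adjacent bases of each repeat copy: left-flank end, then spacer ends
    col = [left[-1]] + [sp[-1] for sp in spacers]
    fix = _deunanimize(col, rng)
    if fix is not None:
        spacers[0] = spacers[0][:-1] + fix
    # right-adjacent bases: spacer starts, then right-flank start
    col = [sp[0] for sp in spacers] + [right[0]]
    fix = _deunanimize(col, rng)
    if fix is not None:
        right = fix + right[1:]
    new = dict(array)
    new["spacers"] = spacers
    parts: list[str] = []
    for i in range(len(array["repeat_offsets"])):
        parts.append(array["repeat"])
        if i < len(spacers):
            parts.append(spacers[i])
    new["seq"] = "".join(parts)
    return left, right, new["seq"], new


def plant_crispr(
    genome_seq: str,
    position: int,
    array: dict,
    rng: np.random.Generator,
) -> tuple[str, dict]:
    """Insert an array into a genome sequence at a 0-based position.

    Returns the modified sequence and a record with 1-based absolute repeat
    and spacer coordinates.
    """
    left, right = genome_seq[:position], genome_seq[position:]
    lf = left[-1] if left else "A"
    rf = right[0] if right else "A"
    _, right_fix, arr_seq, array = embed_array_in_flanks(array, lf, rf, rng)
    if right and right_fix != rf:
        right = right_fix + right[1:]
    new_seq = left + arr_seq + right
    record = {
        "start": position + 1,
        "end": position + len(arr_seq),
        "repeat": array["repeat"],
        "spacers": array["spacers"],
        "repeat_coords": [
            (position + o + 1, position + o + array["repeat_length"])
            for o in array["repeat_offsets"]
        ],
        "spacer_coords": [
            (position + o + 1, position + o + array["spacer_length"])
            for o in array["spacer_offsets"]
        ],
    }
    return new_seq, record


def mutate_copy(seq: str, n_mismatches: int, rng: np.random.Generator) -> str:
    """Introduce exactly n mismatches at distinct positions."""
    if n_mismatches == 0:
        return seq
    arr = _encode(seq)
    pos = rng.choice(len(arr), size=n_mismatches, replace=False)
    arr[pos] = (arr[pos] + rng.integers(1, 4, size=n_mismatches).astype(np.uint8)) % 4
    return _decode(arr)


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------


@dataclass
class CrisprSimConfig:
    arrays_per_strain: int = 1
    repeats_per_array: int = 5
    repeat_length: int = 32
    spacer_length: int = 33
    proto_within_prob: float = 0.3
    proto_between_prob: float = 0.0
    proto_mismatches: int = 0


@dataclass
class PtsSimConfig:
    operons_per_strain: int = 2
    incomplete_per_strain: int = 1
    decoys_per_strain: int = 1
    subunit_lengths: tuple[int, int, int, int] = (480, 480, 840, 900)
    operon_gap: int = 50


@dataclass
class PangenomeSimConfig:
    """All knobs of the simulator; the defaults are the study conditions."""

    seed: int = 0
    groups: list[tuple[str, int]] = field(default_factory=lambda: [("A", 3), ("B", 3)])
    core_families: int = 200
    accessory_families: int = 150
    gene_length: int = 900
    subs_within: float = 0.02
    subs_between: float = 0.15
    loss_prob: float = 0.25
    paralog_fraction: float = 0.02
    paralog_divergence: float = 0.02
    recomb_fraction: float = 0.1
    tract_length: int = 300
    donor_divergence: float = 0.5
    intergenic_length: int = 100
    crispr: CrisprSimConfig = field(default_factory=CrisprSimConfig)
    pts: PtsSimConfig = field(default_factory=PtsSimConfig)
    tree_newick: str | None = None

    def validate(self) -> None:
        for p in (
            self.loss_prob,
            self.paralog_fraction,
            self.recomb_fraction,
            self.crispr.proto_within_prob,
            self.crispr.proto_between_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.core_families < 1 or self.gene_length < 3:
            raise ValueError("core_families and gene_length must be positive")
        if self.gene_length % 3 or self.tract_length % 3:
            raise ValueError("gene_length and tract_length must be codon multiples")
        if not self.groups:
            raise ValueError("at least one group required")
        for gid, n in self.groups:
            if n < 1:
                raise ValueError(f"group {gid} has 0 strains")


@dataclass
class GroundTruth:
    """The simulator's record of everything it planted."""

    tree_newick: str
    membership: dict[str, str]  # gene_id -> family_id
    gene_genome: dict[str, str]  # gene_id -> genome_id
    family_labels: dict[str, str]
    family_groups: dict[str, str]  # family -> group id (where confined)
    recombinants: list[dict]
    arrays: list[dict]  # per planted array: genome, contig, coords, spacers
    protospacers: list[dict]  # spacer provenance -> target genome/coords
    pts_operons: list[dict]  # planted operons with roles and completeness
    pts_genes: list[dict]  # every PTS-like gene: role, operon (or None = decoy)
    gene_categories: dict[str, str]  # gene -> fabricated functional category
    group_of_genome: dict[str, str]


@dataclass
class SimulatedPangenome:
    config: PangenomeSimConfig
    genomes: list[GenomeRecord]
    annotations: list[GeneAnnotation]
    proteins: dict[str, str]
    cds: dict[str, str]
    truth: GroundTruth
    category_hits: dict[str, list[tuple[str, float]]]


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

_CATEGORIES = list("CEGHIJKLMP")
_PTS_ROLES = ("IIA", "IIB", "IIC", "IID")


def _subtree_by_edge(tree: TreeNode, edge_index: int) -> TreeNode:
    return tree.edges()[edge_index]


def simulate_pangenome(config: PangenomeSimConfig) -> SimulatedPangenome:
    """Generate the full synthetic pangenome with ground truth.

    Deterministic: identical config (including seed) gives identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree = build_group_tree(rng, config.groups, config.subs_within, config.subs_between)
    strains = tree.leaf_names()
    group_of = {}
    for gid, n in config.groups:
        for i in range(n):
            group_of[f"{gid}{i + 1}"] = gid
    group_subtrees = {}
    if len(config.groups) > 1:
        for child in tree.children:
            gid = group_of[child.leaf_names()[0]]
            group_subtrees[gid] = child
    else:
        group_subtrees[config.groups[0][0]] = tree

    membership: dict[str, str] = {}
    gene_genome: dict[str, str] = {}
    family_labels: dict[str, str] = {}
    family_groups: dict[str, str] = {}
    recombinants: list[dict] = []
    pts_truth: list[dict] = []
    gene_categories: dict[str, str] = {}
    category_hits: dict[str, list[tuple[str, float]]] = {}

    # --- core families -----------------------------------------------------
    n_core = config.core_families
    core_ids = [f"core{i + 1:04d}" for i in range(n_core)]
    core_seqs: dict[str, dict[str, str]] = {}
    n_recomb = int(round(config.recomb_fraction * n_core))
    n_paralog = int(round(config.paralog_fraction * n_core))
    special = rng.choice(n_core, size=min(n_core, n_recomb + n_paralog), replace=False)
    recomb_set = {core_ids[i] for i in special[:n_recomb]}
    paralog_set = {core_ids[i] for i in special[n_recomb : n_recomb + n_paralog]}
    paralog_extra: dict[str, tuple[str, str]] = {}  # family -> (strain, seq)

    for fam in core_ids:
        root_seq = random_coding_sequence(rng, config.gene_length)
        leaf_seqs = evolve_gene(root_seq, tree, 1.0, rng)
        leaf_seqs = {k: repair_stops(v, root_seq) for k, v in leaf_seqs.items()}
        if fam in recomb_set:
            # import a tract from a distant donor: a strain of another group
            # when one exists (the community's between-phylotype transfer),
            # otherwise a synthetic lineage diverged by donor_divergence
            recipient = strains[rng.integers(0, len(strains))]
            foreign = [s for s in strains if group_of[s] != group_of[recipient]]
            aln = dict(leaf_seqs)
            if foreign:
                donor = foreign[int(rng.integers(0, len(foreign)))]
            else:
                donor_raw = _jc_branch(_encode(root_seq), config.donor_divergence, rng)
                aln["__donor__"] = repair_stops(_decode(donor_raw), root_seq)
                donor = "__donor__"
            n_codons = (config.gene_length - config.tract_length) // 3
            start = 3 * int(rng.integers(0, n_codons + 1)) + 1
            end = start + config.tract_length - 1
            aln, event = plant_recombination(aln, recipient, donor, (start, end))
            aln.pop("__donor__", None)
            leaf_seqs = aln
            recombinants.append(
                {
                    "family": fam,
                    "recipient": recipient,
                    "donor": donor,
                    "start": start,
                    "end": end,
                }
            )
        if fam in paralog_set:
            strain = strains[rng.integers(0, len(strains))]
            dup = _jc_branch(_encode(leaf_seqs[strain]), config.paralog_divergence, rng)
            paralog_extra[fam] = (strain, repair_stops(_decode(dup), leaf_seqs[strain]))
            family_labels[fam] = "paralog-carrier"
        else:
            family_labels[fam] = "core-all"
        core_seqs[fam] = leaf_seqs

    # --- accessory families -------------------------------------------------
    acc_ids = [f"acc{i + 1:04d}" for i in range(config.accessory_families)]
    acc_presence: dict[str, dict[str, str]] = {}
    acc_positions: dict[str, int] = {}
    for fam in acc_ids:
        gid = config.groups[int(rng.integers(0, len(config.groups)))][0]
        sub = group_subtrees[gid]
        while True:
            edges = [sub] + sub.edges()
            origin = edges[int(rng.integers(0, len(edges)))]
            # loss on each descendant edge independently
            carriers: list[str] = []

            def collect(node: TreeNode, alive: bool) -> None:
                if node.is_leaf():
                    if alive:
                        carriers.append(node.name)
                    return
                for c in node.children:
                    child_alive = alive and (rng.random() >= config.loss_prob)
                    collect(c, child_alive)

            if origin.is_leaf():
                carriers = [origin.name]
            else:
                for c in origin.children:
                    collect(c, rng.random() >= config.loss_prob)
            if carriers:
                break
        root_seq = random_coding_sequence(rng, config.gene_length)
        leaf_seqs = evolve_gene(root_seq, origin, 1.0, rng)
        seqs = {
            s: repair_stops(leaf_seqs[s], root_seq) for s in carriers
        }
        acc_presence[fam] = seqs
        acc_positions[fam] = int(rng.integers(0, n_core + 1))
        family_groups[fam] = gid
        group_strains = [s for s in strains if group_of[s] == gid]
        if len(seqs) == 1:
            family_labels[fam] = "singleton"
        elif set(seqs) == set(group_strains):
            family_labels[fam] = "group-core"
        else:
            family_labels[fam] = "group-accessory"

    for fam in core_ids:
        family_groups[fam] = ""  # shared across all groups

    # --- per-genome gene layout --------------------------------------------
    core_order = list(core_ids)
    rng.shuffle(core_order)
    # accessory families slot after a fixed core index, same in every carrier
    slot_map: dict[int, list[str]] = {}
    for fam in acc_ids:
        slot_map.setdefault(acc_positions[fam], []).append(fam)

    genomes: list[GenomeRecord] = []
    annotations: list[GeneAnnotation] = []
    proteins: dict[str, str] = {}
    cds_store: dict[str, str] = {}
    arrays_truth: list[dict] = []
    proto_truth: list[dict] = []
    pts_gene_records: list[dict] = []

    # pre-build per-strain item lists (family, seq, role, block)
    genome_items: dict[str, list[dict]] = {}
    pts_counter = 0
    for strain in strains:
        items: list[dict] = []
        for slot in range(n_core + 1):
            for fam in slot_map.get(slot, ()):  # accessory at this slot
                if strain in acc_presence[fam]:
                    items.append({"family": fam, "seq": acc_presence[fam][strain]})
            if slot < n_core:
                fam = core_order[slot]
                items.append({"family": fam, "seq": core_seqs[fam][strain]})
                if fam in paralog_extra and paralog_extra[fam][0] == strain:
                    items.append({"family": fam, "seq": paralog_extra[fam][1], "paralog": True})
        # planted PTS blocks: operons, incomplete operons, decoys
        blocks: list[list[dict]] = []
        cfg = config.pts
        for _ in range(cfg.operons_per_strain):
            pts_counter += 1
            block = []
            for role, length in zip(_PTS_ROLES, cfg.subunit_lengths):
                block.append(
                    {
                        "family": None,
                        "seq": random_coding_sequence(rng, length),
                        "pts_role": role,
                        "pts_block": f"ptsop{pts_counter}",
                        "pts_complete": True,
                    }
                )
            blocks.append(block)
        for _ in range(cfg.incomplete_per_strain):
            pts_counter += 1
            block = []
            for role, length in zip(_PTS_ROLES[:3], cfg.subunit_lengths[:3]):
                block.append(
                    {
                        "family": None,
                        "seq": random_coding_sequence(rng, length),
                        "pts_role": role,
                        "pts_block": f"ptsop{pts_counter}",
                        "pts_complete": False,
                    }
                )
            blocks.append(block)
        for _ in range(cfg.decoys_per_strain):
            pts_counter += 1
            blocks.append(
                [
                    {
                        "family": None,
                        "seq": random_coding_sequence(rng, 600),
                        "pts_role": "IIC",
                        "pts_block": None,  # isolated: not in a PTS operon
                        "pts_decoy": True,
                    }
                ]
            )
        # insert blocks at spaced-out positions so no two blocks are adjacent
        if items:
            positions = sorted(
                rng.choice(len(items), size=min(len(blocks), len(items)), replace=False),
                reverse=True,
            )
            for pos, block in zip(positions, blocks):
                items[pos:pos] = block
        else:
            for block in blocks:
                items.extend(block)
        genome_items[strain] = items

    # --- CRISPR arrays and protospacer planting decisions -------------------
    ccfg = config.crispr
    strain_arrays: dict[str, list[dict]] = {}
    for strain in strains:
        strain_arrays[strain] = [
            make_crispr_array(
                rng, ccfg.repeats_per_array, ccfg.repeat_length, ccfg.spacer_length
            )
            for _ in range(ccfg.arrays_per_strain)
        ]
    plant_plan: dict[str, list[dict]] = {s: [] for s in strains}
    for strain in strains:
        for ai, array in enumerate(strain_arrays[strain]):
            for si, sp in enumerate(array["spacers"]):
                same = [s for s in strains if s != strain and group_of[s] == group_of[strain]]
                other = [s for s in strains if group_of[s] != group_of[strain]]
                if same and rng.random() < ccfg.proto_within_prob:
                    target = same[int(rng.integers(0, len(same)))]
                    plant_plan[target].append(
                        {
                            "source_genome": strain,
                            "array_index": ai,
                            "spacer_index": si,
                            "seq": mutate_copy(sp, ccfg.proto_mismatches, rng),
                            "mismatches": ccfg.proto_mismatches,
                        }
                    )
                if other and rng.random() < ccfg.proto_between_prob:
                    target = other[int(rng.integers(0, len(other)))]
                    plant_plan[target].append(
                        {
                            "source_genome": strain,
                            "array_index": ai,
                            "spacer_index": si,
                            "seq": mutate_copy(sp, ccfg.proto_mismatches, rng),
                            "mismatches": ccfg.proto_mismatches,
                        }
                    )

    # --- assembly ------------------------------------------------------------
    for strain in strains:
        items = genome_items[strain]
        # strand assignment: PTS operon blocks on '+', their neighbours on '-',
        # everything else random
        strands = [None] * len(items)
        for i, it in enumerate(items):
            if it.get("pts_block") or it.get("pts_decoy"):
                strands[i] = "+"
        for i, it in enumerate(items):
            if it.get("pts_block") or it.get("pts_decoy"):
                for j in (i - 1, i + 1):
                    if 0 <= j < len(items) and strands[j] is None:
                        strands[j] = "-"
        for i in range(len(items)):
            if strands[i] is None:
                strands[i] = "+" if rng.random() < 0.5 else "-"

        n_gaps = len(items) + 1
        # choose intergenic gaps hosting arrays / protospacers (all distinct)
        my_arrays = strain_arrays[strain]
        my_plants = plant_plan[strain]
        n_special = len(my_arrays) + len(my_plants)
        special_gaps = rng.choice(n_gaps, size=min(n_special, n_gaps), replace=False)
        array_gaps = {int(g): a for g, a in zip(special_gaps[: len(my_arrays)], my_arrays)}
        plant_gaps = {
            int(g): p for g, p in zip(special_gaps[len(my_arrays) :], my_plants)
        }

        parts: list[str] = []
        pos = 0  # 0-based cursor
        gene_serial = 0

        def intergenic(gap_index: int) -> None:
            nonlocal pos
            base = _decode(
                rng.integers(0, 4, size=config.intergenic_length).astype(np.uint8)
            )
            if gap_index in array_gaps:
                half = len(base) // 2
                left, right = base[:half], base[half:]
                mid_pos = pos + half
                seq2, record = plant_crispr(left + right, half, array_gaps[gap_index], rng)
                # shift coords to absolute
                shift = pos
                arrays_truth.append(
                    {
                        "genome": strain,
                        "contig": "c1",
                        "start": record["start"] + shift,
                        "end": record["end"] + shift,
                        "repeat": record["repeat"],
                        "spacers": record["spacers"],
                        "repeat_coords": [
                            (a + shift, b + shift) for a, b in record["repeat_coords"]
                        ],
                        "spacer_coords": [
                            (a + shift, b + shift) for a, b in record["spacer_coords"]
                        ],
                    }
                )
                parts.append(seq2)
                pos += len(seq2)
            elif gap_index in plant_gaps:
                plan = plant_gaps[gap_index]
                w = len(plan["seq"])
                at = (len(base) - w) // 2
                seq2 = base[:at] + plan["seq"] + base[at + w :]
                proto_truth.append(
                    {
                        **{k: plan[k] for k in ("source_genome", "array_index", "spacer_index", "mismatches")},
                        "target_genome": strain,
                        "target_contig": "c1",
                        "start": pos + at + 1,
                        "end": pos + at + w,
                    }
                )
                parts.append(seq2)
                pos += len(seq2)
            else:
                parts.append(base)
                pos += len(base)

        prev_block = None
        for i, it in enumerate(items):
            block = it.get("pts_block")
            if i == 0:
                intergenic(0)
            elif block is not None and block == prev_block:
                gap = _decode(
                    rng.integers(0, 4, size=config.pts.operon_gap).astype(np.uint8)
                )
                parts.append(gap)
                pos += len(gap)
            else:
                intergenic(i)
            gene_serial += 1
            gene_id = f"{strain}_g{gene_serial:05d}"
            seq = it["seq"]
            start = pos + 1
            end = pos + len(seq)
            strand = strands[i]
            parts.append(seq if strand == "+" else revcomp(seq))
            pos = end
            fam = it["family"]
            if fam is None:
                fam = f"sgl_{gene_id}"
                membership[gene_id] = fam
                family_labels[fam] = "singleton"
                family_groups[fam] = group_of[strain]
            else:
                membership[gene_id] = fam
            gene_genome[gene_id] = strain
            annotations.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    genome_id=strain,
                    contig_id="c1",
                    start=start,
                    end=end,
                    strand=strand,
                    kind="CDS",
                )
            )
            cds_store[gene_id] = seq
            proteins[gene_id] = translate_cds(seq)
            it["gene_id"] = gene_id
            prev_block = block
        intergenic(len(items))
        genomes.append(GenomeRecord(genome_id=strain, contigs=[("c1", "".join(parts))]))

        # PTS ground truth for this strain
        by_block: dict[str, list[dict]] = {}
        for it in items:
            if it.get("pts_role"):
                pts_gene_records.append(
                    {
                        "gene": it["gene_id"],
                        "genome": strain,
                        "role": it["pts_role"],
                        "operon": it.get("pts_block"),
                        "decoy": bool(it.get("pts_decoy")),
                    }
                )
            if it.get("pts_block"):
                by_block.setdefault(it["pts_block"], []).append(it)
        for block_id, members in by_block.items():
            pts_truth.append(
                {
                    "operon_id": block_id,
                    "genome": strain,
                    "genes": [m["gene_id"] for m in members],
                    "roles": [m["pts_role"] for m in members],
                    "family": "4.A.6",
                    "complete": all(m.get("pts_complete") for m in members)
                    and set(m["pts_role"] for m in members) == set(_PTS_ROLES),
                }
            )

    # --- fabricated functional categories (COG-like) -------------------------
    fam_category: dict[str, str] = {}
    for fam in core_ids + acc_ids:
        if rng.random() < 0.6:
            fam_category[fam] = _CATEGORIES[int(rng.integers(0, len(_CATEGORIES)))]
    for gene_id, fam in membership.items():
        if fam.startswith("sgl_"):
            # PTS and decoy genes read as carbohydrate transport
            cat = "G"
        else:
            cat = fam_category.get(fam)
        if cat is not None:
            gene_categories[gene_id] = cat
            category_hits[gene_id] = [(cat, 1e-5), (cat, 1e-4)]

    truth = GroundTruth(
        tree_newick=tree.newick(),
        membership=membership,
        gene_genome=gene_genome,
        family_labels=family_labels,
        family_groups=family_groups,
        recombinants=recombinants,
        arrays=arrays_truth,
        protospacers=proto_truth,
        pts_operons=pts_truth,
        pts_genes=pts_gene_records,
        gene_categories=gene_categories,
        group_of_genome=group_of,
    )
    return SimulatedPangenome(
        config=config,
        genomes=genomes,
        annotations=annotations,
        proteins=proteins,
        cds=cds_store,
        truth=truth,
        category_hits=category_hits,
    )


_ROLE_ACCESSION = {
    "IIA": ("PF00358", "PTS_EIIA"),
    "IIB": ("PF02302", "PTS_EIIB"),
    "IIC": ("PF02378", "PTS_EIIC"),
    "IID": ("PF03613", "PTS_EIID"),
}


def pts_input_tables(truth: GroundTruth):
    """TC-hit and domain-call tables implied by the planted PTS genes.

    Every PTS-like gene (operon members and isolated decoys alike) gets a
    strong hit to 4.A.6 and a matching EII domain call, so the operon rule is
    what separates true calls from decoys.
    """
    from .pts import DomainCall, TransporterHit

    hits = []
    domains = []
    for rec in truth.pts_genes:
        hits.append(TransporterHit(gene_id=rec["gene"], tc_id="4.A.6", evalue=1e-30))
        acc, cls = _ROLE_ACCESSION[rec["role"]]
        domains.append(DomainCall(gene_id=rec["gene"], domain_id=acc, domain_class=cls))
    return hits, domains


def true_clusters(truth: GroundTruth):
    """ClusterSet implied by the ground-truth membership (the recovery oracle)."""
    from .io_formats import ClusterSet

    fams: dict[str, list[tuple[str, str]]] = {}
    for gene_id, fam in truth.membership.items():
        fams.setdefault(fam, []).append((truth.gene_genome[gene_id], gene_id))
    return ClusterSet(families=fams, genomes=set(truth.gene_genome.values()))


# ---------------------------------------------------------------------------
# small stand-alone simulations for the recombination experiments
# ---------------------------------------------------------------------------


def clonal_gene_set(
    n_genes: int,
    n_taxa: int = 8,
    gene_length: int = 600,
    subs_within: float = 0.02,
    subs_between: float = 0.15,
    seed: int = 0,
) -> list[dict[str, str]]:
    """Clonal (recombination-free) gene alignments on a shared two-clade tree.

    Used for type-I-error calibration of the recombination statistics.
    """
    rng = np.random.default_rng(seed)
    half = n_taxa // 2
    tree = build_group_tree(
        rng, [("L", half), ("R", n_taxa - half)], subs_within, subs_between
    )
    out = []
    for _ in range(n_genes):
        root = random_coding_sequence(rng, gene_length)
        out.append(evolve_gene(root, tree, 1.0, rng))
    return out


def recombinant_gene_set(
    n_genes: int,
    n_taxa: int = 8,
    gene_length: int = 900,
    tract_length: int = 300,
    subs_within: float = 0.02,
    subs_between: float = 0.15,
    seed: int = 0,
) -> list[dict[str, str]]:
    """Gene alignments each carrying one tract imported from a distant donor:
    a taxon of the opposite clade of the two-clade tree, mirroring
    between-phylotype transfer in the community."""
    rng = np.random.default_rng(seed)
    half = n_taxa // 2
    tree = build_group_tree(
        rng, [("L", half), ("R", n_taxa - half)], subs_within, subs_between
    )
    taxa = tree.leaf_names()
    out = []
    for _ in range(n_genes):
        root = random_coding_sequence(rng, gene_length)
        aln = evolve_gene(root, tree, 1.0, rng)
        recipient = taxa[int(rng.integers(0, len(taxa)))]
        foreign = [t for t in taxa if t[0] != recipient[0]]
        donor = foreign[int(rng.integers(0, len(foreign)))]
        start = 3 * int(rng.integers(0, (gene_length - tract_length) // 3 + 1)) + 1
        aln, _ = plant_recombination(
            aln, recipient, donor, (start, start + tract_length - 1)
        )
        out.append(aln)
    return out
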