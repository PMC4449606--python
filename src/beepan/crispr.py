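"""CRISPR array detection, spacer extraction, masked-database protospacer
search and the within/between-group hit tally.

Detection: exact seed k-mers recurring at a near-regular period within the
allowed repeat+spacer length window are chained into candidate arrays; each
candidate's repeat is extended to maximal length through columns where every
copy agrees, then validated against the configured repeat/spacer length
ranges. Planted exact arrays are recovered with exact coordinates.

The protospacer search is an exact Hamming scan (no indels) of both strands
of the spacer-masked genomes, accelerated by chunk pigeonholing: a full-length
match with <= k mismatches must contain at least one exact chunk when the
spacer is cut into k+1 pieces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_formats import GenomeRecord
from .sim import revcomp


@dataclass
class CrisprParams:
    repeat_min: int = 23
    repeat_max: int = 55
    spacer_min: int = 20
    spacer_max: int = 60
    min_repeats: int = 3  # fewer (== 2) -> status "questionable"
    min_copy_identity: float = 0.8
    seed_k: int = 16
    max_mismatches: int = 2

    def __post_init__(self) -> None:
        if self.repeat_min > self.repeat_max or self.spacer_min > self.spacer_max:
            raise ValueError("length ranges must be ordered")
        if not 0 < self.min_copy_identity <= 1:
            raise ValueError("min_copy_identity must be in (0, 1]")

    @property
    def period_min(self) -> int:
        return self.repeat_min + self.spacer_min

    @property
    def period_max(self) -> int:
        return self.repeat_max + self.spacer_max


@dataclass
class CrisprArray:
    genome: str
    contig: str
    start: int  # 1-based inclusive
    end: int
    repeat: str
    repeat_coords: list[tuple[int, int]]
    spacer_coords: list[tuple[int, int]]
    spacers: list[str]
    status: str  # confirmed | questionable

    @property
    def n_repeats(self) -> int:
        return len(self.repeat_coords)


@dataclass
class SpacerHit:
    spacer_id: str
    target_genome: str
    target_contig: str
    position: int  # 1-based start on the forward strand
    strand: str
    mismatches: int
    same_group: bool | None = None


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def _seed_chains(seq: str, params: CrisprParams) -> list[list[int]]:
    """Maximal runs of identical k-mers recurring at in-range periods."""
    k = params.seed_k
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    chains = []
    for kmer in sorted(index):
        pos = index[kmer]
        if len(pos) < 2:
            continue
        run = [pos[0]]
        for p in pos[1:]:
            gap = p - run[-1]
            if params.period_min <= gap <= params.period_max:
                run.append(p)
            else:
                if len(run) >= 2:
                    chains.append(run)
                run = [p]
        if len(run) >= 2:
            chains.append(run)
    return chains


def _extend_chain(seq: str, chain: list[int], k: int) -> tuple[list[int], int]:
    """Extend the seed copies left/right through unanimous columns.

    Returns (copy start positions, repeat length). Extension never crosses a
    neighbouring copy.
    """
    max_left = min(chain[0], min(chain[i] - (chain[i - 1] + k) for i in range(1, len(chain))))
    left = 0
    while left < max_left:
        col = {seq[p - left - 1] for p in chain}
        if len(col) != 1:
            break
        left += 1
    max_right = min(
        len(seq) - (chain[-1] + k),
        min(chain[i] - (chain[i - 1] + k) for i in range(1, len(chain))) - left,
    )
    right = 0
    while right < max_right:
        col = {seq[p + k + right] for p in chain}
        if len(col) != 1:
            break
        right += 1
    starts = [p - left for p in chain]
    return starts, k + left + right


def _validate_candidate(
    seq: str, starts: list[int], rep_len: int, params: CrisprParams
) -> dict | None:
    if not (params.repeat_min <= rep_len <= params.repeat_max):
        return None
    spacers = []
    for a, b in zip(starts, starts[1:]):
        sp = seq[a + rep_len : b]
        if not (params.spacer_min <= len(sp) <= params.spacer_max):
            return None
        spacers.append(sp)
    for s1, s2 in zip(spacers, spacers[1:]):
        if s1 == s2:
            return None
    consensus = seq[starts[0] : starts[0] + rep_len]
    for a in starts:
        copy = seq[a : a + rep_len]
        ident = sum(x == y for x, y in zip(copy, consensus)) / rep_len
        if ident < params.min_copy_identity:
            return None
    return {"starts": starts, "rep_len": rep_len, "spacers": spacers, "repeat": consensus}


def detect_arrays(
    genome: GenomeRecord, params: CrisprParams | None = None
) -> list[CrisprArray]:
    """Detect repeat-spacer arrays on both strands, reported on forward
    coordinates; overlapping candidates are merged keeping the higher repeat
    count."""
    params = params or CrisprParams()
    out: list[CrisprArray] = []
    for contig_id, seq in genome.contigs:
        candidates: dict[tuple, dict] = {}
        for strand_seq, is_rc in ((seq, False), (revcomp(seq), True)):
            for chain in _seed_chains(strand_seq, params):
                starts, rep_len = _extend_chain(strand_seq, chain, params.seed_k)
                cand = _validate_candidate(strand_seq, starts, rep_len, params)
                if cand is None:
                    continue
                if is_rc:
                    n = len(strand_seq)
                    fwd_starts = sorted(n - (a + rep_len) for a in cand["starts"])
                    cand = _validate_candidate(seq, fwd_starts, rep_len, params)
                    if cand is None:
                        continue
                key = (cand["starts"][0], cand["starts"][-1] + cand["rep_len"])
                prev = candidates.get(key)
                if prev is None or len(cand["starts"]) > len(prev["starts"]):
                    candidates[key] = cand
        merged = _merge_overlaps(list(candidates.values()))
        for cand in merged:
            starts, rep_len = cand["starts"], cand["rep_len"]
            status = "confirmed" if len(starts) >= params.min_repeats else "questionable"
            spacer_coords = [
                (a + rep_len + 1, b) for a, b in zip(starts, starts[1:])
            ]
            out.append(
                CrisprArray(
                    genome=genome.genome_id,
                    contig=contig_id,
                    start=starts[0] + 1,
                    end=starts[-1] + rep_len,
                    repeat=cand["repeat"],
                    repeat_coords=[(a + 1, a + rep_len) for a in starts],
                    spacer_coords=spacer_coords,
                    spacers=cand["spacers"],
                    status=status,
                )
            )
    out.sort(key=lambda a: (a.contig, a.start))
    return out


def _merge_overlaps(cands: list[dict]) -> list[dict]:
    """Keep the higher-repeat-count candidate among overlapping ones."""
    cands = sorted(
        cands, key=lambda c: (-len(c["starts"]), c["starts"][0])
    )
    kept: list[dict] = []
    for cand in cands:
        s, e = cand["starts"][0], cand["starts"][-1] + cand["rep_len"]
        if all(
            e <= k["starts"][0] or s >= k["starts"][-1] + k["rep_len"] for k in kept
        ):
            kept.append(cand)
    return sorted(kept, key=lambda c: c["starts"][0])


# ---------------------------------------------------------------------------
# spacers, masking, protospacer search
# ---------------------------------------------------------------------------


def extract_spacers(
    arrays: list[CrisprArray],
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Spacer FASTA records plus per-region (per-array) spacer counts."""
    records: list[tuple[str, str]] = []
    rows = []
    per_genome_serial: dict[str, int] = {}
    for array in arrays:
        serial = per_genome_serial.get(array.genome, 0) + 1
        per_genome_serial[array.genome] = serial
        for i, sp in enumerate(array.spacers):
            records.append((f"{array.genome}.{array.contig}.array{serial}.spacer{i + 1}", sp))
        rows.append(
            {
                "genome": array.genome,
                "contig": array.contig,
                "region": serial,
                "status": array.status,
                "n_spacers": len(array.spacers),
            }
        )
    return records, pd.DataFrame(rows)


def mask_spacers(
    genomes: list[GenomeRecord], arrays: list[CrisprArray]
) -> list[GenomeRecord]:
    """Replace every spacer interval with 'N's of equal length (idempotent)."""
    by_target: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for array in arrays:
        by_target.setdefault((array.genome, array.contig), []).extend(array.spacer_coords)
    out = []
    for g in genomes:
        contigs = []
        for cid, seq in g.contigs:
            chars = list(seq)
            for a, b in by_target.get((g.genome_id, cid), ()):  # 1-based inclusive
                for i in range(a - 1, b):
                    chars[i] = "N"
            contigs.append((cid, "".join(chars)))
        out.append(GenomeRecord(genome_id=g.genome_id, contigs=contigs))
    return out


def _hamming_candidates(seq: str, pattern: str, max_mm: int) -> list[int]:
    """0-based starts of windows within Hamming distance max_mm of pattern,
    found by exact-chunk pigeonholing."""
    w = len(pattern)
    n_chunks = max_mm + 1
    size = w // n_chunks
    starts: set[int] = set()
    for ci in range(n_chunks):
        off = ci * size
        chunk = pattern[off : off + size] if ci < n_chunks - 1 else pattern[off:]
        if not chunk:
            continue
        at = seq.find(chunk)
        while at != -1:
            cand = at - off
            if 0 <= cand <= len(seq) - w:
                starts.add(cand)
            at = seq.find(chunk, at + 1)
    hits = []
    for cand in sorted(starts):
        window = seq[cand : cand + w]
        mm = sum(1 for x, y in zip(window, pattern) if x != y)
        if mm <= max_mm:
            hits.append((cand, mm, "N" in window))
    return hits


def find_protospacers(
    spacers: list[tuple[str, str]],
    masked_genomes: list[GenomeRecord],
    max_mismatches: int = 2,
) -> list[SpacerHit]:
    """Scan both strands of the masked genomes for full-length spacer matches.

    Positions opposite 'N' count as mismatches, but a window overlapping any
    masked (N) position is discarded outright, so no hit ever lands in a
    spacer interval. Self-genome hits are allowed (the spacer loci are
    masked). Spacers shorter than 20 nt are skipped with a warning.
    """
    import warnings

    hits: list[SpacerHit] = []
    for spacer_id, sp in spacers:
        if len(sp) < 20:
            warnings.warn(f"spacer {spacer_id} shorter than 20 nt; skipped", stacklevel=2)
            continue
        for g in masked_genomes:
            for cid, seq in g.contigs:
                for pattern, strand in ((sp, "+"), (revcomp(sp), "-")):
                    for pos, mm, has_n in _hamming_candidates(seq, pattern, max_mismatches):
                        if has_n:
                            continue
                        hits.append(
                            SpacerHit(
                                spacer_id=spacer_id,
                                target_genome=g.genome_id,
                                target_contig=cid,
                                position=pos + 1,
                                strand=strand,
                                mismatches=mm,
                            )
                        )
    hits.sort(key=lambda h: (h.spacer_id, h.target_genome, h.target_contig, h.position, h.strand))
    return hits


def spacer_network(
    hits: list[SpacerHit], group_of_genome: dict[str, str]
) -> tuple[dict[str, int], pd.DataFrame]:
    """Within/between-group counts of distinct hit-bearing spacers plus a
    per-target-genome tally."""
    within: set[str] = set()
    between: set[str] = set()
    rows = []
    for h in hits:
        source_genome = h.spacer_id.split(".")[0]
        sg = group_of_genome.get(source_genome)
        tg = group_of_genome.get(h.target_genome)
        same = sg is not None and sg == tg
        h.same_group = same
        (within if same else between).add(h.spacer_id)
        rows.append(
            {
                "spacer_id": h.spacer_id,
                "source_genome": source_genome,
                "target_genome": h.target_genome,
                "same_group": same,
                "mismatches": h.mismatches,
            }
        )
    counts = {"within_group": len(within), "between_group": len(between)}
    table = (
        pd.DataFrame(rows)
        if rows
        else pd.DataFrame(
            columns=["spacer_id", "source_genome", "target_genome", "same_group", "mismatches"]
        )
    )
    return counts, table
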