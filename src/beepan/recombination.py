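"""Three alignment-based recombination statistics with a site-permutation null.

* Phi: mean pairwise incompatibility of informative sites whose original
  alignment positions are within a window (default 100 bp); recombination
  leaves nearby sites on the same local tree, so a LOW observed Phi relative
  to permuted site orders is the signal.
* NSS: fraction of adjacent informative-site pairs that are compatible; HIGH
  under recombination (neighbors cluster into tracts with a shared history).
* MaxChi: maximum 2x2 chi-square contrasting sequence match/mismatch counts
  in flanking windows around every candidate breakpoint for every taxon
  pair; HIGH at true tract boundaries.

Pair incompatibility is the cycle rank (edges - vertices + components) of the
partition-intersection bipartite graph over observed joint states: 0 iff the
two characters are compatible, and for two binary columns it equals 1 exactly
when all four gametes occur. A gene is called recombinant only when all three
permutation p-values fall below alpha (default 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .phylo import Alignment

_MISSING = -1
_STATE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class RecombinationParams:
    phi_window: int = 100
    maxchi_halfwindow: int | None = None  # None -> max(10, m // 10)
    permutations: int = 1000
    alpha: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def halfwindow(self, m: int) -> int:
        if self.maxchi_halfwindow is not None:
            return self.maxchi_halfwindow
        return max(10, m // 10)


@dataclass
class InformativeSiteMatrix:
    """Parsimony-informative sites; codes 0..3 for A,C,G,T and -1 missing."""

    taxa: list[str]
    codes: np.ndarray  # (n_taxa, m) int8
    positions: np.ndarray  # (m,) original 1-based alignment positions

    @property
    def m(self) -> int:
        return self.codes.shape[1]


def _encode_alignment(aln: Alignment) -> np.ndarray:
    mat = aln.matrix()
    codes = np.full(mat.shape, _MISSING, dtype=np.int8)
    for base, code in _STATE_CODE.items():
        codes[mat == base.encode()] = code
    return codes


def informative_sites(aln: Alignment | dict[str, str]) -> InformativeSiteMatrix:
    """Extract parsimony-informative columns.

    Gaps and ambiguity codes are missing; columns with > 50% missing are
    dropped; a column is informative when >= 2 states are each carried by
    >= 2 non-missing taxa.
    """
    if isinstance(aln, dict):
        aln = Alignment.from_dict(aln)
    codes = _encode_alignment(aln)
    n = codes.shape[0]
    missing_frac = (codes == _MISSING).mean(axis=0)
    keep_cols = []
    for j in np.nonzero(missing_frac <= 0.5)[0]:
        col = codes[:, j]
        states, counts = np.unique(col[col != _MISSING], return_counts=True)
        if (counts >= 2).sum() >= 2:
            keep_cols.append(j)
    keep = np.array(keep_cols, dtype=int)
    return InformativeSiteMatrix(
        taxa=list(aln.taxa),
        codes=codes[:, keep] if len(keep) else np.empty((n, 0), dtype=np.int8),
        positions=np.asarray(aln.columns)[keep] if len(keep) else np.empty(0, dtype=int),
    )


def pair_incompatibility(col_i, col_j) -> int:
    """Cycle rank of the partition-intersection graph of two characters.

    Accepts columns as sequences of state codes (ints, -1 missing) or
    single-character strings ('-'/'N' missing). Zero iff compatible.
    """
    a = _coerce_column(col_i)
    b = _coerce_column(col_j)
    ok = (a != _MISSING) & (b != _MISSING)
    a, b = a[ok], b[ok]
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        return 0
    pairs = set(zip(a.tolist(), b.tolist()))
    left = {s for s, _ in pairs}
    right = {s for _, s in pairs}
    # union-find over the bipartite vertex set
    parent: dict[tuple[int, int], tuple[int, int]] = {}
    for s in left:
        parent[(0, s)] = (0, s)
    for s in right:
        parent[(1, s)] = (1, s)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    comps = len(parent)
    for s, t in pairs:
        ra, rb = find((0, s)), find((1, t))
        if ra != rb:
            parent[rb] = ra
            comps -= 1
    edges = len(pairs)
    vertices = len(left) + len(right)
    return edges - vertices + comps


def _coerce_column(col) -> np.ndarray:
    arr = np.asarray(col)
    if arr.dtype.kind in "US":
        out = np.full(arr.shape, _MISSING, dtype=np.int8)
        for base, code in _STATE_CODE.items():
            out[arr == base] = code
        return out
    return arr.astype(np.int64)


def incompatibility_matrix(matrix: InformativeSiteMatrix) -> np.ndarray:
    """Pairwise incompatibility scores of all informative sites (m x m).

    Duplicate column patterns are scored once; position plays no role here,
    which is exactly what makes the permutation null cheap.
    """
    m = matrix.m
    if m == 0:
        return np.zeros((0, 0))
    uniq, inverse = np.unique(matrix.codes, axis=1, return_inverse=True)
    u = uniq.shape[1]
    s_u = np.zeros((u, u), dtype=np.int16)
    for i, j in combinations(range(u), 2):
        s_u[i, j] = s_u[j, i] = pair_incompatibility(uniq[:, i], uniq[:, j])
    return s_u[np.ix_(inverse, inverse)].astype(np.int16)


# ---------------------------------------------------------------------------
# the three statistics
# ---------------------------------------------------------------------------


def _phi_pairs(positions: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    ia, ib = [], []
    m = len(positions)
    for i in range(m):
        for j in range(i + 1, m):
            if positions[j] - positions[i] <= window:
                ia.append(i)
                ib.append(j)
            else:
                break
    return np.array(ia, dtype=int), np.array(ib, dtype=int)


def phi_statistic(
    matrix: InformativeSiteMatrix, phi_window: int = 100, s: np.ndarray | None = None
) -> float | None:
    """Mean incompatibility over site pairs within the window; None when no
    pair of informative sites falls within the window (not evaluable)."""
    if matrix.m < 2:
        return None
    s = incompatibility_matrix(matrix) if s is None else s
    ia, ib = _phi_pairs(matrix.positions, phi_window)
    if len(ia) == 0:
        return None
    return float(s[ia, ib].mean())


def nss_statistic(
    matrix: InformativeSiteMatrix, s: np.ndarray | None = None
) -> float | None:
    """Fraction of adjacent informative-site pairs that are compatible."""
    if matrix.m < 2:
        return None
    s = incompatibility_matrix(matrix) if s is None else s
    idx = np.arange(matrix.m - 1)
    return float((s[idx, idx + 1] == 0).mean())


def _mismatch_rows(matrix: InformativeSiteMatrix) -> np.ndarray:
    """Per-taxon-pair mismatch indicators (missing counts as mismatch)."""
    codes = matrix.codes
    n = codes.shape[0]
    rows = []
    for a, b in combinations(range(n), 2):
        rows.append(
            (codes[a] != codes[b]) | (codes[a] == _MISSING) | (codes[b] == _MISSING)
        )
    return np.array(rows, dtype=np.int32)


def _maxchi_from_mismatch(d: np.ndarray, k: int) -> np.ndarray:
    """Max chi-square over pairs and breakpoints for stacked mismatch arrays.

    `d` has shape (..., m); returns the max over the last two collapsed axes,
    i.e. an array of shape d.shape[:-2] reduced appropriately by the caller.
    Tables with a zero column margin score 0; flank margins are always k.
    """
    m = d.shape[-1]
    cs = np.concatenate(
        [np.zeros(d.shape[:-1] + (1,), dtype=np.int32), d.cumsum(axis=-1, dtype=np.int32)],
        axis=-1,
    )
    bps = np.arange(k, m - k + 1)
    left = cs[..., bps] - cs[..., bps - k]
    right = cs[..., bps + k] - cs[..., bps]
    # with both flank margins fixed at k, ad - bc = k (right - left), so the
    # chi-square collapses to 2k (r-l)^2 / ((l+r)(2k-l-r)); a zero mismatch or
    # zero match column margin makes the table degenerate -> 0
    tot = left + right
    denom = (tot * (2 * k - tot)).astype(np.float32)
    denom[denom == 0] = np.inf
    diff = (right - left).astype(np.float32)
    return (2.0 * k) * diff * diff / denom


def maxchi_statistic(
    matrix: InformativeSiteMatrix, halfwindow: int
) -> tuple[float, tuple[str, str], int] | None:
    """Maximum Pearson chi-square (no continuity correction) over all taxon
    pairs and breakpoints with full k-site flanks.

    Returns (statistic, (taxon_a, taxon_b), breakpoint original position) or
    None when m < 2*halfwindow.
    """
    m = matrix.m
    k = halfwindow
    if m < 2 * k or k < 1:
        return None
    d = _mismatch_rows(matrix)
    chi = _maxchi_from_mismatch(d, k)  # (npairs, nbp)
    flat = int(np.argmax(chi))
    pi, bi = np.unravel_index(flat, chi.shape)
    pairs = list(combinations(range(len(matrix.taxa)), 2))
    a, b = pairs[pi]
    bp_site = k + int(bi)  # breakpoint after this many informative sites
    bp_pos = int(matrix.positions[bp_site - 1])
    return float(chi[pi, bi]), (matrix.taxa[a], matrix.taxa[b]), bp_pos


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------


def permutation_pvalue(
    statistic: float,
    permuted_statistics: np.ndarray,
    direction: str,
) -> float:
    """Add-one permutation p-value: (1 + #at-least-as-extreme) / (n + 1).

    direction 'le': permuted <= observed is extreme (Phi);
    direction 'ge': permuted >= observed is extreme (NSS, MaxChi).
    """
    perm = np.asarray(permuted_statistics, dtype=float)
    if direction == "le":
        extreme = int((perm <= statistic + 1e-12).sum())
    elif direction == "ge":
        extreme = int((perm >= statistic - 1e-12).sum())
    else:
        raise ValueError("direction must be 'le' or 'ge'")
    return (1 + extreme) / (len(perm) + 1)


def evaluate_gene(
    aln: Alignment | dict[str, str],
    params: RecombinationParams | None = None,
    rng: np.random.Generator | None = None,
) -> dict:
    """Run all three statistics plus permutation tests on one gene alignment.

    Returns a record with m, the observed statistics, the three p-values and
    the verdict: 'recombinant' iff all three p < alpha, 'not-evaluable' when
    any statistic is undefined, else 'clonal'.
    """
    params = params or RecombinationParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    matrix = informative_sites(aln)
    m = matrix.m
    record: dict = {
        "m": m,
        "phi": None,
        "nss": None,
        "maxchi": None,
        "p_phi": None,
        "p_nss": None,
        "p_maxchi": None,
        "verdict": "not-evaluable",
    }
    if m < 2:
        return record
    s = incompatibility_matrix(matrix)
    obs_phi = phi_statistic(matrix, params.phi_window, s=s)
    obs_nss = nss_statistic(matrix, s=s)
    k = params.halfwindow(m)
    mc = maxchi_statistic(matrix, k)
    record["phi"], record["nss"] = obs_phi, obs_nss
    if mc is not None:
        record["maxchi"] = mc[0]
        record["maxchi_pair"] = mc[1]
        record["maxchi_breakpoint"] = mc[2]
    if obs_phi is None or obs_nss is None or mc is None:
        return record

    nperm = params.permutations
    perms = np.array([rng.permutation(m) for _ in range(nperm)])
    ia, ib = _phi_pairs(matrix.positions, params.phi_window)
    phi_perm = s[perms[:, ia], perms[:, ib]].mean(axis=1)
    nss_perm = (s[perms[:, :-1], perms[:, 1:]] == 0).mean(axis=1)
    d = _mismatch_rows(matrix)  # (npairs, m)
    dp = d[:, perms]  # (npairs, nperm, m)
    chi = _maxchi_from_mismatch(dp, k)  # (npairs, nperm, nbp)
    maxchi_perm = chi.max(axis=(0, 2))

    record["p_phi"] = permutation_pvalue(obs_phi, phi_perm, "le")
    record["p_nss"] = permutation_pvalue(obs_nss, nss_perm, "ge")
    record["p_maxchi"] = permutation_pvalue(mc[0], maxchi_perm, "ge")
    alpha = params.alpha
    record["verdict"] = (
        "recombinant"
        if record["p_phi"] < alpha
        and record["p_nss"] < alpha
        and record["p_maxchi"] < alpha
        else "clonal"
    )
    return record


def scan_genes(
    alignments: dict[str, Alignment | dict[str, str]],
    params: RecombinationParams | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Scan a set of per-gene alignments; the group-core recombination census.

    Returns the per-gene table and a summary with the recombinant count and
    the fraction among evaluable genes. Per-gene RNG streams are derived from
    the params seed and the sorted gene order, so results do not depend on
    input dict ordering.
    """
    params = params or RecombinationParams()
    genes = sorted(alignments)
    streams = np.random.SeedSequence(params.seed).spawn(len(genes))
    rows = []
    for gene, ss in zip(genes, streams):
        rec = evaluate_gene(alignments[gene], params, np.random.default_rng(ss))
        rec["gene"] = gene
        rows.append(rec)
    table = pd.DataFrame(rows)
    cols = ["gene", "m", "phi", "nss", "maxchi", "p_phi", "p_nss", "p_maxchi", "verdict"]
    table = table[[c for c in cols if c in table.columns] + [
        c for c in table.columns if c not in cols
    ]]
    evaluable = int((table["verdict"] != "not-evaluable").sum())
    recombinant = int((table["verdict"] == "recombinant").sum())
    summary = {
        "genes": len(genes),
        "evaluable": evaluable,
        "recombinant": recombinant,
        "fraction": recombinant / evaluable if evaluable else float("nan"),
    }
    return table, summary
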