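"""Codon-aware alignment and synonymous/nonsynonymous divergence (NG86).

The counting method of Nei & Gojobori (1986) is used throughout: fractional
synonymous site counts per codon, evolutionary-pathway averaging for codon
pairs differing at more than one position, and Jukes-Cantor correction of the
per-site proportions.  Conventions, stated once and shared by every routine:

* the standard genetic code only;
* point mutations that create a stop codon count as nonsynonymous when
  tallying synonymous-site fractions;
* pathways passing through a stop codon are excluded from pathway averaging;
  if every pathway between a codon pair is blocked, all pathways are used and
  the pair is flagged;
* saturation (pS or pN >= 3/4) yields NaN and a flag, never an exception.

All per-codon and per-codon-pair quantities are precomputed into lookup
tables at import, so large cross-sets of comparisons reduce to integer
indexing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

from ._seq import BASES, jc_correct

__all__ = [
    "CodonAlignment",
    "KsRecord",
    "codon_align",
    "ks_ng86",
    "cross_set_ks",
    "codon_z_test",
    "bh_fdr",
    "conserved_block_mask",
]

# ---------------------------------------------------------------------------
# Genetic-code tables

_STANDARD = CodonTable.unambiguous_dna_by_name["Standard"]
CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
STOP_CODONS = frozenset(_STANDARD.stop_codons)


def _aa(codon: str) -> str:
    return "*" if codon in STOP_CODONS else _STANDARD.forward_table[codon]


AA_BY_CODON = np.array([_aa(c) for c in CODONS])
IS_STOP = np.array([c in STOP_CODONS for c in CODONS])


def _syn_sites(codon: str) -> float:
    """Fractional count of synonymous sites in one codon (NG86).

    For each position, the fraction of the three possible point mutations
    that preserve the amino acid; changes to stop codons are nonsynonymous.
    """
    if codon in STOP_CODONS:
        return float("nan")
    s = 0.0
    for pos in range(3):
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1 :]
            if mut not in STOP_CODONS and _aa(mut) == _aa(codon):
                s += 1.0 / 3.0
    return s


SYN_SITES = np.array([_syn_sites(c) for c in CODONS])


def _pathway_counts(ca: str, cb: str) -> tuple[float, float, bool]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts
    between two non-stop codons; third element flags the all-pathways-blocked
    fallback."""
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    if not diffs:
        return 0.0, 0.0, False

    def walk(order: tuple[int, ...], allow_stops: bool):
        cur = ca
        sd = nd = 0.0
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != cb and not allow_stops:
                return None
            if _aa(nxt) == _aa(cur):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    paths = [walk(o, False) for o in itertools.permutations(diffs)]
    paths = [p for p in paths if p is not None]
    blocked = not paths
    if blocked:
        paths = [walk(o, True) for o in itertools.permutations(diffs)]
    sd = float(np.mean([p[0] for p in paths]))
    nd = float(np.mean([p[1] for p in paths]))
    return sd, nd, blocked


def _build_pair_tables():
    sd = np.full((64, 64), np.nan)
    nd = np.full((64, 64), np.nan)
    blocked = np.zeros((64, 64), dtype=bool)
    for i, ca in enumerate(CODONS):
        if ca in STOP_CODONS:
            continue
        for j, cb in enumerate(CODONS):
            if cb in STOP_CODONS:
                continue
            s, n, b = _pathway_counts(ca, cb)
            sd[i, j], nd[i, j], blocked[i, j] = s, n, b
    return sd, nd, blocked


SD_TABLE, ND_TABLE, BLOCKED_TABLE = _build_pair_tables()

# ---------------------------------------------------------------------------
# Data containers


@dataclass(frozen=True)
class CodonAlignment:
    """Two in-frame, gap-free codon sequences of equal codon count."""

    seq_a: str
    seq_b: str
    removed_columns: int = 0
    conserved_block_filtered: bool = False

    def __post_init__(self):
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences differ in length")
        if len(self.seq_a) % 3:
            raise ValueError("alignment length not a multiple of 3")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codon_indices(self) -> tuple[np.ndarray, np.ndarray]:
        ia = np.array([CODON_INDEX.get(self.seq_a[k : k + 3], -1)
                       for k in range(0, len(self.seq_a), 3)])
        ib = np.array([CODON_INDEX.get(self.seq_b[k : k + 3], -1)
                       for k in range(0, len(self.seq_b), 3)])
        return ia, ib


@dataclass
class KsRecord:
    """One pairwise codon-level comparison."""

    ks: float
    ka: float
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    codons: int
    method: str = "NG86-JC"
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def saturated(self) -> bool:
        return "saturated_s" in self.flags or "saturated_n" in self.flags


# ---------------------------------------------------------------------------
# Alignment


class InternalStopError(ValueError):
    def __init__(self, which: str, codon_index: int):
        self.which = which
        self.codon_index = codon_index
        super().__init__(
            f"internal stop codon in sequence {which} at codon {codon_index}"
        )


def _translate_checked(nuc: str, which: str) -> str:
    nuc = nuc[: len(nuc) - len(nuc) % 3]
    prot = str(Seq(nuc).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    stop = prot.find("*")
    if stop != -1:
        raise InternalStopError(which, stop)
    return prot


_AA_ALIGNER = PairwiseAligner()
_AA_ALIGNER.substitution_matrix = substitution_matrices.load("BLOSUM62")
_AA_ALIGNER.open_gap_score = -10.0
_AA_ALIGNER.extend_gap_score = -0.5
_AA_ALIGNER.mode = "global"


def codon_align(nuc_a: str, nuc_b: str,
                conserved_blocks: bool = False) -> CodonAlignment:
    """Align two in-frame coding sequences at the amino-acid level, thread
    the alignment back to codons and drop every gap-containing codon column.

    Incomplete terminal codons are trimmed; an internal stop raises
    :class:`InternalStopError` naming the codon.  When both translations have
    equal length and at least 70% amino-acid identity the direct (gapless)
    pairing is provably optimal under the affine scoring used and is taken
    without invoking the aligner.
    """
    nuc_a = nuc_a.upper()
    nuc_b = nuc_b.upper()
    prot_a = _translate_checked(nuc_a, "a")
    prot_b = _translate_checked(nuc_b, "b")
    nuc_a = nuc_a[: 3 * len(prot_a)]
    nuc_b = nuc_b[: 3 * len(prot_b)]
    if not prot_a or not prot_b:
        raise ValueError("empty coding sequence")

    if len(prot_a) == len(prot_b):
        ident = sum(x == y for x, y in zip(prot_a, prot_b)) / len(prot_a)
        if ident >= 0.70:
            return CodonAlignment(nuc_a, nuc_b, removed_columns=0)

    aln = _AA_ALIGNER.align(prot_a, prot_b)[0]
    cod_a: list[str] = []
    cod_b: list[str] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for off in range(a1 - a0):
            cod_a.append(nuc_a[3 * (a0 + off) : 3 * (a0 + off) + 3])
            cod_b.append(nuc_b[3 * (b0 + off) : 3 * (b0 + off) + 3])
    kept = len(cod_a)
    removed = int(aln.shape[1]) - kept
    out = CodonAlignment("".join(cod_a), "".join(cod_b), removed_columns=removed)
    if conserved_blocks:
        out = _apply_conserved_blocks(out)
    return out


def conserved_block_mask(prot_a: str, prot_b: str, window: int = 15,
                         min_conserved: float = 0.5) -> np.ndarray:
    """Boolean mask of codon columns retained by the sliding-window
    conserved-block filter: a column is dropped when every window covering it
    has fewer than ``min_conserved`` identical amino-acid pairs."""
    n = len(prot_a)
    same = np.array([a == b for a, b in zip(prot_a, prot_b)])
    if n <= window:
        return np.ones(n, dtype=bool) if same.mean() >= min_conserved \
            else np.zeros(n, dtype=bool)
    keep = np.zeros(n, dtype=bool)
    frac = np.convolve(same.astype(float), np.ones(window) / window, "valid")
    for start, ok in enumerate(frac >= min_conserved):
        if ok:
            keep[start : start + window] = True
    return keep


def _apply_conserved_blocks(aln: CodonAlignment) -> CodonAlignment:
    prot_a = str(Seq(aln.seq_a).translate())
    prot_b = str(Seq(aln.seq_b).translate())
    keep = conserved_block_mask(prot_a, prot_b)
    ca = "".join(aln.seq_a[3 * i : 3 * i + 3] for i in np.flatnonzero(keep))
    cb = "".join(aln.seq_b[3 * i : 3 * i + 3] for i in np.flatnonzero(keep))
    return CodonAlignment(ca, cb,
                          removed_columns=aln.removed_columns
                          + int((~keep).sum()),
                          conserved_block_filtered=True)


# ---------------------------------------------------------------------------
# NG86


def _site_and_diff_counts(ia: np.ndarray, ib: np.ndarray):
    """Vectorized NG86 site/difference counts for codon-index arrays.

    Codon columns containing an unknown codon (index -1) or a stop codon are
    excluded pairwise.
    """
    ok = (ia >= 0) & (ib >= 0)
    ok &= ~IS_STOP[np.where(ok, ia, 0)] & ~IS_STOP[np.where(ok, ib, 0)]
    ia, ib = ia[ok], ib[ok]
    n_codons = ia.size
    s_sites = 0.5 * (SYN_SITES[ia].sum() + SYN_SITES[ib].sum())
    n_sites = 3.0 * n_codons - s_sites
    sd = SD_TABLE[ia, ib].sum()
    nd = ND_TABLE[ia, ib].sum()
    blocked = bool(BLOCKED_TABLE[ia, ib].any())
    return s_sites, n_sites, sd, nd, n_codons, blocked


def ks_ng86(alignment: CodonAlignment, min_codons: int = 10) -> KsRecord:
    """Nei-Gojobori (1986) Ks/Ka with Jukes-Cantor correction."""
    ia, ib = alignment.codon_indices()
    s_sites, n_sites, sd, nd, n_codons, blocked = _site_and_diff_counts(ia, ib)
    if n_codons < min_codons:
        raise ValueError(
            f"only {n_codons} comparable codons (< {min_codons} required)")
    flags: list[str] = []
    if blocked:
        flags.append("blocked_pathway_fallback")

    if s_sites == 0.0:
        flags.append("no_synonymous_sites")
        ks = float("nan")
    else:
        ps = sd / s_sites
        if ps >= 0.75:
            flags.append("saturated_s")
            ks = float("nan")
        else:
            ks = jc_correct(ps)
    pn = nd / n_sites
    if pn >= 0.75:
        flags.append("saturated_n")
        ka = float("nan")
    else:
        ka = jc_correct(pn)
    return KsRecord(ks=ks, ka=ka, s_sites=float(s_sites),
                    n_sites=float(n_sites), sd=float(sd), nd=float(nd),
                    codons=int(n_codons), flags=tuple(flags))


def cross_set_ks(copy_set_a, copy_set_b, min_codons: int = 10,
                 conserved_blocks: bool = False):
    """All-against-all Ks between two sets of coding sequences.

    Exactly ``len(a) * len(b)`` comparisons are attempted; per-pair failures
    are collected, not fatal.  Returns ``(records, failures)`` where each
    record is ``(i, j, KsRecord)`` and each failure ``(i, j, message)``.
    """
    records, failures = [], []
    for i, a in enumerate(copy_set_a):
        for j, b in enumerate(copy_set_b):
            try:
                aln = codon_align(a, b, conserved_blocks=conserved_blocks)
                records.append((i, j, ks_ng86(aln, min_codons=min_codons)))
            except (ValueError, InternalStopError) as exc:
                failures.append((i, j, str(exc)))
    return records, failures


# ---------------------------------------------------------------------------
# Codon-based Z-test for purifying selection


def _ds_dn_from_indices(ia: np.ndarray, ib: np.ndarray):
    s_sites, n_sites, sd, nd, _, _ = _site_and_diff_counts(ia, ib)
    ds = jc_correct(sd / s_sites) if s_sites > 0 else float("nan")
    dn = jc_correct(nd / n_sites) if n_sites > 0 else float("nan")
    return ds, dn


def codon_z_test(alignment: CodonAlignment, n_bootstrap: int = 1000,
                 seed: int = 0):
    """One-tailed codon-based Z-test of purifying selection (H1: dN < dS).

    Variances of dS and dN come from a bootstrap over codon columns.
    Returns ``(Z, p, flags)``; degenerate variance yields ``p = 1`` with a
    flag.
    """
    rng = np.random.default_rng(seed)
    ia, ib = alignment.codon_indices()
    ds, dn = _ds_dn_from_indices(ia, ib)
    flags: list[str] = []
    if not np.isfinite(ds) or not np.isfinite(dn):
        return float("nan"), 1.0, ("undefined_distance",)

    n = ia.size
    reps = np.empty((n_bootstrap, 2))
    for r in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        reps[r] = _ds_dn_from_indices(ia[idx], ib[idx])
    reps = reps[np.all(np.isfinite(reps), axis=1)]
    if len(reps) < 2:
        return float("nan"), 1.0, ("degenerate_bootstrap",)
    var = reps.var(axis=0, ddof=1)
    se = float(np.sqrt(var.sum()))
    if se == 0.0:
        return 0.0, 1.0, ("degenerate_variance",)
    z = (ds - dn) / se
    from scipy.stats import norm

    p = float(norm.sf(z))
    return float(z), p, tuple(flags)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]
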