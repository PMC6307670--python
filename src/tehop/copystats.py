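"""Copy statistics: counting at coverage thresholds, dereplication of
identical copies, and nucleotide diversity among copies.

Nucleotide diversity is the mean pairwise model-corrected distance among
aligned copies (pairwise deletion of gapped/ambiguous sites), with a
standard error from a bootstrap over alignment columns.  The default
correction is Kimura two-parameter; p-distance and Jukes-Cantor are
available.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from ._seq import canonical_strand, encode, jc_correct, _PURINE

__all__ = [
    "CopyHit",
    "DiversityEstimate",
    "count_copies",
    "merge_overlapping_hits",
    "dereplicate_identical",
    "nucleotide_diversity",
]


@dataclass(frozen=True)
class CopyHit:
    chrom: str
    start: int          # half-open, 0-based subject interval
    end: int
    strand: str
    identity: float
    aligned_length: int
    coverage: float     # aligned consensus span / consensus length

    def __post_init__(self):
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity outside [0,1]")
        if not 0.0 <= self.coverage <= 1.0001:
            raise ValueError("coverage outside [0,1]")


@dataclass(frozen=True)
class DiversityEstimate:
    pi: float
    se: float
    n_sequences: int
    model: str
    n_failed_pairs: int = 0


def merge_overlapping_hits(hits):
    """Collapse same-strand hits overlapping >50% reciprocally to one locus
    (keeps the hit with the larger coverage), preventing double counting of
    internally deleted copies."""
    out: list[CopyHit] = []
    for h in sorted(hits, key=lambda h: (h.chrom, h.strand, h.start, h.end)):
        merged = False
        for i, kept in enumerate(out):
            if kept.chrom != h.chrom or kept.strand != h.strand:
                continue
            ov = min(kept.end, h.end) - max(kept.start, h.start)
            if ov <= 0:
                continue
            if ov > 0.5 * (kept.end - kept.start) and ov > 0.5 * (h.end - h.start):
                if h.coverage > kept.coverage:
                    out[i] = h
                merged = True
                break
        if not merged:
            out.append(h)
    return out


def count_copies(hits, min_coverage: float, merge: bool = True) -> int:
    """Number of hits with coverage >= min_coverage (inclusive)."""
    if not 0.0 <= min_coverage <= 1.0:
        raise ValueError("min_coverage outside [0,1]")
    pool = merge_overlapping_hits(hits) if merge else list(hits)
    return sum(h.coverage >= min_coverage for h in pool)


def dereplicate_identical(sequences):
    """Group exactly identical sequences after strand normalization.

    Returns ``(groups, n_variants_with_multiplicity, total_copies_in_groups)``
    where ``groups`` maps each canonical sequence to the list of member
    indices, and the two counts summarize multi-copy groups only.
    """
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(sequences):
        groups.setdefault(canonical_strand(s.upper()), []).append(i)
    multi = {k: v for k, v in groups.items() if len(v) > 1}
    return groups, len(multi), sum(len(v) for v in multi.values())


def _pair_site_matrices(seqs_enc):
    """Per-pair boolean site matrices needed for distance bootstraps:
    (valid, transition, transversion), each (n_pairs, L)."""
    n = len(seqs_enc)
    pairs = list(combinations(range(n), 2))
    L = seqs_enc[0].size
    valid = np.empty((len(pairs), L), dtype=bool)
    ts = np.empty((len(pairs), L), dtype=bool)
    tv = np.empty((len(pairs), L), dtype=bool)
    for k, (i, j) in enumerate(pairs):
        a, b = seqs_enc[i], seqs_enc[j]
        ok = (a < 4) & (b < 4)
        diff = ok & (a != b)
        is_ts = diff & (_PURINE[np.where(ok, a, 0)] == _PURINE[np.where(ok, b, 0)])
        valid[k] = ok
        ts[k] = is_ts
        tv[k] = diff & ~is_ts
    return valid, ts, tv


def _pi_from_counts(nvalid, nts, ntv, model):
    with np.errstate(divide="ignore", invalid="ignore"):
        P = nts / nvalid
        Q = ntv / nvalid
        p = P + Q
        if model == "p":
            d = p
        elif model == "JC":
            d = np.where(p < 0.75, -0.75 * np.log1p(-4.0 * p / 3.0), np.nan)
        elif model == "K2P":
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            d = np.where((w1 > 0) & (w2 > 0),
                         -0.5 * np.log(np.maximum(w1, 1e-300))
                         - 0.25 * np.log(np.maximum(w2, 1e-300)), np.nan)
        else:
            raise ValueError(f"unknown model: {model!r}")
    return d


def nucleotide_diversity(sequences, model: str = "K2P",
                         n_bootstrap: int = 1000, seed: int = 0
                         ) -> DiversityEstimate:
    """Mean pairwise corrected distance among aligned copies, with a
    column-bootstrap standard error.

    Pairs whose correction is undefined (saturation) are dropped from the
    mean and counted in ``n_failed_pairs``.
    """
    seqs = [s.upper() for s in sequences]
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences are not aligned (unequal lengths)")
    enc = [encode(s) for s in seqs]
    valid, ts, tv = _pair_site_matrices(enc)

    d = _pi_from_counts(valid.sum(axis=1).astype(float),
                        ts.sum(axis=1).astype(float),
                        tv.sum(axis=1).astype(float), model)
    finite = np.isfinite(d)
    pi = float(d[finite].mean()) if finite.any() else float("nan")
    n_failed = int((~finite).sum())

    if pi == 0.0:
        return DiversityEstimate(pi=0.0, se=0.0, n_sequences=len(seqs),
                                 model=model, n_failed_pairs=n_failed)

    rng = np.random.default_rng(seed)
    # column bootstrap via multinomial column weights
    weights = rng.multinomial(L, np.full(L, 1.0 / L), size=n_bootstrap).T
    weights = weights.astype(float)                     # (L, n_bootstrap)
    nvalid = valid.astype(float) @ weights              # (n_pairs, B)
    nts = ts.astype(float) @ weights
    ntv = tv.astype(float) @ weights
    dboot = _pi_from_counts(nvalid, nts, ntv, model)
    pis = np.nanmean(dboot, axis=0)
    se = float(np.nanstd(pis, ddof=1))
    return DiversityEstimate(pi=pi, se=se, n_sequences=len(seqs),
                             model=model, n_failed_pairs=n_failed)
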