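"""Neutral-rate calibration and TE insertion-time estimation.

The neutral substitution rate of a lineage is calibrated from the mean
synonymous divergence of single-copy orthologs against a counterpart species
with a known divergence time: r = mean_Ks / (2 * t).  Each genomic copy is
then dated against the species consensus (a proxy for the element the copy
lineage diverged from) with T = k / (2 r), where k is the synonymous
divergence between copy and consensus.  Rates carry an explicit per-year
unit tag so that per-My rates cannot be fed in silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import encode, jc_correct, p_distance
from .ks import InternalStopError, codon_align, ks_ng86

__all__ = [
    "NeutralRate",
    "CopyAge",
    "BurstProfile",
    "neutral_rate",
    "copy_ages",
    "entry_time",
    "proliferation_profile",
]


@dataclass(frozen=True)
class NeutralRate:
    lineage: str
    r: float                    # substitutions / site / year
    mean_ks: float
    divergence_time_my: float
    unit: str = "per_year"

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError("rate must be positive")
        if self.unit != "per_year":
            raise ValueError(
                f"rate unit must be 'per_year', got {self.unit!r}")


@dataclass(frozen=True)
class CopyAge:
    copy_id: str
    k: float                    # substitutions per site vs consensus
    t_my: float                 # insertion age, My
    mode: str                   # "ks" | "nucleotide"


def neutral_rate(mean_ks: float, divergence_time_my: float,
                 lineage: str = "") -> NeutralRate:
    """r = mean_Ks / (2 * divergence_time_my * 1e6), per site per year."""
    if not mean_ks > 0:
        raise ValueError("mean_ks must be positive")
    if not divergence_time_my > 0:
        raise ValueError("divergence time must be positive")
    r = mean_ks / (2.0 * divergence_time_my * 1e6)
    return NeutralRate(lineage=lineage, r=r, mean_ks=mean_ks,
                       divergence_time_my=divergence_time_my)


def _age_from_k(k: float, rate: NeutralRate) -> float:
    # T = k / 2r in years; a single 1e6 factor converts to My
    return k / (2.0 * rate.r) / 1e6


def copy_ages(copies: dict, species_consensus: str, rate: NeutralRate,
              mode: str = "ks", min_codons: int = 10):
    """Age every copy against the species consensus.

    ``copies`` maps copy id to sequence.  In ``ks`` mode sequences must be
    in-frame coding sequences and k is the NG86 Ks; in ``nucleotide`` mode k
    is the Jukes-Cantor-corrected whole-element distance (the fallback for
    copies without an intact ORF).  Unalignable/saturated copies are skipped
    and reported.  Returns ``(ages, skipped)``.
    """
    if not isinstance(rate, NeutralRate):
        raise TypeError("rate must be a NeutralRate (unit-tagged)")
    ages: list[CopyAge] = []
    skipped: list[tuple[str, str]] = []
    cons_enc = encode(species_consensus.upper())
    for cid, seq in copies.items():
        try:
            if mode == "ks":
                aln = codon_align(seq, species_consensus)
                rec = ks_ng86(aln, min_codons=min_codons)
                if not np.isfinite(rec.ks):
                    skipped.append((cid, "saturated"))
                    continue
                k = rec.ks
            elif mode == "nucleotide":
                if len(seq) != len(species_consensus):
                    raise ValueError("length mismatch in nucleotide mode")
                k = jc_correct(p_distance(encode(seq.upper()), cons_enc))
                if not np.isfinite(k):
                    skipped.append((cid, "saturated"))
                    continue
            else:
                raise ValueError(f"unknown mode {mode!r}")
        except (ValueError, InternalStopError) as exc:
            skipped.append((cid, str(exc)))
            continue
        ages.append(CopyAge(copy_id=cid, k=float(k),
                            t_my=float(_age_from_k(k, rate)), mode=mode))
    return ages, skipped


def entry_time(ages, burst_gap_my: float = 0.25) -> dict:
    """Entry-time summaries for one species.

    Three estimators are reported: the maximum copy age, the robust 95th
    percentile, and the mean age of the oldest burst (``burst_mean``).  The
    last averages out the per-copy dating noise (a single copy's k is a small
    substitution count, so individual ages scatter widely around the cohort
    age) and is the preferred entry estimate when an invasion cohort is
    present; the oldest burst is delimited by the largest age gap of at least
    ``burst_gap_my``, falling back to the ages above the age-range midpoint
    when no such gap exists or the burst is tiny.
    """
    t = np.asarray([a.t_my if isinstance(a, CopyAge) else a for a in ages],
                   dtype=float)
    if t.size == 0:
        raise ValueError("no ages")
    out = {"max": float(t.max()), "q95": float(np.percentile(t, 95.0)),
           "n": int(t.size)}
    ts = np.sort(t)
    gaps = np.diff(ts)
    oldest = None
    if gaps.size and gaps.max() >= burst_gap_my:
        cut = int(gaps.argmax()) + 1
        cand = ts[cut:]
        if cand.size >= 5:
            oldest = cand
    if oldest is None:
        mid = 0.5 * (ts[0] + ts[-1])
        cand = ts[ts >= mid]
        oldest = cand if cand.size else ts
    out["burst_mean"] = float(oldest.mean())
    return out


@dataclass(frozen=True)
class BurstProfile:
    bursts: tuple          # (min_my, max_my, n, fraction) per burst, recent first
    gaps: tuple            # (younger_edge_my, older_edge_my) quiescence windows
    gap_threshold_my: float


def proliferation_profile(ages_my, gap_threshold_my: float = 0.1
                          ) -> BurstProfile:
    """Single-linkage clustering of copy ages on the age axis.

    Maximal empty age intervals of width >= ``gap_threshold_my`` are reported
    as quiescence gaps; the contiguous clusters they delimit are bursts with
    (min, max, n, fraction of all copies).
    """
    t = np.sort(np.asarray(ages_my, dtype=float))
    if t.size < 5:
        raise ValueError("need at least 5 ages")
    total = t.size
    breaks = np.flatnonzero(np.diff(t) >= gap_threshold_my)
    bursts, gaps = [], []
    start = 0
    for b in breaks:
        bursts.append((float(t[start]), float(t[b]), int(b - start + 1),
                       float((b - start + 1) / total)))
        gaps.append((float(t[b]), float(t[b + 1])))
        start = b + 1
    bursts.append((float(t[start]), float(t[-1]), int(total - start),
                   float((total - start) / total)))
    return BurstProfile(bursts=tuple(bursts), gaps=tuple(gaps),
                        gap_threshold_my=gap_threshold_my)
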