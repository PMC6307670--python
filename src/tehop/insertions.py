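"""Insertion polymorphism between haploid brothers.

Covers four steps: identity-by-descent (IBD) window discovery from SNP
density in fixed windows; nonreference insertion calling from junction reads
using the target-site-duplication (TSD) overlap signature; classification of
calls into family-specific versus common; and the de novo insertion-rate
bound from the number of informative (IBD) genomes surveyed.

Only IBD regions are informative for de novo insertions: where brothers
inherited different maternal alleles, a polymorphic (segregating) insertion
is indistinguishable from a new one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IBDWindow",
    "InsertionCall",
    "ibd_windows",
    "call_insertions",
    "classify_family_occupancy",
    "insertion_rate_bound",
]


@dataclass(frozen=True)
class IBDWindow:
    chrom: str
    start: int
    end: int
    snp_count: int
    state: str  # "IBD" | "non-IBD"


@dataclass
class InsertionCall:
    chrom: str
    start: int              # breakpoint interval (TSD span), half-open
    end: int
    tsd_len: int
    tsd_seq: str | None
    left_reads: int
    right_reads: int
    min_mapq: float
    samples: frozenset = frozenset()
    families: frozenset = frozenset()
    classification: str = ""   # "family_specific" | "common"
    excised: bool = False
    in_ibd: bool | None = None


# ---------------------------------------------------------------------------
# IBD windows


def _poisson_mixture_em(counts: np.ndarray, max_iter: int = 200,
                        tol: float = 1e-8):
    """Two-component Poisson mixture fit by EM; returns (lam_low, lam_high,
    weight_low, posterior_low) or None when the fit degenerates."""
    counts = counts.astype(float)
    lam0, lam1 = max(counts.min(), 0.05), max(counts.mean() * 2.0, 1.0)
    w = 0.5
    if lam1 <= lam0:
        return None
    from scipy.stats import poisson

    post = None
    for _ in range(max_iter):
        p0 = w * poisson.pmf(counts, lam0)
        p1 = (1.0 - w) * poisson.pmf(counts, lam1)
        tot = p0 + p1
        tot[tot == 0] = 1e-300
        post = p0 / tot
        w_new = post.mean()
        lam0_new = (post * counts).sum() / max(post.sum(), 1e-12)
        lam1_new = ((1 - post) * counts).sum() / max((1 - post).sum(), 1e-12)
        moved = abs(lam0_new - lam0) + abs(lam1_new - lam1) + abs(w_new - w)
        lam0, lam1, w = lam0_new, lam1_new, w_new
        if moved < tol:
            break
    if not np.isfinite(lam0) or not np.isfinite(lam1) or lam1 <= 2 * lam0 + 0.5:
        return None
    return lam0, lam1, w, post


def ibd_windows(snp_table: pd.DataFrame, chrom_lengths: dict,
                window_bp: int = 10_000, method: str = "mixture",
                threshold: int = 2):
    """Classify fixed windows as IBD / non-IBD from between-brother SNP
    density.

    ``snp_table`` needs columns ``chrom`` and ``pos`` (0-based) and must
    already exclude homozygous-versus-reference sites.  Classification uses a
    two-component Poisson mixture over window counts (windows assigned to the
    low-rate component are IBD); when the mixture degenerates — or with
    ``method='threshold'`` — windows with at most ``threshold`` SNPs are IBD.
    Returns ``(windows, ibd_fraction)``.
    """
    windows: list[IBDWindow] = []
    counts = []
    keys = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        n_win = max(1, -(-length // window_bp))
        sub = snp_table[snp_table["chrom"] == chrom] if len(snp_table) else snp_table
        binned = np.zeros(n_win, dtype=int)
        if len(sub):
            idx = np.minimum(sub["pos"].to_numpy() // window_bp, n_win - 1)
            np.add.at(binned, idx, 1)
        for w in range(n_win):
            keys.append((chrom, w * window_bp, min((w + 1) * window_bp, length)))
            counts.append(binned[w])
    counts = np.asarray(counts)
    if counts.sum() == 0:
        warnings.warn("empty SNP table: all windows classified IBD")
        is_ibd = np.ones(counts.size, dtype=bool)
    elif method == "mixture":
        fit = _poisson_mixture_em(counts)
        if fit is None:
            is_ibd = counts <= threshold
        else:
            _, _, _, post = fit
            is_ibd = post >= 0.5
    elif method == "threshold":
        is_ibd = counts <= threshold
    else:
        raise ValueError(f"unknown method {method!r}")
    for (chrom, start, end), c, ibd in zip(keys, counts, is_ibd):
        windows.append(IBDWindow(chrom=chrom, start=start, end=end,
                                 snp_count=int(c),
                                 state="IBD" if ibd else "non-IBD"))
    span_ibd = sum(w.end - w.start for w in windows if w.state == "IBD")
    span = sum(w.end - w.start for w in windows)
    return windows, span_ibd / span


# ---------------------------------------------------------------------------
# Insertion calling


def _cluster_positions(positions: np.ndarray, tol: int):
    """Group sorted positions into clusters with single-linkage tolerance."""
    order = np.argsort(positions)
    clusters = []
    cur = [order[0]]
    for idx in order[1:]:
        if positions[idx] - positions[cur[-1]] <= tol:
            cur.append(idx)
        else:
            clusters.append(cur)
            cur = [idx]
    clusters.append(cur)
    return clusters


def call_insertions(junction_reads: pd.DataFrame, min_mapq: float = 10,
                    tsd_range: tuple[int, int] = (2, 10),
                    min_reads_per_side: int = 1,
                    cluster_tol: int = 15,
                    reference: dict | None = None):
    """Call nonreference insertions from junction-read alignments.

    ``junction_reads`` columns: ``chrom, start, end, side, mapq, sample``
    where ``side`` is ``TE-left`` (read runs out of the genome into the TE's
    5' end: its genomic interval ends at the breakpoint) or ``TE-right``
    (genomic interval starts at the breakpoint), plus optional ``ref`` rows
    for reads spanning the locus without the TE (excision evidence).

    Reads below ``min_mapq`` are discarded before clustering — no emitted
    call carries lower evidence.  A left cluster and a right cluster whose
    genomic intervals overlap by a length within ``tsd_range`` produce a
    call, the overlap being the TSD.  Returns ``(calls, low_confidence)``.
    """
    reads = junction_reads[junction_reads["mapq"] >= min_mapq]
    calls: list[InsertionCall] = []
    low_conf: list[InsertionCall] = []
    for chrom, sub in reads.groupby("chrom", sort=True):
        left = sub[sub["side"] == "TE-left"]
        right = sub[sub["side"] == "TE-right"]
        refr = sub[sub["side"] == "ref"]
        if left.empty or right.empty:
            continue
        lpos = left["end"].to_numpy()
        rpos = right["start"].to_numpy()
        lclusters = _cluster_positions(lpos, cluster_tol)
        rclusters = _cluster_positions(rpos, cluster_tol)
        used_r: set[int] = set()
        for lc in lclusters:
            if len(lc) < min_reads_per_side:
                continue
            # modal breakpoint of the cluster
            vals, cnts = np.unique(lpos[lc], return_counts=True)
            l_end = int(vals[cnts.argmax()])
            best = None
            for ri, rc in enumerate(rclusters):
                if ri in used_r or len(rc) < min_reads_per_side:
                    continue
                vals, cnts = np.unique(rpos[rc], return_counts=True)
                r_start = int(vals[cnts.argmax()])
                tsd = l_end - r_start
                if best is None or abs(tsd) < abs(best[1]):
                    best = (ri, tsd, r_start, rc)
            if best is None:
                continue
            ri, tsd, r_start, rc = best
            lrows = left.iloc[lc]
            rrows = right.iloc[rc]
            samples = frozenset(lrows["sample"]) | frozenset(rrows["sample"])
            tsd_seq = None
            if reference is not None and chrom in reference and tsd > 0:
                tsd_seq = reference[chrom][r_start:l_end]
            excised = False
            if not refr.empty:
                near = refr[(refr["start"] < l_end) & (refr["end"] > r_start)]
                excised = bool(set(near["sample"]) & set(samples))
            call = InsertionCall(
                chrom=chrom, start=min(r_start, l_end),
                end=max(r_start, l_end), tsd_len=tsd, tsd_seq=tsd_seq,
                left_reads=len(lc), right_reads=len(rc),
                min_mapq=float(min(lrows["mapq"].min(), rrows["mapq"].min())),
                samples=samples, excised=excised)
            if tsd_range[0] <= tsd <= tsd_range[1]:
                used_r.add(ri)
                calls.append(call)
            else:
                low_conf.append(call)
    return calls, low_conf


def classify_family_occupancy(calls, family_of_sample: dict,
                              exclusion_mask=None):
    """Merge calls across families by breakpoint proximity and classify.

    Calls whose breakpoints lie within ``max(tsd_range)`` of each other are
    one locus.  A locus seen in >= 2 families is "common"; otherwise
    "family-specific".  ``exclusion_mask`` is an optional list of
    ``(chrom, start, end)`` intervals removed before classification (e.g., a
    supergene region when one haplotype is the reference).  Returns
    ``(merged_calls, summary)``.
    """
    if exclusion_mask:
        def excluded(c):
            return any(c.chrom == chrom and c.start < end and c.end > start
                       for chrom, start, end in exclusion_mask)
        calls = [c for c in calls if not excluded(c)]
    if not calls:
        return [], {"n_total": 0, "n_common": 0, "n_family_specific": 0,
                    "per_family_unique": {}}
    tol = max(abs(c.tsd_len) for c in calls)
    merged: list[InsertionCall] = []
    for c in sorted(calls, key=lambda c: (c.chrom, c.start)):
        target = None
        for m in merged:
            if m.chrom == c.chrom and abs(m.start - c.start) <= tol:
                target = m
                break
        if target is None:
            merged.append(InsertionCall(
                chrom=c.chrom, start=c.start, end=c.end, tsd_len=c.tsd_len,
                tsd_seq=c.tsd_seq, left_reads=c.left_reads,
                right_reads=c.right_reads, min_mapq=c.min_mapq,
                samples=c.samples, excised=c.excised))
        else:
            target.samples = target.samples | c.samples
            target.left_reads += c.left_reads
            target.right_reads += c.right_reads
            target.excised = target.excised or c.excised
    for m in merged:
        m.families = frozenset(family_of_sample[s] for s in m.samples)
        m.classification = "common" if len(m.families) >= 2 else "family_specific"
    n_common = sum(m.classification == "common" for m in merged)
    per_family: dict = {}
    for m in merged:
        if m.classification == "family_specific":
            fam = next(iter(m.families))
            per_family[fam] = per_family.get(fam, 0) + 1
    summary = {"n_total": len(merged), "n_common": n_common,
               "n_family_specific": len(merged) - n_common,
               "per_family_unique": per_family}
    return merged, summary


def insertion_rate_bound(n_individuals: int, mean_ibd_fraction: float,
                         n_new_insertions_observed: int) -> dict:
    """De novo insertion-rate bound per genome per generation.

    The number of informative genomes is g = n_individuals *
    mean_ibd_fraction.  With zero observed new insertions the rate is
    bounded above by 1/g; otherwise the point estimate n/g is returned.
    """
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    if not 0.0 < mean_ibd_fraction <= 1.0:
        raise ValueError("mean IBD fraction must be in (0, 1]")
    g = n_individuals * mean_ibd_fraction
    if n_new_insertions_observed == 0:
        return {"effective_genomes": g, "bound": 1.0 / g, "kind": "upper_bound"}
    return {"effective_genomes": g,
            "bound": n_new_insertions_observed / g, "kind": "point_estimate"}
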