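"""Horizontal-transfer tests.

Three independent lines of evidence are implemented:

* presence/absence of the element across a genome panel (patchy taxonomic
  distribution), by seeded ungapped local search;
* the contrast between interspecies TE Ks and nuclear-gene Ks for each
  species pair, tested with the Games-Howell procedure (studentized range,
  Welch-Satterthwaite degrees of freedom) — a horizontally transferred
  element has accumulated significantly fewer synonymous substitutions than
  resident genes;
* phylogenetic incongruence: neighbor-joining trees from model-corrected
  distances, compared by Robinson-Foulds distance.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import studentized_range

from ._seq import revcomp

__all__ = [
    "LocalHit",
    "PresenceCall",
    "GamesHowellResult",
    "SpeciesPairContrast",
    "local_hits",
    "presence_scan",
    "games_howell",
    "ks_contrast_report",
    "nj_tree",
    "robinson_foulds",
]


# ---------------------------------------------------------------------------
# Presence scan (seeded ungapped local search)


@dataclass(frozen=True)
class LocalHit:
    chrom: str
    start: int
    end: int
    strand: str
    identity: float
    length: int
    q_start: int
    q_end: int


@dataclass(frozen=True)
class PresenceCall:
    species: str
    present: bool
    best_hit_length: int
    best_hit_identity: float
    n_copies_40: int


def _best_segment(mask: np.ndarray, match=1.0, mismatch=-2.0):
    """Best-scoring contiguous segment of a match mask (Kadane)."""
    score = np.where(mask, match, mismatch)
    best = cur = 0.0
    best_lo = best_hi = cur_lo = 0
    for i, s in enumerate(score):
        if cur <= 0:
            cur = s
            cur_lo = i
        else:
            cur += s
        if cur > best:
            best = cur
            best_lo, best_hi = cur_lo, i + 1
    return best_lo, best_hi, best


def local_hits(query: str, target: str, chrom: str = "chr", k: int = 12,
               min_len: int = 30):
    """Ungapped seeded local hits of query against both strands of target.

    Exact k-mer seeds are grouped by diagonal; each diagonal's overlap is
    scored with +1/-2 and the best-scoring segment reported.  Suited to the
    indel-free divergence this package's simulator produces and to >=90%
    identity searches generally.
    """
    from ._seq import encode

    query = query.upper()
    target = target.upper()
    hits: list[LocalHit] = []
    qenc = encode(query)
    weights = (4 ** np.arange(k)).astype(np.int64)

    def kmer_hashes(arr):
        # rolling k-mer hash; windows containing non-ACGT marked invalid
        if arr.size < k:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
        win = np.lib.stride_tricks.sliding_window_view(arr.astype(np.int64), k)
        return win @ weights, (win < 4).all(axis=1)

    qh, qok = kmer_hashes(qenc)
    qmap: dict[int, list[int]] = {}
    for i in np.flatnonzero(qok):
        qmap.setdefault(int(qh[i]), []).append(int(i))

    for strand in "+-":
        t = target if strand == "+" else revcomp(target)
        tenc = encode(t)
        th, tok = kmer_hashes(tenc)
        diags: set[int] = set()
        if th.size:
            cand = np.flatnonzero(np.isin(th, qh[qok]) & tok)
            for j in cand:
                for i in qmap.get(int(th[j]), ()):
                    diags.add(int(j) - i)
        tarr = np.frombuffer(t.encode(), dtype=np.uint8)
        qarr = np.frombuffer(query.encode(), dtype=np.uint8)
        claimed: list[tuple[int, int]] = []
        for d in sorted(diags):
            q0 = max(0, -d)
            t0 = q0 + d
            n = min(len(query) - q0, len(t) - t0)
            if n < min_len:
                continue
            mask = qarr[q0 : q0 + n] == tarr[t0 : t0 + n]
            lo, hi, score = _best_segment(mask)
            if hi - lo < min_len:
                continue
            ts, te = t0 + lo, t0 + hi
            if any(min(te, ce) - max(ts, cs) > 0.5 * (te - ts)
                   for cs, ce in claimed):
                continue
            claimed.append((ts, te))
            ident = float(mask[lo:hi].mean())
            if strand == "+":
                start, end = ts, te
            else:
                start, end = len(t) - te, len(t) - ts
            hits.append(LocalHit(chrom=chrom, start=start, end=end,
                                 strand=strand, identity=ident,
                                 length=hi - lo, q_start=q0 + lo,
                                 q_end=q0 + hi))
    return sorted(hits, key=lambda h: (-h.length * h.identity, h.start))


def presence_scan(consensus: str, genome, species: str = "",
                  min_hit_len: int = 100, min_identity: float = 0.90
                  ) -> PresenceCall:
    """Presence call for one genome: present iff at least one local hit with
    length > min_hit_len (strict) and identity > min_identity (strict).

    ``genome`` is a mapping of chromosome name to sequence or a single
    string.  Copies at >=40% consensus coverage are counted alongside.
    """
    if isinstance(genome, str):
        genome = {"chr": genome}
    all_hits: list[LocalHit] = []
    for chrom, seq in genome.items():
        if seq:
            all_hits.extend(local_hits(consensus, seq, chrom=chrom))
    qualifying = [h for h in all_hits
                  if h.length > min_hit_len and h.identity > min_identity]
    best = max(all_hits, key=lambda h: (h.length, h.identity), default=None)
    n40 = sum(h.length / len(consensus) >= 0.40 for h in all_hits)
    return PresenceCall(
        species=species,
        present=bool(qualifying),
        best_hit_length=0 if best is None else best.length,
        best_hit_identity=0.0 if best is None else best.identity,
        n_copies_40=n40,
    )


# ---------------------------------------------------------------------------
# Games-Howell


@dataclass(frozen=True)
class GamesHowellResult:
    label_a: str
    label_b: str
    mean_a: float
    mean_b: float
    q: float
    df: float
    p: float
    flags: tuple[str, ...] = ()


def games_howell(groups) -> list[GamesHowellResult]:
    """Games-Howell post-hoc pairwise comparisons.

    ``groups`` is a list of ``(label, values)``.  For each pair,
    q = |m_i - m_j| / sqrt((s_i^2/n_i + s_j^2/n_j)/2), Welch-Satterthwaite
    degrees of freedom, and p from the studentized-range distribution with
    k = number of groups.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    stats = []
    for label, vals in groups:
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        if v.size < 2:
            raise ValueError(f"group {label!r} has fewer than 2 finite values")
        stats.append((label, v.mean(), v.var(ddof=1), v.size))
    k = len(stats)
    out = []
    for (la, ma, va, na), (lb, mb, vb, nb) in combinations(stats, 2):
        sa, sb = va / na, vb / nb
        flags: list[str] = []
        if sa + sb == 0.0:
            if ma == mb:
                out.append(GamesHowellResult(la, lb, ma, mb, 0.0,
                                             float(na + nb - 2), 1.0,
                                             ("zero_variance",)))
            else:
                out.append(GamesHowellResult(la, lb, ma, mb, float("inf"),
                                             float(na + nb - 2), 0.0,
                                             ("zero_variance_degenerate",)))
            continue
        q = abs(ma - mb) / np.sqrt((sa + sb) / 2.0)
        df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
        p = float(studentized_range.sf(q, k, df))
        out.append(GamesHowellResult(la, lb, float(ma), float(mb), float(q),
                                     float(df), p, tuple(flags)))
    return out


@dataclass(frozen=True)
class SpeciesPairContrast:
    pair: tuple[str, str]
    te_n: int
    te_mean_ks: float
    te_var_ks: float
    gene_n: int
    gene_mean_ks: float
    gene_var_ks: float
    q: float
    df: float
    p: float
    htt_consistent: bool


def ks_contrast_report(te_ks_by_pair: dict, gene_ks_by_pair: dict,
                       alpha: float = 1e-4) -> list[SpeciesPairContrast]:
    """One TE-vs-nuclear-gene Ks contrast per species pair.

    The decision is "HTT-consistent" iff the TE mean Ks is below the gene
    mean Ks and the Games-Howell p-value is below ``alpha``.  Pairs missing
    from either input are skipped.
    """
    out = []
    for pair in sorted(te_ks_by_pair):
        if pair not in gene_ks_by_pair:
            continue
        te = np.asarray(te_ks_by_pair[pair], dtype=float)
        te = te[np.isfinite(te)]
        gene = np.asarray(gene_ks_by_pair[pair], dtype=float)
        gene = gene[np.isfinite(gene)]
        if te.size < 2 or gene.size < 2:
            continue
        res = games_howell([("te", te), ("gene", gene)])[0]
        decision = bool(te.mean() < gene.mean() and res.p < alpha)
        out.append(SpeciesPairContrast(
            pair=pair, te_n=te.size, te_mean_ks=float(te.mean()),
            te_var_ks=float(te.var(ddof=1)), gene_n=gene.size,
            gene_mean_ks=float(gene.mean()),
            gene_var_ks=float(gene.var(ddof=1)),
            q=res.q, df=res.df, p=res.p, htt_consistent=decision))
    return out


# ---------------------------------------------------------------------------
# Trees


def nj_tree(labels, matrix) -> str:
    """Neighbor-joining tree (Newick, with branch lengths) from a symmetric
    distance matrix; taxa are processed in sorted label order for
    deterministic tie-breaking."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] != matrix.shape[1] or matrix.shape[0] != len(labels):
        raise ValueError("matrix shape does not match labels")
    if not np.allclose(matrix, matrix.T):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(matrix), 0.0):
        raise ValueError("distance matrix diagonal is not zero")
    order = np.argsort(np.asarray(labels, dtype=object))
    labels = [labels[i] for i in order]
    matrix = matrix[np.ix_(order, order)]
    tree = nj(DistanceMatrix(matrix, labels))
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def robinson_foulds(newick_a: str, newick_b: str) -> int:
    """Unrooted Robinson-Foulds distance (count of bipartitions present in
    exactly one tree); the two trees must share a leaf set."""
    import dendropy
    from dendropy.calculate import treecompare

    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    leaves_a = {l.taxon.label for l in ta.leaf_node_iter()}
    leaves_b = {l.taxon.label for l in tb.leaf_node_iter()}
    if leaves_a != leaves_b:
        raise ValueError("trees have different leaf sets")
    for t in (ta, tb):
        t.is_rooted = False
        t.collapse_basal_bifurcation()
        t.encode_bipartitions()
    return int(treecompare.symmetric_difference(ta, tb))
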