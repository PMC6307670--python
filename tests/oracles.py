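"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity by the most direct enumeration available,
sharing nothing with the package implementation beyond the stated
conventions (standard genetic code; stop-creating point mutations count as
nonsynonymous; pathways through stop codons excluded, all-paths fallback
when every pathway is blocked).
"""

from __future__ import annotations

import itertools
import math

import numpy as np

_CODE = {}
_BASES = "TCAG"
_AAS = ("FFLLSSSSYY**CC*W" "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR" "VVVVAAAADDEEGGGG")
for _i, (_b1, _b2, _b3) in enumerate(itertools.product(_BASES, repeat=3)):
    _CODE[_b1 + _b2 + _b3] = _AAS[_i]


def translate(codon: str) -> str:
    return _CODE[codon]


def syn_sites_codon(codon: str) -> float:
    """Fractional synonymous sites of one codon by direct enumeration."""
    s = 0.0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1 :]
            if _CODE[mut] != "*" and _CODE[mut] == _CODE[codon]:
                s += 1 / 3
    return s


def pathway_diffs(ca: str, cb: str):
    """Pathway-averaged (Sd, Nd) between two non-stop codons."""
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    if not diffs:
        return 0.0, 0.0

    def steps(order, allow):
        cur = ca
        sd = nd = 0
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if _CODE[nxt] == "*" and nxt != cb and not allow:
                return None
            if _CODE[nxt] == _CODE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    results = [steps(o, False) for o in itertools.permutations(diffs)]
    results = [r for r in results if r is not None]
    if not results:
        results = [steps(o, True) for o in itertools.permutations(diffs)]
    return (sum(r[0] for r in results) / len(results),
            sum(r[1] for r in results) / len(results))


def ng86(seq_a: str, seq_b: str):
    """Brute-force NG86 over a gap-free in-frame alignment; returns
    (Ks, Ka, S, N, Sd, Nd).  NaN where the correction is undefined."""
    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    S = Sd = Nd = 0.0
    n_codons = 0
    for k in range(0, len(seq_a), 3):
        ca, cb = seq_a[k : k + 3], seq_b[k : k + 3]
        if _CODE[ca] == "*" or _CODE[cb] == "*":
            continue
        n_codons += 1
        S += (syn_sites_codon(ca) + syn_sites_codon(cb)) / 2
        sd, nd = pathway_diffs(ca, cb)
        Sd += sd
        Nd += nd
    N = 3 * n_codons - S

    def jc(p):
        return float("nan") if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    ks = float("nan") if S == 0 else jc(Sd / S)
    ka = float("nan") if N == 0 else jc(Nd / N)
    return ks, ka, S, N, Sd, Nd


def orf_scan(seq: str, min_len: int):
    """Naive six-frame stop-to-stop scan; returns a set of
    (start, end, strand) forward-strand intervals."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    out = set()
    for strand in "+-":
        s = seq if strand == "+" else "".join(comp[b] for b in reversed(seq))
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, len(s) - 2, 3)]
            run_start = frame
            pos = frame
            for c in codons:
                if _CODE.get(c, "") == "*":
                    if pos - run_start >= min_len:
                        out.add(_fwd(run_start, pos, strand, len(s)))
                    run_start = pos + 3
                pos += 3
            if pos - run_start >= min_len:
                out.add(_fwd(run_start, pos, strand, len(s)))
    return out


def _fwd(s, e, strand, n):
    return (s, e, "+") if strand == "+" else (n - e, n - s, "-")


def studentized_range_cdf(q: float, k: int, df: float) -> float:
    """P(Q <= q) for the studentized range, by direct numerical integration
    of the double integral (outer over the scale factor s = sqrt(chi2/df),
    inner over the location of the minimum)."""
    from scipy.integrate import quad
    from scipy.stats import norm

    def inner(s):
        qs = q * s

        def f(z):
            return norm.pdf(z) * (norm.cdf(z) - norm.cdf(z - qs)) ** (k - 1)

        val, _ = quad(f, -8.0, 8.0, limit=200)
        return k * val

    ln_c = (df / 2) * math.log(df) - math.lgamma(df / 2) \
        - (df / 2 - 1) * math.log(2)

    def outer(s):
        return math.exp(ln_c + (df - 1) * math.log(s) - df * s * s / 2) \
            * inner(s)

    val, _ = quad(outer, 1e-8, 10.0, limit=200)
    return val


def pairwise_pi_p(seqs):
    """O(n^2 L) mean pairwise p-distance with pairwise deletion."""
    n = len(seqs)
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            num = den = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in "ACGT" and b in "ACGT":
                    den += 1
                    num += a != b
            vals.append(num / den)
    return float(np.mean(vals))


def random_codon_seq(rng, n_codons, allow_gaps=False):
    """Random in-frame coding sequence without stop codons."""
    codons = [c for c in _CODE if _CODE[c] != "*"]
    return "".join(codons[rng.integers(0, len(codons))]
                   for _ in range(n_codons))
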