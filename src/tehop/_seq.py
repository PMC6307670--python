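"""Small shared sequence helpers (DNA alphabet, distances, encodings)."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# integer encoding: A=0 C=1 G=2 T=3, anything else (N, gap) = 4
_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 (A=0 C=1 G=2 T=3, other=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[arr].tobytes().decode("ascii")


def orient_like(seq: str, ref: str) -> str:
    """Return ``seq`` or its reverse complement, whichever matches ``ref``
    better over their common prefix length."""
    n = min(len(seq), len(ref))
    fwd = sum(a == b for a, b in zip(seq[:n], ref[:n]))
    rc = revcomp(seq)
    rev = sum(a == b for a, b in zip(rc[:n], ref[:n]))
    return seq if fwd >= rev else rc


def canonical_strand(seq: str) -> str:
    """Return the lexicographically smaller of a sequence and its reverse
    complement (deterministic strand normalization)."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def p_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Proportion of differing sites, pairwise-deleting sites where either
    sequence is not an unambiguous base."""
    ok = (a < 4) & (b < 4)
    n = int(ok.sum())
    if n == 0:
        return float("nan")
    return float(((a != b) & ok).sum() / n)


def jc_correct(p: float) -> float:
    """Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3)."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


_PURINE = np.array([True, False, True, False])  # A, G


def k2p_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Kimura two-parameter distance with pairwise deletion."""
    ok = (a < 4) & (b < 4)
    n = int(ok.sum())
    if n == 0:
        return float("nan")
    diff = (a != b) & ok
    ts = diff & (_PURINE[np.where(ok, a, 0)] == _PURINE[np.where(ok, b, 0)])
    P = float(ts.sum() / n)               # transitions
    Q = float(diff.sum() / n) - P         # transversions
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return float("nan")
    return float(-0.5 * np.log(w1) - 0.25 * np.log(w2))


def corrected_distance(a: np.ndarray, b: np.ndarray, model: str = "K2P") -> float:
    if model == "p":
        return p_distance(a, b)
    if model == "JC":
        return jc_correct(p_distance(a, b))
    if model == "K2P":
        return k2p_distance(a, b)
    raise ValueError(f"unknown distance model: {model!r}")
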