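"""Element anatomy: consensus reconstruction and structural annotation.

A species-specific consensus is rebuilt from genomic copies by strand
normalization, placement of every fragment against a reference fragment
(edit-distance infix alignment) and majority rule over the resulting columns.
Structural annotation covers open reading frames (stop-to-stop, both
strands), terminal inverted repeats, and the two diagnostic mariner
transposase motifs (DD34D catalytic triad spacing, C-terminal YSPDLAP).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from ._seq import canonical_strand, revcomp

__all__ = [
    "ConsensusResult",
    "Orf",
    "TirPair",
    "MotifHits",
    "TECopySet",
    "build_consensus",
    "find_orfs",
    "find_tirs",
    "scan_mariner_motifs",
]


@dataclass
class ConsensusResult:
    status: str                       # "ok" | "remnant_only"
    consensus: str | None
    n_fragments_used: int


@dataclass(frozen=True)
class Orf:
    start: int          # 0-based, forward-strand coordinates, half-open
    end: int
    strand: str         # "+" | "-"
    frame: int          # 0..2 within its strand
    length_nt: int
    first_atg: int | None   # offset of first internal ATG within the ORF, nt
    translation: str


@dataclass(frozen=True)
class TirPair:
    left: tuple[int, int]
    right: tuple[int, int]
    length: int
    identity: float


@dataclass(frozen=True)
class MotifHits:
    dd34d: tuple[tuple[int, int], ...]   # (second D, third D) positions
    yspdlap: tuple[int, ...]             # start positions (<=1 mismatch)


@dataclass
class TECopySet:
    te_name: str
    species: str
    copies: list = field(default_factory=list)  # (sequence, (start, end), strand)
    consensus: str | None = None
    orfs: list = field(default_factory=list)
    tir: TirPair | None = None
    motifs: MotifHits | None = None

    @property
    def autonomous(self) -> bool:
        """Intact ORF + TIR pair + DD34D catalytic motif."""
        return bool(self.orfs) and self.tir is not None \
            and self.motifs is not None and bool(self.motifs.dd34d)


# ---------------------------------------------------------------------------
# Consensus


def _parse_cigar(cigar: str):
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + int(ch)
        else:
            yield n, ch
            n = 0


def build_consensus(copies, min_fragment_bp: int = 100) -> ConsensusResult:
    """Majority-rule consensus over genomic fragments of one element.

    Fragments shorter than ``min_fragment_bp`` are dropped; if fewer than two
    remain the element is reported as remnant-only.  Every fragment is
    normalized to a canonical strand, placed against the longest fragment by
    infix edit-distance alignment, and columns with at least two supporting
    fragments are called by majority (ties broken A<C<G<T); columns with less
    support emit N.
    """
    seqs = [s.upper() for s in copies if len(s) >= min_fragment_bp]
    if len(seqs) < 2:
        return ConsensusResult("remnant_only", None, len(seqs))

    # deterministic reference: longest fragment, ties by canonical sequence
    ref = canonical_strand(sorted(seqs, key=lambda s: (-len(s), canonical_strand(s)))[0])
    L = len(ref)
    counts = np.zeros((L, 4), dtype=np.int64)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    used = 0
    for frag in sorted(seqs):
        fwd = edlib.align(frag, ref, mode="HW", task="path")
        rev = edlib.align(revcomp(frag), ref, mode="HW", task="path")
        res, seq = (fwd, frag) if fwd["editDistance"] <= rev["editDistance"] \
            else (rev, revcomp(frag))
        start = res["locations"][0][0]
        qpos, tpos = 0, start
        for n, op in _parse_cigar(res["cigar"]):
            if op in "=X":
                for k in range(n):
                    b = base_idx.get(seq[qpos + k])
                    if b is not None:
                        counts[tpos + k, b] += 1
                qpos += n
                tpos += n
            elif op == "I":      # insertion in fragment relative to reference
                qpos += n
            elif op == "D":      # deletion in fragment
                tpos += n
        used += 1

    support = counts.sum(axis=1)
    best = counts.argmax(axis=1)          # argmax takes lowest index on ties: A<C<G<T
    cons = np.where(support >= 2, best, 4)
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    consensus = lut[cons].tobytes().decode("ascii")
    return ConsensusResult("ok", canonical_strand(consensus), used)


# ---------------------------------------------------------------------------
# ORFs

_STOPS = {"TAA", "TAG", "TGA"}


def _orfs_one_strand(seq: str, strand: str, min_len_nt: int, total_len: int):
    out = []
    for frame in range(3):
        # stop-to-stop segments within this frame
        seg_start = frame
        pos = frame
        while pos + 3 <= len(seq):
            codon = seq[pos : pos + 3]
            if codon in _STOPS:
                if pos - seg_start >= min_len_nt:
                    out.append((seg_start, pos, frame))
                seg_start = pos + 3
            pos += 3
        if pos - seg_start >= min_len_nt:
            out.append((seg_start, pos, frame))
    orfs = []
    for s, e, frame in out:
        sub = seq[s:e]
        atg = sub.find("ATG")
        while atg != -1 and atg % 3:
            atg = sub.find("ATG", atg + 1)
        translation = str(Seq(sub).translate())
        if strand == "+":
            start, end = s, e
        else:
            start, end = total_len - e, total_len - s
        orfs.append(Orf(start=start, end=end, strand=strand, frame=frame,
                        length_nt=e - s,
                        first_atg=None if atg == -1 else atg,
                        translation=translation))
    return orfs


def find_orfs(seq: str, min_len_nt: int = 300) -> list[Orf]:
    """All stop-to-stop open reading frames >= min_len_nt on both strands,
    sorted by length descending (ties by start, then strand)."""
    seq = seq.upper()
    orfs = _orfs_one_strand(seq, "+", min_len_nt, len(seq))
    orfs += _orfs_one_strand(revcomp(seq), "-", min_len_nt, len(seq))
    return sorted(orfs, key=lambda o: (-o.length_nt, o.start, o.strand))


# ---------------------------------------------------------------------------
# TIRs

_TIR_ALIGNER = PairwiseAligner()
_TIR_ALIGNER.mode = "local"
_TIR_ALIGNER.match_score = 2.0
_TIR_ALIGNER.mismatch_score = -3.0
_TIR_ALIGNER.open_gap_score = -5.0
_TIR_ALIGNER.extend_gap_score = -2.0


def find_tirs(seq: str, min_len: int = 10, min_identity: float = 0.80,
              terminal_window: int = 150, min_score: float = 25.0) -> TirPair | None:
    """Best local alignment between the 5' terminal region and the reverse
    complement of the 3' terminal region; None when no hit meets the length,
    identity and score thresholds.

    The score floor (match 2 / mismatch -3 units) plays the same gating role
    as einverted's alignment threshold: without it, short 80%-identity local
    matches arise constantly between 150-bp random windows.
    """
    seq = seq.upper()
    if len(seq) < 2 * min_len:
        raise ValueError("sequence shorter than twice the minimum TIR length")
    w = min(terminal_window, len(seq) // 2)
    left = seq[:w]
    right_rc = revcomp(seq[-w:])
    alns = _TIR_ALIGNER.align(left, right_rc)
    if len(alns) == 0 or alns[0].score < min_score:
        return None
    aln = alns[0]
    (l0, l1) = (int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1]))
    (r0, r1) = (int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1]))
    matches = sum(
        left[a0 + k] == right_rc[b0 + k]
        for (a0, a1), (b0, _b1) in zip(*aln.aligned)
        for k in range(a1 - a0)
    )
    span = max(l1 - l0, r1 - r0)
    identity = matches / span
    if span < min_len or identity < min_identity:
        return None
    # map right interval from RC coordinates back to forward coordinates
    right = (len(seq) - w + (w - r1), len(seq) - w + (w - r0))
    return TirPair(left=(l0, l1), right=right, length=span,
                   identity=float(identity))


# ---------------------------------------------------------------------------
# Mariner motifs


def scan_mariner_motifs(protein: str) -> MotifHits:
    """DD34D spacing occurrences and YSPDLAP (<=1 mismatch) occurrences.

    A DD34D hit is a pair of aspartates exactly 34 residues apart
    (positions j and j+35) preceded by at least one further aspartate — the
    D..D-x(34)-D catalytic-triad signature of mariner transposases.
    """
    protein = protein.upper()
    first_d = protein.find("D")
    dd34d = []
    if first_d != -1:
        for j in range(first_d + 1, len(protein) - 35):
            if protein[j] == "D" and protein[j + 35] == "D":
                dd34d.append((j, j + 35))
    motif = "YSPDLAP"
    ysp = [i for i in range(len(protein) - len(motif) + 1)
           if sum(a != b for a, b in zip(protein[i : i + len(motif)], motif)) <= 1]
    return MotifHits(dd34d=tuple(dd34d), yspdlap=tuple(ysp))
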