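"""Element anatomy: consensus, ORFs, TIRs, mariner motifs."""

import numpy as np
import pytest

import oracles
from tehop._seq import revcomp
from tehop.anatomy import (build_consensus, find_orfs, find_tirs,
                           scan_mariner_motifs)


def _rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


# ---------------------------------------------------------------------------
# Consensus


def test_identical_copies_give_that_copy():
    rng = np.random.default_rng(0)
    s = _rand_seq(rng, 500)
    res = build_consensus([s] * 5)
    assert res.status == "ok"
    assert res.consensus in (s, revcomp(s))


def test_majority_rule_single_column():
    rng = np.random.default_rng(1)
    s = _rand_seq(rng, 400)
    variants = []
    for i in range(5):
        v = list(s)
        v[200] = "AAAGG"[i]          # column votes A,A,A,G,G -> A
        variants.append("".join(v))
    res = build_consensus(variants)
    cons = res.consensus if res.consensus[:5] == s[:5] else revcomp(res.consensus)
    assert cons[200] == "A"


def test_consensus_invariant_to_order_and_strand_flips():
    rng = np.random.default_rng(2)
    s = _rand_seq(rng, 600)
    copies = []
    for _ in range(8):
        v = list(s)
        for pos in rng.integers(0, 600, size=6):
            v[pos] = "ACGT"[rng.integers(0, 4)]
        copies.append("".join(v))
    base = build_consensus(copies).consensus
    shuffled = [copies[i] for i in rng.permutation(len(copies))]
    flipped = [revcomp(c) if i % 2 else c for i, c in enumerate(shuffled)]
    assert build_consensus(flipped).consensus == base


def test_short_fragments_give_remnant_only():
    res = build_consensus(["ACGT" * 10, "ACGT" * 12], min_fragment_bp=100)
    assert res.status == "remnant_only"
    assert res.consensus is None


def test_consensus_approaches_ancestor_with_copy_number():
    """Median consensus-to-ancestor distance decreases as copies accumulate."""
    rng = np.random.default_rng(3)
    anc = _rand_seq(rng, 800)
    meds = []
    for n in (5, 20, 100):
        dists = []
        for rep in range(3):
            copies = []
            for _ in range(n):
                v = np.frombuffer(anc.encode(), dtype=np.uint8).copy()
                pos = rng.integers(0, 800, size=24)     # 3% divergence each
                for p in pos:
                    v[p] = ord("ACGT"[rng.integers(0, 4)])
                copies.append(v.tobytes().decode())
            cons = build_consensus(copies).consensus
            cons = cons if sum(a == b for a, b in zip(cons, anc)) \
                >= sum(a == b for a, b in zip(revcomp(cons), anc)) \
                else revcomp(cons)
            dists.append(np.mean([a != b for a, b in zip(cons, anc)]))
        meds.append(np.median(dists))
    assert meds[0] >= meds[1] >= meds[2]
    assert meds[2] <= 0.001


def test_simulated_consensus_near_true_element(small_world):
    sp = "antB"
    fam = small_world.te[sp]
    res = build_consensus([fam.copies[c] for c in sorted(fam.copies)])
    cons = res.consensus
    master = fam.master_current
    ident = max(np.mean([a == b for a, b in zip(cons, master)]),
                np.mean([a == b for a, b in zip(revcomp(cons), master)]))
    assert ident >= 0.99


# ---------------------------------------------------------------------------
# ORFs


def test_stop_saturated_frame_yields_no_orfs():
    # every frame-0 codon is a stop, so no forward frame-0 ORF can exist;
    # an empty result is also valid when the floor exceeds the sequence
    orfs = find_orfs("TAATAGTGA" * 40, min_len_nt=30)
    assert not [o for o in orfs if o.strand == "+" and o.frame == 0]
    assert find_orfs("ATGAAATGA", min_len_nt=300) == []


def test_planted_transposase_orf_recovered():
    """A 1,059-nt ORF embedded in stop-rich flanks is recovered at its
    planted coordinates at the matching length floor."""
    rng = np.random.default_rng(4)
    inner = oracles.random_codon_seq(rng, 353)          # 1,059 nt, stop-free
    flank_l = "TAATGATAG" * 30
    flank_r = "TGATAATAG" * 30
    seq = flank_l + inner + "TAA" + flank_r
    orfs = find_orfs(seq, min_len_nt=1059)
    fwd = [o for o in orfs if o.strand == "+"]
    assert len(fwd) == 1
    o = fwd[0]
    assert (o.start, o.end) == (len(flank_l), len(flank_l) + 1059)
    assert o.length_nt == 1059


def test_orfs_match_sixframe_bruteforce_oracle():
    rng = np.random.default_rng(5)
    for _ in range(10):
        seq = _rand_seq(rng, 3000)
        got = {(o.start, o.end, o.strand)
               for o in find_orfs(seq, min_len_nt=300)}
        assert got == oracles.orf_scan(seq, 300)


# ---------------------------------------------------------------------------
# TIRs


def test_planted_exact_tir():
    rng = np.random.default_rng(6)
    tir = _rand_seq(rng, 30)
    seq = tir + _rand_seq(rng, 800) + revcomp(tir)
    pair = find_tirs(seq)
    assert pair is not None
    assert pair.identity == 1.0
    assert pair.left == (0, 30)
    assert pair.right == (830, 860)


def test_tir_with_two_mismatches_over_30bp():
    rng = np.random.default_rng(7)
    tir = _rand_seq(rng, 30)
    right = list(revcomp(tir))
    for pos in (8, 20):
        right[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[right[pos]]
    seq = tir + _rand_seq(rng, 700) + "".join(right)
    pair = find_tirs(seq)
    assert pair is not None
    assert pair.identity == pytest.approx(28 / 30, abs=0.01)
    assert pair.identity > 0.93


def test_random_sequence_false_tir_rate_low():
    rng = np.random.default_rng(8)
    false = sum(find_tirs(_rand_seq(rng, 600)) is not None
                for _ in range(300))
    assert false / 300 <= 0.05


# ---------------------------------------------------------------------------
# Motifs


def test_protein_without_d_has_no_catalytic_hits():
    assert scan_mariner_motifs("MKLVNNNRRW" * 20).dd34d == ()


def test_planted_dd34d_and_yspdlap_found():
    prot = ("M" + "A" * 30 + "D" + "G" * 33 + "D" + "H" * 34 + "D"
            + "K" * 20 + "YSPDLAP" + "AA")
    hits = scan_mariner_motifs(prot)
    j = 31 + 34
    assert (j, j + 35) in hits.dd34d
    assert prot.find("YSPDLAP") in hits.yspdlap


def test_yspdlap_tolerates_one_mismatch():
    prot = "A" * 50 + "YSPELAP" + "A" * 10
    assert 50 in scan_mariner_motifs(prot).yspdlap
    prot2 = "A" * 50 + "YSQELAP" + "A" * 10
    assert 50 not in scan_mariner_motifs(prot2).yspdlap
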