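"""Codon divergence engine: NG86 counting, alignment threading, Z-test."""

import numpy as np
import pytest
from hypothesis import given, seed as hyp_seed, settings
from hypothesis import strategies as st

import oracles
from tehop.ks import (CodonAlignment, InternalStopError, bh_fdr, codon_align,
                      codon_z_test, cross_set_ks, ks_ng86)


def test_identical_sequences_have_zero_divergence():
    aln = codon_align("ATGAAATTTGGG", "ATGAAATTTGGG")
    assert aln.removed_columns == 0
    rec = ks_ng86(aln, min_codons=1)
    assert rec.ks == 0.0 and rec.ka == 0.0
    assert rec.s_sites + rec.n_sites == pytest.approx(3 * rec.codons)


def test_single_synonymous_change_hand_worked():
    """100 TTT codons vs 99 TTT + 1 TTC: phenylalanine's third position has
    exactly one synonymous alternative of three, so S = 100/3 per sequence,
    Sd = 1, and Ks is the Jukes-Cantor-corrected 3/100."""
    a = "TTT" * 100
    b = "TTT" * 99 + "TTC"
    rec = ks_ng86(CodonAlignment(a, b))
    assert rec.s_sites == pytest.approx(100 / 3)
    assert rec.sd == pytest.approx(1.0)
    assert rec.nd == pytest.approx(0.0)
    ps = 1.0 / (100 / 3)
    expected = -0.75 * np.log(1 - 4 * ps / 3)
    assert rec.ks == pytest.approx(expected)
    assert rec.ka == 0.0


def test_ng86_matches_bruteforce_oracle_on_random_alignments():
    rng = np.random.default_rng(42)
    for _ in range(120):
        n = int(rng.integers(10, 120))
        a = oracles.random_codon_seq(rng, n)
        # derive b from a by random codon replacement for realistic overlap
        b = list(a)
        for k in range(0, 3 * n, 3):
            if rng.random() < 0.3:
                b[k : k + 3] = oracles.random_codon_seq(rng, 1)
        b = "".join(b)
        rec = ks_ng86(CodonAlignment(a, b), min_codons=1)
        ks, ka, S, N, Sd, Nd = oracles.ng86(a, b)
        assert rec.s_sites == pytest.approx(S, abs=1e-9)
        assert rec.sd == pytest.approx(Sd, abs=1e-9)
        assert rec.nd == pytest.approx(Nd, abs=1e-9)
        if np.isnan(ks):
            assert "saturated_s" in rec.flags or "no_synonymous_sites" in rec.flags
        else:
            assert rec.ks == pytest.approx(ks, abs=1e-9)


def test_ng86_symmetry_in_arguments():
    rng = np.random.default_rng(7)
    a = oracles.random_codon_seq(rng, 50)
    b = oracles.random_codon_seq(rng, 50)
    r1 = ks_ng86(CodonAlignment(a, b))
    r2 = ks_ng86(CodonAlignment(b, a))
    assert r1.s_sites == pytest.approx(r2.s_sites)
    assert r1.sd == pytest.approx(r2.sd)
    if np.isfinite(r1.ks):
        assert r1.ks == pytest.approx(r2.ks)


def test_codon_align_removes_planted_indel_column():
    a = "ATGAAATTTGGGCCTTGA"[:15]          # ATG AAA TTT GGG CCT
    b = "ATGAAACACTTTGGGCCT"               # ATG AAA CAC TTT GGG CCT
    aln = codon_align(a, b)
    assert aln.n_codons == 5
    assert aln.seq_a == a
    assert aln.seq_b == b[:6] + b[9:]
    assert aln.removed_columns == 1


def test_codon_align_rejects_internal_stop():
    with pytest.raises(InternalStopError) as err:
        codon_align("ATGTAAAAATTT", "ATGAAAAAATTT")
    assert err.value.codon_index == 1


def test_cross_set_attempts_every_pair():
    rng = np.random.default_rng(3)
    base = oracles.random_codon_seq(rng, 30)

    def mutant():
        b = list(base)
        for k in range(0, len(base), 3):
            if rng.random() < 0.2:
                b[k : k + 3] = oracles.random_codon_seq(rng, 1)
        return "".join(b)

    A = [mutant() for _ in range(3)]
    B = [mutant() for _ in range(4)]
    records, failures = cross_set_ks(A, B, min_codons=5)
    assert len(records) + len(failures) == 12
    for i, j, rec in records:
        ks, *_ = oracles.ng86(A[i], B[j])
        if np.isfinite(ks):
            assert rec.ks == pytest.approx(ks, abs=1e-9)


def test_z_test_degenerate_and_power():
    ident = CodonAlignment("ATGAAATTTGGG" * 10, "ATGAAATTTGGG" * 10)
    z, p, flags = codon_z_test(ident, n_bootstrap=50, seed=0)
    assert p == 1.0

    # purifying pair: many synonymous, almost no nonsynonymous changes
    rng = np.random.default_rng(10)
    hits = 0
    for rep in range(20):
        a = "".join(["GGA", "CCA", "TCA", "ACA"][rng.integers(0, 4)]
                    for _ in range(500))
        b = list(a)
        for k in range(0, len(a), 3):
            if rng.random() < 0.25:     # third-position (synonymous) change
                b[k + 2] = "ACGT"[rng.integers(0, 4)]
        z, p, _ = codon_z_test(CodonAlignment(a, "".join(b)),
                               n_bootstrap=300, seed=rep)
        hits += p < 0.05
    assert hits >= 18


def test_bh_fdr_hand_computation():
    adj = bh_fdr([0.01, 0.02, 0.04])
    assert adj == pytest.approx([0.03, 0.03, 0.04])
    assert np.all(adj <= 1.0)


@settings(max_examples=40, deadline=None)
@hyp_seed(1234)
@given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1,
                max_size=20))
def test_bh_fdr_monotone_and_bounded(pvals):
    adj = bh_fdr(pvals)
    assert np.all(adj <= 1.0 + 1e-12)
    order = np.argsort(pvals)
    assert np.all(np.diff(adj[order]) >= -1e-12)
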