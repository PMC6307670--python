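"""Simulator ground truth, invariants, determinism, fixtures."""

import json

import numpy as np
import pytest

from tehop._seq import encode
from tehop.simulate import (default_config, simulate_brother_pairs,
                            simulate_world, write_fixtures)

EQUAL_RATES = {s: 3.5e-9 for s in ("flyA", "flyB", "bee", "antA", "antB")}


def tiny_config(**over):
    base = dict(seed=0, n_nuclear_genes=10, gene_length_codons=60,
                max_copies=30, transposition_rate=100.0,
                include_brother_pairs=False, include_genomes=False,
                n_decoy_tes=0, n_reference_genes=50)
    base.update(over)
    return default_config(**base)


def test_zero_rates_give_identical_copies_everywhere():
    cfg = tiny_config(rates={s: 0.0 for s in EQUAL_RATES}, donor_rate=0.0)
    w = simulate_world(cfg)
    src = w.te_source
    for sp, fam in w.te.items():
        for seq in fam.copies.values():
            assert seq == src
    # nuclear genes identical across species as well
    for i in range(10):
        assert len({w.genes[sp][i] for sp in w.species}) == 1


def test_copy_count_within_birth_process_envelope():
    """Random-template mode is a linear (Yule) birth process: over t active
    My the copy number N is geometric with mean e^{lambda t}, so
    P(N >= n) = (1 - 1/m)^(n-1).  With lambda t = ln(20) the 99% envelope
    is checked over replicates."""
    lam, t = np.log(20) / 2.5, 2.5
    counts = []
    for seed in range(40):
        cfg = tiny_config(seed=seed, template_mode="random",
                          transposition_rate=lam, max_copies=4000,
                          htt_events={"antB": t},
                          burst_schedule={"antB": [(t, 0.0)]})
        w = simulate_world(cfg)
        counts.append(len(w.te["antB"].copies))
    m = 20.0
    # geometric: median = ln 2 * m approx; mean m; check mean within
    # 99% envelope of the mean of 40 geometric draws (sd ~ m)
    assert abs(np.mean(counts) - m) < 3 * m / np.sqrt(40) + 1


def test_nuclear_divergence_matches_2rt():
    """Two species split 50 My ago at 5.17e-9/site/year accumulate
    2rt = 0.517 expected substitutions per site; the JC-corrected observed
    divergence recovers it within sampling error."""
    cfg = tiny_config(
        species_tree="(flyA:50,flyB:50);",
        rates={"flyA": 5.17e-9, "flyB": 5.17e-9},
        htt_events={"flyA": 0.2}, n_nuclear_genes=60, gene_length_codons=100)
    w = simulate_world(cfg)
    from tehop._seq import corrected_distance

    a = encode("".join(w.genes["flyA"]))
    b = encode("".join(w.genes["flyB"]))
    d = corrected_distance(a, b, "JC")
    # stop-codon avoidance slightly depresses the realized rate; 5%
    # tolerance covers it together with binomial noise at 18 kb
    assert d == pytest.approx(0.517, rel=0.05)


def test_copy_age_never_exceeds_transfer_time():
    w = simulate_world(tiny_config(seed=3))
    for sp, fam in w.te.items():
        assert max(fam.ages.values()) <= fam.t_h + 1e-12
        assert min(fam.ages.values()) >= 0.0


def test_copy_divergence_from_template_tracks_age():
    """E[raw distance copy vs its template snapshot] = JC p(mu) at
    mu = r x age; checked within 3 sigma binomial bounds."""
    cfg = tiny_config(seed=4, rates=dict(EQUAL_RATES), max_copies=120,
                      transposition_rate=400.0)
    w = simulate_world(cfg)
    fam = w.te["antB"]
    r = EQUAL_RATES["antB"]
    L = len(w.te_source)
    for cid in sorted(fam.copies)[:40]:
        if cid == fam.master_id:
            continue
        age = fam.ages[cid]
        mu = r * age * 1e6
        p_exp = 0.75 * (1 - np.exp(-4 * mu / 3))
        obs = np.mean(encode(fam.copies[cid])
                      != encode(fam.template_snapshots[cid]))
        sd = np.sqrt(max(p_exp * (1 - p_exp), 1e-12) / L)
        assert abs(obs - p_exp) <= 3 * sd + 2 / L


def test_no_te_in_lineages_without_transfer():
    cfg = tiny_config(htt_events={"antB": 2.5, "flyA": 0.5})
    w = simulate_world(cfg)
    assert set(w.te) == {"antB", "flyA"}


def test_transfer_older_than_lineage_rejected():
    with pytest.raises(ValueError):
        simulate_world(tiny_config(htt_events={"antB": 90.0}))


def test_brother_pair_truth_and_effective_genomes():
    bp = simulate_brother_pairs(default_config(seed=2))
    assert bp.effective_genomes == pytest.approx(
        14 * np.mean(list(bp.ibd_truth.values())))
    assert bp.effective_genomes == pytest.approx(14 * 0.62, rel=0.12)
    kinds = {t["kind"] for t in bp.insertion_truth}
    assert kinds == {"common", "family_specific"}


def test_ibd_fraction_one_emits_warning_and_no_dense_windows():
    with pytest.warns(UserWarning):
        bp = simulate_brother_pairs(default_config(seed=1, ibd_fraction=1.0))
    for tab in bp.snp_tables.values():
        # only the residual error-rate SNPs remain
        assert len(tab) < 200


def test_single_planted_insertion_truth():
    bp = simulate_brother_pairs(default_config(
        seed=9, n_common_insertions=0, n_family_specific_insertions=0,
        n_de_novo_insertions=1, tsd_len=4, n_families=1,
        junction_noise_fraction=0.0))
    assert len(bp.insertion_truth) == 1
    assert bp.insertion_truth[0]["tsd_len"] == 4


def test_determinism_and_fixture_manifest(tmp_path):
    cfg = tiny_config(seed=8, include_genomes=True, genome_length=40_000,
                      genome_copy_cap=5, include_brother_pairs=True,
                      pair_genome_length=200_000)
    m1 = write_fixtures(simulate_world(cfg), tmp_path / "a")
    m2 = write_fixtures(simulate_world(cfg), tmp_path / "b")
    assert m1 == m2
    checks = {f["path"]: f["sha256"] for f in m1["files"]}
    assert checks == {f["path"]: f["sha256"] for f in m2["files"]}
    # all six interface classes present
    assert set(m1["file_classes"]) == {
        "genome_fasta", "te_fasta", "gene_fasta", "hit_tsv", "masking_tsv",
        "tpm_tsv", "snp_vcf", "junction_bed", "truth_json"} - set()
    truth = json.loads((tmp_path / "a" / "truth.json").read_text())
    assert truth["htt_times"] == {s: t for s, t in
                                  cfg.htt_events.items()}


def test_expression_tiers_controllable(small_world):
    expr = small_world.expression
    focal = expr[expr["te_name"] == "ActiveMariner_TE"]
    assert (focal["tier_truth"] == "high").all()
    from tehop.expression import classify_expression, expression_tiers

    for row in focal.itertuples():
        tiers = expression_tiers(small_world.reference_tpms[row.sample])
        assert classify_expression(row.tpm, tiers) == "high"
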