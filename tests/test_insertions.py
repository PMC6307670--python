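"""IBD windows, insertion calling, occupancy classification, rate bound."""

import numpy as np
import pandas as pd
import pytest

from tehop.insertions import (call_insertions, classify_family_occupancy,
                              ibd_windows, insertion_rate_bound)


def test_empty_snp_table_all_ibd_with_warning():
    with pytest.warns(UserWarning):
        wins, frac = ibd_windows(pd.DataFrame(columns=["chrom", "pos"]),
                                 {"chr1": 100_000})
    assert frac == 1.0
    assert all(w.state == "IBD" for w in wins)


def test_planted_alternating_blocks_recovered_exactly():
    rows = []
    # windows 0-9 clean, 10-19 dense (40 SNPs each), repeating
    for w in range(40):
        if (w // 10) % 2 == 1:
            rows.extend({"chrom": "chr1", "pos": w * 10_000 + 250 * i}
                        for i in range(40))
    snp = pd.DataFrame(rows)
    wins, frac = ibd_windows(snp, {"chr1": 400_000})
    states = [w.state for w in wins]
    expected = ["IBD" if (w // 10) % 2 == 0 else "non-IBD" for w in range(40)]
    assert states == expected
    assert frac == pytest.approx(0.5)


def test_simulated_pairs_recover_configured_ibd_fraction(brother_world):
    fracs = [ibd_windows(tab, brother_world.chrom_lengths)[1]
             for tab in brother_world.snp_tables.values()]
    assert np.mean(fracs) == pytest.approx(0.62, abs=0.05)
    # window-level accuracy against the generator's truth
    from tehop.simulate import default_config

    assert 0 < np.std(fracs) < 0.2


def test_no_te_reads_no_calls():
    df = pd.DataFrame({"chrom": [], "start": [], "end": [], "side": [],
                       "mapq": [], "sample": []})
    calls, low = call_insertions(df)
    assert calls == [] and low == []


def test_planted_insertion_with_4bp_tsd():
    bp, tsd = 50_000, 4
    rows = []
    for i in range(10):
        rows.append(("chr1", bp + tsd - 100, bp + tsd, "TE-left", 60, "s1"))
        rows.append(("chr1", bp, bp + 100, "TE-right", 60, "s1"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "side",
                                     "mapq", "sample"])
    ref = {"chr1": "A" * bp + "CGTA" + "A" * 1000}
    calls, _ = call_insertions(df, tsd_range=(2, 10), reference=ref)
    assert len(calls) == 1
    c = calls[0]
    assert c.tsd_len == 4
    assert (c.start, c.end) == (bp, bp + tsd)
    assert c.tsd_seq == "CGTA"
    assert c.left_reads == c.right_reads == 10


def test_mapq_floor_is_a_hard_filter():
    rows = [("chr1", 900, 1000, "TE-left", 5, "s1"),
            ("chr1", 998, 1098, "TE-right", 5, "s1")] * 5
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "side",
                                     "mapq", "sample"])
    calls, low = call_insertions(df, min_mapq=10)
    assert calls == [] and low == []


def test_tsd_outside_range_reported_low_confidence():
    rows = []
    for i in range(5):
        rows.append(("chr1", 880, 1000, "TE-left", 60, "s1"))
        rows.append(("chr1", 985, 1100, "TE-right", 60, "s1"))  # 15-bp overlap
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "side",
                                     "mapq", "sample"])
    calls, low = call_insertions(df, tsd_range=(2, 10))
    assert calls == [] and len(low) == 1


def test_benchmark_recall_precision_on_planted_insertions(brother_world):
    """50 planted loci with 5% stray junction reads."""
    from tehop.simulate import default_config, simulate_brother_pairs

    bp = simulate_brother_pairs(default_config(
        seed=17, n_common_insertions=10, n_family_specific_insertions=42))
    truth = {(t["chrom"], t["pos"]) for t in bp.insertion_truth}
    assert len(truth) >= 50
    calls, _ = call_insertions(bp.junction_reads, min_mapq=10)
    merged, summary = classify_family_occupancy(calls, bp.family_of_sample)
    tp = sum(any(c == m.chrom and abs(m.start - p) <= 12 for c, p in truth)
             for m in merged)
    recall = tp / len(truth)
    precision = tp / len(merged)
    assert recall >= 0.9
    assert precision >= 0.95


def test_family_occupancy_classification_and_partition(brother_world):
    calls, _ = call_insertions(brother_world.junction_reads, min_mapq=10)
    merged, summary = classify_family_occupancy(
        calls, brother_world.family_of_sample)
    assert summary["n_common"] + summary["n_family_specific"] \
        == summary["n_total"]
    truth_common = sum(t["kind"] == "common"
                       for t in brother_world.insertion_truth)
    assert summary["n_common"] == truth_common
    # every family retains unique insertions (the per-family polymorphism
    # pattern); generator plants at least two per family
    per_fam = summary["per_family_unique"]
    assert len(per_fam) == 7
    assert min(per_fam.values()) >= 2
    assert any(m.excised for m in merged)
    assert all(m.min_mapq >= 10 for m in merged)


def test_single_family_all_family_specific():
    rows = []
    for loc in (10_000, 20_000):
        rows.append(("chr1", loc - 98, loc + 2, "TE-left", 60, "F1_a"))
        rows.append(("chr1", loc, loc + 100, "TE-right", 60, "F1_a"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "side",
                                     "mapq", "sample"])
    calls, _ = call_insertions(df)
    merged, summary = classify_family_occupancy(calls, {"F1_a": "F1"})
    assert summary["n_common"] == 0
    assert summary["n_family_specific"] == 2


def test_exclusion_mask_removes_calls():
    rows = []
    for loc in (10_000, 50_000):
        rows.append(("chr1", loc - 98, loc + 2, "TE-left", 60, "F1_a"))
        rows.append(("chr1", loc, loc + 100, "TE-right", 60, "F1_a"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "side",
                                     "mapq", "sample"])
    calls, _ = call_insertions(df)
    merged, summary = classify_family_occupancy(
        calls, {"F1_a": "F1"}, exclusion_mask=[("chr1", 0, 20_000)])
    assert summary["n_total"] == 1


def test_insertion_rate_bound_study_arithmetic():
    out = insertion_rate_bound(14, 0.62, 0)
    assert out["effective_genomes"] == pytest.approx(8.68)
    assert out["bound"] == pytest.approx(1 / 8.68)
    assert 0.11 < out["bound"] < 0.12          # "<~1/9 per genome"
    assert insertion_rate_bound(1, 1.0, 0)["bound"] == 1.0
    assert insertion_rate_bound(10, 0.5, 2)["bound"] == pytest.approx(0.4)
    with pytest.raises(ValueError):
        insertion_rate_bound(10, 0.0, 0)
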