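"""HTT inference: presence scan, Games-Howell, contrasts, trees."""

import numpy as np
import pytest

import oracles
from tehop._seq import revcomp
from tehop.htt import (games_howell, ks_contrast_report, local_hits, nj_tree,
                       presence_scan, robinson_foulds)


def _rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


# ---------------------------------------------------------------------------
# Presence scan


def test_planted_full_copy_found():
    rng = np.random.default_rng(0)
    cons = _rand_seq(rng, 1000)
    genome = _rand_seq(rng, 20000) + cons + _rand_seq(rng, 20000)
    call = presence_scan(cons, genome, species="x")
    assert call.present
    assert call.best_hit_identity == pytest.approx(1.0)
    assert call.best_hit_length == 1000
    assert call.n_copies_40 >= 1


def test_planted_copy_on_reverse_strand_found():
    rng = np.random.default_rng(1)
    cons = _rand_seq(rng, 800)
    genome = _rand_seq(rng, 5000) + revcomp(cons) + _rand_seq(rng, 5000)
    assert presence_scan(cons, genome).present


def test_short_fragment_below_length_floor_is_absent():
    rng = np.random.default_rng(2)
    cons = _rand_seq(rng, 1000)
    genome = _rand_seq(rng, 8000) + cons[300:395] + _rand_seq(rng, 8000)
    call = presence_scan(cons, genome)
    assert not call.present           # 95 bp <= 100, strict
    assert call.best_hit_length == 95


def test_empty_genome_absent():
    assert not presence_scan("ACGT" * 300, {}).present


def test_patchy_distribution_recovered_on_genome_panel():
    """Eight carriers planted among 52 genomes: exactly those called."""
    rng = np.random.default_rng(3)
    cons = _rand_seq(rng, 900)
    carriers = set(rng.choice(52, size=8, replace=False).tolist())
    calls = {}
    for g in range(52):
        genome = _rand_seq(rng, 12000)
        if g in carriers:
            # ~95% identity copy
            copy = list(cons)
            for p in rng.integers(0, 900, size=45):
                copy[p] = "ACGT"[rng.integers(0, 4)]
            genome = genome[:6000] + "".join(copy) + genome[6000:]
        calls[g] = presence_scan(cons, genome, species=str(g)).present
    assert {g for g, p in calls.items() if p} == carriers


def test_local_hits_match_exact_substring_scan():
    rng = np.random.default_rng(4)
    cons = _rand_seq(rng, 400)
    genome = (_rand_seq(rng, 3000) + cons + _rand_seq(rng, 2000)
              + cons[:250] + _rand_seq(rng, 3000))
    hits = [h for h in local_hits(cons, genome) if h.length >= 100]
    starts = {h.start for h in hits if h.identity == 1.0}
    assert 3000 in starts and 5400 in starts


# ---------------------------------------------------------------------------
# Games-Howell


def test_identical_groups_not_significant():
    res = games_howell([("a", [1.0, 1.0, 2.0, 2.0]),
                        ("b", [1.0, 1.0, 2.0, 2.0])])[0]
    assert res.q == 0.0
    assert res.p == pytest.approx(1.0)


def test_two_group_textbook_case_against_integration_oracle():
    """means 10 vs 12, s^2 = 1, n = 30: q = 2/sqrt(1/30), df = 58."""
    rng = np.random.default_rng(5)
    a = rng.normal(0, 1, 30)
    a = (a - a.mean()) / a.std(ddof=1) + 10.0
    b = rng.normal(0, 1, 30)
    b = (b - b.mean()) / b.std(ddof=1) + 12.0
    res = games_howell([("a", a), ("b", b)])[0]
    assert res.q == pytest.approx(2.0 / np.sqrt(1.0 / 30.0), rel=1e-9)
    assert res.df == pytest.approx(58.0, rel=1e-9)
    p_oracle = 1.0 - oracles.studentized_range_cdf(res.q, 2, res.df)
    assert res.p == pytest.approx(p_oracle, abs=1e-3)


def test_p_values_agree_with_integration_oracle_over_grid():
    for q, k, df in [(2.0, 2, 10.0), (3.5, 3, 20.0), (1.0, 4, 8.0),
                     (4.5, 2, 60.0), (2.8, 5, 35.0)]:
        from scipy.stats import studentized_range

        p = float(studentized_range.sf(q, k, df))
        p_oracle = 1.0 - oracles.studentized_range_cdf(q, k, df)
        assert p == pytest.approx(p_oracle, abs=1e-3)


def test_degenerate_zero_variance_groups():
    res = games_howell([("a", [3.0, 3.0]), ("b", [3.0, 3.0])])[0]
    assert res.p == 1.0
    res = games_howell([("a", [3.0, 3.0]), ("b", [4.0, 4.0])])[0]
    assert res.p == 0.0 and "zero_variance_degenerate" in res.flags


def test_contrast_decisions():
    te = {("a", "b"): [0.0, 0.001, 0.002] * 20}
    gene = {("a", "b"): list(np.random.default_rng(0).normal(1.0, 0.1, 60))}
    out = ks_contrast_report(te, gene)
    assert len(out) == 1 and out[0].htt_consistent

    # same distribution: negative at alpha = 1e-4 in nearly all replicates
    rng = np.random.default_rng(1)
    false_calls = 0
    for _ in range(100):
        x = rng.normal(0.5, 0.05, 50)
        y = rng.normal(0.5, 0.05, 50)
        out = ks_contrast_report({("a", "b"): x}, {("a", "b"): y})
        false_calls += out[0].htt_consistent
    assert false_calls <= 5


# ---------------------------------------------------------------------------
# Trees


def test_three_taxon_closed_form_branch_lengths():
    # d(ab)=3, d(ac)=5, d(bc)=6 -> a=1, b=2, c=4
    labels = ["a", "b", "c"]
    mat = [[0, 3, 5], [3, 0, 6], [5, 6, 0]]
    nwk = nj_tree(labels, mat)
    import dendropy

    tree = dendropy.Tree.get(data=nwk, schema="newick")
    lens = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
    assert lens["a"] == pytest.approx(1.0)
    assert lens["b"] == pytest.approx(2.0)
    assert lens["c"] == pytest.approx(4.0)


def test_nj_rejects_malformed_matrix():
    with pytest.raises(ValueError):
        nj_tree(["a", "b", "c"], [[0, 1, 2], [9, 0, 3], [2, 3, 0]])


def test_four_taxon_additive_matrix_recovered_exactly():
    # tree ((a:1,b:2):1,(c:3,d:4):2) -> additive distances
    mat = np.array([[0, 3, 7, 8],
                    [3, 0, 8, 9],
                    [7, 8, 0, 7],
                    [8, 9, 7, 0]], dtype=float)
    nwk = nj_tree(["a", "b", "c", "d"], mat)
    assert robinson_foulds(nwk, "((a:1,b:2):1,(c:3,d:4):2);") == 0


def test_nj_recovers_topology_of_random_additive_matrices():
    rng = np.random.default_rng(6)
    import dendropy

    for rep in range(30):
        n = int(rng.integers(4, 9))
        taxa = [f"t{i}" for i in range(n)]
        # random topology via random sequential joining, random edge lengths
        tns = dendropy.TaxonNamespace(taxa)
        tree = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=n, taxon_namespace=tns,
            rng=__import__("random").Random(rep))
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length = float(rng.uniform(0.5, 3.0))
        pdm = tree.phylogenetic_distance_matrix()
        mat = np.zeros((n, n))
        for i, ta in enumerate(tns):
            for j, tb in enumerate(tns):
                if i != j:
                    mat[i, j] = pdm.distance(ta, tb)
        nwk = nj_tree([t.label for t in tns], mat)
        assert robinson_foulds(nwk, tree.as_string(schema="newick")) == 0


def test_rf_trivial_and_quartet_cases():
    assert robinson_foulds("((a,b),(c,d));", "((a,b),(c,d));") == 0
    assert robinson_foulds("((a,b),(c,d));", "((a,c),(b,d));") == 2
    with pytest.raises(ValueError):
        robinson_foulds("((a,b),(c,d));", "((a,b),(c,e));")


def test_simulated_world_incongruence(small_world):
    from tehop.pipeline import run_htt_analysis

    rep = run_htt_analysis(small_world)
    assert rep["rf_species_vs_gene"] == 0
    assert rep["rf_species_vs_te"] > 0
    assert all(c.htt_consistent for c in rep["contrasts"])
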