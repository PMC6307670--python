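"""Orchestration of the two workflows over a simulated (or loaded) world:

* the active-TE screen — expression triage, anatomy, copy statistics and
  insertion polymorphism combined into a ranked evidence table;
* the HTT analysis — presence, TE-vs-gene Ks contrasts, phylogenetic
  incongruence and insertion-time dating bundled into one report.

Every stage threshold defaults to the study values (masked length 200 bp,
divergence 20%, the upper-quartile expression rule, presence hit length
100 bp at 90% identity, copy-coverage 60%/40%, mapq 10, 10 kb IBD windows,
contrast alpha 1e-4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from . import anatomy, copystats, dating, expression, htt, insertions
from ._seq import corrected_distance, encode, orient_like
from .ks import CodonAlignment, ks_ng86
from .simulate import SimulatedWorld, _parse_newick, _tips

log = logging.getLogger("tehop")

__all__ = ["PipelineConfig", "run_active_te_screen", "run_htt_analysis",
           "gene_ks_by_pair", "te_ks_by_pair", "species_split_times"]


@dataclass
class PipelineConfig:
    min_masked_bp: int = 200
    max_divergence: float = 0.20
    presence_min_len: int = 100
    presence_min_identity: float = 0.90
    coverage_within: float = 0.60
    coverage_cross: float = 0.40
    min_mapq: float = 10.0
    ibd_window_bp: int = 10_000
    alpha: float = 1e-4
    max_te_pairs_per_species: int = 20     # cross-set Ks subsampling cap
    max_pi_copies: int = 50
    pi_bootstrap: int = 200
    seed: int = 0

    def echo(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


# ---------------------------------------------------------------------------
# Ks helpers (indel-free in-frame sequences: direct codon pairing)


def _direct_ks(seq_a: str, seq_b: str) -> float:
    n = min(len(seq_a), len(seq_b))
    n -= n % 3
    rec = ks_ng86(CodonAlignment(seq_a[:n], seq_b[:n]))
    return rec.ks


def gene_ks_by_pair(world: SimulatedWorld, max_genes: int | None = None) -> dict:
    """Per-gene Ks for every species pair (one value per ortholog pair)."""
    out = {}
    for a, b in combinations(sorted(world.genes), 2):
        genes_a = world.genes[a]
        genes_b = world.genes[b]
        n = len(genes_a) if max_genes is None else min(max_genes, len(genes_a))
        vals = [_direct_ks(genes_a[i], genes_b[i]) for i in range(n)]
        out[(a, b)] = np.asarray(vals, dtype=float)
    return out


def _orf_seqs(world: SimulatedWorld, species: str, cap: int) -> list[str]:
    s, e = world.orf_interval
    fam = world.te[species]
    ids = sorted(fam.copies)[:cap]
    return [fam.copies[c][s:e] for c in ids]


def te_ks_by_pair(world: SimulatedWorld, cap: int = 20) -> dict:
    """Cross-species TE Ks on transposase ORFs, all copy pairs up to ``cap``
    copies per species (deterministic subsample by copy id)."""
    out = {}
    for a, b in combinations(sorted(world.te), 2):
        sa = _orf_seqs(world, a, cap)
        sb = _orf_seqs(world, b, cap)
        vals = [_direct_ks(x, y) for x in sa for y in sb]
        out[(a, b)] = np.asarray(vals, dtype=float)
    return out


def species_split_times(newick: str) -> dict:
    """Divergence time (My) for every species pair of an ultrametric tree."""
    root = _parse_newick(newick)

    def walk(node, depth):
        if not node.children:
            return {node.name: depth + node.length}, {}
        tips: dict = {}
        splits: dict = {}
        child_tips = []
        for c in node.children:
            t, s = walk(c, depth + node.length)
            splits.update(s)
            child_tips.append(t)
            tips.update(t)
        total_depth = max(tips.values())
        for i in range(len(child_tips)):
            for j in range(i + 1, len(child_tips)):
                for x in child_tips[i]:
                    for y in child_tips[j]:
                        pair = tuple(sorted((x, y)))
                        # ultrametric: split age = tip depth - node depth
                        splits[pair] = total_depth - (depth + node.length)
        return tips, splits

    _, splits = walk(root, 0.0)
    return splits


# ---------------------------------------------------------------------------
# Active-TE screen


@dataclass
class TEEvidence:
    te_name: str
    n_high_samples: int
    intact_orf: bool
    tir_found: bool
    n_identical_variants: int
    n_identical_copies: int
    pi: float
    copy_count: int
    n_nonreference_insertions: int

    def rank_key(self):
        return (-self.n_high_samples,
                -int(self.n_nonreference_insertions > 0),
                -self.n_identical_copies,
                -int(self.intact_orf and self.tir_found),
                -self.copy_count,
                self.pi)


def run_active_te_screen(world: SimulatedWorld,
                         config: PipelineConfig | None = None) -> dict:
    """Rank candidate TEs by the combined evidence for current activity:
    germline expression above the reference upper quartile in every sample,
    intact anatomy, identical-copy variants, low diversity, high copy number
    and nonreference insertions."""
    cfg = config or PipelineConfig()
    log.info("active-TE screen: thresholds %s", cfg.echo())

    tiers = {s: expression.expression_tiers(world.reference_tpms[s])
             for s in sorted(world.reference_tpms)}
    masking_records = [
        expression.TETranscriptRecord(tpm=0.0, **row)
        for row in world.masking.to_dict("records")]
    masked = {r.te_name for r in expression.filter_te_transcripts(
        masking_records, cfg.min_masked_bp, cfg.max_divergence)}

    copy_sets = {"ActiveMariner_TE": world.te[_focal_species(world)].copies}
    for name, d in world.decoys.items():
        copy_sets[name] = d["copies"]

    n_insertions = 0
    if world.brother_pairs is not None:
        calls, _ = insertions.call_insertions(
            world.brother_pairs.junction_reads, min_mapq=cfg.min_mapq)
        merged, _ = insertions.classify_family_occupancy(
            calls, world.brother_pairs.family_of_sample)
        n_insertions = len(merged)

    evidence = []
    for name, copies in copy_sets.items():
        if name not in masked:
            continue
        sub = world.expression[world.expression["te_name"] == name]
        n_high = sum(
            expression.classify_expression(row.tpm, tiers[row.sample]) == "high"
            for row in sub.itertuples())
        seqs = [copies[c] for c in sorted(copies)]
        cons = anatomy.build_consensus(seqs)
        intact = False
        tir_found = False
        if cons.status == "ok":
            orfs = anatomy.find_orfs(cons.consensus, min_len_nt=300)
            intact = bool(orfs)
            tir_found = anatomy.find_tirs(cons.consensus) is not None
        _, n_var, n_cop = copystats.dereplicate_identical(seqs)
        # stride subsample: copy ids are birth-ordered, so a prefix would
        # sample only the oldest cohort and overstate diversity
        stride = max(1, len(seqs) // cfg.max_pi_copies)
        div = copystats.nucleotide_diversity(
            seqs[::stride][: cfg.max_pi_copies],
            n_bootstrap=cfg.pi_bootstrap, seed=cfg.seed)
        evidence.append(TEEvidence(
            te_name=name, n_high_samples=n_high, intact_orf=intact,
            tir_found=tir_found, n_identical_variants=n_var,
            n_identical_copies=n_cop, pi=div.pi, copy_count=len(seqs),
            n_nonreference_insertions=(
                n_insertions if name == "ActiveMariner_TE" else 0)))
    evidence.sort(key=TEEvidence.rank_key)
    log.info("screen: %d candidates ranked", len(evidence))
    return {"tiers": tiers, "ranked": evidence,
            "top_candidate": evidence[0].te_name if evidence else None,
            "thresholds": cfg.echo()}


def _focal_species(world: SimulatedWorld) -> str:
    # the screened host lineage; fall back to the largest family when the
    # configured one carries no element
    focal = getattr(world.config, "focal_species", None)
    if focal in world.te:
        return focal
    return max(sorted(world.te), key=lambda s: len(world.te[s].copies))


# ---------------------------------------------------------------------------
# HTT analysis


def _consensus_by_species(world: SimulatedWorld) -> dict:
    # the consensus must be built over the full copy set: ids are
    # birth-ordered, so any prefix subsample would skew the majority toward
    # the oldest cohort
    out = {}
    for sp, fam in world.te.items():
        seqs = [fam.copies[c] for c in sorted(fam.copies)]
        res = anatomy.build_consensus(seqs)
        # the consensus is reported on a canonical strand; re-orient it to
        # the copies so downstream distances are never cross-strand
        out[sp] = orient_like(res.consensus, seqs[0]) \
            if res.status == "ok" else None
    return out


def _distance_matrix(seq_by_label: dict, model: str = "K2P"):
    labels = sorted(seq_by_label)
    n = len(labels)
    mat = np.zeros((n, n))
    enc = {l: encode(seq_by_label[l].upper()) for l in labels}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = enc[labels[i]], enc[labels[j]]
            m = min(a.size, b.size)
            d = corrected_distance(a[:m], b[:m], model)
            mat[i, j] = mat[j, i] = 0.0 if not np.isfinite(d) else d
    return labels, mat


def calibrate_rates(world: SimulatedWorld, gene_ks: dict) -> dict:
    """Per-lineage neutral rate from the mean ortholog Ks against the closest
    relative with a known split time (an explicit gene-set/counterpart/time
    triple per lineage)."""
    splits = species_split_times(world.tree_newick)
    rates = {}
    for sp in world.species:
        counterpart = min((o for o in world.species if o != sp),
                          key=lambda o: splits[tuple(sorted((sp, o)))])
        pair = tuple(sorted((sp, counterpart)))
        ks = gene_ks[pair]
        ks = ks[np.isfinite(ks)]
        rates[sp] = dating.neutral_rate(float(ks.mean()), splits[pair],
                                        lineage=sp)
    return rates


def run_htt_analysis(world: SimulatedWorld,
                     config: PipelineConfig | None = None,
                     do_presence: bool = False) -> dict:
    """Full HTT report: Ks contrasts per species pair, gene and TE trees with
    Robinson-Foulds incongruence against the true species tree, per-lineage
    rate calibration, copy dating and burst profiles."""
    cfg = config or PipelineConfig()
    log.info("HTT analysis: thresholds %s", cfg.echo())
    report: dict = {"thresholds": cfg.echo()}

    if do_presence and world.genomes:
        cons_focal = _consensus_by_species(world)[_focal_species(world)]
        report["presence"] = {
            sp: htt.presence_scan(cons_focal, world.genomes[sp], species=sp,
                                  min_hit_len=cfg.presence_min_len,
                                  min_identity=cfg.presence_min_identity)
            for sp in sorted(world.genomes)}

    gene_ks = gene_ks_by_pair(world)
    te_ks = te_ks_by_pair(world, cap=cfg.max_te_pairs_per_species)
    contrasts = htt.ks_contrast_report(te_ks, gene_ks, alpha=cfg.alpha)
    report["contrasts"] = contrasts
    log.info("contrasts: %d species pairs", len(contrasts))

    # trees: nuclear genes recover the species history; the TE need not
    gene_concat = {sp: "".join(world.genes[sp]) for sp in world.species}
    labels, mat = _distance_matrix(gene_concat)
    gene_tree = htt.nj_tree(labels, mat)
    consensuses = _consensus_by_species(world)
    te_seqs = {sp: c for sp, c in consensuses.items() if c is not None}
    te_tree = None
    rf_te = None
    if len(te_seqs) >= 4:
        tlabels, tmat = _distance_matrix(te_seqs)
        te_tree = htt.nj_tree(tlabels, tmat)
    true_tree = world.tree_newick
    rf_gene = htt.robinson_foulds(true_tree, gene_tree)
    if te_tree is not None:
        pruned = _prune_to(true_tree, sorted(te_seqs))
        rf_te = htt.robinson_foulds(pruned, te_tree)
    report["gene_tree"] = gene_tree
    report["te_tree"] = te_tree
    report["rf_species_vs_gene"] = rf_gene
    report["rf_species_vs_te"] = rf_te

    # dating
    rates = calibrate_rates(world, gene_ks)
    report["rates"] = rates
    ages_by_species: dict = {}
    entries: dict = {}
    for sp, fam in world.te.items():
        cons = consensuses.get(sp)
        if cons is None:
            continue
        copies = {c: fam.copies[c] for c in sorted(fam.copies)
                  if c != fam.master_id}
        ages, skipped = dating.copy_ages(copies, cons, rates[sp],
                                         mode="nucleotide")
        if not ages:
            continue
        ages_by_species[sp] = ages
        entries[sp] = dating.entry_time(ages)
    report["copy_ages"] = ages_by_species
    report["entry_times"] = entries
    report["burst_profiles"] = {
        sp: dating.proliferation_profile([a.t_my for a in ages])
        for sp, ages in ages_by_species.items() if len(ages) >= 5}
    return report


def _prune_to(newick: str, keep: list) -> str:
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.retain_taxa_with_labels(keep)
    return tree.as_string(schema="newick").strip()
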