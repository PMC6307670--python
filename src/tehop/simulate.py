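"""Forward simulator of a DNA-transposon life cycle across a host clade.

The simulator realizes, with full ground truth, the evolutionary scenario the
rest of the package is built to detect: nuclear genes diverge neutrally along
an ultrametric species tree under a Jukes-Cantor model at per-lineage rates;
a mariner-like element (terminal inverted repeats flanking a transposase ORF
carrying DD34D and YSPDLAP motifs) rides a donor lineage and enters recipient
genomes by horizontal transfer at known times; inside each recipient it
proliferates by a linear birth process restricted to burst windows, new
copies snapshotting the sequence of the active source ("master") lineage —
or of a random extant copy — and diverging neutrally thereafter.  Brother
pairs of haploid males with identity-by-descent (IBD) block structure, SNPs,
planted insertions and junction reads are generated for the
insertion-polymorphism analyses.

Times are My throughout; rates are per site per year; the 1e6 conversion is
applied in exactly one place (:func:`_mu`).  All randomness descends from a
single master seed through named child streams, so identical (config, seed)
reproduce every output bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import decode, encode
from .copystats import CopyHit

__all__ = [
    "SimulationConfig",
    "SimulatedWorld",
    "BrotherPairData",
    "default_config",
    "simulate_world",
    "simulate_brother_pairs",
    "write_fixtures",
]

_STOP_CODONS = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}  # TAA TAG TGA encoded


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class SimulationConfig:
    seed: int = 0
    # ultrametric species history: newick with branch lengths in My, plus a
    # per-species neutral rate (per site per year)
    species_tree: str = "((flyA:20,flyB:20):60,((antA:40,antB:40):20,bee:60):20);"
    rates: dict = field(default_factory=lambda: {
        "flyA": 5.17e-9, "flyB": 5.17e-9, "bee": 1.02e-8,
        "antA": 3.53e-9, "antB": 3.53e-9})
    n_nuclear_genes: int = 200
    gene_length_codons: int = 300
    # horizontal-transfer events: recipient -> time (Mya)
    htt_events: dict = field(default_factory=lambda: {
        "bee": 5.0, "antB": 2.5, "antA": 0.62, "flyB": 0.55, "flyA": 0.23})
    donor_rate: float = 5.0e-9
    transposition_rate: float = 740.0        # events / active copy / My
    # burst windows per recipient, (older, younger) Mya; None -> default of an
    # invasion burst on arrival plus a recent re-proliferation
    burst_schedule: dict | None = None
    te_length: int = 1324
    tir_length: int = 28
    orf_codons: int = 353                    # 1,059 nt transposase ORF
    tsd_len: int = 2
    template_mode: str = "master"            # "master" | "random"
    focal_species: str = "antB"              # the screened host lineage
    vertical: bool = False                   # TE inherited from the clade root
    max_copies: int = 260
    fragment_fraction: float = 0.2           # degraded remnant copies
    n_decoy_tes: int = 5
    decoy_copies: int = 20
    # brother pairs
    n_families: int = 7
    ibd_fraction: float = 0.62
    snp_rate_nonibd: float = 20.0            # SNPs per 10 kb
    snp_rate_ibd: float = 0.15
    pair_genome_length: int = 2_000_000
    ibd_block_mean: int = 40_000
    n_common_insertions: int = 6
    n_family_specific_insertions: int = 28
    n_de_novo_insertions: int = 0
    reads_per_side: int = 8
    read_length: int = 100
    junction_noise_fraction: float = 0.05
    # genomes and expression
    genome_length: int = 300_000             # background per pseudochromosome
    genome_copy_cap: int = 40                # copies physically placed
    n_reference_genes: int = 1800
    tpm_lognormal_params: tuple = (3.96, 0.72)
    samples: tuple = ("ovary_a", "ovary_b", "testis")
    include_brother_pairs: bool = True
    include_genomes: bool = True

    def __post_init__(self):
        if self.transposition_rate < 0 or self.donor_rate < 0:
            raise ValueError("rates must be non-negative")
        if any(r < 0 for r in self.rates.values()):
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.ibd_fraction <= 1.0:
            raise ValueError("ibd_fraction must lie in [0,1]")
        if any(t < 0 for t in self.htt_events.values()):
            raise ValueError("times must be non-negative")
        if not 2 <= self.tsd_len <= 10:
            raise ValueError("tsd_len must lie in 2..10")


def default_config(**overrides) -> SimulationConfig:
    return SimulationConfig(**overrides)


# ---------------------------------------------------------------------------
# Small helpers


def _mu(rate_per_year: float, duration_my: float) -> float:
    """Expected substitutions per site over a branch: the single place where
    My are converted to years."""
    return rate_per_year * duration_my * 1e6


def _rng_for(seed: int, label: str) -> np.random.Generator:
    h = int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, h]))


def _revert_stops(child: np.ndarray, parent: np.ndarray,
                  orf: tuple[int, int] | None):
    """Keep an ORF interval free of in-frame stop codons by reverting any
    stop codon to the parent codon (purifying against nonsense changes)."""
    if orf is None:
        return child
    s, e = orf
    cods = child[s:e].reshape(-1, 3)
    pars = parent[s:e].reshape(-1, 3)
    for i in range(len(cods)):
        if tuple(cods[i]) in _STOP_CODONS:
            cods[i] = pars[i]
    return child


def _evolve(seq: np.ndarray, mu: float, rng: np.random.Generator,
            orf: tuple[int, int] | None = None) -> np.ndarray:
    """One Jukes-Cantor branch: each site keeps its base with probability
    1/4 + 3/4 exp(-4 mu / 3) and otherwise takes one of the other three."""
    if mu <= 0:
        return seq.copy()
    p_same = 0.25 + 0.75 * np.exp(-4.0 * mu / 3.0)
    change = rng.random(seq.size) >= p_same
    out = seq.copy()
    if change.any():
        shift = rng.integers(1, 4, size=int(change.sum()))
        out[change] = (out[change] + shift) % 4
    return _revert_stops(out, seq, orf)


def _random_coding(rng: np.random.Generator, n_codons: int) -> np.ndarray:
    """Random in-frame coding sequence with no internal stops."""
    out = np.empty(3 * n_codons, dtype=np.int8)
    cods = out.reshape(-1, 3)
    for i in range(n_codons):
        while True:
            c = rng.integers(0, 4, size=3).astype(np.int8)
            if tuple(c) not in _STOP_CODONS:
                cods[i] = c
                break
    return out


# ---------------------------------------------------------------------------
# Species tree


@dataclass
class _Node:
    name: str | None
    length: float
    children: list


def _parse_newick(newick: str) -> _Node:
    """Minimal newick parser for trees with branch lengths (My)."""
    s = newick.strip().rstrip(";")
    pos = 0

    def parse() -> _Node:
        nonlocal pos
        children = []
        name = None
        if s[pos] == "(":
            pos += 1
            children.append(parse())
            while s[pos] == ",":
                pos += 1
                children.append(parse())
            assert s[pos] == ")", f"malformed newick at {pos}"
            pos += 1
        start = pos
        while pos < len(s) and s[pos] not in ",()":
            pos += 1
        label = s[start:pos]
        length = 0.0
        if ":" in label:
            name_part, ln = label.split(":")
            name = name_part or None
            length = float(ln)
        elif label:
            name = label
        return _Node(name=name, length=length, children=children)

    return parse()


def _tip_depths(node: _Node, acc: float = 0.0, out=None) -> dict:
    if out is None:
        out = {}
    d = acc + node.length
    if not node.children:
        out[node.name] = d
    for c in node.children:
        _tip_depths(c, d, out)
    return out


def _tips(node: _Node) -> list[str]:
    if not node.children:
        return [node.name]
    out = []
    for c in node.children:
        out.extend(_tips(c))
    return out


# ---------------------------------------------------------------------------
# Element construction


def _build_element(rng: np.random.Generator, cfg: SimulationConfig):
    """Construct the ancestral element: TIRs at both ends, a transposase ORF
    with ATG start, DD34D catalytic spacing and a C-terminal YSPDLAP motif,
    and neutral filler elsewhere.  Returns (sequence, orf_interval)."""
    from .ks import CODON_INDEX

    def codons_for(protein: str) -> list[str]:
        table: dict[str, list[str]] = {}
        from .ks import CODONS, AA_BY_CODON
        for cod, aa in zip(CODONS, AA_BY_CODON):
            table.setdefault(aa, []).append(cod)
        return [table[aa][rng.integers(0, len(table[aa]))] for aa in protein]

    n_aa = cfg.orf_codons - 1  # last codon is the stop
    aas = "ACDEFGHIKLMNPQRSTVWY"
    prot = ["M"] + [aas[rng.integers(0, 20)] for _ in range(n_aa - 1)]
    # strip accidental D's around the planted catalytic triad, then plant it
    d2 = n_aa // 2
    d1 = d2 - 40
    d3 = d2 + 35
    for i in range(1, n_aa):
        if prot[i] == "D" and i not in (d1, d2, d3):
            prot[i] = "E" if rng.random() < 0.5 else "N"
    prot[d1] = prot[d2] = prot[d3] = "D"
    ysp = n_aa - 12
    prot[ysp : ysp + 7] = list("YSPDLAP")
    prot_str = "".join(prot)
    orf_nt = "".join(codons_for(prot_str)) + "TAA"

    tir = decode(rng.integers(0, 4, size=cfg.tir_length).astype(np.int8))
    from ._seq import revcomp

    filler_len = cfg.te_length - 2 * cfg.tir_length - len(orf_nt)
    if filler_len < 2:
        raise ValueError("te_length too short for TIRs plus ORF")
    left_fill = filler_len // 2
    fill_a = decode(rng.integers(0, 4, size=left_fill).astype(np.int8))
    fill_b = decode(rng.integers(0, 4, size=filler_len - left_fill).astype(np.int8))
    seq = tir + fill_a + orf_nt + fill_b + revcomp(tir)
    orf_start = cfg.tir_length + left_fill
    assert len(seq) == cfg.te_length
    # the ORF interval excludes the terminal stop codon for protection purposes
    return encode(seq), (orf_start, orf_start + len(orf_nt))


# ---------------------------------------------------------------------------
# TE proliferation


def _birth_ages(t_h: float, lam: float, windows, rng: np.random.Generator,
                max_copies: int, per_capita: bool) -> list[float]:
    """Birth ages (Mya) of new copies within active ``windows`` (older,
    younger), starting from one copy at ``t_h``.

    With ``per_capita`` (random-template mode) every extant copy transposes
    at rate ``lam``, a linear birth process.  Otherwise (master mode) only
    the active source locus transposes, a Poisson process of rate ``lam``.
    """
    births: list[float] = []
    n = 1
    for hi, lo in sorted(windows, reverse=True):
        tau = min(hi, t_h)
        if tau <= lo or lam <= 0:
            continue
        if per_capita:
            while n < max_copies:
                w = rng.exponential(1.0 / (n * lam))
                tau -= w
                if tau <= lo:
                    break
                births.append(tau)
                n += 1
        else:
            k = min(rng.poisson(lam * (tau - lo)), max_copies - n)
            times = np.sort(rng.uniform(lo, tau, size=k))[::-1]
            births.extend(float(t) for t in times)
            n += k
    return births


def _default_schedule(t_h: float) -> list[tuple[float, float]]:
    """Invasion burst on arrival, quiescence, then a dominant recent
    re-proliferation (the recent cohort outnumbering the invasion cohort
    keeps the majority consensus anchored to the current master sequence,
    the regime in which consensus-based dating is calibrated)."""
    if t_h <= 0.30:
        return [(t_h, 0.0)]
    return [(t_h, t_h - 0.12), (0.15, 0.0)]


@dataclass
class _TeFamily:
    species: str
    t_h: float
    copies: dict                  # copy_id -> sequence (str)
    ages: dict                    # copy_id -> true age (My)
    template_snapshots: dict      # copy_id -> template sequence at birth (str)
    master_id: str
    master_current: str


def _proliferate(species: str, t_h: float, founding_seq: np.ndarray,
                 rate: float, cfg: SimulationConfig,
                 rng: np.random.Generator, orf,
                 windows=None) -> _TeFamily:
    if windows is None:
        windows = (cfg.burst_schedule or {}).get(species) \
            or _default_schedule(t_h)
    births = _birth_ages(t_h, cfg.transposition_rate, windows, rng,
                         cfg.max_copies,
                         per_capita=cfg.template_mode == "random")
    # lineages: (sequence, age of last update); lineage 0 is the founder
    lineages: list[list] = [[founding_seq.copy(), t_h]]
    birth_age_of: list[float] = [t_h]
    snapshots: list[np.ndarray] = [founding_seq.copy()]
    for a in births:
        idx = 0 if cfg.template_mode == "master" \
            else int(rng.integers(0, len(lineages)))
        seq, last = lineages[idx]
        seq = _evolve(seq, _mu(rate, last - a), rng, orf)
        lineages[idx] = [seq, a]
        lineages.append([seq.copy(), a])
        birth_age_of.append(a)
        snapshots.append(seq.copy())
    copies, ages, templates = {}, {}, {}
    master_current = ""
    for i, (seq, last) in enumerate(lineages):
        final = _evolve(seq, _mu(rate, last), rng, orf)
        cid = f"{species}_c{i:03d}"
        copies[cid] = decode(final)
        ages[cid] = birth_age_of[i]
        templates[cid] = decode(snapshots[i])
        if i == 0:
            master_current = decode(final)
    master_id = f"{species}_c000"
    return _TeFamily(species=species, t_h=t_h, copies=copies, ages=ages,
                     template_snapshots=templates, master_id=master_id,
                     master_current=master_current)


# ---------------------------------------------------------------------------
# World containers


@dataclass
class BrotherPairData:
    snp_tables: dict              # family -> DataFrame(chrom, pos)
    junction_reads: pd.DataFrame  # chrom,start,end,side,mapq,sample,family
    insertion_truth: list         # dicts: chrom,pos,tsd_len,families,samples,kind
    ibd_truth: dict               # family -> realized IBD fraction
    family_of_sample: dict
    chrom_lengths: dict
    effective_genomes: float


@dataclass
class SimulatedWorld:
    config: SimulationConfig
    species: list
    tree_newick: str
    rates: dict
    genes: dict                   # species -> list of coding sequences (str)
    te: dict                      # species -> _TeFamily (TE-bearing only)
    te_source: str                # ancestral element sequence
    orf_interval: tuple
    genomes: dict                 # species -> {chrom: sequence}
    hits: dict                    # species -> list[CopyHit]
    decoys: dict                  # te_name -> {"copies": {...}, "intact": bool}
    expression: pd.DataFrame      # columns: te_name, sample, tpm, tier_truth
    reference_tpms: dict          # sample -> np.ndarray
    masking: pd.DataFrame         # repeat-masking summary rows
    brother_pairs: BrotherPairData | None = None

    def truth_record(self) -> dict:
        rec = {
            "seed": self.config.seed,
            "htt_times": {s: f.t_h for s, f in self.te.items()},
            "transposition_rate": self.config.transposition_rate,
            "rates": dict(self.rates),
            "copy_ages": {s: dict(f.ages) for s, f in self.te.items()},
            "template_mode": self.config.template_mode,
            "vertical": self.config.vertical,
        }
        if self.brother_pairs is not None:
            rec["ibd_truth"] = self.brother_pairs.ibd_truth
            rec["effective_genomes"] = self.brother_pairs.effective_genomes
            rec["insertions"] = [
                {k: (sorted(v) if isinstance(v, (set, frozenset)) else v)
                 for k, v in t.items()}
                for t in self.brother_pairs.insertion_truth]
        return rec


# ---------------------------------------------------------------------------
# Simulation stages


def _simulate_genes(cfg: SimulationConfig, root: _Node, rng):
    """Neutral coding genes down the species tree; internal branches use the
    mean rate of descendant tips."""
    L = 3 * cfg.gene_length_codons
    total = cfg.n_nuclear_genes * L
    root_seq = np.concatenate(
        [_random_coding(rng, cfg.gene_length_codons)
         for _ in range(cfg.n_nuclear_genes)])
    orfs = [(g * L, (g + 1) * L) for g in range(cfg.n_nuclear_genes)]

    def branch_rate(node: _Node) -> float:
        tips = _tips(node)
        return float(np.mean([cfg.rates[t] for t in tips]))

    out: dict[str, list[str]] = {}

    # genes evolve fully neutrally: a codon column that acquires a nonsense
    # difference is excluded pairwise by the divergence engine, so no
    # stop-avoidance is imposed here and realized divergence stays at 2rt
    def walk(node: _Node, seq: np.ndarray):
        for child in node.children:
            mu = _mu(branch_rate(child), child.length)
            cseq = _evolve(seq, mu, rng, None) if mu > 0 else seq.copy()
            if child.children:
                walk(child, cseq)
            else:
                out[child.name] = [decode(cseq[s:e]) for s, e in orfs]

    walk(root, root_seq)
    return out


def _simulate_te(cfg: SimulationConfig, root: _Node, rng, element, orf):
    """Either horizontal transfers off an external donor lineage, or (null
    scenario) vertical inheritance from the clade root."""
    depths = _tip_depths(root)
    te: dict[str, _TeFamily] = {}
    if cfg.vertical:
        # null scenario: the element sat in the clade's common ancestor and
        # was inherited vertically; it has been resident (and transposing)
        # over each species' whole lineage depth, so its copies span all
        # ages and its cross-species divergence tracks the species splits —
        # here the per-My transposition rate applies over the full depth
        def walk(node: _Node, seq: np.ndarray):
            for child in node.children:
                rate = cfg.rates[child.name] if not child.children \
                    else float(np.mean([cfg.rates[t] for t in _tips(child)]))
                cseq = _evolve(seq, _mu(rate, child.length), rng, orf)
                if child.children:
                    walk(child, cseq)
                else:
                    depth = depths[child.name]
                    te[child.name] = _proliferate(
                        child.name, depth, cseq, cfg.rates[child.name], cfg,
                        rng, orf, windows=[(depth, 0.0)])

        walk(root, element)
        return te

    events = dict(cfg.htt_events)
    for sp, t_h in events.items():
        if sp not in depths:
            raise ValueError(f"HTT recipient {sp!r} not in species tree")
        if t_h > depths[sp]:
            raise ValueError(
                f"HTT into {sp!r} at {t_h} My predates its lineage root "
                f"({depths[sp]} My)")
    donor_origin = max(events.values()) + 1.0
    donor_seq = element.copy()
    donor_age = donor_origin
    for sp, t_h in sorted(events.items(), key=lambda kv: -kv[1]):
        donor_seq = _evolve(donor_seq, _mu(cfg.donor_rate, donor_age - t_h),
                            rng, orf)
        donor_age = t_h
        te[sp] = _proliferate(sp, t_h, donor_seq, cfg.rates[sp], cfg, rng, orf)
    return te


def _place_copies(cfg: SimulationConfig, world_rng, species, fam: _TeFamily):
    """Assemble a pseudochromosome containing a capped number of copies (with
    target-site duplications) plus degraded fragments; emit the hit table for
    the full copy set."""
    rng = world_rng
    bg = rng.integers(0, 4, size=cfg.genome_length).astype(np.int8)
    ids = sorted(fam.copies)
    placed = ids[: cfg.genome_copy_cap]
    n_frag = int(len(placed) * cfg.fragment_fraction)
    frag_ids = placed[len(placed) - n_frag :] if n_frag else []

    pieces: list[np.ndarray] = []
    cursor = 0
    hits: list[CopyHit] = []
    positions = np.sort(rng.choice(
        np.arange(cfg.tsd_len, cfg.genome_length - cfg.tsd_len),
        size=len(placed), replace=False))
    out_offset = 0
    for cid, pos in zip(placed, positions):
        seq = encode(fam.copies[cid])
        if cid in frag_ids:
            frac = rng.uniform(0.2, 0.5)
            keep = max(60, int(frac * seq.size))
            start = int(rng.integers(0, seq.size - keep))
            seq = seq[start : start + keep]
        pieces.append(bg[cursor:pos])
        out_offset += pos - cursor
        tsd = bg[pos : pos + cfg.tsd_len]
        strand = "+" if rng.random() < 0.5 else "-"
        ins = seq if strand == "+" else (3 - seq)[::-1]
        pieces.append(np.concatenate([tsd, ins]))
        g_start = out_offset + cfg.tsd_len
        g_end = g_start + ins.size
        cov = min(1.0, ins.size / cfg.te_length)
        full = encode(fam.copies[cid])
        master = encode(fam.master_current)
        n = min(full.size, master.size)
        ident = 1.0 - float((full[:n] != master[:n]).mean())
        hits.append(CopyHit(chrom="chr1", start=g_start, end=g_end,
                            strand=strand, identity=min(1.0, ident),
                            aligned_length=int(ins.size), coverage=cov))
        out_offset += cfg.tsd_len + ins.size
        cursor = pos
    pieces.append(bg[cursor:])
    genome = np.concatenate(pieces)
    # full copy-set hit table (virtual coordinates for unplaced copies)
    virt = cfg.genome_length + cfg.te_length * 2
    for j, cid in enumerate(ids[cfg.genome_copy_cap :]):
        start = virt + j * (cfg.te_length + 100)
        hits.append(CopyHit(chrom="virtual", start=start,
                            end=start + cfg.te_length, strand="+",
                            identity=0.99, aligned_length=cfg.te_length,
                            coverage=1.0))
    return {"chr1": decode(genome)}, hits


def _simulate_expression(cfg: SimulationConfig, rng, te_names, focal: str):
    mu, sigma = cfg.tpm_lognormal_params
    reference = {s: rng.lognormal(mu, sigma, size=cfg.n_reference_genes)
                 for s in cfg.samples}

    def draw(sample: str, tier: str) -> float:
        ref = reference[sample]
        lo, q25, q75, q90 = np.percentile(ref, [0, 25, 75, 90])
        if tier == "high":
            return float(q90 * rng.uniform(1.2, 4.0))
        if tier == "mid":
            return float(rng.uniform(q25, q75))
        return float(rng.uniform(0.0, q25 * 0.8))

    rows = []
    for name in te_names:
        for s in cfg.samples:
            if name == focal:
                tier = "high"
            else:
                tier = ["low", "low", "mid"][rng.integers(0, 3)]
            rows.append((name, s, draw(s, tier), tier))
    expr = pd.DataFrame(rows, columns=["te_name", "sample", "tpm", "tier_truth"])
    return expr, reference


def _simulate_masking(cfg: SimulationConfig, rng, te_names, focal: str):
    rows = []
    for i, name in enumerate(te_names):
        if name == focal:
            masked, div = int(0.9 * cfg.te_length), 0.01
        else:
            masked = int(rng.integers(250, 900))
            div = float(rng.uniform(0.03, 0.18))
        rows.append((f"TR_{i:04d}", masked, div, name, "DNA", "Tc1-Mariner",
                     masked + int(rng.integers(50, 600))))
    # records that the masking filter must reject
    rows.append(("TR_short", 150, 0.05, "short_hit", "DNA", "Tc1-Mariner", 800))
    rows.append(("TR_diverged", 400, 0.25, "old_hit", "RNA", "Gypsy", 1200))
    return pd.DataFrame(rows, columns=[
        "transcript_id", "masked_bp", "divergence", "te_name", "te_class",
        "superfamily", "transcript_length"])


def _simulate_decoys(cfg: SimulationConfig, rng, orf_codons):
    """Fossil elements: old proliferations with high copy diversity and, for
    some, broken ORFs."""
    decoys = {}
    for d in range(cfg.n_decoy_tes):
        sub = _rng_for(cfg.seed, f"decoy{d}")
        elem, orf = _build_element(sub, cfg)
        intact = d % 2 == 0
        copies = {}
        for c in range(cfg.decoy_copies):
            age = float(sub.uniform(4.0, 12.0))
            seq = _evolve(elem, _mu(5e-9, 2 * age), sub,
                          orf if intact else None)
            copies[f"decoy{d}_c{c:02d}"] = decode(seq)
        decoys[f"Fossil-{d}_TE"] = {"copies": copies, "intact": intact,
                                    "source": decode(elem)}
    return decoys


# ---------------------------------------------------------------------------
# Brother pairs


def simulate_brother_pairs(cfg: SimulationConfig) -> BrotherPairData:
    """Seven (by default) pairs of haploid brothers: IBD block structure,
    between-brother SNPs, planted nonreference insertions with TSDs, and
    junction reads spanning every insertion breakpoint from both sides."""
    if cfg.n_families < 1:
        raise ValueError("need at least one family")
    rng = _rng_for(cfg.seed, "brothers")
    L = cfg.pair_genome_length
    window = 10_000
    n_win = L // window
    families = [f"F{i+1}" for i in range(cfg.n_families)]
    family_of_sample = {}
    for f in families:
        family_of_sample[f"{f}_a"] = f
        family_of_sample[f"{f}_b"] = f

    if cfg.ibd_fraction >= 1.0 and cfg.snp_rate_nonibd > 0:
        warnings.warn("ibd_fraction = 1: no non-IBD SNPs will be emitted")

    snp_tables: dict[str, pd.DataFrame] = {}
    ibd_truth: dict[str, float] = {}
    ibd_windows_truth: dict[str, np.ndarray] = {}
    for f in families:
        state = np.zeros(n_win, dtype=bool)
        pos = 0
        cur = rng.random() < cfg.ibd_fraction
        while pos < n_win:
            mean_blocks = cfg.ibd_block_mean / window
            other = mean_blocks * (1 - cfg.ibd_fraction) / max(cfg.ibd_fraction, 1e-9)
            mean = mean_blocks if cur else max(other, 1.0)
            ln = max(1, int(rng.exponential(mean)))
            state[pos : pos + ln] = cur
            pos += ln
            cur = not cur
        if cfg.ibd_fraction >= 1.0:
            state[:] = True
        ibd_windows_truth[f] = state
        ibd_truth[f] = float(state.mean())
        counts = np.where(state,
                          rng.poisson(cfg.snp_rate_ibd, n_win),
                          rng.poisson(cfg.snp_rate_nonibd, n_win))
        snps = []
        for w in np.flatnonzero(counts):
            offs = rng.integers(0, window, size=counts[w])
            snps.extend(int(w) * window + offs)
        snp_tables[f] = pd.DataFrame(
            {"chrom": "chr1", "pos": sorted(int(p) for p in snps)})

    # planted insertions
    truth: list[dict] = []
    taken: set[int] = set()

    def new_pos() -> int:
        while True:
            p = int(rng.integers(1000, L - 1000))
            if all(abs(p - q) > 500 for q in taken):
                taken.add(p)
                return p

    for _ in range(cfg.n_common_insertions):
        nf = int(rng.integers(2, min(5, cfg.n_families) + 1))
        fams = list(rng.choice(families, size=nf, replace=False))
        samples = set()
        for f in fams:
            for suffix in ("_a", "_b"):
                if rng.random() < 0.8:
                    samples.add(f + suffix)
            if not samples & {f + "_a", f + "_b"}:
                samples.add(f + "_a")
        truth.append({"chrom": "chr1", "pos": new_pos(),
                      "tsd_len": cfg.tsd_len, "families": set(fams),
                      "samples": samples, "kind": "common"})
    per_family = 0 if cfg.n_family_specific_insertions == 0 \
        else max(2, cfg.n_family_specific_insertions // cfg.n_families)
    for f in families:
        for _ in range(per_family):
            samples = {f + ("_a" if rng.random() < 0.5 else "_b")}
            if rng.random() < 0.3:
                samples = {f + "_a", f + "_b"}
            truth.append({"chrom": "chr1", "pos": new_pos(),
                          "tsd_len": cfg.tsd_len, "families": {f},
                          "samples": samples, "kind": "family_specific"})
    for _ in range(cfg.n_de_novo_insertions):
        f = families[int(rng.integers(0, len(families)))]
        truth.append({"chrom": "chr1", "pos": new_pos(),
                      "tsd_len": cfg.tsd_len, "families": {f},
                      "samples": {f + "_a"}, "kind": "de_novo"})

    # junction reads
    rows = []
    for t in truth:
        bp = t["pos"]
        tsd = t["tsd_len"]
        for sample in sorted(t["samples"]):
            fam = family_of_sample[sample]
            for _ in range(cfg.reads_per_side):
                start = bp + tsd - cfg.read_length + int(rng.integers(-2, 3))
                rows.append(("chr1", max(0, start), bp + tsd, "TE-left",
                             60.0, sample, fam))
            for _ in range(cfg.reads_per_side):
                end = bp + cfg.read_length + int(rng.integers(-2, 3))
                rows.append(("chr1", bp, end, "TE-right", 60.0, sample, fam))
    # excision evidence at one family-specific locus: reads without the TE
    fs = [t for t in truth if t["kind"] == "family_specific"]
    if fs:
        t = fs[-1]
        sample = sorted(t["samples"])[0]
        t["excised_in"] = sample
        for _ in range(4):
            s = t["pos"] - int(rng.integers(20, 60))
            rows.append(("chr1", s, s + cfg.read_length, "ref", 60.0,
                         sample, family_of_sample[sample]))
    # noise: random stray reads, a share of them below the mapq floor
    n_noise = int(len(rows) * cfg.junction_noise_fraction)
    for _ in range(n_noise):
        p = int(rng.integers(0, L - cfg.read_length))
        side = ["TE-left", "TE-right"][int(rng.integers(0, 2))]
        mapq = float(rng.choice([5.0, 25.0, 55.0]))
        sample = sorted(family_of_sample)[int(rng.integers(0, 2 * cfg.n_families))]
        rows.append(("chr1", p, p + cfg.read_length, side, mapq, sample,
                     family_of_sample[sample]))
    junction = pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "side", "mapq", "sample", "family"])
    junction = junction.sort_values(["chrom", "start", "end", "side", "sample"],
                                    ignore_index=True)

    mean_ibd = float(np.mean(list(ibd_truth.values())))
    return BrotherPairData(
        snp_tables=snp_tables, junction_reads=junction,
        insertion_truth=truth, ibd_truth=ibd_truth,
        family_of_sample=family_of_sample,
        chrom_lengths={"chr1": L},
        effective_genomes=2 * cfg.n_families * mean_ibd)


# ---------------------------------------------------------------------------
# Top level


def simulate_world(config: SimulationConfig) -> SimulatedWorld:
    """Realize the full scenario: genes, TE families, genomes, expression,
    masking summaries, fossil decoys and (optionally) brother pairs."""
    root = _parse_newick(config.species_tree)
    species = sorted(_tips(root))
    missing = [s for s in species if s not in config.rates]
    if missing:
        raise ValueError(f"no rate for species: {missing}")

    elem_rng = _rng_for(config.seed, "element")
    element, orf = _build_element(elem_rng, config)

    genes = _simulate_genes(config, root, _rng_for(config.seed, "genes"))
    te = _simulate_te(config, root, _rng_for(config.seed, "te"), element, orf)

    genomes: dict = {}
    hits: dict = {}
    if config.include_genomes:
        for sp in sorted(te):
            g, h = _place_copies(config, _rng_for(config.seed, f"genome:{sp}"),
                                 sp, te[sp])
            genomes[sp] = g
            hits[sp] = h

    decoys = _simulate_decoys(config, _rng_for(config.seed, "decoys"),
                              config.orf_codons)
    focal = "ActiveMariner_TE"
    te_names = [focal] + sorted(decoys)
    expr, reference = _simulate_expression(
        config, _rng_for(config.seed, "expression"), te_names, focal)
    masking = _simulate_masking(
        config, _rng_for(config.seed, "masking"), te_names, focal)

    pairs = simulate_brother_pairs(config) if config.include_brother_pairs \
        else None

    return SimulatedWorld(
        config=config, species=species, tree_newick=config.species_tree,
        rates=dict(config.rates), genes=genes, te=te,
        te_source=decode(element), orf_interval=orf, genomes=genomes,
        hits=hits, decoys=decoys, expression=expr, reference_tpms=reference,
        masking=masking, brother_pairs=pairs)


# ---------------------------------------------------------------------------
# Fixture writing


def _write_fasta(path: Path, records: dict):
    with open(path, "w") as fh:
        for name in records:
            fh.write(f">{name}\n")
            seq = records[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_fixtures(world: SimulatedWorld, directory) -> dict:
    """Write every pipeline input as plain-text files; returns a manifest of
    relative paths, sha256 checksums and file classes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: list[tuple[str, str]] = []

    def add(relpath: str, file_class: str):
        files.append((relpath, file_class))

    for sp, genome in world.genomes.items():
        _write_fasta(directory / f"genome_{sp}.fasta", genome)
        add(f"genome_{sp}.fasta", "genome_fasta")
    for sp, fam in world.te.items():
        _write_fasta(directory / f"te_copies_{sp}.fasta", fam.copies)
        add(f"te_copies_{sp}.fasta", "te_fasta")
    for sp, gene_list in world.genes.items():
        _write_fasta(directory / f"genes_{sp}.fasta",
                     {f"{sp}_g{i:04d}": g for i, g in enumerate(gene_list)})
        add(f"genes_{sp}.fasta", "gene_fasta")

    hit_rows = []
    for sp, hs in world.hits.items():
        for h in hs:
            hit_rows.append(("ActiveMariner_TE", f"{sp}:{h.chrom}",
                             0, h.aligned_length, h.start, h.end,
                             round(h.identity * 100, 2), h.aligned_length))
    pd.DataFrame(hit_rows, columns=[
        "query", "subject", "qstart", "qend", "sstart", "send",
        "identity", "aln_len"]).to_csv(directory / "hits.tsv", sep="\t",
                                       index=False)
    add("hits.tsv", "hit_tsv")

    world.masking.to_csv(directory / "masking_summary.tsv", sep="\t",
                         index=False)
    add("masking_summary.tsv", "masking_tsv")
    world.expression.to_csv(directory / "te_tpm.tsv", sep="\t", index=False)
    add("te_tpm.tsv", "tpm_tsv")
    ref_rows = [(s, f"ref_{i:04d}", t) for s, arr in
                sorted(world.reference_tpms.items())
                for i, t in enumerate(arr)]
    pd.DataFrame(ref_rows, columns=["sample", "gene_id", "tpm"]).to_csv(
        directory / "reference_tpm.tsv", sep="\t", index=False)
    add("reference_tpm.tsv", "tpm_tsv")

    if world.brother_pairs is not None:
        bp = world.brother_pairs
        for fam, tab in bp.snp_tables.items():
            p = directory / f"snps_{fam}.vcf"
            with open(p, "w") as fh:
                fh.write("##fileformat=VCFv4.2\n")
                fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
                for _, row in tab.iterrows():
                    fh.write(f"{row['chrom']}\t{row['pos'] + 1}\t.\tN\tN\t.\t"
                             f"PASS\t.\n")
            add(f"snps_{fam}.vcf", "snp_vcf")
        bed = bp.junction_reads.copy()
        bed["score"] = bed["mapq"]
        bed["name"] = bed["side"] + ":" + bed["sample"]
        bed["strand"] = "+"
        bed[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
            directory / "junction_reads.bed", sep="\t", index=False,
            header=False)
        add("junction_reads.bed", "junction_bed")

    with open(directory / "truth.json", "w") as fh:
        json.dump(world.truth_record(), fh, indent=1, sort_keys=True)
    add("truth.json", "truth_json")

    manifest = {"files": []}
    for rel, fclass in files:
        digest = hashlib.sha256((directory / rel).read_bytes()).hexdigest()
        manifest["files"].append({"path": rel, "class": fclass,
                                  "sha256": digest})
    manifest["n_files"] = len(files)
    manifest["file_classes"] = sorted({f for _, f in files})
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
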