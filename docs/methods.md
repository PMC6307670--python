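# Methods

`tehop` implements an inference chain for identifying a currently active DNA
transposon and demonstrating that it arrived by horizontal transfer, together
with a forward simulator that generates every input with known ground truth.
This note records the models, the parameter choices, and the places where the
design was genuinely open.

## The inference chain

**Expression triage.** Candidate TE transcripts from a repeat-masking summary
are retained when masked length ≥ 200 bp and divergence ≤ 20% (both
inclusive; "greater than" in the tier rule is read strictly, so a TPM exactly
at the upper quartile is *mid*). Tiers compare each transcript's TPM with the
25th/75th percentiles of a single-copy reference gene set, computed by linear
interpolation between closest ranks (`numpy.percentile` default). Percentile
convention matters only within a fraction of a TPM at these sample sizes, but
it is fixed and documented here because the tier boundaries are strict
inequalities.

**Consensus and anatomy.** The species consensus is a majority-rule column
vote over all genomic copies: fragments < 100 bp are dropped, each fragment
is strand-normalized and placed against the longest fragment by infix
edit-distance alignment (edlib), columns with < 2 supporting fragments emit
N, and base ties break A<C<G<T. The consensus is reported on a canonical
strand (lexicographically smaller of the two), which makes it invariant to
input order and to strand flips of individual fragments; callers re-orient it
against their copies before computing distances. ORFs are stop-to-stop
regions on both strands (the `-find 3` convention), with the first in-frame
ATG recorded; the 1,059-nt transposase convention corresponds to a stop-free
stretch of 353 codons. TIRs are found by local alignment (match 2, mismatch
−3, gap open −5, extend −2) between the 5′ terminal 150 bp and the reverse
complement of the 3′ terminal 150 bp, with three gates: length ≥ 10,
identity ≥ 0.80, and score ≥ 25. The score floor plays the role of
einverted's alignment threshold; without it the false-positive rate on random
600-bp sequences is over 50%, with it, measured ≤ 0.5%. The DD34D motif is
reported as two aspartates exactly 34 residues apart preceded by at least one
further aspartate; YSPDLAP is matched with at most one mismatch.

**Copy statistics.** Copy number is the count of hits at consensus coverage
≥ 60% within the focal genome (≥ 40% for cross-species surveys, both
inclusive), after collapsing same-strand hits that overlap > 50% reciprocally
— the same guard against double-counting internally deleted copies that the
coverage rule serves. Nucleotide diversity π is the mean pairwise
model-corrected distance (default Kimura two-parameter; p and Jukes–Cantor
available) with pairwise deletion of gapped/ambiguous sites and a bootstrap
over alignment columns (default 1,000 replicates) for the standard error.
π here replaces a composite-likelihood estimator used in some desktop tools;
the properties the analysis relies on — near-zero values for young
expansions and the ordering between elements — are estimator-robust, and the
model label is carried in every estimate.

**Synonymous divergence (the quantitative core).** Ks/Ka follow Nei–Gojobori
(1986): fractional synonymous-site counts per codon averaged over the two
sequences, pathway averaging over substitution orders for codons differing at
more than one position, and Jukes–Cantor correction of the per-site
proportions. Conventions fixed once: standard genetic code; point mutations
creating a stop count as nonsynonymous in site counting; pathways through
stop codons are excluded, with an all-paths fallback (flagged) when every
pathway is blocked; saturation (p ≥ 3/4) yields NaN plus a flag. All
per-codon quantities are precomputed into 64×64 lookup tables, so large
cross-sets reduce to integer indexing; the test suite checks exact agreement
with an independent brute-force pathway enumerator on 500 random alignments.
NG86-with-JC is the package's single deliberate estimator substitution for
model-averaged ML Ks machinery: the horizontal-transfer argument rests on a
*contrast* between TE and nuclear-gene Ks computed identically, which is
robust to the estimator choice. Codon-aware alignment aligns translations
(BLOSUM62, gap open −10, extend −0.5), threads back to codons, and drops
every gap-containing codon column; when translations have equal length and
≥ 70% identity the gapless pairing is already optimal under this scoring and
is used directly. An optional conserved-block filter (sliding 15-codon
window, ≥ 50% identical amino acids) approximates stricter block selection
and is off by default.

**Horizontal-transfer tests.** Presence in a genome requires at least one
local hit with length > 100 bp and identity > 90% (strict); the scanner is a
seeded (12-mer), ungapped diagonal search scored +1/−2, adequate for ≥ 90%
identity queries and exact on the indel-free sequences the simulator
produces. The Ks contrast compares, per species pair, all cross-species TE
copy pairs against per-ortholog gene Ks with the Games–Howell procedure:
q = |mᵢ−mⱼ|/√((sᵢ²/nᵢ+sⱼ²/nⱼ)/2), Welch–Satterthwaite degrees of freedom,
p from the studentized-range distribution (scipy's implementation, verified
against direct numerical integration of the double integral to 3 decimals).
A pair is called HTT-consistent only when the TE mean is *below* the gene
mean **and** p < α (default 10⁻⁴, matching the reporting convention the
analysis mirrors). Whether each copy pair is an independent observation is a
known pseudo-replication concern; the direction constraint is what protects
the null (a resident element's copies span all ages, so its cross-species Ks
is at least gene-like — see the simulator's vertical scenario). Trees are
neighbor-joining on K2P distances (scikit-bio), with taxa sorted for
deterministic tie-breaks, replacing ML/Bayesian inference: the conclusion
rests on topology incongruence over deep, clean splits, which NJ provably
recovers on additive distances (property-tested over random trees).
Incongruence is the unrooted Robinson–Foulds distance: 0 between species
tree and gene tree, > 0 between species tree and TE tree.

**Dating.** Lineage rates are calibrated as r = mean ortholog Ks / (2·t)
against the *closest* relative with a known split time (an explicit
gene-set/counterpart/time triple per lineage; the closest split keeps Ks
well below the counting-method saturation ceiling). Copy ages use
T = k/2r with k the copy-versus-consensus divergence — synonymous-only
(NG86) for intact ORFs, whole-element JC-corrected nucleotide distance as
the fallback for copies without one, with the mode flagged. Rates carry an
explicit per-year unit tag; the My conversion happens in exactly one place,
and passing an untagged number is a type error. The k/2r convention implies
the consensus tracks the *current* active-source sequence (copy and source
lineages each contribute r·T); this holds when a recent cohort forms the
column majority, and the simulator's default burst schedule realizes that
regime. Entry time is summarized three ways: maximum copy age, 95th
percentile, and the mean age of the oldest burst (`burst_mean`). Individual
copy ages scatter widely — k is a count of a few dozen substitutions — so
the cohort mean is the preferred entry estimate and the extreme statistics
are reported alongside. Burst structure is single-linkage clustering on the
age axis: maximal empty intervals ≥ 0.1 My (configurable) are quiescence
gaps, the clusters between them bursts.

**Insertion polymorphism.** IBD windows: SNP counts in fixed 10-kb windows,
classified by a two-component Poisson mixture fit by EM (low-rate component
= IBD), falling back to a fixed threshold (≤ 2 SNPs/window) when the mixture
degenerates; "very low SNP density" has no numeric threshold in the source
procedure, so the mixture is the documented decision. Insertion calls:
junction reads below mapq 10 are discarded before clustering (hard filter —
no emitted call carries lower evidence); left-side and right-side clusters
whose genomic intervals overlap by a length within 2–10 bp produce a call
with the overlap as the TSD; overlaps outside the range are reported as
low-confidence, not called. A locus with both TE-junction and TE-absent
reads in one individual is flagged as a (somatic) excision. Calls are merged
across families within max(TSD) bp — a documented tolerance where the
mirrored procedure merges "by site" without stating one — and classified
common (≥ 2 families) versus family-specific. The de novo rate bound is
1/g per genome per generation with g = individuals × mean IBD fraction,
because only IBD regions are informative for new insertions between haploid
brothers.

## The simulator

The generator realizes the scenario the pipeline is built to detect, with a
full truth record (transfer times, per-copy ages and template snapshots,
lineage rates, planted insertions, realized IBD fractions).

*Host clade.* An ultrametric five-species tree (two flies splitting 20 Mya,
two ants 40 Mya, bee vs ants 60 Mya, root 80 Mya) given as newick in My.
The timescale is deliberately compressed relative to the deep insect splits
that inspired it so that ortholog synonymous divergence stays below the
counting-method saturation ceiling at every pair while preserving the
ordering the inference uses (TE divergence ≪ species divergence). Default
per-lineage rates are 5.17×10⁻⁹ (flies), 1.02×10⁻⁸ (bee) and 3.53×10⁻⁹
(ants) substitutions/site/year; recovery tests use a uniform 3.5×10⁻⁹
because the r = Ks/2t calibration midpoint-averages a pair of unequal
lineage rates by construction.

*Sequences.* Jukes–Cantor throughout, vectorized per branch; nuclear genes
(default 200 × 300 codons) evolve fully neutrally — codon columns that
acquire nonsense differences are excluded pairwise by the divergence engine,
so no stop-avoidance is imposed and realized divergence stays at 2rt. The
element (1,324 nt) carries 28-bp terminal inverted repeats and a 1,059-nt
transposase ORF with planted DD34D and C-terminal YSPDLAP motifs; only this
ORF is protected against nonsense changes (stop codons revert to the parent
codon), reflecting that dated copies are the intact ones.

*Transfer and proliferation.* A donor lineage (5×10⁻⁹/site/year) carries
the element and seeds each recipient at its transfer time (default: bee
5.0 Mya, focal ant 2.5 Mya, second ant 0.62, flies 0.55/0.23 — orderings
chosen so the TE tree conflicts with the species tree, as observed
empirically when a recipient groups with donors rather than its sister).
Within a recipient, new copies snapshot the current sequence of the active
source locus ("master" mode, default) and diverge neutrally thereafter; the
master itself keeps evolving. A random-template mode (any extant copy, a
linear birth process) is available; master mode is the default because
consensus-anchored k/2r dating presupposes master-copy dynamics — under
random templating every copy is equidistant from the ancestor and the
formula dates lineage splits off the majority backbone instead of
insertions. In master mode births form a Poisson process at the
transposition rate (default 740 events/My while active, giving ≈ 200 copies
over the default 0.27 My of activity); the default burst schedule is an
invasion burst on arrival (0.12 My) and a dominant recent re-proliferation
(0.15 My) separated by quiescence — the bimodal age structure of a
recently reactivated element, with the recent cohort in the majority so the
consensus tracks the current master. The vertical (null) scenario instead
evolves the element down the species tree from the root with continuous
proliferation over each lineage's whole depth: copies span all ages and
cross-species TE Ks is distributed like (in fact slightly above) gene Ks,
which is what makes the contrast's direction requirement an effective
type-I guard.

*Genomes and expression.* Pseudochromosomes are random background (default
300 kb) with a capped number of copies physically inserted with 2-bp
target-site duplications, 20% of them truncated to 20–50% length (degraded
remnants); the full copy set is additionally described by a BLAST-outfmt-6
style hit table. Reference-gene TPMs are log-normal with (μ, σ) =
(3.96, 0.72) — back-derived from reported germline quartiles of ≈ 32.5 and
≈ 85.8 TPM — and TE transcripts are drawn in controllable tiers (the
"high" tier above the reference 90th percentile). Five fossil decoy
elements (20 old, diverse copies each, some with broken ORFs) exercise the
screen's ranking.

*Brother pairs.* Seven families of two haploid brothers on a 2-Mb
pseudochromosome; IBD blocks alternate with exponential lengths
(mean 40 kb) tuned to a stationary IBD fraction of 0.62; SNP counts per
10-kb window are Poisson (20 in non-IBD — heterozygosity between distinct
maternal haplotypes — and 0.15 in IBD, the residual error rate). Planted
insertions (default 6 common + 28 family-specific, TSD 2 bp) emit 8
junction reads per side (±2 bp breakpoint jitter, mapq 60), plus 5% stray
reads, a share of them below the mapq floor, and reference-spanning reads
at one locus as excision evidence. No de novo insertions are planted by
default, matching the observation the rate bound formalizes.

*Determinism.* All randomness descends from one master seed through named,
hashed child streams; identical (config, seed) reproduce every file
bit-for-bit (checksum-verified in the tests).

## What passing tests do and do not show

The simulator has no indels, no sequencing-read errors, no rate
heterogeneity among sites, no selection on TE copies beyond nonsense
protection of the transposase, and genome backgrounds free of repeats other
than the planted elements. Consequently the recovery results demonstrate the
estimators' correctness and calibration under the generating model, not
robustness to alignment error, assembly artifacts, or model misspecification
— on real data the alignment and Ks steps, not the statistics, are the
fragile links. The insertion caller is benchmarked against clean junction
tables; it implements the mapq and TSD-overlap logic, not the upstream read
alignment, and the manual curation step used on real alignments has no
algorithmic counterpart here.

## Numerical and scale choices

Acceptance-scale problem sizes — 20 replicate worlds for parameter
recovery, 100 vertical-null replicates at reduced size (50 genes × 200
codons, ≈ 30 copies), cross-set Ks capped at 20 copies per species
(deterministic subsample; 400 pairs per species pair) — were chosen so the
whole chain demonstrates calibration at desk scale. π subsamples stride
across the birth-ordered copy list (a prefix would sample only the oldest
cohort). Entry recovery is judged on `burst_mean`; degenerate inputs
(empty groups, zero variance, saturation, all-identical bootstrap
replicates) return flagged values rather than raising, except where the
contract demands an error (internal stops, malformed matrices, rate-unit
mismatches).
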