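# Methods

This note documents the models, estimators, numerical choices, and known
limitations behind `gbtskit`, in the order data flows through the pipeline.

## Synthetic cohorts

The simulator emulates the resource population a genotyping panel is
designed from: several drift-differentiated breeds genotyped at candidate
SNPs spread over a small number of reference sequences.

- **Reference.** Uniform-base ACGT sequences (default six sequences; the
  toolkit's convention is a genome integrated into a handful of sequence
  sets rather than chromosome-level scaffolds). Loci are placed at unique
  positions ≥ 200 bp from sequence ends (so probes always have flank) and
  at a configurable minimum gap; infeasible densities raise an error naming
  the sequence.
- **Allele frequencies.** Ancestral p ~ Uniform(0.05, 0.95) — chosen so the
  MAF ≥ 0.05 screening rule has non-trivial attrition; breed k draws
  p_k ~ Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k) (Balding–Nichols), giving
  E[p_k] = p and Var[p_k] = F_k·p(1−p), i.e. F_k is an FST-like
  differentiation parameter. This is the simplest model with controllable
  FST and exactly the allele-frequency structure the downstream
  PCA/admixture analyses assume.
- **Genotypes.** Unadmixed individuals draw Binomial(2, p_k); admixed
  individuals (Dirichlet(1) ancestry q) draw each of their two allele
  copies from breed k with probability q_k. Truth (ancestral and breed
  frequencies, per-sample q, group labels) is returned alongside the data.
- **Sequencing realism.** Per-sample depth ~ Poisson(mean_depth, default
  10×), Bernoulli missingness (default 5 %), a configurable fraction of
  sites with QUAL below the screening threshold (default 5 %), optional
  indel/multi-allelic injection so the biallelic rule has work to do.
- **Defaults.** Ten breeds of 14 birds (≈ a 137-bird, 10-group cohort) over
  six sequences; F = 0.1 where a single value is needed. Missingness,
  depth, and QUAL mix are desk-scale choices a cohort of this kind would
  plausibly show; they are deliberately *not* tuned per analysis.
- **LD block-copy mode.** Real panels show LD decay; a Balding–Nichols
  simulator with independent loci does not. When `ld_block_size > 1`,
  consecutive loci in a block copy the previous locus's allele copies with
  per-copy flip probability ε (`ld_flip_prob`), giving correlation that
  decays roughly geometrically with chain distance. This is a testing
  device for the LD machinery, not a coalescent/recombination model —
  passing LD tests say nothing about ancestral-recombination realism.
- **Determinism.** All randomness flows from one integer seed through
  split `SeedSequence` streams; same spec ⇒ byte-identical FASTA/VCF.

What the simulator does **not** model: pedigrees or mating structure,
linked selection, sequencing error in the genotypes themselves (missingness
and QUAL are independent of the genotype draw), reference bias.
Consequently, passing recovery tests demonstrates correctness of the
estimators under the stated generative model, not robustness to real-data
artefacts.

## Genotype model and I/O

Dosages (ALT-allele counts 0/1/2, −1 missing) in a dense samples × loci
int8 matrix; coordinates are VCF-style 1-based; loci are kept canonically
sorted with no duplicate (sequence, position). Phase is ignored everywhere
(no statistic here uses it). Multi-allelic records are read and flagged but
excluded by the biallelic screening rule before any statistic. The VCF
writer emits VCF v4.2 with GT:DP and QUAL fixed to two decimals so that
identical matrices always serialize byte-identically; reading uses cyvcf2.

## Screening cascade

Rules are applied in a fixed order (QUAL → biallelic → depth → MAF →
missingness → heterozygosity → spacing) with per-rule attrition recorded,
so alternative orders can be compared from the report. Conventions:

- The depth window [1/3, 5]× is relative to the *grand mean* of per-locus
  mean depths over the pre-filter input, computed once; per-locus mean
  depth averages over samples with a called genotype.
- Missing rate uses all samples as denominator; MAF and het rate use
  non-missing calls.
- The heterozygosity rule defaults to *removing* loci with het rate > 0.5
  (excess heterozygosity is the classic paralog/collapsed-repeat signal,
  and ranking prefers *low* het); the opposite direction is available via
  `het_rule="min"` since field practice varies.
- Spacing (≥ 5 bp) is enforced *last and greedily in rank order*, so a
  conflict is resolved in favour of the higher-MAF locus rather than the
  leftmost one.
- Ranking is lexicographic — MAF descending, then missing rate ascending,
  then het rate ascending, then (sequence, position) as a total-order
  tiebreak — which makes selection invariant to sample order and input
  locus order.

Degenerate inputs: an empty survivor set is returned with a warning (the
report is still valid); an all-missing locus gets NaN statistics and fails
the MAF rule.

## Probe design

Two 110 bp probes per SNP. For overlap target v, the second probe starts
s = 110 − round(110·v) bases after the first (banker's rounding; v = 0.65
gives a 72-base shared window, shift 38) and the pair is centred so the SNP
sits mid-overlap, sliding as needed near sequence ends; if no placement
keeps the SNP in the overlap, or within 10 bp of any probe end, the locus
fails with reason "edge". Pass additionally requires GC ∈ [0.30, 0.70] for
both probes (N bases excluded from the GC computation) and ≤ 5 homologous
regions.

"Homologous region" has no standard operational definition at probe scale;
here it is a merged seed-hit window: the reference is indexed by canonical
(strand-collapsed) 15-mers, probe 15-mers are looked up, per-sequence hit
positions are clustered with a 110 bp merge distance, and clusters with
≥ 5 seed hits are counted (the probe's own source window counts one). Seed
counting is a lower-bounded surrogate for alignment: it finds every exact
occurrence and degrades gracefully for diverged copies; k and the hit
threshold are exposed in `ProbeParams`. The locus-evaluation convention
"2 probes, a 120 bp window, 10 bp end distance" is likewise surfaced as
named parameters.

Failed loci are data, not exceptions: the evaluation table records reasons,
and the replacement loop promotes next-ranked reserve candidates (still
respecting spacing) until the panel regains its target size or the reserve
is exhausted.

## Diversity estimators

Plug-in estimators throughout: He = 1 − Σp̂² with no 2n/(2n−1) small-sample
correction (matching common chip-analysis toolchains; the corrected variant
is a flag), PIC in the two-allele Botstein form, Ae = 1/Σp̂² (identically
1/(1−He), asserted to 1e-12 in tests). Group tables recompute frequencies
within each group; cells are unweighted means over loci with ≥ 1 call in
the group, "All" pools every sample and leads the table. All statistics are
invariant to REF/ALT relabeling.

## LD

Composite LD: r² is the squared Pearson correlation of dosage vectors over
samples called at both loci — the right statistic for unphased genotype
files; EM haplotype-frequency r² is out of scope. Pairs with < 4 complete
observations or a monomorphic member are skipped and counted. The decay
curve averages r² in fixed-width distance bins, smooths occupied bins with
a centred 3-bin moving average, and reports the half-decay distance (first
crossing of half the smoothed maximum, linearly interpolated); on curves
that never fall to half-maximum the half-decay distance is NaN. Under the
null, E[r²] ≈ 1/(n−1), which the binned curve should sit at for unlinked
loci — a useful calibration check.

## Population structure

The GRM standardizes each polymorphic locus by its pooled frequency,
entry(i,j) = mean over jointly-called loci of (gᵢ−2p)(gⱼ−2p)/(2p(1−p)).
Because p is estimated from the sample itself, rows are approximately
centred and the expected off-diagonal is ≈ −1/(n−1), not 0 — tests account
for this. PCA is an eigendecomposition of the GRM; scores are eigenvectors
scaled by √eigenvalue, variance explained is normalized over positive
eigenvalues, and sign is fixed by making each component's largest-magnitude
loading positive.

The admixture model is the standard binomial mixture: g_ij ~
Binomial(2, Σₖ q_ik f_kj). EM was chosen over quasi-Newton block relaxation
for its guaranteed monotone likelihood (asserted on every iteration, with a
1e-6 relative slack for floating-point noise) and adequacy at desk scale;
local optima are mitigated by seeded restarts (default 5 for final fits, 1
inside cross-validation for speed). F is clamped to [1e-6, 1−1e-6] to keep
the likelihood finite; Q rows are renormalized each M-step and checked to
1e-8. Convergence is a log-likelihood gain below `tol` (1e-4 default).

Cross-validation masks non-missing genotype *entries* in folds (default 5),
refits, predicts ĝ = 2Σₖ q_ik f_kj, and scores RMSE over masked entries;
best K is the argmin with a smallest-K tiebreak. RMSE replaces the binomial
deviance used by the classic tool because it stays well-behaved when f̂
approaches 0/1; only the strict argmin is implemented — no plateau
heuristic, since none is well defined. Label switching across
restarts/folds is resolved by greedy column matching on Q correlation.

## Phylogenetics

The p-distance between diploid unphased individuals is the allele-sharing
mismatch fraction mean|gᵢ−gⱼ|/2 over jointly-called loci (sequence-style
p-distance is not defined for genotype matrices, so this analogue is fixed
and documented); a breed-level mode uses mean |Δ allele frequency| between
group means. Neighbor joining follows the Saitou–Nei Q-criterion with
deterministic tie-breaking by lexicographic cluster labels (a cluster is
labelled by its smallest leaf), negative limb estimates clamped to zero
with the deficit moved to the sibling limb, and a trifurcating root
(unrooted tree). NJ is exact on additive matrices — verified against
randomly generated trees — and matches scikit-bio's implementation on
noisy matrices in the cross-check test.

Bootstrap resamples loci with replacement; since duplicated loci violate
the container's unique-locus invariant, replicate distances are computed
directly on weighted arrays (multiplicity weights), which is equivalent and
faster. Support of an internal edge is the fraction of replicate trees
containing the same bipartition. Newick output writes branch lengths to 6
significant digits and supports as internal labels, quoting labels that
contain metacharacters.

## Problem sizes

Tests and the acceptance script run at desk scale chosen to make the
statistical assertions sharp while staying quick: cohorts of 20–80 samples,
500–14 000 loci over 0.1–3 Mb of reference, panels of 100–5000 markers,
K ≤ 5 in cross-validation (the library default remains 1–15), 100–200
bootstrap replicates against the 1000× production default. These sizes are
the package's own verification choices; all thresholds they exercise are
the production defaults.

## Known limitations

- No coalescent with recombination: simulated LD comes from the block-copy
  device only.
- Homology counting is seed-based, not alignment-based; highly diverged
  repeats below ~93 % identity of 15-mer seeds can be missed.
- Admixture provides no standard errors for Q and no supervised or
  projection modes.
- Trees are unrooted with no outgroup handling; no ML/Bayesian inference.
- The VCF reader streams plain (or bgzipped) files without index support —
  appropriate for ≤ ~10⁵ loci, not for whole-genome scale.
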