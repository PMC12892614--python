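# Methods

This note documents the statistical procedures implemented in `sncfrag`, the
design of the synthetic cohort generator, the numerical conventions, and the
limitations of what passing tests demonstrate.

## Annotation model

A *species* is a unique read sequence after adapter trimming and collapsing
(the package starts from collapsed reads; trimming is out of scope).  Species
of 15–45 nt are retained; counts are never altered by filtering.  Each species
is matched by exact substring search (zero mismatches, forward strand only)
against the mature parental references.  Nuclear tRNA references carry the 3'
CCA of the mature molecule, so the "mature tRNA only" restriction is enforced
by construction: a fragment that would only match a precursor simply has no
locus.

When a species matches parents from several classes, the precedence list
decides the assignment.  The default order is
`miRNA > nuclear tRNA > mito tRNA > Y RNA > rRNA`: rRNA, being the longest
and hence most promiscuous matcher, absorbs reads last.  The order is
configurable because no community standard exists.  Within the winning class,
parents disagreeing on family produce an `ambiguous` flag and the
lexicographically first family — a deterministic tie-break that keeps
aggregation single-valued.  Multi-locus species contribute their count once
per class to expression, but to every matched locus in cleavage profiles;
this avoids double-counting abundance while preserving positional signal.

Family RPM is `count x 1e6 / denominator`.  The denominator policy is
configurable: all retained reads (default) or annotated reads only.  Class
totals pool nuclear + mito tsRNAs into `tsRNA`, with `rsRNA`, `ysRNA` and
`miRNA` alongside.

## Differential signature

Per family and contrast (HC vs UC, HC vs CD) the model is ordinary least
squares of RPM on `[intercept, case indicator, age, sex]`, two-sided t-test on
the case coefficient with `n − 4` df.  The fit is on raw RPM (a
`log2(RPM+1)` variant sits behind a flag for robustness studies).  Sex is
encoded 0/1 with female = 0; the coefficient sign depends on this and is
documented for that reason.  Only the two groups of a contrast enter the fit —
symptomatic controls are reported descriptively, never used for signature
selection.  Bonferroni correction uses `m` = families tested within one
contrast; the two corrected tables are then intersected.  The signature is
the set of families with adjusted P < α in *both* contrasts and identical
direction; direction is recorded per family and callers may restrict to
up-regulated families.

Degenerate inputs: a constant expression vector is reported as coefficient 0
with P = 1 (the intercept fits it exactly; there is no group signal), and a
rank-deficient design (e.g. a single-sex subset) raises an error naming the
collinear column.

## Risk score and evaluation

The score of a sample is the signed z-sum over signature families on the
`log2(RPM+1)` scale, with per-family mean μ and SD τ (n−1 denominator) taken
from a stated reference population.  Zero-variance families are dropped with
a warning.  Down-regulated families enter with direction −1 — the natural
signed extension needed for mixed-direction signatures such as miRNA panels.

AUC is the concordant-pair fraction with ties counted ½ (computed via the
rank identity; exact, no trapezoid approximation), with curve points at every
distinct threshold.  Cases are expected to score higher and no orientation
flip is applied, so AUC < 0.5 is reportable.  DeLong's test compares two
correlated AUCs through placement values; zero variance of the difference
returns P = 1 with a warning.

Cross-validation is stratified by group so every fold contains HC, UC and CD;
within a group the remainder of `n mod k` goes one sample per fold, lowest
fold indices first, deterministically given the seed.  Per fold the *entire*
signature procedure is re-run on the training folds and μ/τ are computed on
training samples only — the leakage-free reading of "within the population"
(a full-cohort baseline is available behind `baseline_population="full"` for
comparison with the fixed-population convention).  A training split that
yields an empty signature contributes no AUC by default.  Because a cohort
with no true signal then produces almost no AUC values at all, the harness
also offers `empty_signature="chance"`: an empty signature is the
uninformative classifier — the constant zero score — whose all-ties AUC is
exactly 0.5.  Null-calibration checks use this mode; with real signal the two
modes coincide because empty signatures do not occur.

## Co-expression and pathway scores

Family–gene association uses Spearman correlation with average ranks for
ties; P-values from the t approximation `t = ρ√((n−2)/(1−ρ²))` with `n−2` df
(P = 0 at |ρ| = 1), Benjamini–Hochberg adjusted over all tested pairs
jointly.  A gene is called positively (negatively) co-expressed when at least
20 families show BH-adjusted P < 0.05 with ρ > 0 (ρ < 0); both the α and the
family threshold are configurable, since published analyses of this kind
rarely state them.  Enrichment of a gene list in user-supplied GMT sets is a
one-sided hypergeometric upper-tail test, BH-adjusted across sets — a local,
deterministic replacement for web-service enrichment tools.

The single-sample pathway score is rank-based: per sample, genes are ranked
by expression descending (average ranks for ties) and weighted
`w_g = exp(−rank_g / (0.1 N))`; a set's score is the mean weight inside the
set minus the mean weight of the complement.  The exponential decay constant
`0.1 N` concentrates weight on roughly the top decile of expressed genes,
matching the intent of rank-based pathway activity scores that emphasize
highly expressed genes; because only ranks enter, the score is invariant
under any strictly monotone per-sample transform of expression.  Gene
expression is accepted as already log-scale intensities; no normalization is
applied.

## Cohort divergence

Per-family divergence is `log2((mean_B + ε)/(mean_A + ε))` over
healthy-control means, with the first-listed cohort as denominator — a fixed,
documented convention.  |log2FC| distributions of miRNAs vs noncanonical
families are compared with the two-sample KS test (asymptotic P; at the
family-set sizes involved the exact small-sample distribution is
unnecessary).  Baseline linearity is the R² of OLS between `log10(mean+ε)`
values; for simple regression this is symmetric in the two cohorts.

The pseudocount ε = 0.01 RPM is shared by fold changes and divergence through
one configuration key.  Confidence intervals on descriptive curves use
mean ± 1.96 × SEM with the n−1 SD; Welch (unequal-variance) t-tests are used
for every group comparison, matching the common default of statistical
environments.

## Synthetic cohort generator

The generator emulates a four-group blood small-RNA study: 30 healthy
controls, 65 symptomatic controls, 58 UC and 52 CD samples by default, ages
Uniform(18, 80), sex Bernoulli(1/2), library sizes 1–2 million reads.

*References.* 48 nuclear anticodon families (named from the standard genetic
code, e.g. `Arg-ACG`, mature CCA tail), 22 mitochondrial tRNAs, 8 rRNAs
(12S, 16S, 5S, …), 4 Y RNAs (RNY1–4) and miRNA hairpins; random sequences at
realistic lengths, rejection-sampled so no parent is a substring of another
(exhaustion after 1000 tries is a hard error naming the collision).

*Species.* Per-parent cleavage hotspots `(offset, length, weight)` define the
fragment species; default hotspot lengths reproduce the characteristic peaks
of blood small-RNA data — 17/22 nt for tsRNAs, 27/32 nt for ysRNAs,
15/17/23/26/33 nt for rsRNAs, a single 22-nt mature arm for miRNAs.  Hotspot
weights per parent sum to 1 (validated).

*Counts.* Expected species abundance is
`library_size × family_weight × 2^(group effect + age/sex terms + latent term
+ miRNA cohort shift)`.  Counts are drawn Gamma–multinomial: per-species
Gamma intensities with shape equal to the negative-binomial size parameter
(default 10), then one multinomial of the drawn library size on the
normalized intensities.  Marginally each species is Gamma–Poisson
(overdispersed, as sncRNA-seq counts are), while per-sample species counts
sum exactly to the library size — which makes conservation checks exact.  An
unannotatable fraction (default 2%) of random non-matching reads is added on
top.  Per-family baseline abundances are log-normal (log2 SD 2), and
per-family age slopes and sex offsets default to nonzero so the covariate
adjustment path is always exercised.

*Planted structure.* Group effects are multiplicative log2 shifts on named
families.  The helper `log2_effect_for_sd_units(k, r)` converts "an effect of
k residual SDs" into the log2 shift `d` solving
`(2^d − 1)√r / √((1 + 4^d)/2) = k`; the `(1 + 4^d)/2` factor accounts for the
case group's variance being inflated by the same multiplicative effect, so
the realized regression coefficient is k pooled residual SDs, not less.  A
single latent factor (standard normal per sample, optionally group-shifted)
drives both a chosen set of sncRNA families and a block of genes
(`expression = baseline + loading × latent + Gaussian noise`); the
positive/negative-loading genes form the `POS_PATH`/`NEG_PATH` truth sets,
alongside random decoy sets.  A second cohort generated from a `template`
cohort reuses its hotspots and family parameters — same underlying biology —
and differs only by sampling, design and a per-miRNA cohort shift
(log2 offsets with configurable SD, applied to miRNAs only), the setting for
divergence analyses.  The symptomatic-control group's effect sizes are free
parameters, not fixed relative to UC/CD.

*What the generator does not emulate:* sequencing errors, quality scores,
adapters, RNA modifications that block reverse transcription, pre-tRNA
(flanked) fragments, genome-wide multimapping beyond the generated parents,
and batch structure other than the single cohort shift.  Passing recovery
tests therefore demonstrates correctness of the statistical machinery under a
clean generative model, not robustness to every artifact of real sncRNA-seq.

## Pipeline and reproducibility

Stages run in dependency order and communicate only through declared output
files, so any subset can be re-run; missing optional inputs (gene matrix,
second cohort) skip their stages with explicit log lines.  All randomness
flows from one master seed through named substreams (SHA-256 of the stage
name mixed into the seed sequence), so adding a stage never perturbs earlier
streams and identical configuration + seed reproduce the bundle bit-exactly;
the manifest records config, seeds, package version and SHA-256 of every
output.  Incremental re-computation (caching unchanged upstream stages) is
not implemented; re-running a stage subset explicitly covers that use.

## Problem sizes in tests and the acceptance script

Statistical checks run at the study's own design (205 samples, 300 families)
where the quantity under test demands it: signature recall (10 replicates)
and the null family-wise error rate (200 replicates), cross-validation at
k = 5 with 100 rounds, DeLong type-I error on 2,000 null simulations
(n = 50/50), co-expressed-gene recovery with 500 decoy genes (5 replicates),
and divergence detection over 100 replicate cohort pairs with ≥100 families
per class.  Unit tests use smaller cohorts chosen to exercise the same code
paths quickly.  These sizes are the package's own choices for stable,
repeatable statistics.
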