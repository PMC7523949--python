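# Methods

## Coordinate conventions

All interval arithmetic is 0-based, half-open, on the displayed (coding)
strand; minus-strand genes are reverse-complemented and mirrored exactly
once at load (`shoreline.io.load_locus`). The biological convention —
transcription start site = +1, positions upstream negative, no position 0 —
exists only at the display layer (`to_display_coordinates`), so internal
code never branches on it.

## CpG island detection

No single canonical criterion exists for a CpG island; this package uses the
classical sliding-window definition: a 200-bp window qualifies when GC
fraction ≥ 0.50 and observed/expected CpG ≥ 0.60 (obs/exp = n_CpG · N /
(n_C · n_G)); overlapping or adjacent qualifying windows are merged, the
composition is recomputed on the merged span, and spans shorter than 200 bp
are dropped. All four thresholds are explicit `IslandParams` fields.

Two consequences worth knowing:

* **Boundary resolution is the window size.** A window straddling the true
  island edge qualifies once roughly 40–50% of it overlaps the island, so
  detected boundaries sit up to ~one window (200 bp) outside planted
  boundaries. The island-recovery tests and the acceptance report measure
  this error rather than assuming it away.
* Marginal 200-bp islands can appear inside CpG-containing shores; this is
  real behavior of the composition criteria, not a defect. Downstream code
  always picks the island maximally overlapping the region of interest.

Shores are the 2-kb flanks of an island, clipped at the locus boundary and
truncated at any neighboring island (a shore is defined relative to one
island, so truncation, not overlap). Candidate assay regions are windows of
≤ 450 bp (the practical Sanger amplicon scale) inside a shore with at least
5 CpGs and CpG density at most 0.5× the island's; both the minimum CpG
count and the density ratio are parameters, since "notably lower density"
is a judgment call the operator should own.

## Bisulfite clone quantification

Clones are aligned to the **unconverted** amplicon reference by global
dynamic programming with free end gaps and a bisulfite-asymmetric
substitution rule: reference C vs clone T is a full match (conversion of an
unmethylated C), the reverse (reference T vs clone C) is an ordinary
mismatch. Scores: match +1, mismatch −1, gap −2 (linear). The alignment
engine is Biopython's `PairwiseAligner` with a custom asymmetric matrix;
the test suite checks its scores against an independent plain-DP oracle.
Clones are tried in both orientations (cloned inserts are unoriented) and
the better alignment wins.

Per-CpG calls read off the alignment: C = methylated, T = unmethylated;
anything else is *absent* — a gap, an unexpected base at the C position, or
a disrupted G position, the signature of a CpG-destroying polymorphism.
A clone showing T at the C position of an intact CpG is deliberately called
unmethylated, not absent: in bisulfite data a genomic C→T variant is
indistinguishable from unmethylation on that strand, while a mutated G is
detectable, so the G position carries the polymorphism call.

Conversion rate = fraction of covered non-CpG reference cytosines read as T
(positions read as neither C nor T are uninformative and excluded);
identity = bisulfite-aware matches over the clone-covered alignment span.
QC defaults: identity ≥ 0.90, conversion ≥ 0.95, both configurable. A
profile needs ≥ 20 passing clones to be reportable; up to 32 are accepted
(the practical colony-picking ceiling) and never subsampled.

The reported amplicon methylation is the pooled-call ratio, 100 × methylated
/ (methylated + unmethylated) over all clones and CpGs — not the mean of
per-CpG means; both are computed and carried on the profile, the pooled
value being the headline number because it weights every scorable call
equally.

Pyrosequencing results are consumed as tables (the instrument already
quantifies percent methylation); the package applies only the RLU quality
policy: blue (≥ 20) and yellow (≥ 10) calls are usable, any red call (< 10)
rejects the run for re-assay.

## Cohort statistics

Two-group comparisons use the pooled-variance Student's *t* (Welch behind a
flag), many-group comparisons one-way ANOVA; both delegate to scipy with
explicit handling of degenerate inputs (all-identical values give statistic
0, p 1). The region screen applies one *t*-test per assay region with a
shared Bonferroni threshold α/m, m defaulting to the number of regions
screened together (8 → 0.00625 at α = 0.05; the family size is an argument
because reasonable analysts could instead count genes).

Post-tests: Dunnett many-to-one via `scipy.stats.dunnett` (its
multivariate-*t* integration is stochastic; a seed argument fixes the
adjusted p-values, and the k = 1 case agrees with the plain *t*-test to
10⁻³), Tukey all-pairs via `scipy.stats.tukey_hsd`. The Dunn post-test
after Kruskal–Wallis is implemented here (no scipy equivalent): z statistics
from joint mean ranks with the standard tie correction, Bonferroni-adjusted
over all pairs — the convention of the desktop statistics packages this
workflow traditionally runs in. Adjusted p-values are clamped to ≤ 1 and
are never smaller than the unadjusted p (property-tested).

Missing values (MMSE, genotypes, expression) are dropped pairwise with the
retained/dropped counts reported, never imputed.

## Risk classification

The logistic layer follows the statsmodels Model/Results shape.
`MethylationRiskModel` builds a design matrix from `meth_<region>` columns
(continuous, percent) and the APOE ε4 genotype, encoded either nominally
(indicator per carrier level: heterozygote, homozygote vs non-carrier) or
as the 0/1/2 allele count entered linearly. The nominal encoding is the
default for fitted models; the allele count is the natural score for
APOE-only ROC analyses. Fitting is maximum likelihood (Newton, tolerance
10⁻⁸, ≤ 100 iterations) through `statsmodels.Logit`; complete separation
raises an explicit `SeparationError` rather than returning divergent
coefficients. One degenerate case is handled automatically: when a genotype
cell is empty in one class (typically no ε4-homozygote controls), the
homozygote indicator is quasi-separated, and the encoding collapses to a
single carrier indicator with a warning and one retry.

ROC/AUC uses the midrank (half-credit ties) convention, which makes the AUC
exactly the pairwise concordance probability; variances, the 95% CI
(Wald on the DeLong variance, truncated to [0, 1]) and the paired-curve
test all use DeLong's structural components. The CI method is a choice, not
a standard — binomial-style intervals would differ slightly in small
samples. Stepwise selection is bidirectional under AIC (BIC optional),
starting from the intercept-only model, with the full selection path
returned; an empty selection returns an explicit empty-spec sentinel with a
warning. Model transfer applies the frozen linear predictor to a new
cohort; because ROC is rank-based, transfer AUC is invariant to any
positive rescaling of the coefficients.

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical structure the analysis assumes:

* **Cohort composition** — seven demographic cells: two case/control pairs
  of 48 + 48 (test, replication) and DLB (34) / VaD (40) / FTD (27) groups,
  each with its own age and MMSE mean/SD, female fraction, and APOE ε4
  genotype probabilities; controls are constrained to MMSE > 25. These
  defaults are the study conditions, not tuning knobs.
* **Methylation truth** — per subject and region, Beta-distributed around
  the group mean with concentration 40, putting control SDs near 6–8
  percentage points at mid-range means (chosen to resemble the
  inter-individual scatter such cohorts show; the source material provides
  no numeric SDs, so this is a modeling convention and is flagged as such).
  Disease shifts default to −8 pp in *CR1*/*CLU*/*PICALM*, −6 in *TREM2*
  for AD and −6 in *CLU* for DLB — all under 10 pp, i.e. modest effects of
  the size targeted amplicon methods can detect but array screens often
  miss. Every other region/group pair is null, as are
  methylation–MMSE/age/expression correlations.
* **Measurement** — the recorded `meth_<region>` adds clone-sampling
  binomial noise: 20–32 clones × 10 CpGs of Bernoulli calls around the
  subject's true rate. Read-level simulation (for the alignment path) adds
  bisulfite conversion failures (default 2% per cytosine), uniform
  sequencing errors (0.1%), and optional heterozygous CpG-destroying
  polymorphisms.
* **Landscape** — background / 2-kb shore / ~1-kb island segments with
  graded planted CpG densities (0.004 / 0.02 / 0.10 per position) and GC
  (0.40 / 0.48 / 0.60); incidental CpGs from the random background are
  suppressed so the planted density is the true density.

Not emulated: chromatogram-level artifacts, PCR bias between alleles,
batch/plate effects, cell-composition variation in blood, linkage between
the typed SNPs and methylation, and age trends. Passing tests therefore
demonstrate that the *computational* pipeline recovers truth under its own
assumptions — they say nothing about biological validity of those
assumptions in real blood.

## Problem sizes and numerical choices

Simulation-based tests use sizes chosen to keep the full suite around a
minute on one CPU while leaving Monte-Carlo tolerances meaningful: 10,000
replicates for scalar type-I error checks (vectorized), 250–400 for
FWER checks of the post-tests (each replicate is a full scipy call), 20
seeded cohort replicates for the −8 pp power check (analytically the power
per region is ≈ 0.98 at the 0.00625 threshold, so ≥ 90% joint detection
over three regions is a comfortable margin), 4,000 bootstrap replicates for
the DeLong cross-check. Tolerances follow from the binomial/MC standard
error of each estimate (typically 3–4 SEs), not from observed outcomes.

Ties in ROC scores take half credit everywhere (midrank); alignment
direction ties resolve to the forward orientation; stepwise ties (identical
AIC) keep the current model because improvement must exceed 10⁻⁹.

## Known limitations

* The island detector reports composition-qualified spans only; it does not
  mask repeats, so Alu-dense loci can show extra marginal islands.
* Assay-region selection ranks by proximity to the island and returns one
  window per shore; a primer-design tool would add thermodynamic criteria
  this package deliberately leaves out.
* DeLong CIs are asymptotic; with very small or very imbalanced cohorts a
  bootstrap CI would be preferable.
* The stepwise selector inherits all the usual caveats of stepwise
  inference: selected-model p-values are optimistic and should be treated
  as descriptive.
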