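# Methods

## Models

Phenotypes follow the standard GWAS generating models. Continuous:

    y_i = α₀ + β′G_i + α′X_i + ε_i,   ε_i ~ N(0, σ²)

dichotomous:

    logit P(y_i = 1) = α₀ + β′G_i + α′X_i

with `G` the n×p matrix of minor-allele dosages (0/1/2), SNPs sorted by
position within a chromosome, `X` an n×k covariate matrix (age, sex,
principal components — consumed as given, never computed here), and `β`
sparse: nonzero only inside associated regions. The method makes no
assumption about `β` beyond this linear structure; in particular it needs no
prior weighting of variants by allele frequency.

## The RAS pipeline, stage by stage

**Effect estimation by data splitting.** A random half of the cohort (the
estimation half) provides marginal per-SNP effect estimates `β̂_j`, the
coefficient of `g_j` in `y ~ 1 + g_j + X` — ordinary least squares for
continuous phenotypes (computed via Frisch–Waugh residualization, vectorized
across SNPs), Newton maximum-likelihood logistic regression for dichotomous
ones. SNPs with no dosage variance on the estimation half, and logistic
fits that fail to converge (including perfect separation), contribute
`β̂_j = 0`. Using a held-out half for everything downstream avoids the
double-dipping that would otherwise inflate the association scores; when an
external effect-size source exists it can replace this stage.

**LPRS and association score.** For a window of consecutive SNPs the
localized polygenic risk score `LPRS_i = Σ β̂_j G_ij` is scored against the
phenotype on the evaluation half by refitting `y ~ 1 + LPRS + X` and testing
the LPRS coefficient (two-sided t with n−2−k df, or Wald z for logistic).
`AS = −log₁₀ p` is computed in log space (`logsf`) so extreme associations
do not underflow, and capped at 300. A window whose LPRS is constant after
covariate projection carries no information and scores 0 by convention. An
`in_sample_as` switch scores on the estimation half instead, for comparison
with pipelines that do not hold data out.

**Adaptive windows and the pivotal grid.** `RAS_j = max_t AS(j ± t)` over
the candidate half-widths `T` (default 5,10,…,100 SNPs), ties broken toward
the smallest window. RAS is evaluated at pivotal SNPs 1, 1+d, 1+2d, …
(d = 10 by default); windows are clipped at chromosome ends. Splitting is
repeated `n_split_reps` times (default 10) with fresh random halves; the
reported RAS is the per-repetition maximum averaged over repetitions, while
`t*` is the argmax of the repetition-averaged per-t AS profile, so each
pivotal SNP carries one coherent window for region formation. Enlarging
`T` can only increase RAS; with the window covering all p SNPs the LPRS
reduces to the ordinary genome-wide PRS.

**Peak detection.** The pivotal RAS values form a positional series in
which associated regions appear as peaks over a noise floor of roughly
`−log₁₀ U` scores. A sliding window of `cp_window` points (default 50,
sized so a 100-SNP signal at pivotal interval 10 — about 10 elevated points
plus window spillover — fits inside one window) advances with 90 % overlap.
Within each window:

1. *Change-point test*: the statistic is the maximum over interior splits
   (≥ 3 points per side) of |mean-left − mean-right| standardized by the
   window-wide SD and the usual √(1/k + 1/(W−k)) factor. Standardizing by
   the window SD rather than a pooled per-split SD keeps a noiseless step
   finite and a constant window at 0. Its p-value is the add-one
   permutation tail (1 + #{perm ≥ obs})/(1 + B) over B = 200 seeded
   shuffles of the window, so the test is distribution-free and its
   smallest attainable p is 1/(B+1).
2. *Apex refinement*: the change point marks the boundary of an elevated
   stretch, not its top; the claimed peak is the local maximum reached by
   hill-climbing from the change point in ±5-point steps (strict
   improvement only, bounded to the window). A single ±5 step is the first
   iteration of this climb but cannot cross an elevated stretch wider than
   5 points on a side.
3. *Slope verification* at the apex: one-sided OLS t-tests of the series on
   its index, requiring a significantly positive slope left of the apex and
   a significantly negative slope right of it (both at `slope_alpha`,
   default 0.05). Degenerate segments fail closed.

On success the change point seeds the next window start; otherwise the
window advances by round(0.1·W). The final partial windows are evaluated
down to 6 points. Duplicate apexes keep their smallest p-value.
Permutations are seeded from (master seed, window start), making the whole
scan deterministic.

**Regions and the magnitude threshold.** Apexes surviving a magnitude
threshold become regions spanning the RAS-optimal window `j* ± t*`,
converted to closed base-pair intervals; overlapping regions merge to their
union, keeping the larger peak's metadata. The threshold is what controls
the chromosome-wide (family-wise) type I error: it is calibrated as the
empirical (1−α) quantile of the maximum verified-peak RAS over parametric
null simulations on the actual genotypes (default 200 runs, gaussian
y ~ N(0,1) or Bernoulli at the case fraction), i.e. the smallest observed
value t with fraction{max ≥ t} ≤ α. Only this one scalar is tuned; the
change-point and slope levels stay fixed. A permutation mode (genotype rows
shuffled against intact phenotype/covariate pairs) serves real data with
unknown phenotype distribution, at the cost of also breaking any
genotype–covariate dependence such as population structure (a warning is
logged).

## Quality control

MAF is computed on the full cohort (`min(f, 1−f)`, `f` = mean dosage / 2)
and SNPs with MAF < 1 % are excluded, matching standard array-data practice.
LD pruning follows the PLINK `--indep-pairwise 50 5 0.2` dialect: windows of
50 SNPs advancing by 5; while any retained pair within a window has dosage
r² > 0.2 the pair with the largest r² is resolved by dropping its lower-MAF
member. Pruning is mandatory by default for real input (it prevents LPRS
inflation from redundant SNPs) and optional for simulated data, where the
generator controls LD directly. Missing genotypes are mean-imputed per SNP
before analysis, keeping n constant across windows; dosage columns whose
counted allele has frequency > 0.5 are flipped to minor-allele counts on
read.

## The synthetic study

The generator emulates one genotyping-array chromosome:

* **Genotypes** — each sample draws a latent stationary AR(1) Gaussian
  sequence (corr ρ between neighbours, default 0.9) thresholded at the
  standard-normal quantiles of the Hardy–Weinberg class probabilities
  (1−f)², 2f(1−f), f² of each SNP's MAF. MAFs come from a two-part mixture:
  20 % low-frequency ~ U(0.01, 0.05) and 80 % common ~ U(0.05, 0.5),
  matching the composition of typical array data after rare-variant
  exclusion. SNPs sit every 3 kb, so a 100-SNP signal region spans ≈ 0.3 Mb,
  in line with reported association-region lengths (0.1–1 Mb).
* **Effects** — M region starts are placed uniformly at random with start
  separation ≥ 2·T_sig SNPs (regions never overlap); within a region each
  SNP is causal with probability q and carries
  `β_j = ±c·|log₁₀ MAF_j|` with an equiprobable sign, so rarer variants get
  larger effects. Defaults: M = 1, T_sig = 100, q = 1, c = 0.04
  (continuous; 0.08 is the conventional dichotomous counterpart), σ = 1,
  case fraction 0.2. For dichotomous alternatives the intercept α₀ is
  solved by root finding so the sample-average event probability equals the
  target case fraction; under the null this reduces to α₀ = logit(0.2)
  exactly.

What the generator does *not* emulate: real haplotype block structure
(AR(1) decay is smoother than hot/cold recombination spots), population
structure and relatedness, genotyping error, and rare variants. Passing
tests therefore demonstrate the pipeline's statistical guarantees under
clean, tunable LD — not its behavior under confounding, which on real data
must be handled through the covariates.

## Evaluation conventions

A true region counts as identified if its closed bp interval overlaps any
detected region (shared endpoints count); a detected region overlapping no
true region is a false positive. Per run: *power* is the all-M-regions
event; *type I error* (null runs) and *FPR-A* (alternative runs) are the
any-false-positive events. Rates over R runs carry the binomial standard
error √(rate(1−rate)/R); per-region counts are reported alongside as
diagnostics.

## Problem sizes and numerical choices

The packaged study runs at n = 1,000 samples × p = 500 SNPs (50 pivotal
points, candidate half-widths 5–50, 3 split repetitions), a deliberate
scale-down that keeps a full calibration (200 null runs), a held-out FWER
check (200 runs) and a power sweep (100 runs) within about a minute on one
CPU while preserving every structural feature of the method: windows an
order of magnitude narrower than the chromosome, signal regions ≈ 0.3 Mb,
and the same pivotal spacing. At this scale the synthetic LD differs from
real array LD, so the power check uses c = 0.2 rather than the
full-study 0.04; with c = 0 the detection rate collapses to the type I
error level, as it must.

Other numerical details: all randomness flows through seeded
`SeedSequence`s derived from a master seed plus stage labels, so every
stage is reproducible and no stage reads global RNG state; the AS cap is
300; degenerate fits (zero-variance LPRS, non-converged logistic,
zero-variance slope segments) fail to 0 / False rather than erroring;
regions are 1-based closed intervals internally, converted to 0-based
half-open only in BED export.

## Known limitations

* The change-point test is one plug-in choice (permutation CUSUM); other
  single-change tests can be substituted behind `changepoint_test`.
* Regions spanning a chromosome edge are clipped at the first/last SNP, and
  a series shorter than the sliding window is not scanned.
* Calibration assumes the null phenotype model (or permutation validity) on
  the supplied genotypes; it should be rerun per dataset and configuration.
* Effect estimation is marginal per SNP; shrinkage or joint PRS weighting
  would likely sharpen the LPRS and is left open.
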