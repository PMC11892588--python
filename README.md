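# rascan — regional association detection for GWAS via the RAS statistic

Single-SNP genome-wide association tests struggle with regions where many
common variants each carry a small effect: individually none reaches the
genome-wide threshold, yet jointly the region is clearly associated.
Set-based tests (burden, SKAT and relatives) aggregate such effects but
inherit inflated chromosome-wide type I error in the presence of causal
variants elsewhere on the chromosome, and their results are hard to read off
a plot. `rascan` implements an alternative built around the **regional
association score (RAS)**: a per-SNP, visualizable measure of regional
association strength, scanned for peaks with a change-point procedure whose
chromosome-wide type I error is controlled by simulation-based calibration.
It is aimed at statistical geneticists analyzing genotyping-array data
(common and low-frequency variants, MAF ≥ 1%) with continuous or
dichotomous phenotypes.

## The statistic

For a window of consecutive SNPs indexed by `I₁…I_K` around a pivotal SNP,
the *localized polygenic risk score* of individual *i* is

    LPRS_i = Σ_j  β̂_{I_j} · G_{i,I_j}

where `G` is the n×p minor-allele dosage matrix and `β̂` are per-SNP marginal
effect estimates from a standard GWAS regression (`y ~ 1 + g_j + X`) fitted
on a random half of the sample. On the complementary half the window's
*association score* is

    AS = −log₁₀ p,   p from the t (or Wald) test of γ in  y ~ 1 + γ·LPRS + X,

and the RAS of pivotal SNP *j* adapts the window size:

    RAS_j = max_{t ∈ T} AS( windows j±t ),   T = {5, 10, …, 100} by default.

Sample splitting is repeated (10× by default) and the RAS averaged.
Evaluated at every 10th SNP along a chromosome, the RAS values form a
positional series in which associated regions appear as peaks. A sliding
window (50 pivotal points, 90 % overlap) runs a permutation CUSUM test for a
change point; candidate apexes are verified by one-sided slope tests
(significantly rising on the left, falling on the right) and finally
filtered by a magnitude threshold calibrated on null simulations so that the
probability of reporting *any* region on a null chromosome stays at the
target level (0.05). Reported regions span the RAS-optimal window `j* ± t*`
of each surviving apex.

The package also ships the full synthetic study used to validate those
guarantees: LD-structured genotypes (latent AR(1) Gaussians thresholded at
Hardy–Weinberg quantiles, 20 % low-frequency / 80 % common MAF mixture),
null and alternative phenotype models with `β_j = ±s·c·|log₁₀ MAF_j|` inside
planted signal regions, and scoring of detections as type I error, power
(all M regions recovered) and FPR-A (false positives under the alternative).

## Worked example

Simulate one chromosome (1,000 samples, 500 SNPs at 3 kb spacing, AR(1)
LD ρ=0.9) with a single planted 100-SNP signal region, calibrate the
magnitude threshold on 100 null runs, scan, and score:

```
$ ras simulate --n 1000 --p 500 --t-sig 100 --q 1.0 --c 0.2 --seed 4 --outdir demo/sim
wrote demo/sim/genotypes.tsv, phenotypes.tsv, truth.json (1 true region(s))

$ ras calibrate demo/sim/genotypes.tsv --candidate-T 5:50:5 --split-reps 3 \
      --null-runs 100 --seed 4 --outdir demo/cal
threshold = 2.6215 (empirical FWER 0.050 on 100 null runs)

$ ras scan demo/sim/genotypes.tsv --phenotypes demo/sim/phenotypes.tsv \
      --calibration demo/cal/calibration.json --candidate-T 5:50:5 \
      --split-reps 3 --seed 4 --outdir demo/scan
1 region(s) reported at threshold 2.6215

$ cat demo/scan/regions.tsv
chromosome  start_bp  end_bp  peak_snp_id  peak_pivotal_index  peak_ras  t_star  cp_p_value
1           573000    873000  snp000241    241                 21.51     50      0.00995

$ ras evaluate demo/sim/truth.json demo/scan/regions.tsv --metric power --outdir demo/eval
setting metric  rate  se  n_runs ...
   runs  power   1.0 0.0       1
```

The calibrated threshold 2.62 is the 95th percentile of the maximum
verified-peak RAS over the null runs — any null chromosome clears it with
probability ≤ 0.05. The scan's one region (bp 573,000–873,000, peak
RAS 21.5 at SNP 241 with optimal half-width t\*=50) overlaps the planted
region (bp 570,000–867,000), so this run scores power 1 with no false
positives. `demo/scan/` also contains the RAS series TSV, a BED export, a
trend plot (series, detected peaks, threshold line) and a `manifest.json`
that makes the run byte-for-byte reproducible.

The same pipeline runs on real data: `ras scan` accepts PLINK
`.bed/.bim/.fam` prefixes or dosage TSVs plus phenotype/covariate TSVs, and
`ras calibrate --permute` calibrates against row-permuted genotypes when the
phenotype distribution is unknown.

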