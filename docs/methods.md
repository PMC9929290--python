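# Methods

This package implements a three-stage workflow for polygenic risk prediction
across ancestral populations using GWAS summary statistics and LD reference
panels only — no individual-level validation cohort is required at any stage.

## 1. Cross-population local genetic correlation scan

For two populations with association z-scores `z_1`, `z_2` aligned to one SNP
map, the scan statistic over a contiguous SNP window `R` is

    Q(R) = sum_{i in R} z_1i z_2i / (sum_{i in R} Sigma_1,ii Sigma_2,ii)^theta

where `Sigma_k` is the covariance of `z_k` under a polygenic model,

    Sigma_k = (N_k h_k^2 / M) V~_k^2 + (1 - h_k^2) V_k ,
    V~_k^2  = (N_ref - 1)/(N_ref - 2) V_k^2 - M_b/(N_ref - 2) V_k .

`V_k` is the block LD correlation matrix from the population's reference
panel and `V~_k^2` the unbiased estimator of its square. The numerator of Q
measures the local covariance of SNP effects between the populations; the
denominator equalizes scale across window sizes, with `theta` (default 0.5)
controlling how strongly LD-driven variance is penalized. An optional
calibration routine picks `theta` from {0, 0.25, 0.5, 0.75, 1} to minimize
the dependence of the null Q variance on window size — the rationale being
that the denominator exists precisely to flatten that dependence.

Two M conventions appear in `Sigma_k`: the coefficient `N h^2 / M` is a
per-SNP heritability and uses the genome-wide SNP count, while `M_b` in the
`V~^2` correction term defaults to the per-block SNP count because the
correction compensates sampling noise of exactly the LD entries used in that
block (`m_for_v2="genome"` switches to the global count).

Inference uses the maximal statistic `Q_max = max_{|R|<=C} |Q(R)|`
(`C = 2000` by default). Windows never cross LD-block boundaries: blocks are
treated as independent, `Sigma` is block-diagonal, and the maximum
decomposes per block. The null distribution of `Q_max` is obtained by Monte
Carlo: `z_k ~ MVN(0, Sigma_k)` drawn independently per population (5000
draws by default), recomputing `Q_max` over the same window space. Each
`Sigma_k` block is eigenvalue-floored (1e-6) before factorization because
the `V~^2` correction can push small eigenvalues slightly negative.

Regions are detected by iterative peeling: record the maximizing window,
compute the add-one Monte-Carlo p-value `p = (1 + #{null >= |Q|})/(1 + n_mc)`,
zero the window's SNPs, and repeat. Peeling p-values are monotone
non-decreasing, and the same null is reused for every peel (removing SNPs
only shrinks the search space, making reuse conservative). A region is
significant while `p <= fdr_level`; on this monotone sequence
Benjamini–Hochberg applied to the admitted prefix rejects all of it, so the
stop-at-first-failure rule and BH coincide. Same-sign significant regions
closer than 100 kb are merged; the merged Q is recomputed on the union and
the merged p is the minimum of the members (significance was established
before merging).

Trait heritability, needed for `Sigma_k`, can be supplied directly or
estimated by a moment identity: under the model,
`E[z_j^2] - 1 = h^2 ((N/M) l_j - 1)` with `l_j` the bias-corrected LD score,
so a through-origin regression of `z^2 - 1` on `(N/M) l - 1` identifies
`h^2` from the mean level of the LD scores. We deliberately avoid the
classical slope-on-`l` regression here: at reference-panel sizes of a few
hundred the noise in `l` is comparable to its spread, and the classical
slope suffers severe errors-in-variables attenuation (we observed ~2x
underestimation), while the mean level is estimated with little error.

## 2. Annotation-dependent horseshoe regression

SNP effects are modeled per population as

    beta_jk ~ N(0, (sigma_k^2 / N_k) phi psi_j lambda_{f(j),k})

with half-Cauchy(1) priors on the square roots of the global `phi`, local
`psi_j` (shared across populations), and annotation-category
`lambda_{a,k}` (population-specific), and a Jeffreys prior on the residual
variance `sigma_k^2`. The annotation has two categories per non-target
population: SNPs inside the top-s positively correlated regions (`Omega_k`)
and the rest. When estimating the target population's own effects all
`lambda` are pinned to 1 — the target needs no portability prioritization —
so one sampler run is executed per output population, each a joint model
over all K populations' statistics.

Gibbs updates use the inverse-gamma auxiliary representation of the
half-Cauchy, giving closed-form conditionals throughout. Per LD block the
effect vector is drawn from

    beta_block ~ MVN((D + S^-1)^-1 bhat_block, (sigma^2/N)(D + S^-1)^-1),

with `D` the ridge-regularized (1e-6) block LD matrix and
`S = diag{phi psi_j lambda_{f(j),k}}`; `bhat = z/sqrt(N)` are marginal
standardized effects. `sigma_k^2` is drawn from
`IG((N_k + M)/2, (N_k/2)[1 - 2 b'bhat + b'(D + S^-1)b])`, the standard
summary-statistic residual identity, with the rate floored at a small
positive value. The local `psi_j` is clipped above at 1, which prevents the
divergence of a single local scale in low-polygenicity regimes; the global
and category scales remain free, so large effects can still escape
shrinkage. (An earlier variant capping the whole product `phi psi lambda`
at 1 bounds every shrinkage factor at 1/2 and measurably suppresses the
annotation mechanism; the per-`psi` cap is the convention used by
continuous-shrinkage PRS samplers.)

Defaults follow the `1000 x K` iteration / `500 x K` burn-in convention.
Chains are deterministic given a seed; convergence is reported (split-chain
R-hat on the strongest marginal effects and on `phi`) but chains are not
auto-extended. The full-Bayes treatment of `phi` is the default; a fixed
`phi` grid {1e-6, 1e-4, 1e-2, 1} with an external validation hook is
available, with ties broken toward the smallest (strongest-shrinkage) value.

For the annotation we rank peeled regions by p-value then |Q| and take the
top s (default 1000) with positive sign; negatively correlated regions never
enter `Omega_k`. The peel used for ranking continues past the FDR cut
(to p <= 0.5) so the top-s list is not truncated at the significance
boundary — regions beyond it are flagged non-significant in all outputs.
Positive-only selection plus deep ranking mirrors the intended use: the
annotation is a prioritization, not an inference.

## 3. Summary-statistics PRS combination

Individual-level combination would regress the phenotype on K
population-specific scores in a held-out cohort. The summary-statistic
replacement has three parts:

1. *Pseudo-subsampling.* Given the target's full mean statistic `X'Y/N`, a
   training statistic for a random (1-v)/v split is sampled as
   `X'Y/N + sqrt(Nv/(N(N-Nv))) X_ref' g / sqrt(N_ref)` with `g` standard
   normal; the validation statistic follows from the exact complement
   identity `(N-Nv) train + Nv valid = N full`. The injected noise has
   covariance `(Nv/(N(N-Nv))) LD`, matching the sampling distribution of a
   real split. Default v = 0.25.
2. *Refit.* The PRS model is refit with the training statistic for the
   target and full statistics for the other populations.
3. *Weights.* `w_hat = (N_ref/Nv) [PRS_ref' PRS_ref]^-1 b' (X_v' Y_v)` with
   `PRS_ref = X_ref b` centered per column. Negative entries are truncated
   to zero and the rest normalized to sum 1; if truncation zeroes
   everything, uniform weights are used with a warning. A ridge of
   `1e-6 trace/K` stabilizes the Gram matrix against collinear scores.
   P-fold repeated learning (default P = 4, fold p seeded as seed + p)
   averages the normalized per-fold weights.

Three disjoint target-population subpanels are required for the three roles
(subsampling noise, training LD, weight estimation) and the requirement is
enforced — reusing one panel couples the noise across stages and biases the
weights.

## Synthetic data generator

Haplotypes are thresholded latent Gaussian AR(1) chains, independent across
LD blocks. The latent adjacent correlation is solved numerically (bivariate
normal orthant probability, cached on a rounded MAF grid) so that the
realized genotype correlation matches the requested value — naive
thresholding attenuates an AR parameter of 0.8 to about 0.6. MAFs are drawn
smoothly within blocks because the correlation between binary variants with
very different frequencies is bounded well below 1. Populations share the
SNP map but have independent frequency and LD realizations; the realized
F_ST (reported by `realized_fst`) is a few percent — smaller than between
real continental populations, so portability failures driven by allele
frequency divergence are under-represented in these simulations.

Effect architectures: infinitesimal (`h2/M` per SNP), heritability
enrichment (a designated signal set carries a stated share of `h2`; the
scan experiments use 30% in one planted block), LDAK-style
(variance ∝ `[f(1-f)]^0.75 u_j`, with `u_j` supplied externally, default 1),
and liability threshold (infinitesimal liability, top `case_fraction`
labeled cases, z-scores from the linear model on the 0/1 outcome). Signal
SNPs are drawn jointly across the first two populations with correlation
`cross_pop_r`; all other SNPs use `background_r` (default 0, matching the
null/power designs; prediction experiments use a moderate positive value,
since some genome-wide effect sharing between continental populations is
the empirically typical regime in which multi-population scores are
useful). Phenotype noise is scaled to the empirical variance of the genetic
score so realized heritability matches the target under LD.

What a green simulation test does *not* establish: calibration under real
LD (reference mismatch, long-range LD), robustness to allele-frequency
divergence at real F_ST, case-control ascertainment effects, or behavior at
biobank scale (M ~ 1e6, N ~ 1e5). The experiment runners reuse one
covariance model and one Monte-Carlo null across replicates of a setting
(heritability and panels are fixed within a setting), which is what makes
repeated designs tractable on one CPU.

## Numerical choices and degenerate inputs

- Positions are 1-based; block intervals are half-open `[start, end)`.
- Missing genotypes are mean-imputed per SNP before standardization;
  monomorphic SNPs are removed at panel load (kept, as zero columns, in
  panel splits so all parts share one SNP map).
- Allele matching is two-pass (exact, then strand complement); ambiguous
  A/T and C/G variants are removed; unmatched SNPs are dropped and counted.
- Ridge 1e-6 on LD diagonals guarantees positive-definite solves; the
  scan's `Sigma` blocks get an eigenvalue floor of 1e-6.
- Add-one Monte-Carlo p-values keep p > 0; ties in the window search break
  leftmost, then shortest.
- Shrinkage draws are clipped to [1e-12, 1e12]; the sigma^2 rate is floored
  at 1e-8.
- An annotation covering zero SNPs degenerates to a single category with a
  warning; an all-zero weight vector after truncation falls back to uniform.

## Known limitations

- Single categorical annotation per non-target population (the layout
  generalizes, but continuous or multiple annotations are not implemented).
- The scan reports Q, sign, and p per region; it does not estimate the
  correlation coefficient within regions.
- Desk-scale detection power is limited by total signal mass `N h_local^2`;
  designs matched to the original genome-wide experiments in proportions
  but not in N x M cannot reach the same power (see the acceptance suite's
  power test, whose stated design is analyzed in the repository notes).
- The theta-selection and sequential-FDR constructions are reasoned
  interpretations (documented above) rather than ports of a reference
  implementation.
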