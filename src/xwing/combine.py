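"""Linear combination of population-specific PRS from summary statistics.

Combining K population-specific scores normally requires regressing the
phenotype on the scores in an independent validation cohort. This module
replaces that cohort with summary statistics alone:

1. *Subsampling*: given the target population's full GWAS mean statistic
   X'Y/N, training and validation statistics for a random (1 - v)/v split
   are sampled by injecting reference-panel-structured Gaussian noise,

       X_tr'Y_tr/(N - Nv) = X'Y/N + sqrt(Nv / (N (N - Nv))) X_ref' g / sqrt(N_ref),

   with the validation statistic defined by the exact complement identity
   (N - Nv) * train + Nv * valid = N * full.
2. *Weight estimation*: least-squares mixing weights are recovered from the
   reference-panel PRS Gram matrix,

       w_hat = (N_ref / Nv) [PRS_ref' PRS_ref]^-1 b' (X_v' Y_v),

   with negative entries truncated to zero and the rest normalized to sum 1.
3. *Repeated learning*: P independent splits are drawn, the PRS model is
   refit on each training statistic, and the final weights are the average
   of the per-fold normalized weights.

Three disjoint target-population reference panels are required — one for
subsampling noise, one for PRS-training LD, one for weight estimation —
to avoid overfitting between the stages.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .io import HarmonizedStudySet, InputError, LDPanel, block_ld_set
from .gibbs import GibbsConfig, PosteriorEffects, ShrinkagePlan, fit_posterior_effects

logger = logging.getLogger(__name__)


@dataclass
class SubsampleDraw:
    """One pseudo training/validation split of a GWAS summary statistic."""

    n_total: int
    n_valid: int
    train_stat: np.ndarray    # X_tr' Y_tr / (N - Nv)
    valid_stat: np.ndarray    # X_v' Y_v / Nv
    g: np.ndarray
    seed: int

    @property
    def n_train(self) -> int:
        return self.n_total - self.n_valid

    @property
    def z_train(self) -> np.ndarray:
        """Training z-scores X_tr'Y_tr / sqrt(N_tr)."""
        return self.train_stat * np.sqrt(self.n_train)


@dataclass
class MixWeights:
    w_raw: np.ndarray
    w_norm: np.ndarray
    w_final: np.ndarray
    n_folds: int = 1
    per_fold: list = field(default_factory=list)


def subsample_sumstats(
    stats, valid_fraction: float, panel: LDPanel, seed: int,
) -> SubsampleDraw:
    """Sample pseudo training/validation summary statistics.

    ``stats`` is a SumStats aligned to ``panel``'s SNP order, or a plain
    (z, n) tuple. The injected training noise has covariance
    (Nv / (N (N - Nv))) * LD, so the two pseudo statistics behave like
    statistics computed on a real random split of the GWAS sample.
    """
    if hasattr(stats, "df"):
        z = stats.df["z"].to_numpy(float)
        n = int(np.median(stats.df["n"]))
    else:
        z, n = stats
        z = np.asarray(z, float)
        n = int(n)
    if not 0.0 < valid_fraction < 1.0:
        raise InputError("valid_fraction must lie in (0, 1)")
    if len(z) != panel.m:
        raise InputError("panel SNPs do not match the summary statistics")
    n_valid = int(round(valid_fraction * n))
    if n_valid < 1 or n_valid >= n:
        raise InputError(f"validation size {n_valid} out of range for N={n}")
    full_stat = z / np.sqrt(n)            # X'Y/N
    rng = np.random.default_rng(seed)
    g = rng.standard_normal(panel.n_ref)
    noise_scale = np.sqrt(n_valid / (n * (n - n_valid)))
    noise = noise_scale * (panel.standardized.T @ g) / np.sqrt(panel.n_ref)
    train_stat = full_stat + noise
    valid_stat = (n * full_stat - (n - n_valid) * train_stat) / n_valid
    return SubsampleDraw(
        n_total=n, n_valid=n_valid, train_stat=train_stat,
        valid_stat=valid_stat, g=g, seed=seed,
    )


def estimate_mix_weights(
    b,
    valid_stat: np.ndarray,
    n_valid: int,
    panel: LDPanel,
    ridge_scale: float = 1e-6,
) -> MixWeights:
    """Least-squares mixing weights from the reference-panel PRS Gram matrix.

    Negative raw weights are truncated to zero and the rest normalized to a
    probability vector; an all-zero truncation falls back to uniform weights
    with a warning. A small ridge (ridge_scale * trace / K) stabilizes the
    Gram matrix against collinear population scores.
    """
    bmat = b.b if isinstance(b, PosteriorEffects) else np.atleast_2d(b)
    if bmat.shape[0] != panel.m:
        raise InputError("effect matrix SNPs do not match the panel")
    k = bmat.shape[1]
    prs_ref = panel.standardized @ bmat
    prs_ref = prs_ref - prs_ref.mean(axis=0)
    gram = prs_ref.T @ prs_ref
    tr = np.trace(gram)
    if tr <= 0:
        logger.warning("degenerate PRS Gram matrix; falling back to uniform")
        w = np.full(k, 1.0 / k)
        return MixWeights(w_raw=np.zeros(k), w_norm=w, w_final=w)
    gram = gram + ridge_scale * tr / k * np.eye(k)
    rhs = bmat.T @ (np.asarray(valid_stat, float) * n_valid)
    w_raw = (panel.n_ref / n_valid) * np.linalg.solve(gram, rhs)
    w = np.clip(w_raw, 0.0, None)
    if w.sum() <= 0:
        logger.warning("all mixing weights truncated to zero; using uniform")
        w_norm = np.full(k, 1.0 / k)
    else:
        w_norm = w / w.sum()
    return MixWeights(w_raw=w_raw, w_norm=w_norm, w_final=w_norm,
                      per_fold=[w_norm])


def _check_disjoint_panels(panels3) -> None:
    if len(panels3) != 3:
        raise InputError("exactly three target-population panels are required")
    for i in range(3):
        for j in range(i + 1, 3):
            a, b = panels3[i].dosages, panels3[j].dosages
            if a.shape == b.shape and np.array_equal(a, b, equal_nan=True):
                raise InputError(
                    "subsampling, training-LD and weighting panels must be "
                    f"disjoint; panels {i} and {j} are identical"
                )


def repeated_learning(
    set_: HarmonizedStudySet,
    target: int,
    plan: ShrinkagePlan,
    panels3,
    p_folds: int = 4,
    config: GibbsConfig | None = None,
    valid_fraction: float = 0.25,
    fit_fn=None,
    seed: int = 0,
) -> MixWeights:
    """P-fold summary-statistics repeated learning of mixing weights.

    Each fold subsamples the target population's statistics (default 75/25
    split), refits posterior effects with the subsampled training statistic
    for the target and full statistics for the others, and estimates fold
    weights; the final weights average the per-fold normalized weights.
    ``fit_fn(training_set) -> effects`` overrides the default Gibbs refit.
    Fold p uses seed + p.
    """
    if p_folds < 2:
        raise InputError("repeated learning needs P >= 2 folds")
    _check_disjoint_panels(panels3)
    config = config or GibbsConfig()
    sub_panel, train_panel, weight_panel = panels3
    if fit_fn is None:
        def fit_fn(train_set):
            ld = [block_ld_set(train_set, k) for k in range(train_set.k)]
            return fit_posterior_effects(train_set, plan, config, ld=ld)

    per_fold, raws = [], []
    for p in range(p_folds):
        draw = subsample_sumstats(
            (set_.z_matrix[:, target], set_.n_vector[target]),
            valid_fraction, sub_panel, seed + p,
        )
        z = set_.z_matrix.copy()
        z[:, target] = draw.z_train
        n_vec = set_.n_vector.copy()
        n_vec[target] = draw.n_train
        panels = list(set_.panels)
        panels[target] = train_panel
        train_set = replace(set_, z_matrix=z, n_vector=n_vec, panels=panels)
        try:
            effects = fit_fn(train_set)
        except Exception as err:
            raise RuntimeError(f"PRS refit failed in fold {p}") from err
        w = estimate_mix_weights(effects, draw.valid_stat, draw.n_valid,
                                 weight_panel)
        per_fold.append(w.w_norm)
        raws.append(w.w_raw)
    w_final = np.mean(per_fold, axis=0)
    return MixWeights(
        w_raw=np.mean(raws, axis=0), w_norm=w_final, w_final=w_final,
        n_folds=p_folds, per_fold=per_fold,
    )


def score_and_combine(
    b,
    w: MixWeights,
    genotypes: np.ndarray,
    snp_map=None,
    standardize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual combined and population-specific scores.

    ``genotypes`` is a cohort dosage matrix; missing values are
    mean-imputed and columns are centered. With ``standardize=True``
    (default, consistent with standardized-scale effects) columns are also
    scaled to unit variance; ``standardize=False`` scores centered raw
    dosages, appropriate for per-allele weights. When both the cohort and
    the effects carry SNP maps, effect alleles are verified to match.
    Returns (combined, per_population) scores.
    """
    bmat = b.b if isinstance(b, PosteriorEffects) else np.atleast_2d(b)
    if snp_map is not None and isinstance(b, PosteriorEffects) \
            and b.snp_map is not None:
        mismatch = snp_map["a1"].to_numpy() != b.snp_map["a1"].to_numpy()
        if mismatch.any():
            bad = snp_map["snp_id"].to_numpy()[mismatch][0]
            raise InputError(f"effect allele mismatch at SNP {bad}")
    x = np.asarray(genotypes, float).copy()
    nan_mask = np.isnan(x)
    if nan_mask.any():
        col_mean = np.nanmean(x, axis=0)
        x[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    x -= x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0)
        x /= np.where(sd > 0, sd, 1.0)
    per_pop = x @ bmat
    combined = per_pop @ w.w_final
    return combined, per_pop
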