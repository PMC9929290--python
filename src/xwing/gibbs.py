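"""Annotation-dependent Bayesian horseshoe regression for PRS.

The model, fit from summary statistics and block LD only:

    Y_k = X_k beta_k + eps_k,   eps_k ~ MVN(0, sigma_k^2 I),  p(sigma_k^2) ~ 1/sigma_k^2
    beta_jk ~ N(0, (sigma_k^2 / N_k) * phi * psi_j * lambda_{f(j),k})
    sqrt(psi_j), sqrt(phi), sqrt(lambda_{a,k}) ~ half-Cauchy(1)

phi is a global shrinkage parameter shared by all SNPs and populations,
psi_j a local parameter shared across populations, and lambda_{a,k} an
annotation-category parameter specific to population k. Annotated SNPs
(those in regions with positive cross-population local genetic correlation)
get their own lambda, so when the annotation is informative they are shrunk
less: with no LD the posterior mean is

    E[beta_jk | bhat_jk] = (1 - 1/(1 + phi lambda_{f(j),k} psi_j)) bhat_jk.

Half-Cauchy priors are handled through the conjugate inverse-gamma
auxiliary-variable representation, giving closed-form Gibbs updates. The
effect vector is updated jointly within each LD block:

    beta_block ~ MVN( (D + S^-1)^-1 bhat,  (sigma^2/N) (D + S^-1)^-1 )

with D the block LD matrix and S = diag{phi psi_j lambda_{f(j),k}}.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .io import ConfigError, HarmonizedStudySet, block_ld_set

logger = logging.getLogger(__name__)

_FLOOR = 1e-12
_CEIL = 1e12


@dataclass
class AnnotationMap:
    """Per-population SNP annotation derived from the Omega_k region sets.

    ``omega_sets[k]`` holds the SNP indices annotated for non-target
    population k; category 0 = non-annotated, 1 = annotated.
    """

    m: int
    omega_sets: dict
    s: int = 1000

    @property
    def n_categories(self) -> int:
        return 2

    def indicator(self, k: int) -> np.ndarray:
        ind = np.zeros(self.m, dtype=int)
        idx = self.omega_sets.get(k)
        if idx is not None and len(idx):
            ind[np.asarray(idx, dtype=int)] = 1
        return ind


@dataclass
class RunLayout:
    """Lambda layout for one sampler run.

    ``cat`` maps each (SNP, population) to its lambda category;
    ``n_cat[k]`` categories exist for population k. When ``sample_lambda``
    is False every lambda is pinned to 1 (the target-population run).
    ``out_pop`` selects which population's effects this run contributes;
    None means all populations (the unannotated single-run plan)."""

    out_pop: int | None
    cat: np.ndarray          # M x K integer categories
    n_cat: list
    sample_lambda: bool


@dataclass
class ShrinkagePlan:
    target_index: int
    runs: list


@dataclass
class GibbsConfig:
    n_iter: int | None = None        # default 1000 * K
    n_burnin: int | None = None      # default 500 * K
    thin: int = 1
    seed: int = 0
    phi_mode: str = "full_bayes"     # or "fixed"
    phi_fixed: float = 1.0
    freeze_shrinkage: bool = False   # pin phi, psi, lambda, sigma2 (testing)
    psi_cap: float = 1.0             # upper clip on the local psi_j

    def resolve(self, k: int) -> tuple[int, int]:
        n_iter = 1000 * k if self.n_iter is None else self.n_iter
        # default burn-in: half the chain (500*K under the default length)
        n_burn = n_iter // 2 if self.n_burnin is None else self.n_burnin
        if n_burn >= n_iter:
            raise ConfigError("burn-in must be shorter than the chain")
        return n_iter, n_burn


@dataclass
class PosteriorEffects:
    """M x K posterior mean standardized SNP effects."""

    b: np.ndarray
    snp_map: pd.DataFrame | None = None
    scale: str = "standardized"
    diagnostics: dict = field(default_factory=dict)

    def per_allele(self, freqs: np.ndarray) -> np.ndarray:
        """Convert standardized effects to per-allele weights using allele
        frequencies f: b / sqrt(2 f (1 - f))."""
        f = np.asarray(freqs, float)
        sd = np.sqrt(2.0 * f * (1.0 - f))
        sd = np.where(sd > 0, sd, np.inf)
        return self.b / sd[:, None]

    def to_tsv(self, path: str, population: int, freqs: np.ndarray) -> None:
        out = self.snp_map[["snp_id", "a1", "a2"]].copy()
        out["effect_standardized"] = self.b[:, population]
        out["effect_per_allele"] = self.per_allele(freqs)[:, population]
        out.to_csv(path, sep="\t", index=False)


def make_shrinkage_plan(
    target_index: int,
    annotations: AnnotationMap | None,
    k: int,
    m: int | None = None,
) -> ShrinkagePlan:
    """Encode the lambda assignment scheme.

    Estimating the target population's effects uses lambda = 1 for every SNP
    and population (no annotation-dependent shrinkage). Estimating non-target
    population k uses a two-category split of population k's SNPs by Omega_k,
    while every other population keeps a single free category.
    With ``annotations=None`` (and ``m`` given) the model reduces to the
    plain global+local horseshoe: one lambda-pinned run yields all columns.
    """
    if not 0 <= target_index < k:
        raise ConfigError(f"target index {target_index} outside 0..{k - 1}")
    if annotations is None:
        if m is None:
            raise ConfigError("m is required when no annotation map is given")
        cat = np.zeros((m, k), dtype=int)
        return ShrinkagePlan(target_index=target_index, runs=[
            RunLayout(None, cat, [1] * k, sample_lambda=False)])
    runs = []
    # target run: all lambdas pinned at 1
    for out_pop in range(k):
        if out_pop == target_index:
            cat = np.zeros((annotations.m, k), dtype=int)
            runs.append(RunLayout(out_pop, cat, [1] * k, sample_lambda=False))
        else:
            if out_pop not in annotations.omega_sets:
                raise ConfigError(
                    f"annotation missing for non-target population {out_pop}"
                )
            ind = annotations.indicator(out_pop)
            cat = np.zeros((annotations.m, k), dtype=int)
            n_cat = [1] * k
            if ind.any():
                cat[:, out_pop] = ind
                n_cat[out_pop] = 2
            else:
                logger.warning(
                    "annotation for population %d covers zero SNPs; "
                    "degenerating to a single category", out_pop,
                )
            runs.append(RunLayout(out_pop, cat, n_cat, sample_lambda=True))
    return ShrinkagePlan(target_index=target_index, runs=runs)


def posterior_mean_unlinked(
    beta_hat: np.ndarray, phi: float, psi: np.ndarray, lam: np.ndarray,
) -> np.ndarray:
    """No-LD posterior mean: (1 - 1/(1 + phi lambda psi)) * bhat."""
    shrink = 1.0 - 1.0 / (1.0 + phi * np.asarray(lam) * np.asarray(psi))
    return shrink * np.asarray(beta_hat)


def update_beta_block(
    d: np.ndarray,
    s: np.ndarray,
    beta_hat_block: np.ndarray,
    sigma2: float,
    n: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw beta for one LD block from its full conditional.

    Returns (draw, conditional mean). The conditional is MVN with mean
    solving (D + S^-1) mu = bhat and covariance (sigma2/N)(D + S^-1)^-1.
    """
    s = np.asarray(s, float)
    if np.any(s <= 0):
        raise FloatingPointError("non-positive prior scale in beta update")
    a = d + np.diag(1.0 / s)
    try:
        chol = linalg.cholesky(a, lower=True)
    except linalg.LinAlgError as err:
        raise FloatingPointError("block conditional not positive definite") from err
    mu = linalg.cho_solve((chol, True), beta_hat_block)
    eta = rng.standard_normal(len(s))
    draw = mu + np.sqrt(sigma2 / n) * linalg.solve_triangular(
        chol.T, eta, lower=False
    )
    return draw, mu


def _inv_gamma(rng, shape, rate):
    return np.clip(rate / rng.gamma(shape, size=np.shape(rate) or None),
                   _FLOOR, _CEIL)


class GibbsChain:
    """One MCMC chain over all K populations for a fixed lambda layout."""

    def __init__(
        self,
        beta_hat: np.ndarray,
        n_vec: np.ndarray,
        ld: list,
        block_slices: list,
        layout: RunLayout,
        config: GibbsConfig,
        rng: np.random.Generator,
    ) -> None:
        self.beta_hat = np.atleast_2d(beta_hat)
        self.m, self.k = self.beta_hat.shape
        self.n_vec = np.asarray(n_vec, float)
        self.ld = ld
        self.block_slices = block_slices
        self.layout = layout
        self.config = config
        self.rng = rng
        self.beta = np.zeros((self.m, self.k))
        self.psi = np.ones(self.m)
        self.nu = np.ones(self.m)
        self.lam = [np.ones(nc) for nc in layout.n_cat]
        self.xi = [np.ones(nc) for nc in layout.n_cat]
        self.phi = config.phi_fixed if config.phi_mode == "fixed" else 1.0
        self.zeta = 1.0
        self.sigma2 = np.ones(self.k)

    def prior_scale(self, k: int) -> np.ndarray:
        """phi * psi_j * lambda_{f(j),k}, floored for numerical safety."""
        s = self.phi * self.psi * self.lam[k][self.layout.cat[:, k]]
        return np.clip(s, _FLOOR, _CEIL)

    def update_beta(self) -> None:
        for k in range(self.k):
            s = self.prior_scale(k)
            for blk, sl in zip(self.ld[k], self.block_slices):
                draw, _mu = update_beta_block(
                    blk.v_solve, s[sl], self.beta_hat[sl, k],
                    self.sigma2[k], self.n_vec[k], self.rng,
                )
                self.beta[sl, k] = draw

    def update_shrinkage(self) -> None:
        if self.config.freeze_shrinkage:
            return
        cat = self.layout.cat
        lam_jk = np.column_stack([self.lam[k][cat[:, k]] for k in range(self.k)])
        # scaled squared effects N_k beta_jk^2 / (2 sigma_k^2), M x K
        q = self.n_vec * self.beta ** 2 / (2.0 * self.sigma2)
        # local psi_j, pooled across populations
        rate = 1.0 / self.nu + (q / lam_jk).sum(axis=1) / self.phi
        psi = _inv_gamma(self.rng, (self.k + 1) / 2.0, rate)
        # upper clip on psi (standard in continuous-shrinkage PRS samplers)
        # prevents divergence when very few SNPs carry all the signal
        self.psi = np.minimum(psi, self.config.psi_cap)
        self.nu = _inv_gamma(self.rng, 1.0, 1.0 + 1.0 / self.psi)
        # annotation-dependent lambda_{a,k}
        if self.layout.sample_lambda:
            for k in range(self.k):
                for a in range(self.layout.n_cat[k]):
                    mask = cat[:, k] == a
                    m_a = int(mask.sum())
                    if m_a == 0:
                        continue
                    rate = 1.0 / self.xi[k][a] + \
                        (q[mask, k] / self.psi[mask]).sum() / self.phi
                    self.lam[k][a] = _inv_gamma(self.rng, (m_a + 1) / 2.0, rate)
                    self.xi[k][a] = _inv_gamma(
                        self.rng, 1.0, 1.0 + 1.0 / self.lam[k][a])
        # global phi, pooled across all M*K terms
        if self.config.phi_mode != "fixed":
            lam_jk = np.column_stack(
                [self.lam[k][cat[:, k]] for k in range(self.k)])
            rate = 1.0 / self.zeta + (q / (self.psi[:, None] * lam_jk)).sum()
            self.phi = float(_inv_gamma(self.rng, (self.m * self.k + 1) / 2.0,
                                        rate))
            self.zeta = float(_inv_gamma(self.rng, 1.0, 1.0 + 1.0 / self.phi))
        # residual variance, Jeffreys prior, summary-statistic residual
        for k in range(self.k):
            quad = 1.0
            for blk, sl in zip(self.ld[k], self.block_slices):
                b = self.beta[sl, k]
                quad += b @ blk.v_solve @ b - 2.0 * b @ self.beta_hat[sl, k]
            s = self.prior_scale(k)
            quad += np.sum(self.beta[:, k] ** 2 / s)
            quad = max(quad, 1e-8)
            self.sigma2[k] = float(_inv_gamma(
                self.rng, (self.n_vec[k] + self.m) / 2.0,
                self.n_vec[k] * quad / 2.0))

    def sweep(self) -> None:
        self.update_beta()
        self.update_shrinkage()

    def run(self) -> tuple[np.ndarray, dict]:
        n_iter, n_burn = self.config.resolve(self.k)
        keep = []
        op = self.layout.out_pop if self.layout.out_pop is not None else 0
        trace_idx = np.argsort(-np.abs(self.beta_hat[:, op]))[:5]
        traces = {"phi": [], "lam": [], "beta": []}
        for it in range(n_iter):
            self.sweep()
            if it >= n_burn and (it - n_burn) % self.config.thin == 0:
                keep.append(self.beta.copy())
                traces["phi"].append(self.phi)
                traces["lam"].append(
                    np.concatenate(self.lam).copy())
                traces["beta"].append(self.beta[trace_idx, op])
        draws = np.stack(keep)
        diag = {
            "n_kept": len(keep),
            "rhat_beta": _split_rhat(np.stack(traces["beta"])),
            "rhat_phi": _split_rhat(np.asarray(traces["phi"])[:, None]),
            "lam_mean": np.mean(np.stack(traces["lam"]), axis=0),
        }
        return draws.mean(axis=0), diag


def _split_rhat(draws: np.ndarray) -> float:
    """Max split-chain potential scale reduction over traced parameters."""
    n = draws.shape[0] // 2 * 2
    if n < 4:
        return float("nan")
    halves = draws[:n].reshape(2, n // 2, -1)
    w = halves.var(axis=1, ddof=1).mean(axis=0)
    b = (n // 2) * halves.mean(axis=1).var(axis=0, ddof=1)
    var_plus = (n // 2 - 1) / (n // 2) * w + b / (n // 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / w)
    rhat = rhat[np.isfinite(rhat)]
    return float(rhat.max()) if len(rhat) else float("nan")


def fit_posterior_effects(
    set_: HarmonizedStudySet,
    plan: ShrinkagePlan,
    config: GibbsConfig,
    ld: list | None = None,
) -> PosteriorEffects:
    """Fit the model and return posterior mean standardized effects.

    One chain is run per output population (the lambda layout differs by
    which population's effects are being estimated); column k of the result
    comes from the chain whose layout targets population k. Deterministic
    given ``config.seed``.
    """
    if ld is None:
        ld = [block_ld_set(set_, k) for k in range(set_.k)]
    beta_hat = set_.beta_hat
    b = np.zeros_like(beta_hat)
    diagnostics = {}
    for run_idx, layout in enumerate(plan.runs):
        rng = np.random.default_rng(config.seed + run_idx)
        chain = GibbsChain(beta_hat, set_.n_vector, ld, set_.block_slices,
                           layout, config, rng)
        mean, diag = chain.run()
        if layout.out_pop is None:
            b[:, :] = mean
            diagnostics["all"] = diag
        else:
            b[:, layout.out_pop] = mean[:, layout.out_pop]
            diagnostics[layout.out_pop] = diag
        if diag["rhat_beta"] > 1.2:
            logger.warning(
                "chain for output %s has split-Rhat %.2f > 1.2; consider a "
                "longer chain", layout.out_pop, diag["rhat_beta"],
            )
    return PosteriorEffects(b=b, snp_map=set_.snps, diagnostics=diagnostics)


def tune_phi(
    set_: HarmonizedStudySet,
    plan: ShrinkagePlan,
    grid: tuple[float, ...] = (1e-6, 1e-4, 1e-2, 1.0),
    validation=None,
    config: GibbsConfig | None = None,
    ld: list | None = None,
) -> float:
    """Grid-tune the global shrinkage phi against a validation score hook.

    ``validation(effects) -> float`` scores each fit (e.g. R^2 in a held-out
    cohort); the smallest phi wins ties.
    """
    if not grid:
        raise ConfigError("empty phi grid")
    if validation is None:
        raise ConfigError("tune_phi requires a validation scoring callback")
    config = config or GibbsConfig()
    best_phi, best_score = None, -np.inf
    for phi in sorted(grid):
        cfg = GibbsConfig(
            n_iter=config.n_iter, n_burnin=config.n_burnin, thin=config.thin,
            seed=config.seed, phi_mode="fixed", phi_fixed=phi,
            freeze_shrinkage=config.freeze_shrinkage,
            psi_cap=config.psi_cap,
        )
        effects = fit_posterior_effects(set_, plan, cfg, ld=ld)
        score = float(validation(effects))
        if score > best_score:
            best_phi, best_score = phi, score
    return float(best_phi)
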