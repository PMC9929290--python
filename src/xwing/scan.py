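"""Cross-population local genetic correlation scan.

The scan statistic for a contiguous SNP window R is

    Q(R) = sum_{i in R} z_1i * z_2i / (sum_{i in R} Sigma_1,ii * Sigma_2,ii)^theta

where z_k are the two populations' GWAS z-scores and Sigma_k is the
covariance of z_k under the polygenic model,

    Sigma_k = (N_k h_k^2 / M) V~_k^2 + (1 - h_k^2) V_k.

Significance of the maximal statistic Q_max = max_{|R|<=C} |Q(R)| is
calibrated by Monte-Carlo simulation of z-scores under the independent-traits
null (z_k ~ MVN(0, Sigma_k) drawn independently per population). Regions are
detected by iterative peeling: the maximizing window is recorded, its SNPs
zeroed out, and the search repeated while the add-one Monte-Carlo p-value
stays below the FDR level. Windows never cross LD-block boundaries: the
blocks are independent by construction and Sigma is block-diagonal, so Q_max
decomposes per block.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .io import BlockLD, ConfigError, HarmonizedStudySet, InputError, block_ld_set

logger = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    theta: float = 0.5
    c_max: int = 2000
    n_mc: int = 5000
    merge_bp: int = 100_000
    fdr_level: float = 0.05
    seed: int = 0
    max_regions: int = 50

    def __post_init__(self) -> None:
        if self.theta < 0 or self.c_max < 1 or not 0 < self.fdr_level <= 1:
            raise ConfigError("invalid scan configuration")


@dataclass
class ZCovModel:
    """Per-population covariance model of the z-scores, block-diagonal."""

    h2: np.ndarray                      # K
    m_total: int
    block_sigmas: list                  # per population: list of Sigma_k blocks
    block_slices: list
    eig_floor: float = 1e-6
    _chols: list | None = field(default=None, repr=False)

    @property
    def sigma_diag(self) -> np.ndarray:
        """M x K matrix of Sigma_k diagonal entries."""
        cols = []
        for sigmas in self.block_sigmas:
            cols.append(np.concatenate([np.diag(s) for s in sigmas]))
        return np.column_stack(cols)

    def cholesky_factors(self) -> list:
        """Per population, per block lower Cholesky factors for MC sampling."""
        if self._chols is None:
            out = []
            for sigmas in self.block_sigmas:
                try:
                    out.append([linalg.cholesky(s, lower=True) for s in sigmas])
                except linalg.LinAlgError as err:
                    raise FloatingPointError(
                        "Sigma block not factorizable; increase eig_floor"
                    ) from err
            self._chols = out
        return self._chols


@dataclass
class Region:
    chrom: str
    start_bp: int
    end_bp: int
    start: int            # index into the harmonized SNP map, inclusive
    stop: int             # exclusive
    q: float
    p_value: float
    sign: int
    rank: int
    significant: bool = True

    @property
    def snp_indices(self) -> np.ndarray:
        return np.arange(self.start, self.stop)

    @property
    def n_snps(self) -> int:
        return self.stop - self.start


@dataclass
class NullDistribution:
    qmax_draws: np.ndarray
    seed: int
    theta: float
    c_max: int


def _psd_floor(mat: np.ndarray, floor: float) -> np.ndarray:
    """Clip eigenvalues from below so the matrix admits a Cholesky factor."""
    w, u = np.linalg.eigh((mat + mat.T) / 2)
    if w.min() >= floor:
        return (mat + mat.T) / 2
    return (u * np.maximum(w, floor)) @ u.T


def estimate_h2_moments(stats, ld: list[BlockLD], n: int | None = None) -> float:
    """Method-of-moments (LD-score slope) heritability from z-scores.

    Under the polygenic model E[z_j^2] - 1 = h2 * ((N/M) l_j - 1) with l_j
    the bias-corrected LD score of SNP j from the reference panel, so a
    through-origin regression of z^2 - 1 on (N/M) l - 1 identifies h2 from
    the mean level of the LD scores (robust to reference noise in their
    spread). The estimate is clipped to [0, 1]. ``stats`` is a SumStats or a
    plain z vector (then ``n`` is required); ``ld`` must cover its SNPs in
    order.
    """
    if hasattr(stats, "df"):
        z = stats.df["z"].to_numpy(float)
        n = int(np.median(stats.df["n"])) if n is None else n
    else:
        z = np.asarray(stats, dtype=float)
        if n is None:
            raise ConfigError("n required when stats is a plain z vector")
    ell = []
    for blk in ld:
        r2 = blk.v ** 2
        # bias-corrected r^2: E[r_hat^2] ~= r^2 + (1 - r^2)/(n_ref - 2)
        r2c = r2 - (1.0 - r2) / (blk.n_ref - 2)
        ell.append(r2c.sum(axis=1))
    ell = np.concatenate(ell)
    if len(z) != len(ell):
        raise InputError("LD blocks do not cover the z vector")
    if len(z) < 200:
        logger.warning("h2 estimate from only %d SNPs; expect noise", len(z))
    m = len(z)
    x = (n / m) * ell - 1.0
    denom = float(np.sum(x * x))
    if denom <= 1e-12 * m:
        raise InputError(
            "degenerate LD-score regression: predictor (N/M) l - 1 vanishes")
    h2 = float(np.sum(x * (z ** 2 - 1.0)) / denom)
    if h2 > 1 or h2 < 0:
        logger.warning("h2 estimate %.3f outside [0, 1]; clipped", h2)
    return float(np.clip(h2, 0.0, 1.0))


def build_z_covariance(
    set_: HarmonizedStudySet,
    h2: np.ndarray,
    ld: list[list[BlockLD]] | None = None,
    m_total: int | None = None,
    eig_floor: float = 1e-6,
    regularization: float = 1e-6,
) -> ZCovModel:
    """Assemble per-block Sigma_k = (N h2/M) V~2 + (1 - h2) V for each population."""
    h2 = np.asarray(h2, dtype=float)
    if np.any(h2 < 0) or np.any(h2 > 1):
        raise InputError("h2 must lie in [0, 1] for every population")
    if ld is None:
        ld = [block_ld_set(set_, k, regularization) for k in range(set_.k)]
    m_total = set_.m if m_total is None else m_total
    block_sigmas = []
    for k in range(set_.k):
        n_k = float(set_.n_vector[k])
        sigmas = []
        for blk in ld[k]:
            sigma = (n_k * h2[k] / m_total) * blk.v2_unbiased + (1 - h2[k]) * blk.v
            sigmas.append(_psd_floor(sigma, eig_floor))
        block_sigmas.append(sigmas)
    return ZCovModel(h2=h2, m_total=m_total, block_sigmas=block_sigmas,
                     block_slices=set_.block_slices, eig_floor=eig_floor)


def scan_statistic(
    z1: np.ndarray, z2: np.ndarray,
    sigma1_diag: np.ndarray, sigma2_diag: np.ndarray,
    r: np.ndarray | slice, theta: float,
) -> float:
    """Q(R) for one window."""
    num = float(np.sum(np.asarray(z1)[r] * np.asarray(z2)[r]))
    if theta == 0:
        return num
    den = float(np.sum(np.asarray(sigma1_diag)[r] * np.asarray(sigma2_diag)[r]))
    if den <= 0:
        raise FloatingPointError("non-positive scan denominator with theta > 0")
    return num / den ** theta


def _block_max(prod, den, theta, c_max):
    """Signed max-|Q| window within one block.

    Returns (q, start, stop) with ties broken leftmost, then shortest.
    Widths are scanned in ascending order, so for equal |Q| and start the
    shorter window wins automatically.
    """
    n = len(prod)
    pnum = np.concatenate([[0.0], np.cumsum(prod)])
    pden = np.concatenate([[0.0], np.cumsum(den)])
    best = (0.0, 0, 0)  # |q| signed later
    best_abs = -1.0
    for w in range(1, min(c_max, n) + 1):
        nums = pnum[w:] - pnum[:-w]
        if theta == 0:
            q = nums
        else:
            q = nums / (pden[w:] - pden[:-w]) ** theta
        aq = np.abs(q)
        i = int(np.argmax(aq))
        if aq[i] > best_abs or (aq[i] == best_abs and i < best[1]):
            best_abs = float(aq[i])
            best = (float(q[i]), i, i + w)
    return best


def max_scan_statistic(
    z1: np.ndarray, z2: np.ndarray,
    sigma1_diag: np.ndarray, sigma2_diag: np.ndarray,
    c_max: int, theta: float,
    block_slices: list[slice] | None = None,
) -> tuple[float, tuple[int, int]]:
    """Maximize |Q(R)| over contiguous windows of size <= c_max within blocks.

    Returns the signed Q at the maximizing window and its [start, stop)
    index range. With no block structure the whole vector is one block.
    """
    z1 = np.asarray(z1, float)
    z2 = np.asarray(z2, float)
    if block_slices is None:
        block_slices = [slice(0, len(z1))]
    prod = z1 * z2
    den = np.asarray(sigma1_diag, float) * np.asarray(sigma2_diag, float)
    best_q, best_w = 0.0, (0, 0)
    best_abs = -1.0
    for sl in block_slices:
        q, i, j = _block_max(prod[sl], den[sl], theta, c_max)
        if abs(q) > best_abs:
            best_abs = abs(q)
            best_q, best_w = q, (i + sl.start, j + sl.start)
    return best_q, best_w


def _batch_qmax(prod, den, theta, c_max, block_slices):
    """Per-draw max |Q| for a batch: prod is M x B."""
    n_draws = prod.shape[1]
    out = np.zeros(n_draws)
    for sl in block_slices:
        p = prod[sl]
        d = den[sl]
        n = p.shape[0]
        pnum = np.vstack([np.zeros(n_draws), np.cumsum(p, axis=0)])
        pden = np.concatenate([[0.0], np.cumsum(d)])
        for w in range(1, min(c_max, n) + 1):
            nums = pnum[w:] - pnum[:-w]
            if theta == 0:
                aq = np.abs(nums)
            else:
                aq = np.abs(nums) / ((pden[w:] - pden[:-w]) ** theta)[:, None]
            np.maximum(out, aq.max(axis=0), out=out)
    return out


def simulate_null_qmax(
    model: ZCovModel, config: ScanConfig, pops: tuple[int, int] = (0, 1),
) -> NullDistribution:
    """Monte-Carlo null of Q_max: z_k ~ MVN(0, Sigma_k), independent per
    population (no cross-population correlation under the null)."""
    rng = np.random.default_rng(config.seed)
    chols = model.cholesky_factors()
    sdiag = model.sigma_diag
    den = sdiag[:, pops[0]] * sdiag[:, pops[1]]
    m = sum(sl.stop - sl.start for sl in model.block_slices)
    batch = max(1, min(config.n_mc, int(2e6 / max(m, 1))))
    draws = []
    done = 0
    while done < config.n_mc:
        b = min(batch, config.n_mc - done)
        prod = np.ones((m, b))
        for k in pops:
            zk = np.empty((m, b))
            for sl, chol in zip(model.block_slices, chols[k]):
                eta = rng.standard_normal((sl.stop - sl.start, b))
                zk[sl] = chol @ eta
            prod *= zk
        draws.append(_batch_qmax(prod, den, config.theta, config.c_max,
                                 model.block_slices))
        done += b
    return NullDistribution(
        qmax_draws=np.concatenate(draws), seed=config.seed,
        theta=config.theta, c_max=config.c_max,
    )


def detect_regions(
    set_: HarmonizedStudySet,
    model: ZCovModel,
    null: NullDistribution,
    config: ScanConfig,
    pops: tuple[int, int] = (0, 1),
    p_stop: float | None = None,
) -> list[Region]:
    """Iterative peeling with sequential FDR control.

    Each round finds the current |Q|-maximizing window, computes the add-one
    Monte-Carlo p-value p = (1 + #{null >= |Q|}) / (1 + n_mc), and admits the
    region while p <= fdr_level (with monotone non-decreasing peeling
    p-values, Benjamini-Hochberg on the admitted prefix rejects all of it, so
    this coincides with BH stopped at the first failure). Admitted SNPs are
    zeroed out before the next round.

    ``p_stop`` (> fdr_level) continues the peel past the significance cut so
    the ranked region list can feed the top-s annotation; regions beyond the
    cut carry ``significant=False``.
    """
    if null.theta != config.theta or null.c_max != config.c_max:
        raise ConfigError("null distribution parameters do not match the scan")
    z1 = set_.z_matrix[:, pops[0]].copy()
    z2 = set_.z_matrix[:, pops[1]].copy()
    sdiag = model.sigma_diag
    s1, s2 = sdiag[:, pops[0]], sdiag[:, pops[1]]
    slices = set_.block_slices
    n_mc = len(null.qmax_draws)
    stop = config.fdr_level if p_stop is None else max(p_stop, config.fdr_level)
    regions: list[Region] = []
    last_p = 0.0
    for rank in range(1, config.max_regions + 1):
        q, (i, j) = max_scan_statistic(z1, z2, s1, s2, config.c_max,
                                       config.theta, slices)
        if q == 0.0:
            break
        p = (1 + int(np.sum(null.qmax_draws >= abs(q)))) / (1 + n_mc)
        p = max(p, last_p)  # peeling p-values are monotone by construction
        if p > stop:
            break
        last_p = p
        snps = set_.snps.iloc[i:j]
        regions.append(Region(
            chrom=str(snps["chrom"].iloc[0]),
            start_bp=int(snps["pos"].iloc[0]),
            end_bp=int(snps["pos"].iloc[-1]) + 1,
            start=i, stop=j, q=float(q), p_value=float(p),
            sign=1 if q > 0 else -1, rank=rank,
            significant=p <= config.fdr_level,
        ))
        z1[i:j] = 0.0
        z2[i:j] = 0.0
    return regions


def merge_regions(
    regions: list[Region],
    merge_bp: int,
    set_: HarmonizedStudySet | None = None,
    model: ZCovModel | None = None,
    theta: float = 0.5,
    pops: tuple[int, int] = (0, 1),
) -> list[Region]:
    """Merge same-sign regions separated by less than ``merge_bp``.

    The merged Q is recomputed over the union when the study set and model
    are supplied; the merged p-value is the minimum of the members (the
    members' significance was established before merging).
    """
    if not regions:
        return []
    regs = sorted(regions, key=lambda r: (r.chrom, r.start_bp))
    merged = [regs[0]]
    for r in regs[1:]:
        prev = merged[-1]
        gap = r.start_bp - prev.end_bp
        if r.chrom == prev.chrom and r.sign == prev.sign and gap < merge_bp:
            start, stop = min(prev.start, r.start), max(prev.stop, r.stop)
            if set_ is not None and model is not None:
                sdiag = model.sigma_diag
                q = scan_statistic(
                    set_.z_matrix[:, pops[0]], set_.z_matrix[:, pops[1]],
                    sdiag[:, pops[0]], sdiag[:, pops[1]],
                    slice(start, stop), theta,
                )
            else:
                q = prev.q + r.q
            merged[-1] = Region(
                chrom=prev.chrom, start_bp=prev.start_bp,
                end_bp=max(prev.end_bp, r.end_bp),
                start=start, stop=stop, q=float(q),
                p_value=min(prev.p_value, r.p_value),
                sign=prev.sign, rank=min(prev.rank, r.rank),
                significant=prev.significant or r.significant,
            )
        else:
            merged.append(r)
    return merged


def select_theta(
    model: ZCovModel,
    grid: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0),
    n_draws: int = 200,
    seed: int = 0,
    pops: tuple[int, int] = (0, 1),
) -> float:
    """Pick theta so the null Q variance depends least on window size.

    The denominator of Q exists to equalize scale across region sizes; this
    routine simulates a small z-score null, computes Var(Q) for a ladder of
    window widths, and returns the grid value minimizing the magnitude of the
    log-variance vs log-width slope.
    """
    rng = np.random.default_rng(seed)
    chols = model.cholesky_factors()
    sdiag = model.sigma_diag
    den = sdiag[:, pops[0]] * sdiag[:, pops[1]]
    m = sum(sl.stop - sl.start for sl in model.block_slices)
    prod = np.ones((m, n_draws))
    for k in pops:
        zk = np.empty((m, n_draws))
        for sl, chol in zip(model.block_slices, chols[k]):
            zk[sl] = chol @ rng.standard_normal((sl.stop - sl.start, n_draws))
        prod *= zk
    min_len = min(sl.stop - sl.start for sl in model.block_slices)
    widths = sorted({1, max(2, min_len // 8), max(3, min_len // 2), min_len})
    best_theta, best_score = grid[0], np.inf
    for theta in grid:
        log_vars = []
        for w in widths:
            qs = []
            for sl in model.block_slices:
                p = prod[sl]
                if sl.stop - sl.start < w:
                    continue
                pnum = np.vstack([np.zeros(n_draws), np.cumsum(p, axis=0)])
                pden = np.concatenate([[0.0], np.cumsum(den[sl])])
                nums = pnum[w:] - pnum[:-w]
                if theta > 0:
                    nums = nums / ((pden[w:] - pden[:-w]) ** theta)[:, None]
                qs.append(nums.ravel())
            log_vars.append(np.log(np.var(np.concatenate(qs))))
        slope = np.polyfit(np.log(widths), log_vars, 1)[0]
        if abs(slope) < best_score:
            best_score, best_theta = abs(slope), theta
    return float(best_theta)


def build_annotation(per_pair_regions: dict, s: int, snp_map) -> "AnnotationMap":
    """Top-s positively-correlated regions per non-target population -> Omega_k.

    Regions are ranked by p-value then |Q| descending; negative-correlation
    regions are excluded; if fewer than s positive regions exist, all are
    used. Returns an AnnotationMap whose category 1 marks the Omega_k SNPs.
    """
    from .gibbs import AnnotationMap

    omega = {}
    for k, regions in per_pair_regions.items():
        pos = [r for r in regions if r.sign > 0]
        pos.sort(key=lambda r: (r.p_value, -abs(r.q)))
        idx = set()
        for r in pos[:s]:
            idx.update(range(r.start, r.stop))
        omega[k] = np.array(sorted(idx), dtype=int)
    return AnnotationMap(m=len(snp_map), omega_sets=omega, s=s)


def regions_to_frame(regions: list[Region]):
    import pandas as pd

    return pd.DataFrame([
        {"chrom": r.chrom, "start": r.start_bp, "end": r.end_bp,
         "n_snps": r.n_snps, "q": r.q, "sign": "+" if r.sign > 0 else "-",
         "p": r.p_value, "rank": r.rank, "significant": r.significant}
        for r in regions
    ])
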