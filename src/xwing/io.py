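"""Reading, validation and cross-population harmonization of GWAS inputs.

This module turns the three raw inputs of the workflow — per-population GWAS
summary statistics, genotype reference panels, and LD block definitions —
into a single :class:`HarmonizedStudySet` in which every population's z-scores
refer to the same SNPs, the same effect alleles, and the same block partition.
It also computes per-block LD matrices together with the unbiased estimator of
the squared LD matrix,

    V~2 = (N_ref - 1)/(N_ref - 2) * V @ V  -  M/(N_ref - 2) * V,

which corrects for reference-panel sampling noise and enters the z-score
covariance model of the correlation scan.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _plink

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default header names accepted by :func:`read_sumstats`
DEFAULT_COLUMNS = {
    "snp_id": "SNP", "chrom": "CHR", "pos": "BP",
    "a1": "A1", "a2": "A2", "z": "Z", "beta": "BETA", "se": "SE",
    "n": "N", "maf": "MAF",
}


class InputError(ValueError):
    """Malformed or inconsistent input data."""


class ConfigError(ValueError):
    """Unresolvable configuration (missing columns, mismatched parameters)."""


@dataclass
class SumStats:
    """GWAS summary statistics for one population.

    ``df`` has columns snp_id, chrom, pos, a1 (effect allele), a2, z, n and
    optionally maf. z is the association z-score X'Y/sqrt(N) on standardized
    genotype/phenotype scales.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        req = ["snp_id", "chrom", "pos", "a1", "a2", "z", "n"]
        missing = [c for c in req if c not in self.df.columns]
        if missing:
            raise ConfigError(f"summary statistics missing columns: {missing}")
        dup = self.df["snp_id"].duplicated()
        if dup.any():
            raise InputError(
                f"duplicate snp_id in summary statistics: "
                f"{self.df.loc[dup, 'snp_id'].iloc[0]}"
            )
        if not np.all(np.isfinite(self.df["z"].to_numpy(float))):
            raise InputError("non-finite z-scores after filtering")
        if (self.df["n"] < 2).any():
            bad = self.df.loc[self.df["n"] < 2, "snp_id"].iloc[0]
            raise InputError(f"sample size n < 2 for SNP {bad}")
        if (self.df["a1"] == self.df["a2"]).any():
            raise InputError("a1 == a2 for some SNP")

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class LDPanel:
    """Genotype reference panel with a standardized-dosage accessor.

    ``dosages`` holds raw A1-allele counts (NaN = missing); monomorphic SNPs
    are removed at construction unless ``drop_monomorphic=False`` (needed when
    splitting a panel, where all parts must keep the same SNP map).
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    drop_monomorphic: bool = True
    _std: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise InputError("dosage matrix must be 2-D (samples x SNPs)")
        if self.dosages.shape[1] != len(self.snp_map):
            raise InputError("snp_map length does not match dosage columns")
        if self.n_ref < 3:
            raise InputError("reference panel needs n_ref >= 3")
        self.snp_map = self.snp_map.reset_index(drop=True)
        if self.drop_monomorphic:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                sd = np.nanstd(self.dosages, axis=0)
            mono = ~(sd > 0)
            if mono.any():
                logger.warning(
                    "removed %d monomorphic/all-missing SNPs from panel",
                    int(mono.sum()),
                )
                self.dosages = self.dosages[:, ~mono]
                self.snp_map = self.snp_map.loc[~mono].reset_index(drop=True)

    @property
    def n_ref(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    @property
    def standardized(self) -> np.ndarray:
        """Mean-imputed, column-standardized genotypes (mean 0, unit variance,
        ddof=1; constant columns map to zeros)."""
        if self._std is None:
            x = self.dosages.copy()
            mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
            nan_mask = np.isnan(x)
            if nan_mask.any():
                x[nan_mask] = np.take(mean, np.nonzero(nan_mask)[1])
            x -= x.mean(axis=0)
            sd = x.std(axis=0, ddof=1)
            safe = np.where(sd > 0, sd, 1.0)
            x /= safe
            x[:, sd == 0] = 0.0
            self._std = x
        return self._std

    @property
    def freqs(self) -> np.ndarray:
        """A1 allele frequencies (mean dosage / 2, missing ignored)."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def subset_snps(self, index: np.ndarray) -> "LDPanel":
        return LDPanel(
            self.dosages[:, index],
            self.snp_map.iloc[index].reset_index(drop=True),
            drop_monomorphic=False,
        )


@dataclass
class BlockSpec:
    """Half-open genomic intervals [start, end) partitioning the analysis SNPs."""

    intervals: pd.DataFrame  # columns chrom, start, end
    provenance: str = ""

    def __post_init__(self) -> None:
        iv = self.intervals.reset_index(drop=True)
        iv["chrom"] = iv["chrom"].astype(str)
        for chrom, grp in iv.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            order = np.argsort(starts, kind="stable")
            if np.any(ends[order][:-1] > starts[order][1:]):
                raise InputError(f"overlapping LD blocks on chromosome {chrom}")
        self.intervals = iv.sort_values(["chrom", "start"]).reset_index(drop=True)

    def assign(self, chrom: pd.Series, pos: pd.Series) -> np.ndarray:
        """Block index for each SNP; raises if any SNP is uncovered."""
        out = np.full(len(chrom), -1, dtype=int)
        chrom = chrom.astype(str).to_numpy()
        pos = pos.to_numpy()
        for bi, row in self.intervals.iterrows():
            hit = (chrom == row["chrom"]) & (pos >= row["start"]) & (pos < row["end"])
            out[hit] = bi
        if (out < 0).any():
            i = int(np.nonzero(out < 0)[0][0])
            raise InputError(
                f"SNP at {chrom[i]}:{pos[i]} not covered by any LD block"
            )
        return out

    @classmethod
    def from_bed(cls, path: str) -> "BlockSpec":
        iv = pd.read_csv(
            path, sep=r"\s+", header=None, comment="#",
            names=["chrom", "start", "end"], usecols=[0, 1, 2],
        )
        return cls(iv, provenance=str(path))

    def to_bed(self, path: str) -> None:
        self.intervals.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class HarmonizedStudySet:
    """K populations' z-scores aligned to one SNP map and block partition."""

    snps: pd.DataFrame            # snp_id, chrom, pos, a1, a2
    z_matrix: np.ndarray          # M x K
    n_vector: np.ndarray          # K
    panels: list                  # K LDPanel, SNPs aligned to `snps`
    blocks: BlockSpec
    block_index: np.ndarray       # M, index into blocks.intervals

    def __post_init__(self) -> None:
        self.z_matrix = np.atleast_2d(np.asarray(self.z_matrix, dtype=float))
        self.n_vector = np.asarray(self.n_vector)
        m, k = self.z_matrix.shape
        if m < 1 or k < 2:
            raise InputError("need M >= 1 SNPs and K >= 2 populations")
        if len(self.panels) != k or len(self.n_vector) != k:
            raise InputError("panels/n_vector length must equal K")

    @property
    def m(self) -> int:
        return self.z_matrix.shape[0]

    @property
    def k(self) -> int:
        return self.z_matrix.shape[1]

    @property
    def block_slices(self) -> list[slice]:
        """Contiguous index range of each non-empty block, in order."""
        out = []
        for bi in np.unique(self.block_index):
            idx = np.nonzero(self.block_index == bi)[0]
            if np.any(np.diff(idx) != 1):
                raise InputError(f"block {bi} SNPs are not contiguous")
            out.append(slice(int(idx[0]), int(idx[-1]) + 1))
        return out

    @property
    def beta_hat(self) -> np.ndarray:
        """Marginal standardized effects z / sqrt(N), M x K."""
        return self.z_matrix / np.sqrt(self.n_vector.astype(float))


@dataclass
class BlockLD:
    """Per-block LD matrix V and the unbiased squared-LD estimator V~2."""

    block_index: int
    v: np.ndarray
    v2_unbiased: np.ndarray
    n_ref: int
    ridge: float = 0.0

    @property
    def v_solve(self) -> np.ndarray:
        """V with the ridge term on the diagonal (for factorizations)."""
        return self.v + self.ridge * np.eye(self.v.shape[0])


def read_sumstats(path: str, column_map: dict | None = None) -> SumStats:
    """Read whitespace-delimited summary statistics (gzip transparent).

    ``column_map`` overrides the default header names (keys as in
    :data:`DEFAULT_COLUMNS`). z is taken from the z column when present,
    otherwise derived as beta/se. Rows with missing or non-finite z are
    dropped with a logged count.
    """
    names = dict(DEFAULT_COLUMNS)
    if column_map:
        names.update(column_map)
    raw = pd.read_csv(path, sep=r"\s+")
    df = pd.DataFrame()
    for key in ("snp_id", "chrom", "pos", "a1", "a2", "n"):
        col = names[key]
        if col not in raw.columns:
            raise ConfigError(f"required column '{col}' ({key}) not in {path}")
        df[key] = raw[col]
    if names["z"] in raw.columns:
        df["z"] = pd.to_numeric(raw[names["z"]], errors="coerce")
    elif names["beta"] in raw.columns and names["se"] in raw.columns:
        beta = pd.to_numeric(raw[names["beta"]], errors="coerce")
        se = pd.to_numeric(raw[names["se"]], errors="coerce")
        df["z"] = beta / se
    else:
        raise ConfigError(
            f"neither '{names['z']}' nor '{names['beta']}'+'{names['se']}' in {path}"
        )
    if names["maf"] in raw.columns:
        df["maf"] = pd.to_numeric(raw[names["maf"]], errors="coerce")
    bad = ~np.isfinite(df["z"].to_numpy(float))
    if bad.any():
        logger.warning("dropped %d rows with missing/non-finite z from %s",
                       int(bad.sum()), path)
        df = df.loc[~bad]
    df["chrom"] = df["chrom"].astype(str)
    df["a1"] = df["a1"].astype(str).str.upper()
    df["a2"] = df["a2"].astype(str).str.upper()
    return SumStats(df.reset_index(drop=True))


def write_sumstats(stats: SumStats, path: str) -> None:
    """Write summary statistics in the format :func:`read_sumstats` reads."""
    out = stats.df.rename(columns={
        "snp_id": "SNP", "chrom": "CHR", "pos": "BP", "a1": "A1",
        "a2": "A2", "z": "Z", "n": "N", "maf": "MAF",
    })
    out.to_csv(path, sep="\t", index=False)


def read_genotype_panel(bed_prefix: str) -> LDPanel:
    """Read a PLINK BED/BIM/FAM triplet into a standardized-dosage panel."""
    dosages, bim, _fam = _plink.read_bed(bed_prefix)
    snp_map = bim.rename(columns={"chrom": "chrom"})[
        ["snp_id", "chrom", "pos", "a1", "a2"]
    ].copy()
    snp_map["a1"] = snp_map["a1"].str.upper()
    snp_map["a2"] = snp_map["a2"].str.upper()
    return LDPanel(dosages, snp_map)


def write_genotype_panel(panel: LDPanel, bed_prefix: str) -> None:
    bim = panel.snp_map.copy()
    bim["cm"] = 0
    _plink.write_bed(bed_prefix, panel.dosages, bim)


def is_strand_ambiguous(a1: pd.Series, a2: pd.Series) -> pd.Series:
    """A/T and C/G variants cannot be strand-resolved from allele labels."""
    pair = a1.str.upper() + a2.str.upper()
    return pair.isin(["AT", "TA", "CG", "GC"])


def _complement(alleles: pd.Series) -> pd.Series:
    return alleles.map(lambda a: "".join(_COMPLEMENT.get(c, "N") for c in a))


def _orient(df: pd.DataFrame, ref: pd.DataFrame) -> np.ndarray:
    """Return +1 (same orientation), -1 (swapped) or 0 (unmatched) per SNP.

    Two passes: exact allele match, then strand-complement match.
    """
    sign = np.zeros(len(df), dtype=int)
    for a1, a2 in ((df["a1"], df["a2"]),
                   (_complement(df["a1"]), _complement(df["a2"]))):
        same = (a1.to_numpy() == ref["a1"].to_numpy()) & \
               (a2.to_numpy() == ref["a2"].to_numpy())
        swap = (a1.to_numpy() == ref["a2"].to_numpy()) & \
               (a2.to_numpy() == ref["a1"].to_numpy())
        sign = np.where((sign == 0) & same, 1, sign)
        sign = np.where((sign == 0) & swap, -1, sign)
    return sign


def harmonize_studies(
    stats: list[SumStats],
    panels: list[LDPanel],
    blocks: BlockSpec,
) -> HarmonizedStudySet:
    """Align K studies and their reference panels to one SNP map.

    The SNP set is the intersection across all studies and panels;
    strand-ambiguous variants are removed; alleles are matched exactly or
    after strand complementing, flipping z (study) or dosage (panel) where
    effect/other alleles are swapped; SNPs whose alleles cannot be matched
    are dropped and counted. The first panel's allele coding is the
    reference orientation.
    """
    if len(stats) < 2 or len(stats) != len(panels):
        raise InputError("need K >= 2 studies, each paired with a panel")
    common = None
    for s in stats:
        ids = set(s.df["snp_id"])
        common = ids if common is None else common & ids
    for p in panels:
        common &= set(p.snp_map["snp_id"])
    if not common:
        raise InputError("empty SNP intersection across studies and panels")

    ref = panels[0].snp_map
    ref = ref[ref["snp_id"].isin(common)].copy()
    ambiguous = is_strand_ambiguous(ref["a1"], ref["a2"])
    if ambiguous.any():
        logger.info("removed %d strand-ambiguous SNPs", int(ambiguous.sum()))
    ref = ref.loc[~ambiguous]
    ref = ref.sort_values(["chrom", "pos"]).reset_index(drop=True)

    z_cols, n_vals, keep = [], [], np.ones(len(ref), dtype=bool)
    aligned_stats = []
    for s in stats:
        sub = s.df.set_index("snp_id").loc[ref["snp_id"]].reset_index()
        sign = _orient(sub, ref)
        keep &= sign != 0
        aligned_stats.append((sub, sign))
        n_vals.append(int(np.median(sub["n"])))
    aligned_panels = []
    for p in panels:
        order = pd.Index(p.snp_map["snp_id"]).get_indexer(ref["snp_id"])
        sub_panel = p.subset_snps(order)
        sign = _orient(sub_panel.snp_map, ref)
        keep &= sign != 0
        aligned_panels.append((sub_panel, sign))

    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d SNPs with unmatched alleles", dropped)
    ref = ref.loc[keep].reset_index(drop=True)
    if len(ref) == 0:
        raise InputError("no SNPs left after allele matching")
    for sub, sign in aligned_stats:
        z_cols.append((sub["z"].to_numpy(float) * sign)[keep.to_numpy()
                      if isinstance(keep, pd.Series) else keep])
    out_panels = []
    for sub_panel, sign in aligned_panels:
        panel = sub_panel.subset_snps(np.nonzero(keep)[0])
        flip = sign[keep] == -1
        if flip.any():
            panel.dosages[:, flip] = 2.0 - panel.dosages[:, flip]
            panel.snp_map.loc[flip, ["a1", "a2"]] = \
                panel.snp_map.loc[flip, ["a2", "a1"]].to_numpy()
        panel._std = None
        out_panels.append(panel)

    block_index = blocks.assign(ref["chrom"], ref["pos"])
    return HarmonizedStudySet(
        snps=ref[["snp_id", "chrom", "pos", "a1", "a2"]],
        z_matrix=np.column_stack(z_cols),
        n_vector=np.array(n_vals),
        panels=out_panels,
        blocks=blocks,
        block_index=block_index,
    )


def compute_block_ld(
    panel: LDPanel,
    snp_index: np.ndarray | slice,
    regularization: float = 1e-6,
    block_index: int = 0,
    m_for_v2: int | None = None,
) -> BlockLD:
    """LD correlation matrix and unbiased squared-LD estimator for one block.

    ``m_for_v2`` is the M in the V~2 correction term; defaults to the number
    of SNPs in the block.
    """
    if panel.n_ref <= 2:
        raise InputError("V~2 estimator undefined for n_ref <= 2")
    x = panel.standardized[:, snp_index]
    n = panel.n_ref
    v = x.T @ x / (n - 1)
    np.fill_diagonal(v, 1.0)
    m = v.shape[0] if m_for_v2 is None else int(m_for_v2)
    v2 = (n - 1) / (n - 2) * (v @ v) - m / (n - 2) * v
    return BlockLD(block_index=block_index, v=v, v2_unbiased=v2,
                   n_ref=n, ridge=float(regularization))


def block_ld_set(
    set_: HarmonizedStudySet,
    population: int,
    regularization: float = 1e-6,
    m_for_v2: str = "block",
) -> list[BlockLD]:
    """Block LD matrices for one population, following the study block layout.

    ``m_for_v2``: "block" uses the per-block SNP count in the V~2 correction
    term, "genome" uses the total analysis SNP count.
    """
    if m_for_v2 not in ("block", "genome"):
        raise ConfigError("m_for_v2 must be 'block' or 'genome'")
    panel = set_.panels[population]
    out = []
    for bi, sl in enumerate(set_.block_slices):
        m = None if m_for_v2 == "block" else set_.m
        out.append(compute_block_ld(panel, sl, regularization, bi, m))
    return out


def split_panel(panel: LDPanel, n_parts: int, seed: int) -> list[LDPanel]:
    """Partition panel samples into near-equal disjoint subpanels.

    All parts keep the full SNP map (columns monomorphic within a part are
    standardized to zeros). Deterministic given the seed.
    """
    if n_parts < 2:
        raise InputError("n_parts must be >= 2")
    if panel.n_ref < 3 * n_parts:
        raise InputError(
            f"panel has {panel.n_ref} samples; need >= {3 * n_parts} "
            f"for {n_parts} parts"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(panel.n_ref)
    return [
        LDPanel(panel.dosages[np.sort(part)], panel.snp_map.copy(),
                drop_monomorphic=False)
        for part in np.array_split(perm, n_parts)
    ]
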