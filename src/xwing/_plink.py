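"""Minimal PLINK 1 BED/BIM/FAM reader and writer.

SNP-major BED only (magic ``6c 1b 01``). Genotypes are returned as A1-allele
dosages in {0, 1, 2} with NaN for missing. This covers what the package needs
from reference panels; it is not a general PLINK toolkit.
"""
from __future__ import annotations

import os

import numpy as np
import pandas as pd

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit codes, SNP-major: 00 hom A1, 01 missing, 10 het, 11 hom A2
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])

BIM_COLUMNS = ["chrom", "snp_id", "cm", "pos", "a1", "a2"]
FAM_COLUMNS = ["fid", "iid", "father", "mother", "sex", "pheno"]


def read_bed(prefix: str) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Read a BED/BIM/FAM triplet.

    Returns ``(dosages, bim, fam)`` where ``dosages`` is an ``n_samples x
    n_snps`` float array of A1 dosages (NaN = missing).
    """
    bim = pd.read_csv(
        prefix + ".bim", sep=r"\s+", header=None, names=BIM_COLUMNS,
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None, names=FAM_COLUMNS)
    n, m = len(fam), len(bim)
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _MAGIC:
            raise ValueError(
                f"{prefix}.bed: bad magic bytes {magic!r}; "
                "expected SNP-major PLINK 1 BED"
            )
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    bytes_per_snp = (n + 3) // 4
    if raw.size != bytes_per_snp * m:
        raise ValueError(
            f"{prefix}.bed: size {raw.size} does not match "
            f"{m} SNPs x {bytes_per_snp} bytes"
        )
    raw = raw.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (raw >> (2 * shift)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T
    return np.ascontiguousarray(dosages), bim, fam


def write_bed(
    prefix: str,
    dosages: np.ndarray,
    bim: pd.DataFrame,
    fam: pd.DataFrame | None = None,
) -> None:
    """Write A1 dosages (n_samples x n_snps, NaN = missing) as BED/BIM/FAM."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if len(bim) != m:
        raise ValueError(f"bim has {len(bim)} rows for {m} SNPs")
    if fam is None:
        fam = pd.DataFrame(
            {
                "fid": [f"F{i}" for i in range(n)],
                "iid": [f"I{i}" for i in range(n)],
                "father": 0, "mother": 0, "sex": 0, "pheno": -9,
            }
        )
    codes = np.full((m, n), 1, dtype=np.uint8)  # default missing
    dt = dosages.T
    codes[dt == 2.0] = 0
    codes[dt == 1.0] = 2
    codes[dt == 0.0] = 3
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes
    out = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for shift in range(4):
        out |= padded[:, shift::4] << (2 * shift)
    os.makedirs(os.path.dirname(os.path.abspath(prefix)), exist_ok=True)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_MAGIC)
        fh.write(out.tobytes())
    bim[BIM_COLUMNS].to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    fam[FAM_COLUMNS].to_csv(prefix + ".fam", sep="\t", header=False, index=False)
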