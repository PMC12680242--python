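"""Minimal PLINK 1 binary (bed/bim/fam) reader and writer.

Allele coding: dosage is the count of the A1 (minor) allele. In the
SNP-major .bed two-bit encoding this maps as 0b00 -> 2, 0b10 -> 1,
0b11 -> 0; 0b01 (missing) is rejected on read since the toolkit never
produces missing genotypes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix

__all__ = ["write_plink", "read_plink"]

_MAGIC = bytes([0x6C, 0x1B, 0x01])  # PLINK 1 bed magic + SNP-major flag

# dosage -> 2-bit code (count of A1 allele)
_ENCODE = np.array([0b11, 0b10, 0b00], dtype=np.uint8)
_DECODE = {0b00: 2, 0b10: 1, 0b11: 0}


def write_plink(G: GenotypeMatrix, prefix: str | Path) -> None:
    """Write bed/bim/fam files for a genotype matrix (no missing values)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = G.n_samples, G.n_snps
    codes = _ENCODE[G.dosages.astype(np.int64)]  # n x m, 2-bit codes
    n_bytes = (n + 3) // 4
    packed = np.zeros((m, n_bytes), dtype=np.uint8)
    for shift_idx in range(4):
        rows = codes[shift_idx::4]  # samples congruent to shift_idx mod 4
        packed[:, : rows.shape[0]] |= rows.T << (2 * shift_idx)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.tobytes())
    bim = pd.DataFrame(
        {
            "chrom": 1,
            "snp": G.snp_ids,
            "cm": 0,
            "pos": np.arange(1, m + 1),
            "a1": "A",
            "a2": "B",
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": G.sample_ids,
            "iid": G.sample_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a bed/bim/fam file set written with the conventions above."""
    prefix = Path(prefix)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep="\t", header=None,
                      names=["chrom", "snp", "cm", "pos", "a1", "a2"])
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep="\t", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"])
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK 1 bed file")
    n_bytes = (n + 3) // 4
    packed = raw[3:].reshape(m, n_bytes)
    dosages = np.empty((n, m), dtype=np.int8)
    for shift_idx in range(4):
        idx = np.arange(shift_idx, n, 4)
        codes = (packed[:, : len(idx)] >> (2 * shift_idx)) & 0b11
        if (codes == 0b01).any():
            raise ValueError("missing genotypes are not supported")
        lut = np.zeros(4, dtype=np.int8)
        for code, dose in _DECODE.items():
            lut[code] = dose
        dosages[idx] = lut[codes].T
    maf = dosages.mean(axis=0) / 2.0
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=bim["snp"].astype(str).tolist(),
        maf=maf,
        sample_ids=fam["iid"].astype(str).tolist(),
    )
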