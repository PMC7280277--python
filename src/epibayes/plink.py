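"""Minimal PLINK 1 binary genotype support (.bed/.bim/.fam).

Only the SNP-major layout is handled.  Genotypes are returned as the count
of the A1 allele per individual: 2-bit codes 0b00 -> 2, 0b10 -> 1,
0b11 -> 0, 0b01 -> missing (NaN).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

__all__ = ["read_plink", "write_plink"]

_MAGIC = bytes([0x6C, 0x1B, 0x01])
# code -> A1 allele count; 0b01 is missing
_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink(prefix: str):
    """Read ``prefix``.bed/.bim/.fam.

    Returns ``(sample_ids, snp_ids, genotypes)`` with genotypes a float
    (N, M) matrix of A1 allele counts (NaN = missing).
    """
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype={"iid": str})
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos", "a1", "a2"],
                      dtype={"snp": str})
    n, m = len(fam), len(bim)
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _MAGIC:
            raise ValueError(f"{prefix}.bed is not a SNP-major PLINK bed file")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    bytes_per_snp = (n + 3) // 4
    if raw.size != bytes_per_snp * m:
        raise ValueError(f"{prefix}.bed truncated: expected {bytes_per_snp * m} data bytes, found {raw.size}")
    raw = raw.reshape(m, bytes_per_snp)
    # unpack the four 2-bit codes per byte, LSB pair first
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (raw >> (2 * k)) & 0b11
    geno = _DECODE[codes[:, :n]].T  # (N, M)
    return fam["iid"].tolist(), bim["snp"].tolist(), geno


def write_plink(prefix: str, sample_ids, snp_ids, genotypes) -> None:
    """Write A1 allele counts (NaN = missing) as .bed/.bim/.fam."""
    G = np.asarray(genotypes, dtype=np.float64)
    n, m = G.shape
    if n != len(sample_ids) or m != len(snp_ids):
        raise ValueError("genotype shape does not match id lists")
    # count -> 2-bit code
    codes = np.full(G.shape, 0b01, dtype=np.uint8)  # missing
    codes[G == 2] = 0b00
    codes[G == 1] = 0b10
    codes[G == 0] = 0b11

    bytes_per_snp = (n + 3) // 4
    padded = np.full((m, bytes_per_snp * 4), 0b11, dtype=np.uint8)
    padded[:, :n] = codes.T
    out = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        out |= padded[:, k::4] << (2 * k)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_MAGIC)
        fh.write(out.tobytes())

    with open(prefix + ".fam", "w") as fh:
        for sid in sample_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9{os.linesep}")
    with open(prefix + ".bim", "w") as fh:
        for j, snp in enumerate(snp_ids):
            fh.write(f"1\t{snp}\t0\t{j + 1}\tA\tG{os.linesep}")
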