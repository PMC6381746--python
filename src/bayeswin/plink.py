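"""Minimal PLINK 1 binary (bed/bim/fam) reader and writer.

Genotypes are held as an ``(n_animals, n_snps)`` int8 array with additive
coding 0/1/2 (count of the A2 allele) and ``-1`` for missing. The on-disk
layout is SNP-major with the standard 2-bit codes: ``00`` hom A1 (-> 0),
``10`` het (-> 1), ``11`` hom A2 (-> 2), ``01`` missing. Sample *i* of a
SNP occupies bits ``2i .. 2i+1`` of the record, least-significant first.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

MISSING = -1

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major

# 2-bit code -> additive genotype
_CODE_TO_GENO = np.array([0, MISSING, 1, 2], dtype=np.int8)
_GENO_TO_CODE = {0: 0b00, 1: 0b10, 2: 0b11, MISSING: 0b01}


def write_bed(prefix: str, genotypes: np.ndarray, snp_map: pd.DataFrame,
              animal_ids=None) -> None:
    """Write ``prefix``.bed/.bim/.fam.

    ``snp_map`` needs columns ``chrom``, ``snp_id``, ``pos``, ``a1``, ``a2``.
    """
    G = np.asarray(genotypes)
    n, m = G.shape
    if len(snp_map) != m:
        raise ValueError(f"map has {len(snp_map)} SNPs, matrix has {m}")
    if animal_ids is None:
        animal_ids = [f"id{i + 1}" for i in range(n)]

    codes = np.empty_like(G, dtype=np.uint8)
    for geno, code in _GENO_TO_CODE.items():
        codes[G == geno] = code
    # pad samples up to a multiple of 4, pack 4 samples per byte
    n_pad = (-n) % 4
    if n_pad:
        codes = np.vstack([codes, np.zeros((n_pad, m), dtype=np.uint8)])
    codes = codes.T.reshape(m, -1, 4)
    packed = (codes[:, :, 0] | (codes[:, :, 1] << 2)
              | (codes[:, :, 2] << 4) | (codes[:, :, 3] << 6)).astype(np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())

    bim = pd.DataFrame({
        "chrom": snp_map["chrom"].to_numpy(),
        "snp_id": snp_map["snp_id"].to_numpy(),
        "cm": 0.0,
        "pos": snp_map["pos"].to_numpy(),
        "a1": snp_map["a1"].to_numpy(),
        "a2": snp_map["a2"].to_numpy(),
    })
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame({
        "fid": animal_ids, "iid": animal_ids,
        "father": 0, "mother": 0, "sex": 0, "pheno": -9,
    })
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)


def read_bed(prefix: str):
    """Read ``prefix``.bed/.bim/.fam -> (genotypes, snp_map, animal_ids)."""
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None,
                      names=["chrom", "snp_id", "cm", "pos", "a1", "a2"])
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"])
    n, m = len(fam), len(bim)
    n_bytes = (n + 3) // 4
    expected = 3 + n_bytes * m
    size = os.path.getsize(prefix + ".bed")
    if size != expected:
        raise ValueError(f"{prefix}.bed is {size} bytes, expected {expected}")
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ValueError("not a SNP-major PLINK bed file")
        raw = np.frombuffer(fh.read(), dtype=np.uint8).reshape(m, n_bytes)
    # unpack 2-bit fields, low bits first
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (raw >> (2 * k)) & 0b11
    G = _CODE_TO_GENO[codes[:, :n]].T.copy()
    snp_map = bim[["chrom", "snp_id", "pos", "a1", "a2"]].copy()
    return G, snp_map, fam["iid"].tolist()
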