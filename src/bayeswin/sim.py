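"""Synthetic genotype/phenotype generator for the window-GWAS pipeline.

The generator emulates the statistical structure the association analyses
assume: autosomal biallelic SNPs arranged in linkage-disequilibrium blocks,
a small number of additive QTLs on the liability scale, 5-category visual
scores obtained by thresholding liabilities, and estimated breeding values
of stated accuracy.

LD model
--------
Each chromosome is tiled with blocks of ``ld_block_bp`` base pairs. A block
carries ``n_founder_haplotypes`` founder haplotypes; every animal draws two
founder haplotypes per block (independently across blocks) and its genotype
is their sum. Within a block adjacent SNPs therefore share the founder
assignment and show blocky r^2; across blocks and chromosomes SNPs are
independent. Founder allele counts are fixed at ``round(p * n_founders)``
(clamped to keep every SNP polymorphic), so population allele frequencies
land in the configured MAF range up to sampling error.

Liability model
---------------
liability = contemporary-group effect + b1*age + b2*age^2 + Z alpha + e,
with residual variance chosen so that var(Z alpha) / (var(Z alpha) +
var(e)) equals the configured heritability. Scores 1..5 cut the liability
at four thresholds (default: empirical quintiles, so all categories are
populated).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .plink import MISSING

__all__ = ["SimConfig", "simulate_genotypes", "simulate_qtl_effects",
           "simulate_ordinal_phenotypes", "simulate_ebv", "make_snp_map",
           "genotype_frequencies"]


@dataclass
class SimConfig:
    """Parameters of the synthetic study population."""

    n_animals: int = 1000
    chrom_lengths_bp: tuple = (40_000_000,) * 5     # 5 autosomes, 40 Mb each
    snps_per_chrom: tuple = (1000,) * 5
    maf_range: tuple = (0.05, 0.5)
    ld_block_bp: int = 500_000
    n_founder_haplotypes: int = 8
    n_qtl: int = 10
    architecture: str = "spike_slab"                # or "laplace"
    genetic_variance: float = 1.0                   # liability-scale var of Z alpha
    h2: float = 0.44                                # liability heritability
    n_contemporary_groups: int = 20
    cg_sd: float = 0.3                              # CG effect SD, liability units
    age_range_days: tuple = (150, 270)
    age_b1: float = 0.004                           # liability units per day
    age_b2: float = -5e-6                           # per day^2
    thresholds: tuple | None = None                 # None -> liability quintiles
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.chrom_lengths_bp) != len(self.snps_per_chrom):
            raise ValueError("chrom_lengths_bp and snps_per_chrom differ in length")
        if self.n_animals <= 0 or any(s <= 0 for s in self.snps_per_chrom):
            raise ValueError("dimensions must be positive")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if not (0.0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("MAF range must satisfy 0 < lo <= hi <= 0.5")
        if self.thresholds is not None and not np.all(np.diff(self.thresholds) > 0):
            raise ValueError("thresholds must be strictly increasing")
        if self.architecture not in ("spike_slab", "laplace"):
            raise ValueError(f"unknown architecture {self.architecture!r}")

    @property
    def n_snps(self) -> int:
        return int(sum(self.snps_per_chrom))

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("chrom_lengths_bp", "snps_per_chrom", "maf_range",
                    "age_range_days", "thresholds"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def make_snp_map(config: SimConfig) -> pd.DataFrame:
    """Evenly spaced SNP coordinates per chromosome (strictly increasing)."""
    rows = []
    for c, (length, m) in enumerate(zip(config.chrom_lengths_bp,
                                        config.snps_per_chrom), start=1):
        if m > length:
            raise ValueError("more SNPs than base pairs on a chromosome")
        pos = np.unique(np.linspace(1, length, m, dtype=np.int64))
        while len(pos) < m:  # rounding collisions on very dense maps
            extra = pos[-1] + 1 + np.arange(m - len(pos), dtype=np.int64)
            pos = np.unique(np.concatenate([pos, extra]))
        rows.append(pd.DataFrame({
            "chrom": c,
            "snp_id": [f"snp_{c}_{j + 1}" for j in range(m)],
            "pos": pos[:m],
            "a1": "A",
            "a2": "B",
        }))
    return pd.concat(rows, ignore_index=True)


def simulate_genotypes(config: SimConfig, rng: np.random.Generator | None = None):
    """Draw (genotypes, snp_map) under the founder-haplotype block model."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    snp_map = make_snp_map(config)
    n, m = config.n_animals, len(snp_map)
    nf = config.n_founder_haplotypes
    G = np.empty((n, m), dtype=np.int8)

    for c in np.unique(snp_map["chrom"]):
        idx = np.flatnonzero(snp_map["chrom"].to_numpy() == c)
        pos = snp_map["pos"].to_numpy()[idx]
        block_of = pos // config.ld_block_bp
        for b in np.unique(block_of):
            cols = idx[block_of == b]
            k = len(cols)
            p = rng.uniform(*config.maf_range, size=k)
            counts = np.clip(np.rint(p * nf).astype(int), 1, nf - 1)
            founders = np.zeros((nf, k), dtype=np.int8)
            for j in range(k):
                carriers = rng.choice(nf, size=counts[j], replace=False)
                founders[carriers, j] = 1
            picks = rng.integers(0, nf, size=(n, 2))
            G[:, cols] = founders[picks[:, 0]] + founders[picks[:, 1]]

    if config.missing_rate > 0:
        mask = rng.random(G.shape) < config.missing_rate
        G[mask] = MISSING
    return G, snp_map


def genotype_frequencies(G: np.ndarray) -> np.ndarray:
    """Per-SNP allele-2 frequency, ignoring missing entries."""
    Gf = np.asarray(G, dtype=float)
    Gf[G == MISSING] = np.nan
    return np.nanmean(Gf, axis=0) / 2.0


def simulate_qtl_effects(G: np.ndarray, config: SimConfig,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Allele-substitution effects, scaled so sum 2p(1-p) alpha^2 hits the target.

    ``spike_slab``: exactly ``n_qtl`` nonzero normal effects; ``laplace``:
    every SNP carries a double-exponential effect.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    m = G.shape[1]
    if config.n_qtl > m:
        raise ValueError("n_qtl exceeds number of SNPs")
    alpha = np.zeros(m)
    if config.architecture == "spike_slab":
        if config.n_qtl == 0:
            return alpha
        qtl = rng.choice(m, size=config.n_qtl, replace=False)
        alpha[qtl] = rng.standard_normal(config.n_qtl)
    else:
        alpha = rng.laplace(0.0, 1.0, size=m)
    p = genotype_frequencies(G)
    raw = np.sum(2.0 * p * (1.0 - p) * alpha**2)
    if raw > 0:
        alpha *= np.sqrt(config.genetic_variance / raw)
    return alpha


def simulate_ordinal_phenotypes(G: np.ndarray, alpha: np.ndarray,
                                config: SimConfig,
                                rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Liabilities, 1-5 scores, contemporary groups and ages for every animal.

    Returns a DataFrame with columns ``animal``, ``score``, ``cg``, ``age``,
    ``liability``, ``genetic_value`` (the last two are simulation truths kept
    for validation, not model inputs).
    """
    n, m = G.shape
    if len(alpha) != m:
        raise ValueError("effect vector length does not match genotype matrix")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)

    Gf = np.asarray(G, dtype=float)
    Gf[G == MISSING] = np.nan
    col_mean = np.nanmean(Gf, axis=0)
    filled = np.where(np.isnan(Gf), col_mean, Gf)
    g = filled @ alpha

    var_g = float(np.var(g))
    if config.h2 >= 1.0:
        var_e = 0.0
    elif config.h2 <= 0.0 or var_g == 0.0:
        g = np.zeros(n)
        var_e = 1.0
    else:
        var_e = var_g * (1.0 - config.h2) / config.h2
    e = rng.normal(0.0, np.sqrt(var_e), size=n)

    cg = rng.integers(0, config.n_contemporary_groups, size=n)
    cg_eff = rng.normal(0.0, config.cg_sd, size=config.n_contemporary_groups)
    age = rng.integers(config.age_range_days[0], config.age_range_days[1] + 1,
                       size=n).astype(float)
    liability = cg_eff[cg] + config.age_b1 * age + config.age_b2 * age**2 + g + e

    if config.thresholds is None:
        thr = np.quantile(liability, [0.2, 0.4, 0.6, 0.8])
        if not np.all(np.diff(thr) > 0):  # degenerate liability distribution
            thr = np.sort(thr) + np.arange(4) * 1e-9
    else:
        thr = np.asarray(config.thresholds, dtype=float)
    score = 1 + np.searchsorted(thr, liability, side="left")

    return pd.DataFrame({
        "animal": [f"id{i + 1}" for i in range(n)],
        "score": score.astype(int),
        "cg": cg,
        "age": age,
        "liability": liability,
        "genetic_value": g,
    })


def simulate_ebv(true_bv: np.ndarray, accuracy: np.ndarray | float,
                 rng: np.random.Generator | None = None,
                 seed: int | None = None) -> pd.DataFrame:
    """EBVs of given accuracy: EBV = r*TBV_c + sqrt(1-r^2)*eps.

    ``TBV_c`` is the centred true breeding value; ``eps`` is drawn with the
    additive SD so that corr(EBV, TBV) -> r. Returns columns ``animal``,
    ``ebv``, ``reliability`` (= r^2), ``accuracy``.
    """
    true_bv = np.asarray(true_bv, dtype=float)
    n = len(true_bv)
    r = np.broadcast_to(np.asarray(accuracy, dtype=float), (n,)).copy()
    if np.any((r < 0) | (r > 1)):
        raise ValueError("accuracy must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    centred = true_bv - true_bv.mean()
    sd = centred.std()
    if sd == 0:
        sd = 1.0
    eps = rng.normal(0.0, sd, size=n)
    ebv = r * centred + np.sqrt(1.0 - r**2) * eps
    return pd.DataFrame({
        "animal": [f"id{i + 1}" for i in range(n)],
        "ebv": ebv,
        "reliability": r**2,
        "accuracy": r,
    })
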