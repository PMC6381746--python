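"""Iterative genotype quality control and missing-genotype imputation.

One QC iteration applies, in fixed order: autosome filter, per-SNP call
rate, per-animal call rate, minor-allele frequency, Hardy-Weinberg
equilibrium, and within-chromosome LD pruning. The cascade repeats until a
full pass removes nothing (removing animals can push a SNP below a
threshold and vice versa), then residual missing genotypes are imputed to
the per-SNP modal genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .plink import MISSING

__all__ = ["QCThresholds", "QCReport", "hwe_test", "ld_prune",
           "qc_pipeline", "impute_missing"]


@dataclass
class QCThresholds:
    snp_call_rate_min: float = 0.95
    animal_call_rate_min: float = 0.90
    maf_min: float = 0.05
    hwe_p_min: float = 1e-5
    r2_max: float = 0.98
    max_autosome: int = 29  # cattle; chromosome ids above this are dropped

    def __post_init__(self):
        for name in ("snp_call_rate_min", "animal_call_rate_min",
                     "maf_min", "hwe_p_min", "r2_max"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")


@dataclass
class QCReport:
    """Per-iteration removal bookkeeping plus surviving index sets."""

    removals: list = field(default_factory=list)  # (iteration, filter, kind, count)
    n_iterations: int = 0
    snps_in: int = 0
    animals_in: int = 0
    kept_snps: np.ndarray | None = None
    kept_animals: np.ndarray | None = None

    def add(self, iteration, filt, kind, count):
        if count:
            self.removals.append((iteration, filt, kind, int(count)))

    def removed(self, kind: str) -> int:
        return sum(c for _, _, k, c in self.removals if k == kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.removals,
                            columns=["iteration", "filter", "kind", "removed"])


def hwe_test(n_AA: int, n_AB: int, n_BB: int) -> float:
    """Chi-square goodness-of-fit p-value for Hardy-Weinberg proportions.

    Monomorphic SNPs return 1.0 (no deviation is testable). No continuity
    correction: the downstream cutoff (1e-5) targets extreme deviations
    symptomatic of genotyping error.
    """
    if min(n_AA, n_AB, n_BB) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_AB + n_BB
    if n == 0:
        raise ValueError("no genotyped animals")
    p = (2 * n_AA + n_AB) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_AA, n_AB, n_BB], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def _fill_mean(G: np.ndarray) -> np.ndarray:
    Gf = np.asarray(G, dtype=float)
    Gf[G == MISSING] = np.nan
    mean = np.nanmean(Gf, axis=0)
    inds = np.where(np.isnan(Gf))
    Gf[inds] = np.take(mean, inds[1])
    return Gf


def ld_prune(G: np.ndarray, snp_map: pd.DataFrame, r2_max: float = 0.98) -> np.ndarray:
    """Greedy within-chromosome LD pruning; returns kept SNP indices.

    SNPs are scanned left to right by position; the later (larger-bp) SNP
    of a pair with genotype r^2 above ``r2_max`` is dropped, so the result
    is deterministic. Missing genotypes are mean-filled for the correlation.
    """
    chroms = snp_map["chrom"].to_numpy()
    pos = snp_map["pos"].to_numpy()
    kept: list[int] = []
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        idx = idx[np.argsort(pos[idx], kind="stable")]
        X = _fill_mean(G[:, idx])
        X = X - X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0  # constant columns correlate with nothing
        X /= sd
        corr = (X.T @ X) / X.shape[0]
        keep_local: list[int] = []
        for j in range(len(idx)):
            if all(corr[j, k] ** 2 <= r2_max for k in keep_local):
                keep_local.append(j)
        kept.extend(idx[keep_local])
    return np.sort(np.asarray(kept, dtype=int))


def _genotype_counts(col: np.ndarray):
    return ((col == 0).sum(), (col == 1).sum(), (col == 2).sum())


def qc_pipeline(G: np.ndarray, snp_map: pd.DataFrame,
                thresholds: QCThresholds | None = None):
    """Run the iterative QC cascade; returns (G', map', QCReport).

    Raises ``ValueError`` if every SNP or every animal is removed.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    t = thresholds
    n0, m0 = G.shape
    report = QCReport(snps_in=m0, animals_in=n0)

    snp_idx = np.arange(m0)
    animal_idx = np.arange(n0)
    Gc = G
    mapc = snp_map.reset_index(drop=True)

    iteration = 0
    while True:
        iteration += 1
        removed_any = False

        # 1. autosomes only
        keep = (mapc["chrom"].to_numpy() >= 1) & \
               (mapc["chrom"].to_numpy() <= t.max_autosome)
        report.add(iteration, "autosome", "snp", (~keep).sum())
        if not keep.all():
            removed_any = True
            Gc, mapc, snp_idx = Gc[:, keep], mapc[keep].reset_index(drop=True), snp_idx[keep]
        _check_nonempty(Gc)

        # 2. SNP call rate
        call = (Gc != MISSING).mean(axis=0)
        keep = call >= t.snp_call_rate_min
        report.add(iteration, "snp_call_rate", "snp", (~keep).sum())
        if not keep.all():
            removed_any = True
            Gc, mapc, snp_idx = Gc[:, keep], mapc[keep].reset_index(drop=True), snp_idx[keep]
        _check_nonempty(Gc)

        # 3. animal call rate
        call = (Gc != MISSING).mean(axis=1)
        keep = call >= t.animal_call_rate_min
        report.add(iteration, "animal_call_rate", "animal", (~keep).sum())
        if not keep.all():
            removed_any = True
            Gc, animal_idx = Gc[keep], animal_idx[keep]
        _check_nonempty(Gc)

        # 4. minor allele frequency
        Gm = np.ma.masked_equal(Gc, MISSING)
        p = Gm.mean(axis=0).filled(0.0) / 2.0
        maf = np.minimum(p, 1.0 - p)
        keep = maf >= t.maf_min
        report.add(iteration, "maf", "snp", (~keep).sum())
        if not keep.all():
            removed_any = True
            Gc, mapc, snp_idx = Gc[:, keep], mapc[keep].reset_index(drop=True), snp_idx[keep]
        _check_nonempty(Gc)

        # 5. Hardy-Weinberg equilibrium
        def _hwe_col(col):
            counts = _genotype_counts(col[col != MISSING])
            return hwe_test(*counts) if sum(counts) else 1.0
        pvals = np.array([_hwe_col(Gc[:, j]) for j in range(Gc.shape[1])])
        keep = pvals >= t.hwe_p_min
        report.add(iteration, "hwe", "snp", (~keep).sum())
        if not keep.all():
            removed_any = True
            Gc, mapc, snp_idx = Gc[:, keep], mapc[keep].reset_index(drop=True), snp_idx[keep]
        _check_nonempty(Gc)

        # 6. LD pruning
        kept_local = ld_prune(Gc, mapc, t.r2_max)
        report.add(iteration, "ld_prune", "snp", Gc.shape[1] - len(kept_local))
        if len(kept_local) < Gc.shape[1]:
            removed_any = True
            Gc = Gc[:, kept_local]
            mapc = mapc.iloc[kept_local].reset_index(drop=True)
            snp_idx = snp_idx[kept_local]
        _check_nonempty(Gc)

        if not removed_any:
            break

    report.n_iterations = iteration
    report.kept_snps = snp_idx
    report.kept_animals = animal_idx
    return Gc.copy(), mapc, report


def _check_nonempty(G):
    if G.shape[1] == 0:
        raise ValueError("quality control removed every SNP")
    if G.shape[0] == 0:
        raise ValueError("quality control removed every animal")


def impute_missing(G: np.ndarray) -> np.ndarray:
    """Replace missing genotypes by the per-SNP modal genotype.

    Ties go to the smaller genotype code. A fully missing SNP is an error:
    the call-rate filter should have removed it.
    """
    G = np.asarray(G)
    out = G.copy()
    missing_cols = np.flatnonzero((G == MISSING).any(axis=0))
    for j in missing_cols:
        col = G[:, j]
        obs = col[col != MISSING]
        if obs.size == 0:
            raise ValueError(f"SNP column {j} is entirely missing")
        counts = np.bincount(obs, minlength=3)
        mode = int(np.argmax(counts))  # argmax returns the first (smallest) tie
        out[col == MISSING, j] = mode
    return out
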