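"""Whole-genome Bayesian regression: model specification and fitting.

The observation model is  y = X beta + Z alpha + e  where y is either a
continuous pseudo-phenotype (deregressed breeding values) or the latent
liability underlying an ordinal 1..K score. Two marker-effect priors are
available:

``bayesc``
    spike-and-slab mixture: alpha_k = 0 with probability 1 - pi, else
    N(0, sigma2_alpha), with pi fixed (default 0.01) and sigma2_alpha
    given a scaled inverse chi-square hyperprior.

``blasso``
    double-exponential (Laplace) prior via the normal/exponential scale
    mixture; the shrinkage parameter lambda^2 carries a Gamma hyperprior
    and is updated from the data.

For ordinal scores a probit threshold model is used: liabilities are
standard-normal data augmentation variables (residual variance fixed at
1), redrawn each cycle from truncated normals, with the cutpoints sampled
from their uniform conditionals. Contemporary-group indicator columns
absorb the location, so no intercept is included in the ordinal design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri as _scipy_ndtri

from . import _gibbs

__all__ = ["ModelSpec", "McmcConfig", "PosteriorSummary", "fit",
           "build_design", "update_effect_bayesc", "update_effect_blasso",
           "update_liabilities", "update_cutpoints"]


@dataclass
class ModelSpec:
    prior: str = "bayesc"                 # "bayesc" | "blasso"
    likelihood: str = "gaussian"          # "gaussian" | "ordinal"
    pi: float = 0.01                      # spike-slab inclusion proportion
    df_effect_var: float = 5.0            # scaled-inv-chi2 df, effect variance
    df_resid_var: float = 5.0             # scaled-inv-chi2 df, residual variance
    prior_r2: float = 0.5                 # heuristic setting the prior scales
    bl_shape: float = 1.1                 # Gamma shape for lambda^2
    bl_rate: float | None = None          # None -> mode-matched to prior_r2
    fix_effect_var: float | None = None   # fix sigma2_alpha (validation runs)
    fix_resid_var: float | None = None    # fix sigma2_e (ordinal forces 1.0)
    fix_cutpoints: np.ndarray | None = None
    n_categories: int = 5

    def __post_init__(self):
        if self.prior not in ("bayesc", "blasso"):
            raise ValueError(f"unknown prior {self.prior!r}")
        if self.likelihood not in ("gaussian", "ordinal"):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")
        if self.likelihood == "ordinal" and self.fix_resid_var not in (None, 1.0):
            raise ValueError("ordinal likelihood requires residual variance 1")


@dataclass
class McmcConfig:
    n_iter: int = 800_000
    burn_in: int = 200_000
    thin: int = 100
    seed: int = 0
    store_effect_chains: bool = False

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorSummary:
    """Posterior means and retained variance-component chains."""

    alpha_mean: np.ndarray
    inclusion_freq: np.ndarray
    beta_mean: np.ndarray
    cutpoints_mean: np.ndarray
    sigma2_snp_chain: np.ndarray     # var across animals of Z alpha, per draw
    sigma2_e_chain: np.ndarray
    hyper_chain: np.ndarray          # sigma2_alpha (bayesc) or lambda2 (blasso)
    alpha_chain: np.ndarray | None
    n_samples: int
    spec: ModelSpec

    @property
    def sigma2_snp(self) -> float:
        return float(self.sigma2_snp_chain.mean())

    @property
    def sigma2_e(self) -> float:
        return float(self.sigma2_e_chain.mean())

    def to_frame(self, snp_map: pd.DataFrame | None = None) -> pd.DataFrame:
        out = pd.DataFrame({
            "alpha_hat": self.alpha_mean,
            "inclusion_freq": self.inclusion_freq,
        })
        if snp_map is not None:
            out.insert(0, "snp_id", snp_map["snp_id"].to_numpy())
            out.insert(1, "chrom", snp_map["chrom"].to_numpy())
            out.insert(2, "pos", snp_map["pos"].to_numpy())
        return out


def build_design(phenotypes: pd.DataFrame, age: str = "linear",
                 intercept: bool = False) -> np.ndarray:
    """Fixed-effect design: contemporary-group indicators plus the age
    covariate (centred; optionally with a quadratic term)."""
    cols = []
    if intercept:
        cols.append(np.ones(len(phenotypes)))
    if "cg" in phenotypes:
        cg = pd.get_dummies(phenotypes["cg"]).to_numpy(dtype=float)
        cols.append(cg)
    if "age" in phenotypes and age in ("linear", "quadratic"):
        a = phenotypes["age"].to_numpy(dtype=float)
        a = a - a.mean()
        cols.append(a[:, None])
        if age == "quadratic":
            cols.append((a**2 - (a**2).mean())[:, None])
    if not cols:
        return np.empty((len(phenotypes), 0))
    return np.column_stack(cols)


def _prior_scales(y_var: float, sum_var_z: float, spec: ModelSpec):
    """Set hyperprior scales from the prior-R^2 heuristic: the mode of each
    scaled-inv-chi2 sits at the share of phenotypic variance the prior
    assigns to markers (R^2) or residual (1 - R^2)."""
    r2 = spec.prior_r2
    nu_a, nu_e = spec.df_effect_var, spec.df_resid_var
    msx = max(sum_var_z, 1e-12)
    if spec.prior == "bayesc":
        target = r2 * y_var / (max(spec.pi, 1e-4) * msx)
        scale_a = target * (nu_a + 2.0) / nu_a
    else:
        scale_a = 1.0  # unused under the Laplace prior
    scale_e = max((1.0 - r2) * y_var, 1e-8) * (nu_e + 2.0) / nu_e
    if spec.bl_rate is None:
        lam2_target = 2.0 * max(1.0 - r2, 0.05) * msx / max(r2, 0.05)
        bl_rate = max(spec.bl_shape - 1.0, 0.1) / lam2_target
    else:
        bl_rate = spec.bl_rate
    return scale_a, scale_e, bl_rate


def default_cutpoints(scores: np.ndarray, n_cat: int) -> np.ndarray:
    """Probit-scale cutpoints from observed cumulative category frequencies."""
    n = len(scores)
    cum = np.array([(scores <= c).sum() for c in range(1, n_cat)]) / n
    cum = np.clip(cum, 1.0 / (n + 1), 1.0 - 1.0 / (n + 1))
    return _scipy_ndtri(cum)


def fit(y: np.ndarray, X: np.ndarray | None, Z: np.ndarray,
        spec: ModelSpec | None = None,
        mcmc: McmcConfig | None = None) -> PosteriorSummary:
    """Run the Gibbs sampler and return posterior summaries.

    ``y`` is the continuous dependent variable (Gaussian likelihood) or the
    integer scores in 1..n_categories (ordinal). ``X`` may be None for a
    fixed-effect-free model.
    """
    spec = spec or ModelSpec()
    mcmc = mcmc or McmcConfig()
    Z = np.asarray(Z)
    n, m = Z.shape
    if X is None:
        X = np.empty((n, 0))
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] != n:
        raise ValueError("X and Z disagree on the number of animals")

    Zt = np.ascontiguousarray(Z.T, dtype=np.float64)
    Xt = np.ascontiguousarray(X.T)

    likelihood = (_gibbs.LIK_ORDINAL if spec.likelihood == "ordinal"
                  else _gibbs.LIK_GAUSSIAN)
    prior = (_gibbs.PRIOR_BLASSO if spec.prior == "blasso"
             else _gibbs.PRIOR_BAYESC)

    n_cat = spec.n_categories
    if likelihood == _gibbs.LIK_ORDINAL:
        scores = np.asarray(y, dtype=np.int64)
        if scores.min() < 1 or scores.max() > n_cat:
            raise ValueError(f"scores must lie in 1..{n_cat}")
        if spec.fix_cutpoints is not None:
            cut0 = np.asarray(spec.fix_cutpoints, dtype=np.float64)
            if len(cut0) != n_cat - 1 or not np.all(np.diff(cut0) > 0):
                raise ValueError("fix_cutpoints must be n_categories-1 "
                                 "strictly increasing values")
        else:
            cut0 = default_cutpoints(scores, n_cat)
        # liabilities start at the midpoint of their category's interval
        edges = np.concatenate([[cut0[0] - 1.0], cut0, [cut0[-1] + 1.0]])
        y0 = 0.5 * (edges[scores - 1] + edges[scores])
        y_var = 1.0 / max(1.0 - spec.prior_r2, 0.5)  # latent-scale heuristic
        fix_s2e = 1.0
    else:
        scores = np.zeros(n, dtype=np.int64)
        y0 = np.asarray(y, dtype=np.float64).copy()
        cut0 = np.zeros(1)
        y_var = float(np.var(y0)) or 1.0
        fix_s2e = spec.fix_resid_var if spec.fix_resid_var is not None else -1.0

    var_z = Zt.var(axis=1)
    scale_a, scale_e, bl_rate = _prior_scales(y_var, float(var_z.sum()), spec)
    fix_s2a = spec.fix_effect_var if spec.fix_effect_var is not None else -1.0

    sample_cut = spec.fix_cutpoints is None
    res = _gibbs.run_chain(
        mcmc.seed, likelihood, prior, scores, y0, Xt, Zt, cut0, n_cat,
        float(spec.pi), float(spec.df_effect_var), float(scale_a),
        float(fix_s2a), float(spec.df_resid_var), float(scale_e),
        float(fix_s2e), float(spec.bl_shape), float(bl_rate),
        int(mcmc.n_iter), int(mcmc.burn_in), int(mcmc.thin),
        mcmc.store_effect_chains, sample_cut)

    (alpha_mean, incl_freq, beta_mean, cut_mean, s2snp_chain, s2e_chain,
     hyper_chain, alpha_chain, status) = res
    if status != 0:
        raise RuntimeError(
            "divergent variance draws in the Gibbs sampler "
            f"(last sigma2_e draws: {s2e_chain[-5:]})")
    return PosteriorSummary(
        alpha_mean=alpha_mean,
        inclusion_freq=incl_freq,
        beta_mean=beta_mean,
        cutpoints_mean=cut_mean,
        sigma2_snp_chain=s2snp_chain,
        sigma2_e_chain=s2e_chain,
        hyper_chain=hyper_chain,
        alpha_chain=alpha_chain if mcmc.store_effect_chains else None,
        n_samples=len(s2snp_chain),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# thin wrappers around the jitted conditional updates (unit-testable pieces)

def update_effect_bayesc(residual, z_k, sigma2_alpha, sigma2_e, pi, seed=None):
    """Draw (alpha_k, inclusion) given a residual that excludes marker k."""
    if seed is not None:
        _gibbs.seed_rng(seed)
    z_k = np.asarray(z_k, dtype=float)
    r = float(z_k @ np.asarray(residual, dtype=float))
    czz = float(z_k @ z_k)
    return _gibbs.bayesc_draw(r, czz, sigma2_alpha, sigma2_e, pi)


def update_effect_blasso(residual, z_k, tau2_k, sigma2_e, seed=None):
    """Draw alpha_k under the Laplace scale mixture, given tau2_k."""
    if seed is not None:
        _gibbs.seed_rng(seed)
    z_k = np.asarray(z_k, dtype=float)
    r = float(z_k @ np.asarray(residual, dtype=float))
    czz = float(z_k @ z_k)
    return _gibbs.blasso_draw(r, czz, tau2_k, sigma2_e)


def update_liabilities(scores, eta, cutpoints, seed=None):
    """Draw liabilities from N(eta_i, 1) truncated to each score's interval."""
    if seed is not None:
        _gibbs.seed_rng(seed)
    scores = np.asarray(scores, dtype=np.int64)
    cut = np.asarray(cutpoints, dtype=float)
    n_cat = len(cut) + 1
    y = np.asarray(eta, dtype=float).copy()
    e = np.zeros_like(y)  # so eta_i = y_i - e_i inside the kernel
    _gibbs.update_liabilities_inplace(scores, y, e, cut, n_cat)
    return y


def update_cutpoints(liabilities, scores, cutpoints, seed=None):
    """Uniform conditional cutpoint draw; returns the new cutpoint vector."""
    if seed is not None:
        _gibbs.seed_rng(seed)
    cut = np.asarray(cutpoints, dtype=float).copy()
    _gibbs.update_cutpoints_inplace(np.asarray(scores, dtype=np.int64),
                                    np.asarray(liabilities, dtype=float),
                                    cut, len(cut) + 1)
    if not np.all(np.diff(cut) > 0):
        raise AssertionError("cutpoint ordering violated")
    return cut
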