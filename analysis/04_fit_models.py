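"""Fit the four model x dependent-variable combinations:

  BayesC / Bayesian LASSO  x  ordinal score (threshold probit)
                              or dEBV (Gaussian, intercept only).

Chains here are 20,000 cycles with 5,000 burn-in (thinning 10) — scaled
down from production-length chains; the methods note discusses the choice.
Per-SNP posterior effect tables land under scratch/, variance-component
chains under scratch/, and a compact fit summary in results/.
"""

import time

import pandas as pd

from bayeswin import models, plink
from paths import RESULTS, SCRATCH, SEED

CHAIN = dict(n_iter=20_000, burn_in=5_000, thin=10)


def main():
    G, snp_map, ids = plink.read_bed(str(SCRATCH / "panel_qc"))
    pheno = pd.read_csv(SCRATCH / "phenotypes.csv")
    pheno = pheno.set_index("animal").loc[ids].reset_index()
    debv = pd.read_csv(SCRATCH / "debv.csv")

    idx = {a: i for i, a in enumerate(ids)}
    debv = debv[debv["animal"].isin(idx)]
    rows_debv = [idx[a] for a in debv["animal"]]

    summaries = []
    for prior in ("bayesc", "blasso"):
        # ordinal score as dependent variable
        X = models.build_design(pheno)
        t0 = time.time()
        post = models.fit(pheno["score"].to_numpy(), X, G,
                          models.ModelSpec(prior=prior, likelihood="ordinal"),
                          models.McmcConfig(seed=SEED, **CHAIN))
        _save(post, snp_map, f"{prior}_phenotype")
        summaries.append(_row(prior, "phenotype", post, time.time() - t0))

        # deregressed EBVs: Gaussian likelihood, intercept-only fixed part
        y = debv["debv"].to_numpy()
        Zd = G[rows_debv]
        t0 = time.time()
        post = models.fit(y, _intercept(len(y)), Zd,
                          models.ModelSpec(prior=prior, likelihood="gaussian"),
                          models.McmcConfig(seed=SEED + 1, **CHAIN))
        _save(post, snp_map, f"{prior}_debv")
        summaries.append(_row(prior, "debv", post, time.time() - t0))

    out = pd.DataFrame(summaries)
    out.to_csv(RESULTS / "fit_summary.tsv", sep="\t", index=False)
    print(out.to_string(index=False))


def _intercept(n):
    import numpy as np
    return np.ones((n, 1))


def _row(prior, dependent, post, secs):
    return {"prior": prior, "dependent": dependent,
            "sigma2_snp": round(post.sigma2_snp, 3),
            "sigma2_e": round(post.sigma2_e, 3),
            "n_samples": post.n_samples, "seconds": round(secs, 1)}


def _save(post, snp_map, tag):
    post.to_frame(snp_map).to_csv(SCRATCH / f"effects_{tag}.tsv",
                                  sep="\t", index=False)
    pd.DataFrame({"sigma2_snp": post.sigma2_snp_chain,
                  "sigma2_e": post.sigma2_e_chain,
                  "hyper": post.hyper_chain}).to_csv(
        SCRATCH / f"chains_{tag}.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
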