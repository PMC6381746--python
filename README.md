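# bayeswin

Window-based Bayesian genome-wide association for ordinal visual scores in
beef cattle. Subjective 1–5 conformation/precocity/muscling scores assigned
at weaning are widely used as selection criteria in Brazilian Nellore
breeding; this package implements the full analysis chain for locating
genome regions associated with such scores:

1. **Genotype QC** — iterative cascade (autosomes, SNP/animal call rate,
   MAF, Hardy–Weinberg, LD pruning at r² > 0.98) repeated until a full
   pass removes nothing, plus modal imputation of residual missingness.
2. **EBV deregression** — `dEBV = EBV/r²` with Garrick-style information
   weights and the accuracy > 0.60 filter, turning shrunken breeding
   values into usable pseudo-phenotypes.
3. **Whole-genome Bayesian regression** `y = Xβ + Zα + e` with
   - **BayesC**: spike-and-slab marker prior, π fixed at 0.01, and
   - **Bayesian LASSO**: double-exponential prior via the normal/
     exponential scale mixture with λ² learned from the data;
   each under a **Gaussian** likelihood (dEBV) or an **ordinal probit
   threshold** likelihood (scores), the latter via liability augmentation
   with residual variance fixed at 1. Numba-compiled Gibbs samplers,
   exactly reproducible by seed.
4. **Window association criterion** — markers grouped in 1 Mb windows
   overlapping every 100 kb; each window is scored by the percentage of
   additive genetic variance it explains,

       %σ²_j = σ²_j / σ²_SNP · h² / h²_SNP · 100,

   where σ²_j and σ²_SNP are variances across animals of the window and
   whole-genome GEBVs (GEBV_ij = Σ_k X_ik α̂_k), h² the trait heritability
   and h²_SNP = σ²_SNP/(σ²_SNP + σ²_e) the marker heritability. Windows
   above 0.25% are called significant and can be annotated against a
   BED/GFF3 gene table.
5. **Synthetic data generator** — founder-haplotype LD blocks, planted
   QTLs, liability-scale heritability, 5-category scores and EBVs of
   stated accuracy, so the whole chain is testable without any download.

See `docs/methods.md` for the model details, priors, numerical choices and
limitations.

## Worked example

The numbered drivers under `analysis/` run a complete synthetic study
(800 animals × 2000 SNPs on 4 chromosomes, 10 QTLs, liability h² = 0.44);
each stage prints what it found and writes tables under `results/`:

```bash
cd analysis
python 01_simulate.py   # genotypes + scores + EBVs -> scratch/analysis/
python 02_qc.py         # iterative QC -> results/qc_report.tsv
python 03_deregress.py  # accuracy filter + deregression
python 04_fit_models.py # 4 fits: {BayesC, LASSO} x {score, dEBV}
python 05_windows.py    # 1 Mb / 100 kb window scan -> results/
python 06_report.py     # summary table + gene annotation demo
```

Output of `06_report.py` for this configuration (seed 20250927):

```
trait  prior dependent  sigma2_snp  sigma2_e        h2_snp  windows_to_10pct
score bayesc phenotype       0.900     1.000         0.474                 1
score bayesc      debv       1.792     1.436 0.244 [0.555]                 1
score blasso phenotype       2.012     1.000         0.668                 1
score blasso      debv       2.248     0.988 0.306 [0.695]                 1
```

Reading this: for the ordinal-score fits the residual variance is fixed at
1, so `sigma2_snp` is on the liability scale and `h2_snp` estimates the
liability heritability — BayesC's 0.474 is close to the simulated 0.44,
while the LASSO over-absorbs polygenic noise into the genetic term. For
dEBV fits the bracketed number is the share of additive genetic variance
the markers capture and `h2_snp` rescales it by h². A single window
suffices to explain 10% of the genetic variance because this synthetic
architecture plants a few large QTLs; `05_windows.py` additionally reports
that 7–8 of the 10 planted QTLs fall inside the top-20 non-overlapping
windows. `results/significant_windows.tsv` lists the windows above the
0.25% calling threshold and `results/annotated_windows.tsv` their overlaps
with a (synthetic) gene annotation.

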