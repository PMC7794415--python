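# dermrisk

Composite disease risk scores and lifetime risk trajectories for the
three major skin cancers — basal cell carcinoma (BCC), squamous cell
carcinoma (SCC), and melanoma.

Large survey-based case-control cohorts make it possible to combine
dozens of weak risk factors — pigmentation, moles, sun exposure, family
history, and a polygenic risk score (PRS) — into composite scores whose
*tails* identify people at several-fold elevated risk even when overall
discrimination is modest.  `dermrisk` implements that full analysis
path as a tested, reusable package, exercised end-to-end on a synthetic
cohort generator that emulates the data structure such a study
produces (hazard-driven outcomes with ages at diagnosis, family
history, missingness, and yearly follow-up waves), so every stage is
verifiable without access to any private cohort.

## The model in brief

Per cancer, case status is fit with a binomial GLM (logit link) over
~32 risk factors: survey factors selected in stages (all-factor screen
at p < 0.05 with a union rule across the three cancers, then an
extra-phenotype scan at p < 1e-8 with mixed-variable clustering of the
hits), demographic covariates (sex, ancestry PCs, and age as an
orthogonal polynomial of degree 2–4), a 0–3 family-history score, and a
clumping-and-thresholding PRS (p ≤ 1e-6, 250 kb window, r² ≤ 0.1).
Composite scores are weighted factor sums using the fitted
coefficients:

- **DRS** — all factors; the global risk score;
- **DRSA** — the same weights with the age block removed; age
  independent, so it can be crossed with age to yield lifetime risk
  trajectories `P_a` by DRSA stratum, m-year incidence
  `I_a = (P_a − P_{a−m}) / (1 − P_{a−m})`, and the survival-weighted
  expected age of diagnosis
  `m = Σ S_a I_a a / Σ S_a I_a` (ages 30–90);
- six grouped scores (Demographic, Family, Mole, Susceptibility,
  Exposure, Miscellaneous) plus the PRS.

Evaluation covers ROC/PR AUC, odds ratio per SD, percentile-bin tail
enrichment against the middle band, per-bin age of diagnosis, and — in
follow-up data — expected vs observed 2-year incidence per stratum,
with small-cell masking throughout.  See `docs/methods.md` for the
complete account.

## Worked example

```python
import numpy as np
from dermrisk import association_power
from dermrisk.pipeline import RunConfig, run_pipeline
from dermrisk.synthetic import GeneratorConfig, default_variant_effects

# analytic GWAS power at the study's training-set case/control counts
for label, (ca, co) in [("BCC", (14898, 88110)), ("SCC", (7479, 95529)),
                        ("melanoma", (3998, 99010))]:
    print(f"power[{label}] = {association_power(0.1, 1.2, 1e-6, ca, co):.3f}")

# end-to-end run on a generated 5,000-participant cohort
ve = default_variant_effects(200, n_causal=10, effect=np.log(1.6))
gen = GeneratorConfig(n_participants=5000, n_variants=200,
                      variant_effects=ve, seed=3)
report = run_pipeline(RunConfig(generator=gen, seed=3))
for c in ("bcc", "scc", "melanoma"):
    e = report["stages"]["evaluate"][c]["DRS"]
    p = report["stages"]["prs"][c]
    print(f"{c}: PRS variants={p['n_variants']}  AUC(DRS)={e['auc']:.3f}  "
          f"OR/SD={e['or_per_sd']:.2f}  top-bin fold={e['top_bin_fold']:.1f}")
```

prints

```
power[BCC] = 1.000
power[SCC] = 0.977
power[melanoma] = 0.596
bcc: PRS variants=5  AUC(DRS)=0.802  OR/SD=3.84  top-bin fold=10.7
scc: PRS variants=0  AUC(DRS)=0.770  OR/SD=2.89  top-bin fold=7.7
melanoma: PRS variants=0  AUC(DRS)=0.783  OR/SD=2.82  top-bin fold=14.0
```

The power values are the analytic two-sided Wald powers to detect a
MAF-0.1, OR-1.2 variant at significance 1e-6 with each cancer's
training case count: detection is near-certain for BCC and a coin flip
for melanoma, which is why the melanoma PRS selects the fewest
variants.  The pipeline lines are validation-set numbers from the
synthetic cohort: the DRS discriminates well (AUC ~0.8), each SD of
score multiplies the odds roughly threefold, and the top percentile
bin carries an order-of-magnitude higher prevalence than the middle of
the distribution — the long-tail behaviour that motivates composite
scores.  At n = 5,000 only strongly associated variants clear the 1e-6
PRS threshold, so two of the three PRS models are empty; the report
also contains deviance decompositions, DRSA trajectories, expected
onset ages per stratum, and follow-up concordance tables (written as
TSVs when `out_dir` is set).

A CLI mirrors the library: `dermrisk simulate|prs|fit|score|evaluate|`
`trajectory|run`, e.g.

```bash
dermrisk run --n 5000 --variants 200 --seed 3 --out results/demo
```

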