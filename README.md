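# mirsig

Discovery and evaluation of miRNA prognostic signatures by
bootstrap-stability LASSO-Cox selection.

## The problem

Advanced-cancer cohorts treated with standard first-line chemotherapy
show widely varying progression-free survival (PFS), and expression-based
signatures are a standard route to stratifying patients into low- and
high-risk groups before treatment.  The discovery recipe this package
implements — common in miRNA biomarker studies of colorectal and other
cancers — chains:

1. a **paired differential-expression screen** on tumour vs adjacent
   normal tissue (empirical-Bayes moderated t, Benjamini–Hochberg FDR);
2. a **univariate Cox screen** of the surviving features against PFS
   (Wald p < 0.1);
3. **LASSO-Cox bagging**: B = 1000 bootstrap resamples, each fitting an
   L1-penalized Cox path `min −(1/n)ℓ(β) + λ‖β‖₁` with 10-fold
   cross-validated partial-likelihood deviance and the 1-SE rule; the
   **RMIP** (resample model inclusion proportion) of a feature is the
   fraction of resamples in which it carries a nonzero coefficient;
4. a **risk signature**: unpenalized Cox refit of the top-k features by
   RMIP (k = 2 by default), risk score = Σ βⱼxⱼ, dichotomized at the
   training-set median (validation cohorts reuse the training cutoff);
5. **evaluation**: Kaplan–Meier curves with median PFS and log-rank
   tests, response-by-risk contingency tables with progressive rates,
   interaction Cox models, and time-dependent ROC AUC under
   inverse-probability-of-censoring weighting.

All survival machinery (Cox partial-likelihood fitting, KM/Greenwood,
log-rank, the penalized path with exact KKT verification) is implemented
in the package and cross-checked in the test suite against independent
oracles (lifelines, scikit-survival's coxnet, Bioconductor limma,
brute-force enumeration).  Because real qRT-PCR cohort data of this kind
are typically not public, the package ships a synthetic-study generator
with known ground truth (planted fold-changes, planted hazard
coefficients, calibrated censoring, response categories linked to risk)
so the whole chain is exercisable and verifiable end to end.

## Worked example

```python
import json
from mirsig import PipelineConfig, SimulationDesign, run_pipeline, simulate_study

design = SimulationDesign(n_features=220, de_fraction=0.15).scaled_effects(8.0)
study = simulate_study(design, seed=7)          # 21 tissue pairs + 67/40/44 patients
config = PipelineConfig(seed=7, B_resamples=200)
run_pipeline(config, study, "signature_run")

report = json.load(open("signature_run/report.json"))
```

Summarizing `report.json` (signature, then per-cohort medians, log-rank
p and 12-month AUC) gives:

```
signature features: ['miR-0001', 'miR-0002']
coefficients: [-1.91, 0.514]
training median cutoff: -9.575
training: median PFS low 35.802 / high 3.661 months, log-rank p 5.9e-08, AUC(12m) 0.93
internal: median PFS low 18.898 / high 2.651 months, log-rank p 1.5e-06, AUC(12m) 0.90
external: median PFS low 13.707 / high 2.4 months, log-rank p 1.1e-07, AUC(12m) 0.90
```

Reading it: the bagging stage ranked the two planted prognostic features
(`miR-0001`, `miR-0002`) first by RMIP out of the 33 candidates that
survived the screens; the refit coefficients recover the planted
direction (protective and harmful, respectively); and in all three
cohorts the high-risk half of the patients — split at the training
median risk score — progresses far earlier than the low-risk half, with
a 12-month AUC near 0.9.  `signature_run/` also holds the per-stage
artifacts: `de_result.tsv`, `cox_screen.tsv`, `rmip.tsv` (sorted by
RMIP), `signature.json`, `report.json`, and a `manifest.json` with
SHA-256 digests proving two same-seed runs are byte-identical.

The same chain is available from the shell:

```sh
mirsig simulate --seed 7 --out-dir fixtures/
mirsig run-all --fixture-dir fixtures/ --seed 7 --out-dir signature_run/
```

with per-stage subcommands (`de-screen`, `cox-screen`, `select`,
`fit-signature`, `evaluate`) for running stages individually.

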