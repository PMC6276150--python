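# erisk

Estrogen-receptor-specific breast cancer absolute-risk modelling on
synthetic prospective cohorts.

Most breast cancer (BC) risk prediction models treat BC as a single
outcome, although ER+ and ER− tumours are etiologically distinct:
reproductive history and body height are associated with ER+ tumours only,
while menopausal factors, hormone replacement therapy (HRT), BMI and
alcohol act similarly on both subtypes. `erisk` implements the full
methodology needed to build, validate and appraise ER-specific risk
models, for biostatisticians and epidemiologists who want a tested,
reproducible reference implementation:

- **Cause-specific piecewise-exponential hazards** on the age scale with
  cutoffs at 45, 50, 55, 60, 65, 70 and 75 years. ER+ and ER− tumours are
  mutually competing causes fitted *jointly*; each covariate coefficient is
  either shared between the two causes or cause-specific, realised by
  design-matrix aliasing so the likelihood-ratio test for etiologic
  heterogeneity, `2(ll_free − ll_shared) ~ χ²_df`, is valid.
- **Gompertz competing events**: tumours of unknown ER status, other
  primary cancers and non-cancer deaths are pooled into one competing
  channel with hazard `h(t) = exp(α + γt)`, fitted by left-truncated MLE.
- **Competing-risks absolute risk**: the 5-year cumulative incidence
  `P_k(a, 5) = ∫ h_k(t) S(a, t) dt` is evaluated by exact piecewise
  integration, with external recalibration that combines the source
  cohort's coefficients with a target cohort's baseline hazards.
- **Validation**: fivefold cross-validated and external C-statistics
  (horizon-truncated Harrell concordance), expected-to-observed ratios
  (E/O) with log-Poisson confidence intervals, decile calibration tables.
- **Decision curve analysis**: net benefit
  `NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t)` against treat-all/treat-none, the
  benefit-to-harm threshold algebra `p_t·B = (1−p_t)·H`, and the clinical
  *applicability area* between a model's curve and the extreme-strategy
  envelope.
- **Synthetic cohorts** with the covariate codings, published hazard
  ratios as ground truth, ~25% of tumours relabelled unknown-ER, and
  administrative censoring — so every stage is testable without access to
  individual cohort data.
- **Chained-equations multiple imputation** with Rubin pooling for missing
  risk factors.

## Worked example

```python
import numpy as np
from erisk import (
    simulate_cohort, default_model_spec, split_person_time,
    fit_piecewise, fit_gompertz, lrt_heterogeneity, project_risks,
)

cohort = simulate_cohort(50_000, seed=1)          # synthetic derivation cohort
spec = default_model_spec()                       # height & parity cause-specific
model = fit_piecewise(split_person_time(cohort, spec.cutoffs), spec)
gomp = fit_gompertz(cohort)

hr = np.exp(model.coef("shared:menopausal_status=post"))
pct = 100 * (np.exp(model.coef("er_pos:height_cm")) - 1)
print(f"postmenopausal vs premenopausal HR: {hr:.2f}")
print(f"ER+ hazard increase per 10 cm height: {pct:+.1f}%")

risks = project_risks(model, gomp, cohort, horizon=5.0)
print(f"mean 5-year ER+ risk: {risks.risk_er_pos.mean():.4f}")
```

prints (seed 1):

```
postmenopausal vs premenopausal HR: 0.78
ER+ hazard increase per 10 cm height: +25.9%
mean 5-year ER+ risk: 0.0060
```

The HR of 0.78 estimates the protective association of being
postmenopausal (with menopause at ≤45) at recruitment, age held fixed by
the piecewise baseline; the generating value is 0.66. The height effect
(generating value +19% per 10 cm for ER+ tumours) is one of the
coefficients allowed to differ between ER+ and ER− tumours; with roughly
1,300 recorded ER+ tumours at this cohort size both estimates sit within
sampling error of the truth (about 1.5 standard errors here). The mean
projected 5-year ER+ risk of about 0.6% reflects the simulated incidence
after exclusion of tumours recorded with unknown receptor status.

The same pipeline is scriptable from the shell:

```bash
erisk simulate --n 50000 --seed 1 --out cohort.csv
erisk fit --cohort cohort.csv --out model.json
erisk project --model model.json --cohort cohort.csv --out risks.csv
erisk validate --mode cv --cohort cohort.csv --seed 1 --out report.json
erisk dca --risks risks.csv --cohort cohort.csv --out-prefix dca
erisk run --config examples/pipeline.yaml     # everything, with a manifest
```

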