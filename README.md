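# emodyad

Analysis toolkit for **dyadic daily-diary emotion studies**: it scores
each person's *mean emotion* and *emodiversity* (the breadth and
relative frequency of distinct emotions) from 14-day evening diaries of
adolescent–caregiver dyads, and links those features to each member's
anxious and depressive symptoms with **bivariate actor–partner
interdependence models (APIM)** estimated by full-information maximum
likelihood with sandwich (robust) standard errors.

It is written for researchers running intensive longitudinal family
studies who want a scriptable, tested alternative to SEM point-and-click
workflows, plus a synthetic-cohort generator with known ground truth for
validating every stage.

## The measures and the model

Each evening, both dyad members rate 16 emotion adjectives (7 negative,
9 positive) on a 0–4 frequency scale. Per valence:

- **daily composite** — mean of that day's available items;
- **mean emotion** — mean of daily composites across days;
- **emodiversity** — with `c_j` the ratings of emotion `j` summed over
  days, sorted non-decreasingly, and `m` categories:

  `Gini = 1 − [ 2 Σ_j j·c_(j) / (m Σ_j c_(j)) − (m+1)/m ]`

  1 means all `m` emotions were reported equally often; the minimum
  `1/m` means every report concentrated on a single emotion.

The four standard models cross valence (negative/positive) with symptom
(anxious/depressive). In each, both members' symptom scores are
regressed on six dyad-level terms — each member's mean emotion,
emodiversity, and their (centered) product — with correlated residuals
between partners:

```
y_adol = b0 + b1·a_mean + b2·a_div + b3·a_mean×a_div
            + b4·c_mean + b5·c_div + b6·c_mean×c_div + e_adol
y_cg   = (same six terms) + e_cg,     cov(e_adol, e_cg) free
```

Every path is free (just identified), so complete-data ML equals
per-equation least squares; dyads missing one symptom contribute the
univariate marginal of the observed one (FIML). Inference uses the
sandwich covariance `A⁻¹BA⁻¹` from per-dyad scores; paths are reported
standardized (β = b·SD(x)/SD(y)) with delta-rule SEs, and interactions
are unpacked as conditional-effect curves with delta-method bands.

## Worked example

```bash
emodyad simulate --outdir sim --seed 4 --n-dyads 175
emodyad all --config analysis.yaml
```

with `analysis.yaml`:

```yaml
outdir: run
seed: 4
diary_path: sim/diary.csv
baseline_path: sim/baseline.csv
min_days: 6
```

Or in Python:

```python
import pandas as pd
from emodyad import (SyntheticConfig, generate_dyads, apply_exclusions,
                     summarize_dyads, ApimSpec, build_design, fit_apim,
                     robust_se, standardize)

dyads, truth = generate_dyads(SyntheticConfig(n_dyads=175, seed=4))
retained, report = apply_exclusions(dyads, min_days=6)
summaries = summarize_dyads(retained)
base = pd.DataFrame([vars(b) for d in retained
                     for b in (d.adolescent_baseline, d.caregiver_baseline)])
design = build_design(summaries, base, ApimSpec("negative", "anxious"))
fit = standardize(robust_se(fit_apim(design), design), design)
print(f"retained {report.n_retained_dyads}/{report.n_input_dyads} dyads")
print(fit.summary_table().round(3).to_string(index=False))
```

which prints (seed 4):

```
retained 175/175 dyads
outcome         path      b   beta  se_beta      z     p  ci_low  ci_high
 y_adol       a_mean  0.378  0.273    0.085  3.211 0.001   0.106    0.439
 y_adol        a_div  0.848  0.146    0.105  1.384 0.166  -0.061    0.352
 y_adol a_mean_x_div  1.269  0.091    0.080  1.141 0.254  -0.065    0.248
 y_adol       c_mean -0.086 -0.047    0.087 -0.537 0.591  -0.217    0.124
 y_adol        c_div  0.328  0.061    0.098  0.623 0.534  -0.131    0.253
 y_adol c_mean_x_div  1.215  0.072    0.069  1.041 0.298  -0.064    0.208
   y_cg       a_mean -0.000 -0.000    0.078 -0.001 0.999  -0.154    0.154
   y_cg        a_div -0.092 -0.024    0.085 -0.278 0.781  -0.189    0.142
   y_cg a_mean_x_div  0.129  0.014    0.067  0.207 0.836  -0.117    0.144
   y_cg       c_mean  0.469  0.380    0.094  4.057 0.000   0.197    0.564
   y_cg        c_div  0.429  0.119    0.105  1.129 0.259  -0.087    0.325
   y_cg c_mean_x_div  1.763  0.156    0.077  2.012 0.044   0.004    0.308
```

Here the cohort was generated with true actor effects of mean negative
emotion of 0.5 (adolescent) and 0.55 (caregiver), smaller true actor
emodiversity and interaction effects (0.1), and null partner effects.
At n = 175 the two mean-emotion actor paths are the clearly flagged
effects (b = 0.38 and 0.47, p ≤ .001, each within ~1.5 robust SEs of
truth), the small actor effects hover near their detection threshold
(e.g. the caregiver interaction at p = .044), and every partner path —
truly zero — stays null. `truth` carries all generating values, so any
run can be checked this way.

The pipeline additionally writes the exclusion report, per-person
summary table, a starred descriptives/correlation table, four
standardized path tables, and conditional-effect curve CSVs (99% bands
by default) into the output directory, plus a `manifest.yaml` with
checksums of every output.

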