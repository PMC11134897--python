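# hrvreact

Heart-rate-variability (HRV) reactivity analysis for early cardiotoxicity
screening in cardio-oncology.

Patients starting cardiotoxic chemotherapy (anthracyclines, HER2-targeted
therapy) can develop cancer-therapy-related cardiac dysfunction (CTRCD)
months before the ejection fraction falls.  One candidate early marker is
*autonomic reactivity*: how strongly beat-to-beat heart-rate variability
responds to controlled physiological challenges.  `hrvreact` implements the
full desk pipeline for that analysis, aimed at biosignal/biostatistics
researchers working with RR-interval recordings:

* a synthetic cohort generator emulating the three-condition protocol
  (supine rest, active standing, 0.1 Hz paced breathing; ~10 min each) at
  two timepoints, with echocardiographic strain panels and troponin flags;
* NN-interval preprocessing: ectopic/artifact exclusion and stable-segment
  selection (300 consecutive NN intervals after an initial 180 s skip);
* the standard index panel per segment: mean NN/HR, SDNN, pNN50, Welch-based
  LF/HF band powers with normalised units and log10(LF/HF), and Poincaré
  SD1/SD2 with both ratio conventions;
* per-subject reactivity deltas Δ = maneuver − supine for every index;
* ROC evaluation of each Δ as a cardiotoxicity predictor: trapezoidal AUC
  with tie handling, Hanley–McNeil CI and test of AUC = 0.5, and the optimal
  cut-off by minimal distance to the ideal corner (0, 1), reported with
  sensitivity/specificity;
* cohort statistics: KS-gated log10 transform, t-tests, repeated-measures
  ANOVA, chi-squared/Fisher, Pearson correlation tables, and the clinical
  classification rules (LASr significant reduction; echo/troponin CTRCD
  labels).

The science and every convention are documented in
[docs/methods.md](docs/methods.md).

## Worked example

```python
import numpy as np
from hrvreact import (SimConfig, SUPINE, BREATHING, BASELINE,
                      clean_to_nn, select_segment, compute_all, compute_deltas)
from hrvreact.simulate import draw_subject_params, generate_rr_series
from hrvreact.study import cohort_deltas
from hrvreact.roc import analyze

config = SimConfig(seed=42)          # 50 subjects, 46% cardiotoxicity arm
params = draw_subject_params(config, 0)
indexes = {}
for condition in (SUPINE, BREATHING):
    series = generate_rr_series(config, params, condition, BASELINE, subject_index=0)
    cleaned = clean_to_nn(series)
    segment = select_segment(cleaned.series, L=300, skip_s=180.0)
    indexes[condition] = compute_all(segment)

deltas = compute_deltas(indexes)
scores, is_case = cohort_deltas(config, index="sdnn_ms", maneuver=BREATHING)
result = analyze(scores, is_case, name="sdnn_ms", maneuver=BREATHING)
```

This prints (via the formatting in the snippet's long form):

```
supine    SDNN  27.00 ms   LF   331.3 ms^2   SD1  19.27 ms   (excluded 2)
breathing SDNN  59.53 ms   LF  3354.7 ms^2   SD1  23.63 ms   (excluded 8)
delta SDNN (breathing) = +32.53 ms
AUC 0.997 (95% CI 0.978-1.000), p 0, cutoff ≤ 19.6394, sens 95%, spec 100%
```

Reading it: paced breathing at 0.1 Hz entrains large slow oscillations, so
this control-arm subject's SDNN roughly doubles (Δ = +32.5 ms) and LF power
rises an order of magnitude.  Cardiotoxicity-arm subjects, whose
condition-induced parameter changes are attenuated (λ = 0.3), show much
smaller deltas, so across the cohort the breathing SDNN delta separates the
arms almost perfectly: subjects with Δ ≤ 19.6 ms are flagged, catching 95%
of cases while keeping all controls.

## Command line

```bash
hrvreact simulate --show-defaults            # print the generator defaults
hrvreact simulate --out-dir data --seed 1    # tachograms + cohort.csv
hrvreact validate data                       # dialect/completeness report
hrvreact run --out-dir results --seed 1      # full pipeline + manifest
```

`run` writes `indexes.csv`, `deltas.csv`, `roc_table.csv` (one row per
index × maneuver), summary and comparison tables, correlation matrices, and
a `manifest.json` with the config snapshot and a SHA-256 digest of every
output; identical config + seed reproduces identical digests.  Per-stage
tools (`preprocess`, `indexes`, `deltas`, `roc`, `stats`) operate on the
same plain-text tachogram and CSV formats.

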