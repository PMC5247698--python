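# steatoquant

Digital image analysis of liver steatosis for histopathology research:
measured fat proportionate area (mFPA) from H&E-stained biopsy fields,
hepatocyte/lobule morphometry, and the non-parametric cohort statistics
that relate fat content to serum transaminases.

Steatosis — fat accumulation in hepatocytes — is conventionally called
abnormal above 5% of the liver parenchyma, yet subjective visual grading of
that percentage is unreliable. This package implements the quantitative
alternative: segment the near-white fat vacuoles out of calibrated RGB
microscope fields, measure fat as an area proportion of parenchyma, relate
it to hepatocyte swelling and lobule expansion, and test how transaminase
elevations track fat brackets. Because real biopsy archives cannot be
redistributed, the package ships a first-class synthetic-data module that
renders ground-truthed H&E-like fields and draws patient cohorts with a
programmed correlation structure, so every stage of the pipeline is
verifiable end to end.

## The measurements

**mFPA.** A pixel is a fat candidate when all three colour channels sit at
or above a whiteness threshold (default 200/255). Connected components are
filtered by an area window (20–8000 µm²) and circularity
(4π·area/perimeter² ≥ 0.5); elongated sinusoids and oversized vessel lumens
fail the filters and are excluded from *both* the fat numerator and the
parenchyma denominator — an automated stand-in for a pathologist's manual
editing, with a manual exclusion mask also supported. Per biopsy, fields
are pooled:

    mFPA = 100 · Σ fat area / Σ parenchyma area   (over 21 sampled fields)

**Morphometry.** A hepatocyte measured along two perpendicular diameters
d₁, d₂ has area A = π·d₁·d₂/4 (ellipse). The lobule is idealised as a
regular hexagon whose radius R is the portal-tract-to-central-vein
distance, giving a hepatocytes-per-lobule approximation

    HpL = (3√3/2)·R² / HA

with HA and R taken as per-biopsy medians (an apothem convention,
2√3·R²/HA, is available behind a switch; the two differ by exactly 4/3).

**Statistics.** Spearman rank correlations (exact permutation p for n ≤ 9),
Mann–Whitney U (exact null for tie-free n ≤ 14, tie/continuity-corrected
normal approximation otherwise), Kruskal–Wallis across the mFPA brackets
<5 / 5–9.9 / 10–19.9 / ≥20 %, and ROC curves with trapezoidal AUROC —
which equals the concordance probability P(score⁺ > score⁻) + ½P(equal) —
plus sensitivity/specificity at clinical transaminase cut-offs
(31, 33, 41, 67, 75 U/L).

## Worked example

```python
from steatoquant import CohortSpec, cohort_report, generate_cohort

cohort = generate_cohort(CohortSpec(n_patients=136, seed=42))
report = cohort_report(cohort)
```

Running `python examples/cohort_statistics.py` (which does exactly this)
prints:

```
bracket occupancy: {'<5': 74, '5-9.9': 26, '10-19.9': 24, '>=20': 12}

Spearman correlation with mFPA (pooled):
  ha_um2   rs = +0.837  p = 7.5e-37
  lr_um    rs = +0.717  p = 8.8e-23
  alt_u_l  rs = +0.276  p = 0.0011
  ast_u_l  rs = +0.239  p = 0.0052

ALT medians by mFPA bracket (U/L):
  <5       55 (38-78)
  5-9.9    65 (42-97)
  10-19.9  75 (41-107)
  >=20     108 (82-170)
  Kruskal-Wallis across brackets: H = 12.4, p = 0.006

ALT as a test for >=5% steatosis:
  AUROC = 0.63
```

Hepatocyte area correlates strongly with fat content, transaminases
weakly; ALT medians climb across the fat brackets; and ALT alone is a
poor-to-fair screening test for 5% steatosis — the qualitative picture the
analysis is designed to expose. Other example scripts cover single-field
segmentation against ground truth, 21-field biopsy pooling with the
adequacy check, lobule geometry, and the full pipeline.

A CLI mirrors the library for shell use:

```bash
steatoquant simulate field --fat 0.1 --seed 7 --out fields/
steatoquant simulate cohort --n 136 --seed 7 --out cohort.csv
steatoquant mfpa --fields fields/ --n 1 --out biopsy.json
steatoquant cohort-report --in cohort.csv --out report.json
steatoquant run-all --seed 7 --out run/
```

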