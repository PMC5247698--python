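# Methods

This note records the models, parameter choices and numerical conventions
behind `steatoquant`, and what the synthetic-data validation does and does
not establish about real histology.

## Fat segmentation model

Fat vacuoles in an H&E section are optically empty, so they appear
near-white in every colour channel while eosin-stained cytoplasm is pink
and haematoxylin-stained nuclei are blue-purple. Segmentation is a joint
channel threshold: a pixel is a fat candidate when R, G and B all sit at or
above the configured bounds (default 200/255 each). The threshold default
sits roughly midway between typical eosin pinks (red ≈ 200 but green/blue
far lower) and vacuole white (≥ 235 in all channels); it is exposed in
`SegmentationParams` because staining intensity varies between
laboratories and scanners.

Candidate components (8-connected throughout) are then triaged:

- **Off-section background**: components touching the field border and
  covering more than 10% of the field are slide background, removed from
  the tissue entirely (they are neither fat nor parenchyma). The size
  floor distinguishes a section edge from a vacuole that merely lies near
  the border.
- **Area window** (default 20–8000 µm²): objects smaller than a
  microvesicle are noise; objects larger than any plausible vacuole
  (a 100 µm-diameter circle is ~7850 µm²) are vessel lumens or tears.
- **Circularity** (4π·area/perimeter², default floor 0.5, perimeter from
  the 8-connected contour): vacuoles are near-circular; dilated sinusoids
  are elongated ribbons scoring far below the floor.

Components failing the filters move to an exclusion mask and leave both
the numerator and the denominator of the fat fraction, an automated proxy
for the manual artifact editing a pathologist performs; a user-supplied
exclusion mask is honoured the same way and always wins. Holes inside
candidate components are filled by default (a nucleus overlapping a
vacuole should not punch a hole in it).

Per-biopsy mFPA pools areas over the sampled fields —
`100·Σfat/Σparenchyma` — rather than averaging per-field ratios, because
the quantity is defined as a single area proportion; fields with more
usable tissue therefore weigh more. The two aggregations coincide exactly
when parenchyma areas are equal.

**Field-count adequacy.** The conventional sampling depth is 21 randomly
selected non-overlapping fields per biopsy at ×20 magnification. The
published account of how that number was selected is not available to this
package, so `adequacy_check` implements a reconstruction, labelled as
such: the running pooled estimate after k fields is deemed adequate when
it moved by at most 0.5 percentage points (configurable) over the last 5
added fields. It is a stopping heuristic, not a test.

## Morphometry model

Hepatocyte area is an ellipse through two perpendicular diameters,
π·d₁·d₂/4; per-biopsy HA is the median over sampled cells (50 recommended;
fewer warns). Lobule radius is the median portal-tract-to-central-vein
distance. Hepatocytes per lobule divides the idealised hexagonal lobule
cross-section by HA. Whether the measured distance is the hexagon's
circumradius or its apothem is genuinely ambiguous in the field's usage;
the default is **circumradius** (area (3√3/2)·R²) because a portal tract
sits at a lobule corner, which is the circumradius endpoint, with the
apothem convention (2√3·a²) behind a switch. The two differ by exactly
4/3. HpL is a 2-D areas ratio on the section plane; no stereological 3-D
correction is attempted, and it should be read as an index, not a count.
Even-length medians are the midpoint of the central pair.

## Statistical conventions

- **Spearman**: average ranks for ties; exact two-sided p by full
  vectorised permutation enumeration for n ≤ 9 (9! = 362 880 pairings),
  the t approximation above.
- **Mann–Whitney U**: exact null when the pooled sample is tie-free and
  n ≤ 14, otherwise the normal approximation with tie and continuity
  corrections. The U reported is for the first group.
- **Kruskal–Wallis**: H with tie correction, chi-square p on k−1 df; an
  optional seeded Monte-Carlo permutation p for small samples.
- **ROC**: positive call at score ≥ threshold, thresholds sweeping +∞ then
  every unique score; AUROC by trapezoid, which equals the tie-adjusted
  pairwise concordance probability. Sensitivity/specificity are reported
  at configurable transaminase cut-offs, defaulting to 31/33/41/67/75 U/L
  (the conventional AST and ALT upper normal limits and higher working
  cut-offs).
- **Brackets**: <5, 5–9.9, 10–19.9, ≥20 % mFPA, boundaries assigned
  upward (5.0% is steatotic). The edges are config-locked: the analysis is
  defined over exactly this partition.
- **Multiplicity**: adjacent-bracket pairwise p-values are reported raw,
  matching standard practice in this literature; a Holm adjustment is
  available but off by default.
- Missing biochemistry is handled by pairwise-complete deletion per
  analysis.

## Synthetic fields

The field generator emulates a ×20-objective capture: default 512×512 px
at 0.5 µm/px. All geometry is parametrised in microns and rasterised last,
so a seed fixes the physical scene independently of pixel calibration
(halving the resolution changes the measured fraction only by
rasterisation error). Vacuoles are non-overlapping discs with diameters
drawn uniformly from 10–80 µm — spanning micro- to macrovesicular
droplets; the real vacuole size distribution in steatotic biopsies is not
well documented, so this range is a modelling choice. Discs are placed by
rejection sampling, largest first (which packs dense targets reliably),
with the final disc shrunk to close the remaining area budget; the target
fraction is defined against parenchyma (non-artifact tissue) and is
achievable up to a hard 0.6 packing bound, beyond which, or after 2000
failed placements for any disc, generation fails loudly naming the
fraction achieved.

Colours: parenchyma ≈ RGB (200, 120, 150) with Gaussian jitter clipped at
195 per channel, nuclei ≈ (80, 60, 140) speckle at ~2000/mm², vacuoles and
artifacts ≥ 235 grey-white. The clip guarantees no stained pixel can pass
the default whiteness rule, so at `artifact_density = 0` the segmentation
ground truth equals the rendered disc pixels *exactly* — recovery tests
are pixel-sharp, not approximate. Artifacts come in two kinds, Poisson in
number: elongated sinusoid ribbons (capsules ~0.3–0.6 field lengths long,
4–8 µm wide — low circularity by construction) and round vessel lumens
(radius 56–90 µm — above the area window by construction).

What passing on these fields does **not** show: robustness to staining
variation, blur, uneven illumination, touching/merged vacuoles, fibrosis,
or ballooned hepatocytes. The segmentation defaults are meaningful for
typical H&E but must be re-tuned per laboratory on real material.

## Synthetic cohorts

The cohort generator draws the patient table the statistics consume.
Fat fraction is sex-specific truncated log-normal (medians 7% male / 3%
female, σ_log = 1.2, truncated at 40%, male fraction 78/136 ≈ 0.57),
giving a pooled median near 5% with a right-skewed IQR of roughly 1.7–9.5%
and all four brackets occupied at n = 136. Linked variables follow
monotone mean-response curves plus noise:

- HA: 260 + 200·(1 − e^(−m/12)) µm², additive Gaussian noise σ = 35.4 —
  hepatocytes keep swelling across the observed fat range;
- LR: 455 + 115·(1 − e^(−m/5.5)) µm, additive σ = 41.4 — the lobule
  expands early and plateaus above ~10% mFPA;
- ALT: 50·e^(0.036·min(m,30)) U/L, log-scale σ = 0.59;
- AST: 33·e^(0.013·min(m,30)) U/L, log-scale σ = 0.475.

Transaminase (and GGT/bilirubin/ALP) noise is applied on the log scale so
the marginals stay positive and right-skewed with realistic medians/IQRs
(ALT 60 (39–93), AST 35 (26–50), GGT 78 (46–140), bilirubin 11 (7–15),
albumin 47 (45–49) normal, ALP 82 (68–118)). The noise scales were
calibrated once by large-sample simulation so the population Spearman
correlations with mFPA are 0.816 (HA), 0.64 (LR), 0.358 (ALT) and 0.198
(AST) — the correlation structure the analysis is designed to detect.
HpL is never sampled: it is computed per patient from LR and HA through
the hexagon model, so its negative association with fat (lobule plateau +
continued hepatocyte swelling → HpL decline through the 10–19.9% bracket)
is an emergent consequence of the link shapes, which is exactly what the
trend-recovery tests probe. GGT, bilirubin, albumin and ALP are drawn
independently of fat content.

One RNG per call, seeded explicitly; equal seeds give bit-identical
fields, cohorts, and end-to-end report tables (output files embed the
config hash and seed).

## Problem sizes used in validation

The shipped validation runs use 21 fields of 512² px per biopsy at five
fat fractions for recovery; 50 seeded 256² fields for artifact rejection;
100 random instances (n ≤ 200) for the AUROC/concordance identity; every
tie-free Mann–Whitney configuration up to n = 12 against full enumeration;
2000 null replicates at n = 30/group for empirical test size; and 100
seeded n = 136 cohorts for trend recovery. These sizes make the checks
sharp while keeping a full run in the order of a minute on one CPU.

## Known limitations

- The editing proxy is shape-based; artifacts that are both white and
  vacuole-shaped (small round vessel cross-sections in the vacuole size
  range) cannot be distinguished without context a human editor has.
- HpL inherits every idealisation of the hexagon model and both of its
  radius conventions; absolute values should not be compared across
  conventions or with stereological counts.
- The cohort generator reproduces marginals and rank correlations, not the
  joint distribution of a real clinic population (no age–fat interaction,
  no comorbidity structure, biochemistry independence where real data may
  covary).
- p-values from the asymptotic Mann–Whitney path at very small bracket
  sizes (n < 10) are approximate; the exact path covers only tie-free
  small samples, and a Monte-Carlo Kruskal–Wallis option exists for that
  regime.
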