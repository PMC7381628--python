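# shapenum

An EEG/ERP analysis toolkit for visual numerosity experiments in which small
sets of Gaussian-blob elements (3–6) are arranged either on the vertices of
simple shapes (triangle, square, pentagon, hexagon) or at random positions,
with controllable luminance polarity. It is aimed at cognitive
neuroscientists who want a fully testable, simulation-backed implementation
of the classical ERP analysis chain for this paradigm:

- **stimulus generation** — vertex, contour and interior element placement
  under a minimum-spacing constraint, balanced randomized trial schedules,
  luminance rendering;
- **synthetic recordings** — 64-channel / 1 kHz EEG with planted evoked
  components, autocorrelated spatially-structured noise, stereotyped eye
  blinks with known scalp propagation, gross artifacts, and trial-level
  accuracy/RT with planted condition effects, so every downstream stage can
  be validated by parameter recovery;
- **preprocessing** — zero-phase 0.1–30 Hz Butterworth filtering (12 and
  48 dB/octave slopes), regression-based ocular correction, −100…1000 ms
  epoching with baseline subtraction, ±75 µV artifact rejection, and
  common-average-referenced grand averages;
- **component statistics** — mean amplitudes of the posterior N1
  (160–220 ms) and N2 (250–400 ms) over P7/PO5/PO7 | P8/PO6/PO8 and of a
  left mid-frontal (LMF) component (400–650 ms) over FC1/FC3/C1/C3, with
  repeated-measures ANOVAs (Greenhouse–Geisser correction, partial η²) and
  Bonferroni post-hocs;
- **topographic statistics** — global field power
  GFP = √(K⁻¹ Σᵢ (uᵢ − ū)²), global dissimilarity
  DISS(u, v) = √(K⁻¹ Σᵢ (uᵢ/GFPᵤ − vᵢ/GFP_v)²) = √(2(1 − r)), and a
  point-wise within-subject randomization TANOVA with a 10 ms stability
  criterion;
- **microstate segmentation** — atomize-and-agglomerate hierarchical
  clustering (AAHC, polarity-sensitive) of concatenated grand averages,
  template-count selection by the cross-validation criterion
  CV(q) = σ̂²·((K−1)/(K−1−q))², and winner-take-all back-fitting quantified
  as global explained variance GEV_m = Σ_{t:L_t=m}(GFP_t·r_t)² / Σ_t GFP_t².

## Worked example

Run the full pipeline on a simulated 19-subject sample of the
shape-vs-random experiment:

```python
from shapenum.pipeline import PipelineConfig, run

cfg = PipelineConfig(experiment=1, n_subjects=19, seed=1,
                     tanova_permutations=1000)
report = run(cfg)
```

With this seed the report contains (abridged):

```text
N2 configuration effect: F(1,18) = 265.79, p = 3.17e-12, partial eta2 = 0.937
LMF numerosity effect:   F(3,54) = 105.47, eps = 0.949, p = 1.54e-21
N2 shape - random: -1.52 uV
LMF means by numerosity: {3: 3.05, 4: 2.31, 5: 1.65, 6: 1.55}
LMF 5 vs 6 (Bonferroni): p = 1.000
TANOVA configuration windows (ms): [(244.0, 410.0)]
microstates selected q*: 5
```

Reading: the shape configuration deepens the N2 negativity by ~1.5 µV
(exactly the planted gap); the left mid-frontal component orders
numerosities 3 > 4 > 5 ≈ 6, with the 5-vs-6 post-hoc null as planted; the
TANOVA flags a stable topographic difference covering the N2 window, where
the simulation plants a genuine map-shape difference between conditions;
and segmentation recovers the planted generators (template correlations
> 0.999 in `report.recovery`).

The same stages are available from a shell:

```bash
shapenum stimgen --experiment 1 --reps 100 --seed 1 --out out/stim
shapenum simulate --experiment 1 --subjects 2 --reps 10 --seed 1 --out out/sim
shapenum run --experiment 1 --subjects 19 --seed 1 --out out/run
```

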