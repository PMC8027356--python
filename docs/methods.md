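# Methods

## The measurement being modelled

Oxygen-gradient ektacytometry records the elongation index (EI) of a sheared
red-blood-cell suspension — the axis ratio of its elliptical laser
diffraction pattern, a dimensionless deformability readout in [0, 1) —
through one controlled oxygen cycle: a fully oxygenated plateau, a slow
nitrogen-driven deoxygenation (nominally 1,300 s), and a rapid
reoxygenation (nominally 280 s), all at 30 Pa shear and 37 °C. In sickle
cell anemia, HbS polymerizes as pO₂ falls, cells sickle and the EI drops;
on reoxygenation most cells recover. Four scalars summarise a curve:

| parameter | definition | meaning |
|---|---|---|
| EI_max | max smoothed EI at pO₂ 100–150 mmHg on the pre-deoxygenation plateau | arterial-circulation deformability |
| EI_min | min smoothed EI at pO₂ < 20 mmHg during deoxygenation | deformability at venous-like hypoxia |
| PoS | pO₂ of the first *sustained* drop of smoothed EI to 95 % of EI_max | oxygen tension where sickling accelerates |
| Recovery | post-reoxygenation EI maximum as % of EI_max | reversibility of sickling |

EI_max is read from the pre-deoxygenation plateau *only*. This is
deliberate: Recovery compares the reoxygenation window against that
baseline and can exceed 100 % when poorly deformable cells lyse during the
run, raising the surviving population's average deformability. A global
maximum would cap Recovery at 100 % and erase that effect.

## Extraction procedure and numerical choices

* **Smoothing** — rolling median, default window 11 samples, applied
  identically before every extractor. The median is robust to
  diffraction-readout spikes and preserves plateaus. On a noise-free trace
  smoothing is unnecessary; `smooth_window=1` makes extraction exact.
* **Phase segmentation** — the pO₂ series is smoothed with a wider rolling
  median (default 51 samples, because the deoxygenation ramp is slow
  relative to pO₂ readout noise). The deoxygenation onset is the first
  index starting a run of k = 5 consecutive decreasing samples whose total
  drop is ≥ 0.25 mmHg, *confirmed* by a decline of at least 2 % of the pO₂
  range one smoothing window later — the confirmation step rejects
  noise-only runs on the plateau. The reoxygenation onset is the first
  confirmed sustained rise after it, snapped to the raw-pO₂ minimum in its
  neighbourhood (the ramp corner is sharp in the raw series but blurred by
  the median). On the nominal noiseless cycle the boundaries are exact
  (100 s and 1,400 s).
* **PoS crossing rule** — first sample at or below 0.95 × EI_max that stays
  below for k = 5 consecutive samples; the reported pO₂ is linearly
  interpolated between the bracketing samples on the smoothed pO₂ axis.
  The sustained-run requirement prevents noise-triggered early crossings.
  A curve that never sustains the drop has an *undefined* PoS — a
  first-class outcome (non-sickling cells), flagged and excluded pairwise
  downstream with reported counts, never an error.
* **Degenerate inputs** — monotone pO₂ (no cycle) raises a segmentation
  error; a trace that never reaches pO₂ < 20 mmHg yields a flagged,
  undefined EI_min; Recovery falls back to the final 20 samples (flagged)
  if pO₂ never re-enters the normoxic window.
* Defaults live in one `ExtractionConfig`; the two pO₂ windows
  (100–150 mmHg, < 20 mmHg) are fixed by the assay definition, everything
  else is a robustness parameter.

## Protocol computations

Each run is standardised to 200 × 10⁶ red cells, so the whole-blood volume
is `200 / RBC count` µL with the count in 10⁶ cells/µL. Storage-time QC:
samples analysed 16–32 h post collection are inside the protocol window;
beyond 24 h cold storage may shift EI_max/EI_min (PoS is comparatively
stable), so a caution flag is attached. Flags are advisory annotations
carried into reports, never hard filters.

## The synthetic cohort generator

No raw traces are publicly available for the cohort whose statistics this
package reproduces, so validation is built on a generator that emulates the
cohort's observable structure.

**Biomarkers.** %HbF is a truncated normal on [5.6, 50.6] with the parent
location solved so the *truncated* mean is 23.0 (parent sd 11.5); Hb and
RBC count are handled the same way. %F-cells follows a logistic curve in
log %HbF (the established log-linear HbF/F-cell relationship) plus Gaussian
noise, clipped to the observed range [24, 99.2]; the logistic midpoint is
solved so the simulated mean is 67.7. %DRBCs decays exponentially with
%HbF plus noise, clipped to [0, 4.8] — the clip at 0 reproduces the real
zero-DRBC samples.

**Cell classes.** Each patient's red cells are a three-class mixture, the
minimal set the three biomarkers can drive:

* *F-cells* — protected: high EI ceiling (~0.6), high floor, low sickling
  midpoint; no irreversible fraction, no lysis.
* *non-F sickle cells* — the bulk: sizeable EI drop with a sigmoid
  transition in pO₂; partly irreversible, slightly lysis-prone.
* *dense cells* — dehydrated, rigid: low ceiling, near-zero floor, sickling
  at much higher pO₂; mostly irreversible and strongly lysis-prone.

Each class is an EI-vs-pO₂ sigmoid `L + (U − L)·σ((p − p50)/s)`. The
population EI on deoxygenation is the weight-averaged class EI — the real
instrument averages a diffraction pattern nonlinearly, but modelling optics
is out of scope and the arithmetic mixture preserves the monotone structure
the analysis tests. On reoxygenation each class replays its sigmoid with
its irreversible fraction held at the floor, and lysed fractions are
removed with weight renormalisation — lysis concentrated in the rigid
classes is what produces Recovery > 100 % mechanistically.

**Weights.** Dense weight = `dense_amplification × %DRBC/100` (capped at
0.5). The amplification (calibrated ≈ 6.9) reflects that the measured %DRBC
— cells beyond the MCHC > 41 g/dl cutoff — is the extreme tail of a shifted
density distribution: the poorly deformable subpopulation it proxies is
substantially larger than the counted tail. The F-cell weight is the
F-cell fraction times a logistic "protection" function of %HbF, applied to
the non-dense remainder; the rest are non-F sickle cells. Two further
per-patient effects carry biology the weights alone cannot: the F-cell
floor rises linearly with %HbF (more HbF per F-cell at higher total HbF —
this is what lets EI_min correlate more strongly with %HbF than with
%F-cells, as observed), and all class parameters receive per-patient
Gaussian jitter (variability not captured by the three biomarkers).

**Traces.** pO₂ follows the nominal plateau (100 s at 150 mmHg) / linear
decline to 5 mmHg over 1,300 s / linear rise over 280 s profile at 1 Hz;
per-sample Gaussian noise is added to EI (sd 0.003) and pO₂ (sd 0.3 mmHg).

**Reproducibility.** One master seed; patient *i* uses an independent
substream seeded by `(seed, i)`, so cohorts are bit-identical regardless of
generation order or batching, and the vectorised analytic forward map draws
the very same biomarkers as the full pipeline.

## Calibration

The shipped `default_calibrated.yaml` is the frozen output of
`calibrate_generator`: after solving the marginal means exactly, a
coordinate search over link-noise sds, class-model parameters and jitter
sds minimises the RMS deviation of the nine observable correlations
(3 biomarkers × EI_min/EI_max/PoS) from the published matrix, requiring
every entry within ±0.05. The search evaluates a noise-free analytic
forward map (closed-form EI_max/EI_min, bisection for PoS) rather than full
trace extraction; the extraction step shifts the correlations by < 0.006,
well inside tolerance, because measurement noise is small at the smoothing
defaults. Calibration targets *post-extraction* correlations, so what
attenuation there is, is accounted for. The frozen configuration was
verified on seeds never used during the search (max per-entry deviation
≤ 0.02 at n = 8,000).

Problem sizes used by the shipped checks: correlation recovery at
n = 5,000, marginal means at n = 10,000, sign-pattern stability at n = 500
across 20 seeds — sizes at which Monte-Carlo error (≈ 0.01 on r at
n = 5,000) is small against the ±0.05 contract.

## What passing tests do and do not show

The generator reproduces the *observable* cohort structure: marginal means,
the correlation matrix, its sign pattern, the PoS-threshold behaviour
(%HbF > 30 and %F-cells > 80 ⇒ PoS reliably < 25 mmHg), the EI_max → 0.6
ceiling in the absence of dense cells, and Recovery > 100 % via lysis. It
does **not** model polymerization kinetics, oxygen–hemoglobin dissociation,
2,3-DPG or storage biochemistry, hydroxyurea pharmacodynamics, or the
rhomboid diffraction patterns of deeply deoxygenated sickle cells; the
published per-patient joint distribution is unknown (only marginals and
pairwise correlations are printed), so the joint model is a calibrated
construction and conclusions that depend on higher-order structure are
outside what it can validate. Its marginal *spreads* come out narrower than
the real cohort's (a truncation and calibration trade-off); only the means
are calibrated. Passing tests demonstrate that the extraction and
statistics pipeline is correct and that the published correlation structure
is *representable* by a plausible mixture physiology — not that this
physiology is the mechanism in real patients.

Two deliberate behavioural notes. First, with the calibrated default
config an extreme all-F-cell, high-HbF patient still shows a shallow
(~20 %) EI decline with a defined PoS rather than a perfectly flat curve;
truly flat, undefined-PoS behaviour is the normal-control scenario,
provided as a separate single-class configuration in the test suite. This
is the configuration the correlation calibration selects, and it matches
the observation that essentially all sickle-cell patients' curves sickle.
Second, the monotone-physiology guarantees (more dense cells never raise
EI_max; more F-cells never raise PoS) are properties of the mixture formula
at fixed class models; per-patient jitter can reorder two *different*
patients, which is intended between-patient variability.

## Known limitations

* The trace CSV dialect is this package's own; native instrument exports
  must be converted (one-off column mapping). The suspension-medium
  viscosity is stored verbatim as a value-with-unit string and never
  normalised — printed values in circulation ("approximately 28 Pa·s") are
  five orders of magnitude above typical mPa·s ektacytometry media, so
  silent unit correction would be worse than fidelity.
* p-values are reported at full precision without multiple-testing
  correction, matching the analysis being reproduced; Holm adjustment is
  left to the user.
* The PoS of a curve already below threshold at the deoxygenation onset is
  reported at the phase-start pO₂ with a flag rather than interpolated.
* Segmentation assumes one cycle per trace; repeated-cycle recordings must
  be split upstream.
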