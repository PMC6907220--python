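# Methods

## The assay being modelled

The package analyses a *non-simultaneous* drug-combination screen: suspension
lymphoma cells are pretreated for 9 days with one of 60 epigenetic-enzyme
inhibitors (DNMT, HDAC, HAT, HMT, HDM and BRD classes) on 384-well plates,
then exposed to a fixed dose of doxorubicin + rituximab, the key constituents
of R-CHOP. Each compound is tested on a five-point serial-dilution ladder:
the supplier-advised top dose followed by four tenfold dilutions, spanning a
10,000-fold concentration range. Every plate carries randomized DMSO
(vehicle) and benzethonium-chloride (BzCl, cytotoxic) control wells, and each
condition exists in two paired arms: pretreatment followed by vehicle
("mono") and pretreatment followed by the combination ("combo"). Viability is
read out as ATP-dependent luminescence (CellTiter-Glo style counts).

## Normalization and plate QC

Percent viability anchors each well on the in-plate controls:

    viability(w) = 100 · (counts(w) − mean_BzCl) / (mean_DMSO − mean_BzCl)

so the DMSO mean maps to 100 % and the BzCl mean to 0 %; growth inhibition is
the complement. Values are clamped to [−20, 120] (clamp count logged): the
range keeps over-/under-shoot information while bounding every downstream
score by ±140 points. Normalization is affine, hence order-preserving in the
raw counts.

Plate QC is automated, replacing manual curve inspection with three
conventional, configurable criteria (failures use strict comparisons):

| statistic | default cutoff | failure code |
|---|---|---|
| Z′ = 1 − 3(σ₊ + σ₋)/\|μ₋ − μ₊\| | ≥ 0.4 | `LOW_ZPRIME` |
| negative-control CV | ≤ 0.2 | `HIGH_CONTROL_CV` |
| signal window μ₋/μ₊ | ≥ 3-fold | `LOW_SIGNAL_WINDOW` |

A plate missing a control type cannot be normalized and fails with
`MISSING_CONTROLS`. Control SDs are sample SDs (ddof = 1). The automated QC
is a design choice, not a reconstruction of the original manual inspection,
whose criteria are not documented.

## Dose–response profiles and the 4PL fit

Profiles aggregate wells per (cell line, compound, arm): mean, sample SD and
well count at each dose, pooled across all QC-passing replicate plates
(QC-failing plates are excluded and logged; a `include_qc_failed` override
exists and marks the profile accordingly). Aggregation is permutation-
invariant over wells and plates.

The four-parameter logistic is auxiliary — used for cytotoxic-dose (IC50)
estimation and plotting, never for the sensitization score. It is fit in the
inhibitory orientation against log₁₀ dose,

    v(d) = emax + (e0 − emax) / (1 + (d/IC50)^h),

by bounded least squares (`scipy.optimize.curve_fit`), parameterized as
(emax, span ≥ 0, log₁₀ IC50, h) so e0 ≥ emax holds by construction. Bounds:
emax ∈ [−20, 120], span ∈ [0, 160], log₁₀ IC50 within ±2 decades of the
tested range, h ∈ [0.05, 10]. The start point puts the midpoint at the dose
whose response is nearest half-span. Fits need ≥ 4 distinct doses; flat
profiles (zero total variance) or R² < 0.3 come back `converged=False`
with descriptive e0/emax only and no IC50. On noise-free Hill data the fit
recovers IC50 and slope to ≪ 1 % relative error (tested over a parameter
sweep).

## The reprogramming score

For each (cell line, compound), with per-dose replicate-mean viabilities in
both arms:

    Δ(d)  = viability_mono(d) − viability_combo(d)
    score = max_d Δ(d),   best_dose = argmax_d Δ(d)

The score is computed on *measured* means at the tested doses only — no
interpolation and no fit dependence. Doses present in a single arm are
excluded and logged; ties at the maximum resolve to the lowest dose, since
low-dose sensitization is the phenotype of interest. A hit requires the score
*strictly above* 30 percentage points ("above a threshold of 30 %") *and*
plate QC to pass. The hit matrix tallies hits per cell line and, when a
library is supplied, per target class. Raising the threshold can only shrink
the hit set (tested as a property).

`sensitizing_vs_cytotoxic_dose` compares each hit's best dose to the IC50 of
its own mono-arm curve, flagging whether sensitization occurs below the
cytotoxic range and reporting the IC50/best-dose ratio; it returns an
indeterminate record when the mono fit did not converge (typical for
compounds that never reach 50 % inhibition in range).

## Synergy scoring

Dose matrices cross epigenetic-inhibitor doses with doxorubicin+rituximab
levels. Single-agent inhibition fractions come from the zero-dose margins of
the same plate set. The null model is Bliss independence,

    E[f_ab] = f_a + f_b − f_a·f_b,

which matches the semantics "score ≈ 0 ⇔ the two killing effects are
independent". The per-replicate summary is 100 · mean(observed − expected)
over the full matrix; replicates are summarized by the *median* score (even
counts: mean of the middle pair). Classification uses configurable cutoffs:
median > +5 synergy, < −5 antagonism, else additive. The null model is a
plug-in callable (`NULL_MODELS`) — highest-single-agent is included and
ZIP/Loewe-style models can be registered without touching the scoring code;
Bliss is the default because it is the simplest model consistent with the
verbal definition above.

## The synthetic-data generator

No raw plates from the original screen are public, so the generator is the
test substrate for every stage. It emulates:

- **Mono-arm viability**: Hill curves per (cell line, compound),
  v(d) = emax + (e0 − emax)/(1 + (d/IC50)^h), e0 = 100.
- **Sensitization**: a step effect — the combo arm subtracts
  `sensitization_effect` percentage points at and above a per-compound
  `sensitizing_dose` (floored at 0), plus an optional `combo_baseline`
  applied at every dose (default 0). The step parameterization makes the
  planted effect *exactly* the reprogramming score a noise-free pipeline run
  must recover (`GroundTruth.expected_score` gives the value including any
  baseline and flooring). An IC50-shift sensitization mode was considered and
  rejected for the default because it decouples the planted parameter from
  the score.
- **Counts**: counts = μ₊ + (v/100)(μ₋ − μ₊) with anchors μ₋ = 100,000 and
  μ₊ = 2,000, then multiplicative Gaussian noise (default CV 3 %) and
  additive Gaussian noise (default SD 300 counts ≈ 0.3 viability points),
  clipped at 0.
- **Layout**: one 384-well plate per (cell line, arm, replicate); 60
  compounds × 5 doses plus 16 + 16 randomized control wells (332 of 384
  used). Default study conditions: 4 cell lines, 2 replicates per arm,
  16 plates total.
- **Ground truth**: 12 sensitizers per cell line with 50-point effects;
  sensitizers get a cytotoxic IC50 at their top dose and a sensitizing dose
  two tenfold dilutions lower, so sensitization sits well below cytotoxicity,
  as observed for real reprogramming compounds. Non-sensitizers draw varied
  Hill parameters (IC50 at-to-above the tested range, slope 0.8–2, emax
  0–20) from the seed.
- **Determinism**: one mandatory seed drives layout placement and noise
  through independent `numpy` `SeedSequence` substreams; identical
  (config, truth, seed) triples produce byte-identical CSV output.

The on-plate passaging robot (five pipetting steps per 3-day cycle at 40 µL
working volume, 20 µL transfers) is simulated step by step with explicit
volume bookkeeping under perfect mixing and zero dead volume; each cycle
multiplies the old-media fraction by 0.25 (¾ of media exchanged), halves the
cells, and relaxes the media drug concentration as c ← c/4 + ¾·c_fresh, so
nominal dosing is a fixed point. A closed form (0.25^k, 0.5^k, geometric
relaxation) cross-checks the stepwise simulation.

**What the generator does not model**: spatial/edge effects, reader drift,
cell-growth and treatment kinetics over the 9 days, or immune-mediated
rituximab effects. Passing tests therefore demonstrate correctness of the
*analysis* under the declared generative model, not robustness to real-plate
artefacts; the noise model is deliberately simple and pluggable.

## Numerical conventions and edge cases

- Well addresses: row letter + 1-based column, canonicalized to uppercase
  without zero-padding ("a07" → "A7"); CSVs sort wells row-major.
- CSV dialect: comma-separated UTF-8, '.' decimal, floats at 10 significant
  digits (`%.10g`) — write/load round trips are byte-stable.
- "Exact" recovery claims are asserted at 1e-9 absolute tolerance (machine
  precision through the affine simulate→normalize round trip).
- Under noise, the per-dose delta plateau of a planted sensitizer is flat, so
  the argmax dose can land anywhere on the plateau up to the mono IC50;
  the sensitizing-below-cytotoxic fraction is exactly 1 only on noise-free
  data and slightly below 1 (~0.92–0.96) at the default 3 % noise.
- Problem sizes in tests and the acceptance script: full default screens
  (16 plates, 23,040 assigned wells each run), 20 seeds for the noisy
  recovery estimate, and a 12-point grid for the 4PL sweep — one full
  acceptance run takes a few seconds on one CPU.

## Known limitations

- No B-score/LOESS spatial correction (a simulator edge-effect mode would
  expose the limitation, and the QC statistics would not catch smooth
  gradients).
- No AUC/DSS drug-sensitivity summaries; decisions rest on the score and
  synergy stages.
- The hit threshold is applied to replicate-mean profiles, not per replicate;
  with two replicates per arm this is the lower-variance choice.
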