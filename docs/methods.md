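# Methods

`ctscreen` reimplements, as a tested library, the analysis stack of a
qRT-PCR high-throughput screen for transcriptional inducers: plate-based
relative quantification, vehicle-null hit calling, dose-response
confirmation, and landmark-profile marker selection. This note documents
the statistical model behind each stage, the tunable parameters and their
defaults, what the synthetic-data generators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Relative quantification (Livak 2^-ΔΔCt)

Each well yields threshold cycles Ct for a target transcript (TRIB1 in the
motivating screen) and a housekeeping calibrator (GAPDH or B2M). Per well,

    ΔCt   = Ct_target − Ct_calibrator
    ΔΔCt  = ΔCt_well − mean(ΔCt over the plate's DMSO vehicle wells)
    fold  = 2^−ΔΔCt

Under the Livak sign convention adopted here, up-regulation gives negative
ΔΔCt and fold > 1. Some write-ups print the subtraction in the opposite
order; only the Livak order is coherent with a "Z-score < −2" hit rule for
inducers, so that order is the package default and the convention is
explicit in the data model rather than configurable per call site.

Because ΔΔCt subtracts the within-plate vehicle mean, it is exactly
invariant to any additive per-plate, per-gene Ct offset (instrument or
batch drift); this invariance is asserted by the test suite.

**Censoring.** A reaction that never crosses threshold ("Undetermined") is
censored at the cycle ceiling (default 55) instead of dropped. A censored
*calibrator* invalidates the well's normalization and excludes the well
(with a warning); a censored *target* is retained as a strong
low-expression signal, since knockout-scale effects can push the target
past the ceiling while remaining biologically directional.

## Hit calling

The vehicle null is the plate's own set of DMSO wells (≥ 2 required;
the emulated design uses 32). With mean m and sample (n−1) SD s of the
DMSO ΔCt values, a well is a hit iff all three strict gates pass:

    fold > 2          (min_fold, default 2.0)
    ΔΔCt / s < −2     (max_ddct_z, default −2.0; ΔΔCt is a constant shift
                       of ΔCt, so their SDs coincide)
    −10 < (Ct_cal − mean_cal)/sd_cal < 10   (calibrator_z_bound, 10.0)

Boundary values are non-hits (strict inequalities as printed in the
protocol this emulates). Hits are called per plate, never pooled across
plates. A robust null variant (median / Gaussian-scaled MAD) is available
but non-default. Campaign-level reconciliation across duplicate plates
defaults to rule `both` (hit in every replicate) with `any` as the
alternative; `both` is the conservative choice for a triage funnel whose
downstream stages re-test every nominated compound.

Under a pure null the joint criterion's per-well rate is bounded by the
one-sided Gaussian tail P(Z < −2) ≈ 0.0228, and in practice sits far below
it because the fold gate binds harder than the Z gate at realistic noise.

## Dose-response confirmation

The response model is the four-parameter logistic on dose d,

    fold(d) = bottom + (top − bottom) / (1 + (EC50 / d)^hill),

the default sigmoid of standard curve-fitting software for this assay
class (recorded as an assumption; the emulated study names only the
software, not the model). Fitting is unweighted least squares over all
replicate points — replicates are *not* pre-averaged — with EC50 optimized
on the log scale. Initialization: bottom = min fold, top = max fold,
EC50 = geometric-mean dose, hill = 1, plus five deterministically jittered
restarts; the lowest-RSS solution wins. Bounds: EC50 in
[min_dose/100, max_dose·100], hill in [0.1, 10]. Fits are canonicalized to
hill > 0, so induction has top > bottom and inhibition top < bottom.
Non-convergence and flat (response-free) data return a fit object flagged
`converged=False`, never an exception; an EC50 outside the tested dose
range is returned but flagged as extrapolated.

The minimal effective concentration (MEC) mirrors a per-dose summary
table: replicate folds are averaged per dose, and the MEC is the lowest
tested dose whose mean reaches the threshold (default 2-fold, ≥
comparator). A series that never reaches it is inactive and rendered
`IA [max]` with the maximal per-dose mean fold in brackets.

## Landmark profiling

Expression matrices (genes × samples, GCT v1.2/1.3 or CSV) are quantile
normalized: each column's sorted values are replaced by the row-wise mean
of all columns' sorted values, so every sample shares one empirical
distribution. Ties resolve by stable sort order, which makes the
transformation idempotent.

LFC is computed per (treatment, dose, timepoint) stratum as the mean over
replicates of log2 intensity minus the mean log2 of the vehicle samples at
the same timepoint; a stratum without matched vehicle is an error, and
vehicle-vs-itself LFC is identically 0.

Marker selection between two treatment classes scores each gene with the
signal-to-noise ratio

    score = (mean_A − mean_B) / (sd_A + sd_B),

each group SD floored at max(0.2·|group mean|, 1e-8) — a standard SNR
regularization preventing near-constant genes from dominating; the exact
statistic and flooring of the original analysis tool are unpublished, so
both are recorded as assumptions and a Welch-t-like alternative is
selectable. Ranks are 1..n by descending score, ties broken by raw mean
difference then gene label, making the ranking deterministic. Permutation
p-values (sample-label shuffling, two-sided) are provided for completeness
but back no headline result.

## Synthetic-data generators

No raw screening data exist to replay, so the generators define the study
conditions and every quantitative claim in the tests refers to them:

- **Plates.** 384 wells; 32 DMSO vehicle wells (fixed in columns 23–24 —
  the real layout is unpublished and all statistics used are
  layout-invariant); 352 compounds per plate at a single 12 µM screening
  dose; each compound set plated in duplicate.
- **Ct model.** Ct = baseline + plate shift + well noise, with baselines
  target 24 / calibrator 18 cycles (arbitrary realistic values), additive
  per-plate per-gene shifts ~ N(0, 0.5²) cycles, and i.i.d. well noise
  ~ N(0, 0.25²) cycles per gene. Gaussian cycle-scale noise is log-scale
  noise on abundance; independence across genes makes the DMSO ΔCt SD
  √2·0.25 ≈ 0.354 cycles, which the tests verify by variance propagation.
  Actives shift the target Ct by −log2(fold), with fold taken from the
  compound's own 4PL curve at the plated dose (defaults: EC50 2.3 µM,
  hill 1.2, screening-dose fold 3.5 — the scale of the screen's confirmed
  inducer); the calibrator is untouched unless an off-target shift is
  requested to exercise the calibrator gate.
- **Dose-response.** fold(d) × mean-one lognormal noise with CV 0.10 over
  8-point 2-fold dilution series from 25 µM, triplicates.
- **Profiles.** Log-normal intensities with baseline log2 levels uniform
  on [4, 12], Gaussian log2 noise (SD 0.25), triplicates per condition,
  and marker genes spiked with signed LFCs per group.

All generators are pure functions of (parameters, seed); regeneration is
byte-identical. Noise magnitudes are stated assumptions (the real screen's
noise is unpublished) and are exposed in `NoiseModel`.

What the generators do **not** emulate: plate-position (edge/gradient)
artifacts, amplification-efficiency differences between primer pairs,
compound toxicity, carry-over, or correlated gene-gene biology. Passing
tests therefore certify the *analysis* — that the estimators recover what
the stated model generates — not robustness to spatial artifacts the
pipeline deliberately does not model (no B-score correction, by design).

## Problem sizes and tolerances

Parameter-recovery checks use 200 simulated datasets per curve (median
EC50/Emax within ±15%/±10% of the generating values); the hit-caller
oracle equivalence runs 50 plates; null calibration uses a 20-plate
vehicle-only campaign with the hit rate bounded by 0.0228 + 3 Monte-Carlo
SDs; the power check uses a 10-set duplicate campaign (880 actives at fold
3.5), sized so the ~0.6% Monte-Carlo error is small against the expected
~0.97 recall and its 0.95 bound. Exactness identities (one-cycle doubling,
plate-shift invariance, quantile-normalization idempotence, SNR
antisymmetry) are asserted to 1e-9 or tighter.

## Known limitations

- Single-calibrator normalization only (no Pfaffl efficiency correction,
  no multi-gene geometric-mean calibrators).
- No plate-spatial modeling or correction; no multiple-testing control
  across the campaign (the emulated protocol applied none).
- 4PL only — no 5PL or biphasic models, no profile-likelihood confidence
  intervals.
- The GCT reader models row descriptions but ignores v1.3 column metadata
  beyond skipping it.
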