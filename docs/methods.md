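# Methods

## Kinetic model and quantification

CBF quantification uses the single-compartment general kinetic model for
pCASL. The inverse (quantification) form is

    CBF = λ · ΔM · exp(PLD/T1b) / (2 · α · T1t · M0t · (1 − exp(−τ/T1t)))

evaluated in mL/g/ms and scaled by 6.0 × 10⁶ to mL/100 g/min (×100 for
per-100 g, ×60 000 ms/min). The forward model ΔM(t) is piecewise: zero
before the arterial transit time (ATT), a bolus-accumulation branch
with the tissue T1 over [ATT, ATT+τ], and a decay branch afterwards.
The label is taken to relax with the *blood* T1 during transit and
after the bolus (no outflow, no exchange-compartment change at
arrival). This convention was chosen so that the quantification
equation above is the exact algebraic inverse of the forward model at
ATT = 0 and readout at t = τ + PLD; the round trip holds to machine
precision and is enforced by tests.

A useful consequence: for ATT ≤ PLD the extra transit decay exp(−ATT/T1b)
cancels exactly against the shortened post-bolus decay, so quantification
assuming ATT = 0 remains exact. This mirrors the single-PLD design
assumption that transit times are shorter than the post-labeling delay;
with mouse transit times around 200 ms and PLD = 300 ms the assumption
holds in the regimes simulated here.

Defaults (all overridable through `AcquisitionParams`): τ = 3000 ms,
PLD = 300 ms, T1b = 2230 ms (blood at 7 T), λ = 0.9 mL/g, α = 0.9.
The labeling efficiency is an input, not a fitted quantity — in practice
it is measured with a flow-compensated acquisition at the carotids and
supplied via the sidecar. The default tissue T1 of 1700 ms is a typical
mouse-brain value at 7 T, used by the simulators when no
inversion-recovery fit is supplied.

The hypercapnia driver is a block design with mono-exponential
transitions: baseline CBF before CO₂ onset, exponential approach with
time constant τ_resp toward baseline·(1 + CVR/100) during the block,
exponential return afterwards. τ_resp defaults to 30 s (fast response
under isoflurane); 120 s is a representative choice for the slower
response under urethane + α-chloralose.

## Time-encoded pCASL and ATT estimation

The labeling train is split into sub-boli modulated across repeats by
the rows of a Hadamard matrix of order n+1; the all-ones column is the
unmodulated reference and is dropped, giving an (n+1) × n scheme in
which every sub-bolus is labeled in exactly half the repeats. Decoding
regresses the encoded signals on an intercept (static tissue signal)
plus a labeled-indicator design by least squares — equivalent to the
scaled Hadamard transform for a complete scheme, but tolerant of
dropped encodes as long as the design keeps full rank. Decode∘encode is
the identity to machine precision, and decoded noise follows the
analytic (AᵀA)⁻¹ propagation.

ATT fitting exploits that the inflow model is linear in CBF for fixed
ATT: CBF is profiled out in closed form and the ATT search is
one-dimensional — a 10 ms grid over [0, longest PLD + sub-bolus
duration] followed by bounded local refinement, with SSE ties broken
toward the smaller ATT.

Default scheme: Hadamard-8, seven 250 ms sub-boli, 25 ms readout gap,
effective PLDs 25–1525 ms. The gap matters: because transit decay and
post-bolus decay share the blood T1, the decoded curve is *exactly*
independent of any ATT at or below the shortest effective PLD, so that
region of parameter space is unidentifiable and the tie-break maps it
to zero. A 25 ms shortest PLD keeps the fastest transit times of
interest (≥ 50 ms) strictly inside the identifiable range while the
longest PLD still brackets slow transit. Monte-Carlo calibration (200
replicates per condition, decoded-ΔM SNR 20) shows |bias| < 5 ms for
ATT between 50 and 400 ms, with a replicate spread of 10–18 ms.

## Inversion-recovery T1 mapping

Model: S(TI) = |M0·(1 − 2·β·exp(−TI/T1))| with inversion factor
β ∈ (0.5, 1]. Magnitude data lose polarity, so every candidate split
index is tried (samples before the split negated), the signed model is
fitted — linear in (M0, M0·2β) with a bounded one-dimensional search
over T1 — and the lowest-residual solution is kept. Fits with T1
outside (100, 5000) ms or β far outside its physical range are flagged
rather than returned silently. With eight inversion times spanning
50–4000 ms and 1 % Gaussian noise, T1 recovery bias is below 1 % with a
spread under 3 % (500-replicate calibration). Per-voxel and per-ROI
fitting are both provided; per-voxel is the default for map making.

## Run processing definitions

* ΔM is control − label per adjacent frame pair; a 180-frame, 21-minute
  run yields 90 pair-dynamics of 14 s each.
* ROI profiles are voxel means of the CBF maps (flagged voxels
  excluded, never zero-filled), smoothed with a centered three-point
  moving average whose edges shrink to the available samples (seven
  points for the craniotomy-hemisphere profiles, where physiological
  variance is larger).
* Baseline CBF: mean of the 20 pair-dynamics immediately before the
  first dynamic starting at or after CO₂ onset. With onset at 420 s
  this is dynamics 11–30 (1-based) of 90. The acquisition console
  counts each label/control pair of ~7 s as one "dynamic", under which
  20 repetitions span ≈2.3 min; in this implementation the profile unit
  is the 14 s pair-dynamic and the window is the 20 profile points
  before onset.
* CVR: 100·(mean of last 20 CO₂-block dynamics / baseline − 1), i.e.
  percent change. Reported group values in the literature (13 %, 31 %,
  233 %) are only consistent with percent change, not a raw ratio.
* Brain volume: voxel count × voxel volume. LDF traces are filtered
  with the same three-point window and normalized to the mean of the
  first 7 minutes.
* Frame alignment is an identity stub: simulated series are
  motion-free, and scanner data are expected to be motion-corrected
  upstream. Deformable registration and partial-volume correction are
  out of scope.

## Synthetic data

The phantom is a 12 × 12 × 3 grid (0.225 × 0.225 × 1.5 mm voxels) with
disjoint regions — a dorsal cortex band, a central thalamus blob, and
remaining tissue — each carrying its own CBF, ATT, CVR and tissue
parameters; a full-slice "midbrain" ROI is exposed for analysis.
Control frames are M0t plus noise; label frames subtract the kinetic
model ΔM evaluated at readout with the hypercapnia profile driving
CBF(t). Noise is additive Gaussian per frame (ΔM SNR in these
simulations is high enough that Rician bias in magnitude data is
negligible; `simulate_ir` applies the magnitude after adding noise).
`noise_sd_for_snr` converts a target per-dynamic ΔM SNR into the frame
noise level. All generators are deterministic given a seed.

Cohort endpoints are drawn from normals truncated at zero with location
at the reported group median and scale IQR/1.349, sharing a per-mouse
standard-normal random effect with weight √ρ across sessions (ρ = 0.5
by default; the true within-mouse correlation is unknown and
configurable). A symmetric family reproduces medians and IQR widths,
not the skew of asymmetric reported intervals. Values not reported for
some sessions (9-month CBF/CVR, early transgenic CVR) are held at the
nearest reported value, consistent with the stable trajectories and
absent genotype differences in the source cohort. Dropouts remove all
sessions after the dropout age; with two transgenic dropouts at 2.5 and
10 months, group sizes are 9 wild-type vs 8 transgenic from the first
session and 9 vs 7 at 12 months, which is what makes the paired
anesthesia contrasts n = 9 and n = 7.

What the simulators do *not* emulate: anatomy beyond coarse region
geometry, motion, B0/B1 inhomogeneity, physiological drift or CO₂
feedback, label dispersion, and partial-volume mixtures. Passing
recovery tests therefore validates the processing definitions and
estimator calibration, not robustness to those real-data effects.

## Statistics

SPSS conventions throughout, because reported asymptotic Z values are
only reproducible under them: paired zero differences are dropped
before ranking; the signed-rank Z is
(W⁺ − n(n+1)/4)/√(n(n+1)(2n+1)/24 − Σ(t³−t)/48) with no continuity
correction; the Friedman statistic carries the tie correction
1 − Σ(t³−t)/(n(k³−k)); quartiles are Tukey hinges. With all n
differences one-signed and distinct, Z is −2.67 at n = 9 and −2.37 at
n = 7 — the anesthesia-contrast configurations. (SPSS standardizes the
smaller rank sum, so its printed Z is negative for increases as well;
the package returns the signed, antisymmetric Z.)

Mann–Whitney U uses exact enumeration for min(n) ≤ 10 without ties and
the tie-corrected normal approximation otherwise. The *p*-value of the
asymptotic mode applies the continuity correction, which keeps it
within 0.02 of the exact p at n = 9/9 (without the correction the gap
reaches 0.04); the reported Z remains the plain standardized U. At
n = 4 per group the exact test's only two-sided rejection region at
α = 0.05 is complete group separation (p = 2/70 ≈ 0.029; the next
attainable p is 4/70 ≈ 0.057), so its power under a 30-point shift with
sd 12 is the separation probability (≈ 0.68), while the
normal-approximation power — what an a-priori sample-size calculation
computes — is ≈ 0.83. Both are reported by the acceptance script.

Bonferroni post hocs compare only consecutive age groups (m = 3 for
four ages, cut-off 0.05/3 ≈ 0.017) to limit the correction's
stringency.

## Problem sizes

Monte-Carlo calibrations use 200 replicates per ATT condition, 500
inversion-recovery replicates, 10⁴ null simulations for the
Mann–Whitney type-I rate (5000 in the acceptance script) and 2000 for
power; the end-to-end run uses the full 180-frame phantom. These sizes
give Monte-Carlo standard errors comfortably below the tolerances they
are checked against.
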