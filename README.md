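# aslkit

Arterial spin labeling (ASL) MRI perfusion analysis for small-animal
brain imaging: absolute cerebral blood flow (CBF) from pseudo-continuous
ASL (pCASL), cerebrovascular reactivity (CVR) from a hypercapnia block
design, arterial transit time (ATT) from Hadamard time-encoded pCASL,
inversion-recovery T1 mapping, and the nonparametric statistics used for
small longitudinal cohorts — plus synthetic-data generators with known
ground truth so the whole pipeline can be validated end to end.

It is aimed at preclinical imaging groups who quantify mouse brain
perfusion at high field and need a tested, scriptable reference
implementation of the standard processing definitions.

## The model

ΔM, the control-minus-label signal difference of a pCASL pair, is
converted to CBF with the single-compartment general kinetic model:

```
CBF = λ · ΔM · exp(PLD/T1b) / (2 · α · T1t · M0t · (1 − exp(−τ/T1t)))
```

where λ = 0.9 mL/g is the blood–brain partition coefficient, τ = 3000 ms
the labeling duration, PLD = 300 ms the post-labeling delay, α the
labeling efficiency, T1b = 2230 ms the blood T1 at 7 T, and T1t/M0t the
tissue T1 and equilibrium magnetization from an inversion-recovery fit.
The equation is evaluated in mL/g/ms and scaled by 6.0 × 10⁶ to
mL/100 g/min. A matching forward model (label decaying with T1b in
transit, accumulating with T1t during the bolus) predicts ΔM inflow
curves; it is the exact inverse of the quantification at ATT = 0 and
drives both the simulators and the ATT fit.

For a hypercapnia run (CO₂ between minutes 7 and 14 of a 21-minute,
180-frame scan), baseline CBF is the mean of the 20 pair-dynamics before
CO₂ onset and CVR is the percent change of the last 20 dynamics of the
CO₂ block over that baseline. ATT is estimated by least-squares fitting
of the inflow model to the decoded per-sub-bolus signals of a Hadamard
time-encoded scan. Cohort endpoints are compared with Mann–Whitney U
(genotype), Friedman (age), and Wilcoxon signed-rank tests (paired
contrasts; SPSS conventions: zero differences dropped, tie-corrected
variance, no continuity correction on Z), with Bonferroni correction
over consecutive-age post hocs and median (Tukey-hinge IQR) summaries.

## Worked example

```python
import numpy as np
from aslkit import (AcquisitionParams, TissueParams, PerfusionTruth, analyze_run,
                    build_scheme, decode, estimate_att)
from aslkit.synthetic import (uniform_phantom, noise_sd_for_snr,
                              simulate_pcasl_run, simulate_te_pcasl)

acq = AcquisitionParams()          # tau=3000 ms, PLD=300 ms, T1b=2230 ms, lambda=0.9, alpha=0.9
tissue = TissueParams(1700.0, 1000.0)

# a 21-min hypercapnia run: truth CBF 120 mL/100 g/min, CVR 30 %, ATT 200 ms
noise = noise_sd_for_snr(PerfusionTruth(120.0, 200.0), tissue, acq, snr=20.0)
phantom = uniform_phantom(cbf=120.0, cvr_pct=30.0, att=200.0, noise_sd=noise)
series = simulate_pcasl_run(phantom, acq, seed=7)
result = analyze_run(series, 1700.0, 1000.0, acq, phantom.roi_set())
print(f"baseline CBF : {result.baseline['uniform']:.1f} mL/100 g/min")
print(f"CVR          : {result.cvr_pct['uniform']:.1f} %")

# arterial transit time from a time-encoded scan of the same phantom
scheme = build_scheme(7)           # Hadamard-8, 7 x 250 ms sub-boli
encoded = simulate_te_pcasl(phantom, scheme, acq, seed=8)
mask = phantom.region_masks()["uniform"]
fit = estimate_att(decode(encoded[mask].mean(axis=0), scheme), tissue, acq)
print(f"ATT          : {fit.att:.0f} ms (fitted CBF {fit.cbf:.0f})")
```

Output:

```
baseline CBF : 120.1 mL/100 g/min
CVR          : 29.9 %
ATT          : 200 ms (fitted CBF 120)
```

The recovered baseline (120.1 vs truth 120), CVR (29.9 % vs 30 %) and
ATT (200 ms vs 200 ms) show the quantification inverting the simulated
acquisition at a per-dynamic ΔM signal-to-noise ratio of 20.

The same pipeline is available from the shell:

```sh
aslkit simulate --out study --seed 5
aslkit quantify --asl study/run.nii.gz --sidecar study/run.json \
    --t1map study/t1map.nii.gz --m0map study/m0map.nii.gz \
    --rois study/roi_midbrain.nii.gz --rois study/roi_cortex.nii.gz --out quant
aslkit att --encoded study/te_run.nii.gz --scheme study/scheme.json \
    --roi study/roi_thalamus.nii.gz --out att.json
aslkit cohort-stats --table study/cohort.csv --out stats
```

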