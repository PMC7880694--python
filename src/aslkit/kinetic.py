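"""Buxton general kinetic perfusion model for pCASL.

Forward and inverse single-compartment kinetics for pseudo-continuous
arterial spin labeling (pCASL).  The inverse direction converts a
control-minus-label signal difference ΔM into absolute cerebral blood
flow (CBF, mL/100 g/min); the forward direction predicts the ΔM inflow
curve for a given perfusion/transit-time ground truth, which drives both
the synthetic-data generators and the arterial transit time (ATT) fit.

Quantification equation (evaluated in mL/g/ms, then scaled to
mL/100 g/min)::

    CBF = λ · ΔM · exp(PLD/T1b) / (2 · α · T1t · M0t · (1 − exp(−τ/T1t)))

where λ is the blood–brain partition coefficient, τ the labeling
duration, PLD the post-labeling delay, α the labeling efficiency, T1b
the longitudinal relaxation time of arterial blood and T1t/M0t the
tissue relaxation time and equilibrium magnetization.

The forward model uses the matching convention: label decays with T1b
during transit and after the bolus, and accumulates with the apparent
tissue T1 (here T1t, no outflow) while the bolus is being delivered.
With that convention the quantification equation is the exact algebraic
inverse of the forward model at ATT = 0 and readout time t = τ + PLD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AcquisitionParams",
    "TissueParams",
    "PerfusionTruth",
    "DegenerateAcquisitionError",
    "CBF_UNIT_FACTOR",
    "quantify_cbf",
    "gkm_delta_m",
    "hypercapnia_cbf_profile",
]

#: mL/g/ms -> mL/100 g/min  (×100 for per-100 g, ×60 000 for per-minute)
CBF_UNIT_FACTOR = 6.0e6


class DegenerateAcquisitionError(ValueError):
    """Raised when the quantification denominator underflows (τ ≪ T1t)."""


@dataclass(frozen=True)
class AcquisitionParams:
    """pCASL acquisition constants; single source of truth for quantification.

    Parameters
    ----------
    tau : float
        Labeling duration in ms.
    pld : float
        Post-labeling delay in ms.
    t1_blood : float
        Longitudinal relaxation time of arterial blood in ms (2230 ms at 7 T).
    lambda_bbp : float
        Blood–brain partition coefficient in mL/g (0.9).
    alpha : float
        Labeling (inversion) efficiency, fraction in (0, 1].
    """

    tau: float = 3000.0
    pld: float = 300.0
    t1_blood: float = 2230.0
    lambda_bbp: float = 0.9
    alpha: float = 0.9

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.pld < 0:
            raise ValueError(f"pld must be >= 0, got {self.pld}")
        if not self.t1_blood > 0:
            raise ValueError(f"t1_blood must be > 0, got {self.t1_blood}")
        if not self.lambda_bbp > 0:
            raise ValueError(f"lambda_bbp must be > 0, got {self.lambda_bbp}")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")


@dataclass(frozen=True)
class TissueParams:
    """Tissue relaxation time T1t (ms) and equilibrium magnetization M0t (a.u.)."""

    t1_tissue: float = 1700.0
    m0_tissue: float = 1.0

    def __post_init__(self) -> None:
        if not self.t1_tissue > 0:
            raise ValueError(f"t1_tissue must be > 0, got {self.t1_tissue}")
        if not self.m0_tissue > 0:
            raise ValueError(f"m0_tissue must be > 0, got {self.m0_tissue}")


@dataclass(frozen=True)
class PerfusionTruth:
    """Ground-truth perfusion state: CBF in mL/100 g/min, ATT in ms."""

    cbf: float
    att: float = 0.0

    def __post_init__(self) -> None:
        if self.cbf < 0:
            raise ValueError(f"cbf must be >= 0, got {self.cbf}")
        if self.att < 0:
            raise ValueError(f"att must be >= 0, got {self.att}")


def quantify_cbf(delta_m, tissue: TissueParams, acq: AcquisitionParams):
    """Convert a ΔM signal difference to absolute CBF in mL/100 g/min.

    ``delta_m`` may be a scalar or an array (a map); the operation is
    linear in ΔM and applied elementwise.  NaN inputs propagate (masked
    voxels); infinities are rejected.
    """
    dm = np.asarray(delta_m, dtype=float)
    if np.isinf(dm).any():
        raise ValueError("delta_m contains non-finite (infinite) values")
    denom = (
        2.0
        * acq.alpha
        * tissue.t1_tissue
        * tissue.m0_tissue
        * -np.expm1(-acq.tau / tissue.t1_tissue)
    )
    if denom <= 0 or not np.isfinite(denom):
        raise DegenerateAcquisitionError(
            f"quantification denominator degenerate ({denom!r}); "
            "check tau/T1t and M0t"
        )
    cbf = acq.lambda_bbp * dm * np.exp(acq.pld / acq.t1_blood) / denom
    cbf = cbf * CBF_UNIT_FACTOR
    return float(cbf) if np.isscalar(delta_m) else cbf


def gkm_delta_m(truth: PerfusionTruth, tissue: TissueParams, acq: AcquisitionParams, t):
    """Predicted ΔM(t) (a.u.) at time ``t`` (ms) since label onset.

    Piecewise single-compartment inflow:

    * ``t < att`` — no label has arrived, ΔM = 0;
    * ``att <= t < att + tau`` — bolus accumulates with T1t, scaled by
      T1b decay during transit;
    * ``t >= att + tau`` — delivered bolus decays with T1b.

    Continuous in t, linear in CBF, and exactly inverted by
    :func:`quantify_cbf` at ``att=0``, ``t = tau + pld``.
    """
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ValueError("t must be >= 0")
    f = truth.cbf / CBF_UNIT_FACTOR  # mL/g/ms
    amp = 2.0 * acq.alpha * tissue.m0_tissue * f / acq.lambda_bbp * tissue.t1_tissue
    transit_decay = np.exp(-truth.att / acq.t1_blood)
    s = t - truth.att  # time since bolus arrival
    rising = amp * transit_decay * -np.expm1(-np.clip(s, 0.0, acq.tau) / tissue.t1_tissue)
    post = np.exp(-np.clip(s - acq.tau, 0.0, None) / acq.t1_blood)
    dm = np.where(s <= 0.0, 0.0, rising * post)
    return float(dm) if dm.ndim == 0 else dm


def hypercapnia_cbf_profile(
    baseline_cbf: float,
    cvr_pct: float,
    t_on: float,
    t_off: float,
    tau_response: float,
    times,
):
    """CBF(t) for a hypercapnia block design (simulation driver).

    Baseline before ``t_on``; mono-exponential approach (time constant
    ``tau_response``, seconds) to ``baseline·(1 + cvr_pct/100)`` during
    the CO₂ block; mono-exponential return to baseline after ``t_off``.
    All times in seconds.
    """
    if not tau_response > 0:
        raise ValueError("tau_response must be > 0")
    if not t_on < t_off:
        raise ValueError("t_on must precede t_off")
    times = np.asarray(times, dtype=float)
    plateau = baseline_cbf * (1.0 + cvr_pct / 100.0)
    rise = plateau + (baseline_cbf - plateau) * np.exp(
        -np.clip(times - t_on, 0.0, None) / tau_response
    )
    at_off = plateau + (baseline_cbf - plateau) * np.exp(-(t_off - t_on) / tau_response)
    fall = baseline_cbf + (at_off - baseline_cbf) * np.exp(
        -np.clip(times - t_off, 0.0, None) / tau_response
    )
    out = np.where(times < t_on, baseline_cbf, np.where(times < t_off, rise, fall))
    return float(out) if out.ndim == 0 else out
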