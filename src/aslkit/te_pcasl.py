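"""Hadamard time-encoded pCASL: scheme construction, decoding, ATT fitting.

In time-encoded pCASL the labeling train is divided into sub-boli whose
label/control state varies across repeats according to the rows of a
Hadamard matrix.  Decoding the acquired volumes recovers one ΔM value
per sub-bolus, i.e. a multi-delay inflow curve from a single scan, from
which the arterial transit time (ATT) is estimated by fitting the
kinetic inflow model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import hadamard
from scipy.optimize import minimize_scalar

from .kinetic import AcquisitionParams, PerfusionTruth, TissueParams, gkm_delta_m

__all__ = [
    "TeAslScheme",
    "DecodedSeries",
    "AttFit",
    "build_scheme",
    "encode",
    "decode",
    "estimate_att",
]


@dataclass(frozen=True)
class TeAslScheme:
    """Hadamard encoding description.

    ``matrix`` is n_encodes × n_subboli with entries ±1; +1 means the
    sub-bolus is *labeled* in that encode.  Columns are mutually
    orthogonal and each sub-bolus is labeled in exactly half of the
    encodes.  ``effective_plds`` is the delay from the end of each
    sub-bolus to the readout, strictly decreasing with sub-bolus index
    (later sub-boli sit closer to the readout).
    """

    matrix: np.ndarray
    subbolus_durations: np.ndarray  # ms, per sub-bolus
    effective_plds: np.ndarray  # ms, per sub-bolus

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(
            self, "subbolus_durations", np.asarray(self.subbolus_durations, float)
        )
        object.__setattr__(
            self, "effective_plds", np.asarray(self.effective_plds, float)
        )
        n_enc, n_sub = m.shape
        if self.subbolus_durations.shape != (n_sub,) or self.effective_plds.shape != (
            n_sub,
        ):
            raise ValueError("durations/effective_plds must have one entry per sub-bolus")
        if not np.all(np.abs(m) == 1):
            raise ValueError("encoding matrix entries must be ±1")
        gram = m.T @ m
        if not np.allclose(gram, np.diag(np.diag(gram))):
            raise ValueError("encoding matrix columns must be mutually orthogonal")
        first = m[0]
        if not (np.all(first == 1) or np.all(first == -1)):
            raise ValueError("first row must be all +1 or all −1 (global reference)")
        if not np.all(self.subbolus_durations > 0):
            raise ValueError("sub-bolus durations must be > 0")
        if not np.all(np.diff(self.effective_plds) < 0):
            raise ValueError("effective PLDs must strictly decrease with sub-bolus index")

    @property
    def n_encodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_subboli(self) -> int:
        return self.matrix.shape[1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "matrix": self.matrix.astype(int).tolist(),
                "subbolus_durations_ms": self.subbolus_durations.tolist(),
                "effective_plds_ms": self.effective_plds.tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "TeAslScheme":
        d = json.loads(text)
        return cls(
            matrix=np.asarray(d["matrix"], float),
            subbolus_durations=np.asarray(d["subbolus_durations_ms"], float),
            effective_plds=np.asarray(d["effective_plds_ms"], float),
        )


@dataclass(frozen=True)
class DecodedSeries:
    """Per-sub-bolus ΔM (a.u.) against the effective-PLD axis (ms)."""

    delta_m: np.ndarray
    pld_axis: np.ndarray
    subbolus_duration: float = 250.0

    def __post_init__(self) -> None:
        dm = np.asarray(self.delta_m, float)
        pld = np.asarray(self.pld_axis, float)
        object.__setattr__(self, "delta_m", dm)
        object.__setattr__(self, "pld_axis", pld)
        if dm.shape != pld.shape:
            raise ValueError("delta_m and pld_axis lengths must match")
        if (pld < 0).any():
            raise ValueError("pld_axis must be >= 0")


@dataclass(frozen=True)
class AttFit:
    """ATT fit result; ``converged`` is False when the fit is degenerate."""

    att: float
    cbf: float
    sse: float = 0.0
    converged: bool = True


def build_scheme(
    n_subboli: int, subbolus_duration: float = 250.0, readout_gap: float = 25.0
) -> TeAslScheme:
    """Build a Hadamard scheme of order ``n_subboli + 1``.

    ``n_subboli + 1`` must be a power of two.  The all-ones reference
    column of the Hadamard matrix is dropped (it carries no sub-bolus
    modulation).  Sub-boli are played back-to-back; the effective PLD of
    sub-bolus j (0-based, earliest first) is
    ``(n_subboli − 1 − j)·duration + readout_gap``.

    The default gap of 25 ms keeps the shortest effective PLD strictly
    below the fastest transit times of interest: with transit-decay and
    post-bolus decay sharing the blood T1, an ATT at or below the
    shortest PLD leaves the decoded curve shape unchanged and is not
    identifiable.
    """
    order = n_subboli + 1
    if order < 2 or order & (order - 1):
        raise ValueError(f"n_subboli + 1 must be a power of 2, got {order}")
    if subbolus_duration <= 0 or readout_gap < 0:
        raise ValueError("subbolus_duration must be > 0 and readout_gap >= 0")
    h = hadamard(order).astype(float)
    matrix = h[:, 1:]  # drop the unmodulated reference column
    j = np.arange(n_subboli)
    plds = (n_subboli - 1 - j) * subbolus_duration + readout_gap
    return TeAslScheme(
        matrix=matrix,
        subbolus_durations=np.full(n_subboli, float(subbolus_duration)),
        effective_plds=plds,
    )


def encode(delta_m: np.ndarray, scheme: TeAslScheme, static: float = 0.0) -> np.ndarray:
    """Forward-encode per-sub-bolus ΔM into per-encode signals.

    Each labeled sub-bolus (matrix entry +1) subtracts its ΔM from the
    static tissue signal, mirroring a label frame; −1 leaves it at the
    control level.
    """
    dm = np.asarray(delta_m, float)
    if dm.shape[-1] != scheme.n_subboli:
        raise ValueError("one ΔM per sub-bolus required")
    labeled = (1.0 + scheme.matrix) / 2.0  # 1 where labeled
    return static - dm @ labeled.T


def decode(encoded_signals: np.ndarray, scheme: TeAslScheme) -> DecodedSeries:
    """Recover per-sub-bolus ΔM from encoded signals (least squares).

    The design regresses each encode's signal on an intercept (static
    signal) plus −1·(labeled indicator) per sub-bolus, so a sub-bolus
    labeled in half the encodes yields its full ΔM and a constant
    signal decodes to all-zero ΔM.  Tolerates dropped encodes as long
    as the remaining design has full rank.
    """
    s = np.asarray(encoded_signals, float)
    if s.shape[-1] != scheme.n_encodes:
        raise ValueError("one signal per encoding row required")
    labeled = (1.0 + scheme.matrix) / 2.0
    design = np.column_stack([np.ones(scheme.n_encodes), -labeled])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient encoding scheme: cannot decode")
    coef, *_ = np.linalg.lstsq(design, s.T if s.ndim > 1 else s, rcond=None)
    dm = coef[1:].T if s.ndim > 1 else coef[1:]
    return DecodedSeries(
        delta_m=dm,
        pld_axis=scheme.effective_plds,
        subbolus_duration=float(scheme.subbolus_durations[0]),
    )


def _model_curve(
    att: float, tissue: TissueParams, acq: AcquisitionParams, decoded: DecodedSeries
) -> np.ndarray:
    """Unit-CBF ΔM prediction at each effective PLD for a candidate ATT."""
    dur = decoded.subbolus_duration
    sub_acq = AcquisitionParams(
        tau=dur,
        pld=acq.pld,
        t1_blood=acq.t1_blood,
        lambda_bbp=acq.lambda_bbp,
        alpha=acq.alpha,
    )
    truth = PerfusionTruth(cbf=1.0, att=att)
    t = dur + decoded.pld_axis  # time since each sub-bolus label onset
    return gkm_delta_m(truth, tissue, sub_acq, t)


def estimate_att(
    decoded: DecodedSeries,
    tissue: TissueParams,
    acq: AcquisitionParams,
    grid_step: float = 10.0,
) -> AttFit:
    """Least-squares (CBF, ATT) fit of the inflow model to a decoded series.

    The model is linear in CBF for fixed ATT, so CBF is profiled out in
    closed form and only ATT is searched: a coarse grid at ``grid_step``
    ms over [0, max PLD + sub-bolus duration], followed by bounded local
    refinement.  Ties on the grid break toward the smaller ATT.
    """
    if decoded.delta_m.size < 3:
        raise ValueError("need at least 3 sub-boli to fit ATT")
    data = decoded.delta_m

    def sse_and_cbf(att: float) -> tuple[float, float]:
        m = _model_curve(att, tissue, acq, decoded)
        mm = float(m @ m)
        if mm <= 0:
            return float(data @ data), 0.0
        cbf = float(max(m @ data, 0.0) / mm)
        r = data - cbf * m
        return float(r @ r), cbf

    att_max = float(decoded.pld_axis.max() + decoded.subbolus_duration)
    grid = np.arange(0.0, att_max + grid_step, grid_step)
    sses = np.array([sse_and_cbf(a)[0] for a in grid])
    if not np.isfinite(sses).all():
        return AttFit(att=np.nan, cbf=np.nan, sse=np.nan, converged=False)
    # ties (within rounding of the signal energy) break toward smaller att
    tol = 1e-10 * float(data @ data) + 1e-30
    best = int(np.argmax(sses <= sses.min() + tol))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    if hi > lo:
        res = minimize_scalar(
            lambda a: sse_and_cbf(a)[0], bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-3},
        )
        att_hat = float(res.x) if res.success else float(grid[best])
    else:
        att_hat = float(grid[best])
    sse, cbf_hat = sse_and_cbf(att_hat)
    # on a flat SSE stretch (unidentifiable region) keep the grid point,
    # which ties toward the smaller att
    if sses[best] <= sse + tol:
        att_hat, (sse, cbf_hat) = float(grid[best]), sse_and_cbf(float(grid[best]))
    if cbf_hat == 0.0 and np.allclose(data, 0.0):
        return AttFit(att=np.nan, cbf=0.0, sse=sse, converged=False)
    return AttFit(att=att_hat, cbf=cbf_hat, sse=sse, converged=True)
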