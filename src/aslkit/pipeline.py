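"""pCASL run processing: ΔM, CBF maps, ROI profiles, baseline CBF and CVR.

The processing definitions mirror a hypercapnia block-design perfusion
experiment: CBF is computed per label/control pair, ROI time profiles
are smoothed with a short centered sliding window, baseline CBF is the
mean of the last ``n_reps`` dynamics before CO₂ onset, and
cerebrovascular reactivity (CVR) is the percent CBF change from that
baseline to the last ``n_reps`` dynamics of the CO₂ block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetic import CBF_UNIT_FACTOR, AcquisitionParams

__all__ = [
    "AslSeries",
    "RoiSet",
    "PerfusionResult",
    "pairwise_delta_m",
    "cbf_series",
    "sliding_window_filter",
    "baseline_cbf",
    "cvr",
    "roi_profile",
    "brain_volume",
    "ldf_normalize",
    "align_frames",
    "analyze_run",
]


@dataclass
class AslSeries:
    """4-D pCASL time series (x, y, z, frame) with run timing.

    Frames alternate label/control; ``label_first`` states which comes
    first.  ``co2_on``/``co2_off`` give the CO₂ block in seconds from
    run start.  ``frame_duration`` is seconds per frame, so one ΔM
    dynamic (a label/control pair) spans ``2·frame_duration``.
    """

    volumes: np.ndarray
    frame_duration: float  # s
    label_first: bool = True
    co2_on: float = 420.0
    co2_off: float = 840.0
    voxel_dims: tuple[float, float, float] = (0.225, 0.225, 1.5)  # mm

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes, float)
        self.volumes = v
        if v.ndim != 4:
            raise ValueError("volumes must be 4-D (x, y, z, frame)")
        if v.shape[-1] % 2:
            raise ValueError("frame count must be even (label/control pairs)")
        if self.frame_duration <= 0:
            raise ValueError("frame_duration must be > 0")
        run_end = v.shape[-1] * self.frame_duration
        if not (self.co2_on < self.co2_off <= run_end):
            raise ValueError("require co2_on < co2_off <= run end")
        if any(d <= 0 for d in self.voxel_dims):
            raise ValueError("voxel_dims must be > 0")

    @property
    def n_dynamics(self) -> int:
        return self.volumes.shape[-1] // 2

    def dynamic_times(self) -> np.ndarray:
        """Start time (s) of each label/control pair-dynamic."""
        return np.arange(self.n_dynamics) * 2.0 * self.frame_duration


@dataclass
class RoiSet:
    """Named binary masks on the series grid (cortex, thalamus, ...)."""

    masks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("all masks must share one grid")
        for name, m in self.masks.items():
            if not m.any():
                raise ValueError(f"mask {name!r} is empty")
            self.masks[name] = m.astype(bool)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def names(self) -> list[str]:
        return list(self.masks)


@dataclass
class PerfusionResult:
    """Per-ROI CBF profiles and summary endpoints."""

    roi_profiles: dict[str, np.ndarray]  # mL/100 g/min per dynamic
    baseline: dict[str, float]
    cvr_pct: dict[str, float]
    dynamic_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        for name, b in self.baseline.items():
            if b < 0:
                raise ValueError(f"baseline CBF must be >= 0 for ROI {name!r}")


def pairwise_delta_m(series: AslSeries) -> np.ndarray:
    """Control − label per pair: (x, y, z, n_dynamics) from 2·n frames."""
    v = series.volumes
    label = v[..., 0::2] if series.label_first else v[..., 1::2]
    control = v[..., 1::2] if series.label_first else v[..., 0::2]
    return control - label


def align_frames(series: AslSeries) -> AslSeries:
    """Rigid frame alignment stub.

    Synthetic runs are motion-free, so this is the identity; it marks
    the place a motion-correction step takes for scanner data.
    """
    return series


def cbf_series(
    delta_m: np.ndarray,
    t1t: np.ndarray | float,
    m0t: np.ndarray | float,
    acq: AcquisitionParams,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Voxelwise CBF maps (mL/100 g/min) from a ΔM dynamic series.

    ``t1t``/``m0t`` may be scalars or per-voxel maps; voxels outside
    ``mask`` (or with NaN tissue parameters) come out NaN.
    """
    dm = np.asarray(delta_m, float)
    t1t = np.broadcast_to(np.asarray(t1t, float), dm.shape[:-1]).copy()
    m0t = np.broadcast_to(np.asarray(m0t, float), dm.shape[:-1]).copy()
    if mask is not None:
        t1t[~mask] = np.nan
        m0t[~mask] = np.nan
    valid = np.isfinite(t1t) & np.isfinite(m0t) & (t1t > 0) & (m0t > 0)
    out = np.full(dm.shape, np.nan)
    # vectorized form of the quantification equation; tests pin it to quantify_cbf
    denom = 2.0 * acq.alpha * t1t * m0t * -np.expm1(-acq.tau / t1t)
    with np.errstate(invalid="ignore", divide="ignore"):
        cbf = (
            acq.lambda_bbp
            * dm
            * np.exp(acq.pld / acq.t1_blood)
            / denom[..., None]
            * CBF_UNIT_FACTOR
        )
    out[valid] = cbf[valid]
    return out


def sliding_window_filter(profile: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average; edges use the available shrunken window."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    p = np.asarray(profile, float)
    if window > p.size:
        raise ValueError("window longer than profile")
    kernel = np.ones(window)
    sums = np.convolve(p, kernel, mode="same")
    counts = np.convolve(np.ones_like(p), kernel, mode="same")
    return sums / counts


def _first_dynamic_at(times: np.ndarray, t: float) -> int:
    """Index of the first dynamic whose start time is >= t."""
    return int(np.searchsorted(np.asarray(times, float), t, side="left"))


def baseline_cbf(
    profile: np.ndarray, times: np.ndarray, co2_on: float, n_reps: int = 20
) -> float:
    """Mean of the ``n_reps`` dynamics immediately preceding CO₂ onset."""
    p = np.asarray(profile, float)
    i_on = _first_dynamic_at(times, co2_on)
    if i_on < n_reps:
        raise ValueError(
            f"need >= {n_reps} dynamics before CO2 onset, have {i_on}"
        )
    return float(np.mean(p[i_on - n_reps : i_on]))


def cvr(
    profile: np.ndarray,
    times: np.ndarray,
    co2_on: float,
    co2_off: float,
    n_reps: int = 20,
) -> float:
    """Percent CBF change: 100·(mean of last ``n_reps`` CO₂ dynamics / baseline − 1)."""
    p = np.asarray(profile, float)
    t = np.asarray(times, float)
    base = baseline_cbf(p, t, co2_on, n_reps)
    in_block = np.nonzero((t >= co2_on) & (t < co2_off))[0]
    if in_block.size < n_reps:
        raise ValueError(
            f"need >= {n_reps} dynamics inside the CO2 block, have {in_block.size}"
        )
    plateau = float(np.mean(p[in_block[-n_reps:]]))
    if base == 0:
        raise ZeroDivisionError("zero baseline CBF: CVR undefined")
    return 100.0 * (plateau - base) / base


def roi_profile(cbf_maps: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mean CBF over ``mask`` per dynamic, ignoring NaN (flagged) voxels."""
    m = np.asarray(mask, bool)
    if not m.any():
        raise ValueError("empty ROI mask")
    with np.errstate(invalid="ignore"):
        return np.nanmean(cbf_maps[m, :], axis=0)


def brain_volume(mask: np.ndarray, voxel_dims) -> float:
    """Volume in mm³: voxel count × voxel volume."""
    dims = np.asarray(voxel_dims, float)
    return float(np.count_nonzero(mask) * np.prod(dims))


def ldf_normalize(
    profile: np.ndarray,
    times: np.ndarray,
    baseline_duration: float = 420.0,
    window: int = 3,
) -> np.ndarray:
    """Filter an LDF trace, then normalize to its first-``baseline_duration`` mean."""
    p = sliding_window_filter(np.asarray(profile, float), window)
    t = np.asarray(times, float)
    base = p[t < baseline_duration]
    if base.size == 0:
        raise ValueError("no samples inside the baseline period")
    mean = float(np.mean(base))
    if mean == 0:
        raise ZeroDivisionError("zero LDF baseline")
    return p / mean


def analyze_run(
    series: AslSeries,
    t1t: np.ndarray | float,
    m0t: np.ndarray | float,
    acq: AcquisitionParams,
    rois: RoiSet,
    window: int = 3,
    n_reps: int = 20,
    mask: np.ndarray | None = None,
) -> PerfusionResult:
    """Full run analysis: ΔM → CBF maps → filtered ROI profiles → baseline/CVR."""
    series = align_frames(series)
    dm = pairwise_delta_m(series)
    maps = cbf_series(dm, t1t, m0t, acq, mask=mask)
    times = series.dynamic_times()
    profiles: dict[str, np.ndarray] = {}
    base: dict[str, float] = {}
    reactivity: dict[str, float] = {}
    for name in rois.names():
        prof = sliding_window_filter(roi_profile(maps, rois[name]), window)
        profiles[name] = prof
        base[name] = baseline_cbf(prof, times, series.co2_on, n_reps)
        reactivity[name] = cvr(prof, times, series.co2_on, series.co2_off, n_reps)
    return PerfusionResult(
        roi_profiles=profiles, baseline=base, cvr_pct=reactivity, dynamic_times=times
    )
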