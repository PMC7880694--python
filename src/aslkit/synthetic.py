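"""Synthetic data generation with known ground truth.

Generates every input the analysis needs — 4-D pCASL runs with a
hypercapnia block, inversion-recovery series, time-encoded pCASL
signals, laser Doppler flowmetry (LDF) traces, and multi-mouse cohort
endpoint tables — so the whole pipeline can be exercised against known
truth.  The defaults emulate a longitudinal mouse study: 21-minute
pCASL runs of 180 frames with 7.5 % CO₂ administered between minutes 7
and 14, wild-type and transgenic (amyloidosis-model) groups of nine
mice followed at 3, 6, 9 and 12 months under isoflurane plus a terminal
session under urethane/α-chloralose (U&A), and a time-encoded ATT scan
at 12 months with and without CO₂.

Generative endpoint distributions are truncated normals matched to
reported group medians and interquartile ranges, with a mouse-level
random effect carrying the longitudinal correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetic import (
    AcquisitionParams,
    PerfusionTruth,
    TissueParams,
    gkm_delta_m,
    hypercapnia_cbf_profile,
)
from .pipeline import AslSeries, RoiSet
from .relaxometry import IrSeries
from .te_pcasl import TeAslScheme, encode

__all__ = [
    "RegionTruth",
    "PhantomSpec",
    "CohortSpec",
    "default_phantom",
    "uniform_phantom",
    "noise_sd_for_snr",
    "simulate_pcasl_run",
    "simulate_te_pcasl",
    "simulate_ir",
    "simulate_cohort",
    "simulate_ldf",
    "DEFAULT_COHORT1",
]


@dataclass(frozen=True)
class RegionTruth:
    """Ground truth for one phantom region."""

    perfusion: PerfusionTruth
    tissue: TissueParams
    cvr_pct: float = 0.0


@dataclass
class PhantomSpec:
    """Digital perfusion phantom: grid geometry plus per-region truth.

    Regions (disjoint): a dorsal cortex band, a central thalamus blob,
    and the remaining sub-cortical tissue.  A ``midbrain`` ROI covering
    the whole slice is exposed alongside the disjoint regions, mirroring
    a full mid-brain slice ROI.
    """

    grid: tuple[int, int, int] = (12, 12, 3)
    voxel_dims: tuple[float, float, float] = (0.225, 0.225, 1.5)  # mm
    regions: dict[str, RegionTruth] = field(default_factory=dict)
    noise_sd: float = 0.0  # frame noise, fraction of M0t

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.regions:
            raise ValueError("phantom needs at least one region")
        masks = self.region_masks()
        stack = np.stack([masks[n] for n in self.regions], axis=0)
        if (stack.sum(axis=0) > 1).any():
            raise ValueError("region masks must be disjoint")

    def region_masks(self) -> dict[str, np.ndarray]:
        nx, ny, nz = self.grid
        cortex = np.zeros(self.grid, bool)
        cortex[:, ny - 3 :, :] = True  # dorsal band
        thal = np.zeros(self.grid, bool)
        thal[nx // 2 - 2 : nx // 2 + 2, ny // 2 - 2 : ny // 2 + 2, :] = True
        rest = ~(cortex | thal)
        available = {"cortex": cortex, "thalamus": thal, "rest": rest}
        if set(self.regions) == {"uniform"}:
            return {"uniform": np.ones(self.grid, bool)}
        missing = set(self.regions) - set(available)
        if missing:
            raise ValueError(f"unknown region names: {sorted(missing)}")
        return {name: available[name] for name in self.regions}

    def roi_set(self) -> RoiSet:
        """Analysis ROIs: the disjoint regions plus a full-slice midbrain ROI."""
        masks = dict(self.region_masks())
        masks["midbrain"] = np.ones(self.grid, bool)
        return RoiSet(masks=masks)

    def truth_maps(self) -> tuple[np.ndarray, ...]:
        """(cbf, att, cvr, t1t, m0t) voxel maps from region truth."""
        maps = [np.zeros(self.grid) for _ in range(5)]
        masks = self.region_masks()
        for name, rt in self.regions.items():
            m = masks[name]
            maps[0][m] = rt.perfusion.cbf
            maps[1][m] = rt.perfusion.att
            maps[2][m] = rt.cvr_pct
            maps[3][m] = rt.tissue.t1_tissue
            maps[4][m] = rt.tissue.m0_tissue
        return tuple(maps)


def default_phantom(noise_sd: float = 0.0) -> PhantomSpec:
    """Three-region phantom with cortex-dominant reactivity."""
    tissue = TissueParams(t1_tissue=1700.0, m0_tissue=1000.0)
    return PhantomSpec(
        regions={
            "cortex": RegionTruth(PerfusionTruth(cbf=160.0, att=180.0), tissue, 30.0),
            "thalamus": RegionTruth(PerfusionTruth(cbf=140.0, att=220.0), tissue, 10.0),
            "rest": RegionTruth(PerfusionTruth(cbf=120.0, att=200.0), tissue, 15.0),
        },
        noise_sd=noise_sd,
    )


def uniform_phantom(
    cbf: float = 120.0,
    cvr_pct: float = 30.0,
    att: float = 200.0,
    tissue: TissueParams | None = None,
    noise_sd: float = 0.0,
) -> PhantomSpec:
    """Single-region phantom for parameter-recovery experiments."""
    tissue = tissue or TissueParams(t1_tissue=1700.0, m0_tissue=1000.0)
    return PhantomSpec(
        regions={"uniform": RegionTruth(PerfusionTruth(cbf=cbf, att=att), tissue, cvr_pct)},
        noise_sd=noise_sd,
    )


def noise_sd_for_snr(
    truth: PerfusionTruth,
    tissue: TissueParams,
    acq: AcquisitionParams,
    snr: float,
) -> float:
    """Frame noise sd (fraction of M0t) giving a per-dynamic ΔM SNR.

    ΔM is a difference of two frames, so its sd is √2 × the frame sd;
    the returned value makes single-voxel, single-dynamic ΔM/σ equal
    ``snr`` at baseline.
    """
    dm = gkm_delta_m(truth, tissue, acq, acq.tau + acq.pld)
    return float(dm / (snr * np.sqrt(2.0)) / tissue.m0_tissue)


def simulate_pcasl_run(
    phantom: PhantomSpec,
    acq: AcquisitionParams | None = None,
    n_frames: int = 180,
    frame_duration: float = 7.0,
    co2_on: float = 420.0,
    co2_off: float = 840.0,
    tau_response: float = 30.0,
    label_first: bool = True,
    seed: int | np.random.Generator = 0,
) -> AslSeries:
    """Simulate a hypercapnia pCASL run with the phantom's ground truth.

    Control frames are M0t + noise; label frames are M0t − ΔM(t) + noise
    with ΔM from the kinetic model evaluated at readout (t = τ + PLD)
    and CBF(t) following the mono-exponential hypercapnia block profile.
    Additive Gaussian noise with sd ``phantom.noise_sd × M0t`` per frame.
    """
    acq = acq or AcquisitionParams()
    rng = np.random.default_rng(seed)
    cbf_map, att_map, cvr_map, t1t_map, m0t_map = phantom.truth_maps()
    frame_times = np.arange(n_frames) * frame_duration
    vols = np.empty(phantom.grid + (n_frames,))
    masks = phantom.region_masks()
    # per-region ΔM(t) time courses (regions are homogeneous)
    for name, rt in phantom.regions.items():
        cbf_t = hypercapnia_cbf_profile(
            rt.perfusion.cbf, rt.cvr_pct, co2_on, co2_off, tau_response, frame_times
        )
        # ΔM linear in CBF: scale the unit-CBF prediction
        dm_unit = gkm_delta_m(
            PerfusionTruth(cbf=1.0, att=rt.perfusion.att),
            rt.tissue,
            acq,
            acq.tau + acq.pld,
        )
        dm_t = np.atleast_1d(cbf_t) * dm_unit
        m = masks[name]
        label_idx = np.arange(0, n_frames, 2) if label_first else np.arange(1, n_frames, 2)
        sub = np.full((int(m.sum()), n_frames), rt.tissue.m0_tissue)
        sub[:, label_idx] = rt.tissue.m0_tissue - dm_t[label_idx]
        vols[m, :] = sub
    if phantom.noise_sd > 0:
        sd_map = phantom.noise_sd * m0t_map
        vols += rng.standard_normal(vols.shape) * sd_map[..., None]
    return AslSeries(
        volumes=vols,
        frame_duration=frame_duration,
        label_first=label_first,
        co2_on=co2_on,
        co2_off=co2_off,
        voxel_dims=phantom.voxel_dims,
    )


def simulate_ir(
    phantom: PhantomSpec,
    inversion_times,
    inv_factor: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Magnitude IR volumes (x, y, z, TI): |M0(1 − 2β e^(−TI/T1))| + noise."""
    rng = np.random.default_rng(seed)
    ti = np.asarray(inversion_times, float)
    _, _, _, t1t_map, m0t_map = phantom.truth_maps()
    signed = m0t_map[..., None] * (
        1.0 - 2.0 * inv_factor * np.exp(-ti / t1t_map[..., None])
    )
    if phantom.noise_sd > 0:
        signed = signed + rng.standard_normal(signed.shape) * (
            phantom.noise_sd * m0t_map[..., None]
        )
    return np.abs(signed)


def simulate_te_pcasl(
    phantom: PhantomSpec,
    scheme: TeAslScheme,
    acq: AcquisitionParams | None = None,
    seed: int | np.random.Generator = 0,
    att_override: dict[str, float] | None = None,
) -> np.ndarray:
    """Encoded te-pCASL volumes (x, y, z, n_encodes).

    Per-sub-bolus ΔM follows the kinetic model with each region's CBF
    and ATT (optionally overridden, e.g. for a hypercapnic state with
    shortened transit times); the Hadamard scheme mixes sub-boli into
    encode signals on top of the static M0t signal.
    """
    acq = acq or AcquisitionParams()
    rng = np.random.default_rng(seed)
    vols = np.empty(phantom.grid + (scheme.n_encodes,))
    masks = phantom.region_masks()
    for name, rt in phantom.regions.items():
        att = att_override.get(name, rt.perfusion.att) if att_override else rt.perfusion.att
        sub_acq = AcquisitionParams(
            tau=float(scheme.subbolus_durations[0]),
            pld=acq.pld,
            t1_blood=acq.t1_blood,
            lambda_bbp=acq.lambda_bbp,
            alpha=acq.alpha,
        )
        t = scheme.subbolus_durations + scheme.effective_plds
        dm = gkm_delta_m(
            PerfusionTruth(cbf=rt.perfusion.cbf, att=att), rt.tissue, sub_acq, t
        )
        vols[masks[name], :] = encode(dm, scheme, static=rt.tissue.m0_tissue)
    if phantom.noise_sd > 0:
        _, _, _, _, m0t_map = phantom.truth_maps()
        vols += rng.standard_normal(vols.shape) * (phantom.noise_sd * m0t_map[..., None])
    return vols


def simulate_ldf(
    cbf_profile: np.ndarray,
    times: np.ndarray,
    attenuation: float = 0.5,
    noise_sd: float = 0.0,
    gain: float = 250.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """LDF trace from a CBF(t) truth profile.

    LDF senses red-blood-cell flux at the cortical surface and reports
    a smaller fractional hypercapnic response than ASL; ``attenuation``
    scales the fractional CBF change (default 0.5, i.e. the LDF response
    is about half the ASL one).  Returns a DataFrame (time_s, ldf).
    """
    rng = np.random.default_rng(seed)
    p = np.asarray(cbf_profile, float)
    base = float(p[0]) if p[0] != 0 else float(np.mean(p))
    rel = 1.0 + attenuation * (p / base - 1.0)
    sig = gain * rel
    if noise_sd > 0:
        sig = sig + rng.standard_normal(sig.shape) * noise_sd * gain
    return pd.DataFrame({"time_s": np.asarray(times, float), "ldf": sig})


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

#: (median, (q1, q3)) generative defaults per genotype/anesthesia/age/endpoint.
#: Sessions at 3–12 months are isoflurane; 12.3 months is urethane +
#: α-chloralose.  9-month CBF/CVR and early transgenic CVR are held at the
#: nearest reported value (groups were stable from 6 months and genotypes
#: indistinguishable).
DEFAULT_COHORT1: dict = {
    ("WT", "isoflurane"): {
        "cbf": {3: (155, (143, 159)), 6: (121, (112, 124)), 9: (121, (112, 124)), 12: (126, (84, 141))},
        "cvr": {3: (13, (7, 17)), 6: (31, (23, 37)), 9: (31, (23, 37)), 12: (26, (6, 47))},
        "att": {12: (206, (186, 240))},
        "att_co2": {12: (192, (189, 205))},
    },
    ("TG", "isoflurane"): {
        "cbf": {3: (147, (133, 151)), 6: (126, (103, 135)), 9: (126, (103, 135)), 12: (114, (103, 130))},
        "cvr": {3: (13, (7, 17)), 6: (31, (23, 37)), 9: (31, (23, 37)), 12: (30, (17, 34))},
        "att": {12: (223, (202, 246))},
        "att_co2": {12: (197, (187, 207))},
    },
    ("WT", "urethane-chloralose"): {
        "cbf": {12.3: (28, (26, 30))},
        "cvr": {12.3: (233, (193, 245))},
    },
    ("TG", "urethane-chloralose"): {
        "cbf": {12.3: (25, (21, 40))},
        "cvr": {12.3: (265, (178, 312))},
    },
}


@dataclass
class CohortSpec:
    """Cohort design: group sizes, endpoint distributions, dropouts.

    ``params`` maps (genotype, anesthesia) → endpoint → age → (median,
    (q1, q3)).  Values are drawn from normals truncated at zero with
    scale IQR/1.349, sharing a per-mouse standard-normal random effect
    with weight √correlation across sessions (longitudinal correlation).
    ``dropouts`` maps genotype → ages (months) at which one mouse leaves
    the study; sessions after that age are missing for that mouse.
    """

    n_per_group: int = 9
    params: dict = field(default_factory=lambda: DEFAULT_COHORT1)
    dropouts: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {"TG": (2.5, 10.0)}
    )
    correlation: float = 0.5

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if not 0 <= self.correlation <= 1:
            raise ValueError("correlation must be in [0, 1]")


def _trunc_normal(rng: np.random.Generator, loc, scale, z_shared, rho) -> float:
    for _ in range(100):
        z = np.sqrt(rho) * z_shared + np.sqrt(1 - rho) * rng.standard_normal()
        v = loc + scale * z
        if v >= 0:
            return float(v)
    return float(max(loc, 0.0))


def simulate_cohort(
    spec: CohortSpec | None = None, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Per-mouse endpoint table with columns
    (mouse_id, genotype, age_months, anesthesia, endpoint, value).

    Deterministic under a fixed seed.  Dropouts remove all sessions at
    ages strictly greater than the dropout age for the affected mice
    (assigned in mouse-id order within the genotype).
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(seed)
    rows = []
    genotypes = sorted({g for g, _ in spec.params})
    for geno in genotypes:
        drop_ages = spec.dropouts.get(geno, ())
        for i in range(spec.n_per_group):
            mouse = f"{geno}{i + 1:02d}"
            z_shared = rng.standard_normal()
            dropout_age = drop_ages[i] if i < len(drop_ages) else np.inf
            for (g, anesthesia), endpoints in spec.params.items():
                if g != geno:
                    continue
                for endpoint, by_age in endpoints.items():
                    for age, (med, (q1, q3)) in by_age.items():
                        if age > dropout_age:
                            continue
                        scale = (q3 - q1) / 1.349 if q3 > q1 else 0.0
                        v = (
                            _trunc_normal(rng, med, scale, z_shared, spec.correlation)
                            if scale > 0
                            else float(med)
                        )
                        rows.append(
                            {
                                "mouse_id": mouse,
                                "genotype": geno,
                                "age_months": float(age),
                                "anesthesia": anesthesia,
                                "endpoint": endpoint,
                                "value": v,
                            }
                        )
    return pd.DataFrame(rows).sort_values(
        ["genotype", "mouse_id", "age_months", "endpoint"], ignore_index=True
    )
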