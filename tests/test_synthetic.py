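"""Synthetic-data generators: determinism, truth recovery, cohort tables."""

import numpy as np
import pandas as pd
import pytest

from aslkit import analyze_run, estimate_att, decode, fit_inversion_recovery, IrSeries
from aslkit import build_scheme
from aslkit.kinetic import AcquisitionParams, PerfusionTruth, TissueParams
from aslkit.pipeline import ldf_normalize
from aslkit.stats import median_iqr
from aslkit.synthetic import (
    CohortSpec,
    default_phantom,
    noise_sd_for_snr,
    simulate_cohort,
    simulate_ir,
    simulate_ldf,
    simulate_pcasl_run,
    simulate_te_pcasl,
    uniform_phantom,
)


class TestPcaslRun:
    def test_deterministic_under_seed(self, acq):
        ph = default_phantom(noise_sd=0.01)
        a = simulate_pcasl_run(ph, acq, seed=11)
        b = simulate_pcasl_run(ph, acq, seed=11)
        c = simulate_pcasl_run(ph, acq, seed=12)
        assert np.array_equal(a.volumes, b.volumes)
        assert not np.array_equal(a.volumes, c.volumes)

    def test_noiseless_pipeline_recovers_truth(self, acq):
        # for ATT <= PLD the transit decay cancels against the shorter
        # post-bolus decay, so quantification is exact despite att > 0
        ph = default_phantom(noise_sd=0.0)
        s = simulate_pcasl_run(ph, acq, seed=0)
        res = analyze_run(s, 1700.0, 1000.0, acq, ph.roi_set())
        for name, rt in ph.regions.items():
            assert res.baseline[name] == pytest.approx(rt.perfusion.cbf, rel=1e-6)
            assert res.cvr_pct[name] == pytest.approx(rt.cvr_pct, abs=0.2)

    def test_recovery_error_decreases_with_snr(self, acq):
        truth = PerfusionTruth(120.0, 200.0)
        tis = TissueParams(1700.0, 1000.0)
        errs = []
        for snr in (5.0, 40.0):
            sub_errs = []
            for seed in range(4):
                ph = uniform_phantom(cbf=120.0, cvr_pct=30.0, att=200.0,
                                     noise_sd=noise_sd_for_snr(truth, tis, acq, snr))
                s = simulate_pcasl_run(ph, acq, seed=seed)
                res = analyze_run(s, 1700.0, 1000.0, acq, ph.roi_set())
                sub_errs.append(abs(res.cvr_pct["uniform"] - 30.0))
            errs.append(np.mean(sub_errs))
        assert errs[1] < errs[0]


class TestTePcaslAndIr:
    def test_noiseless_te_pcasl_att_exact(self, acq):
        ph = default_phantom(noise_sd=0.0)
        scheme = build_scheme(7)
        vols = simulate_te_pcasl(ph, scheme, acq, seed=0)
        masks = ph.region_masks()
        tis = TissueParams(1700.0, 1000.0)
        for name, rt in ph.regions.items():
            fit = estimate_att(decode(vols[masks[name]].mean(axis=0), scheme), tis, acq)
            assert fit.att == pytest.approx(rt.perfusion.att, abs=1.0)

    def test_hypercapnic_att_override_shortens_estimate(self, acq):
        ph = uniform_phantom(att=223.0, noise_sd=0.0)
        scheme = build_scheme(7)
        tis = TissueParams(1700.0, 1000.0)
        base = simulate_te_pcasl(ph, scheme, acq, seed=0)
        hyper = simulate_te_pcasl(ph, scheme, acq, seed=0, att_override={"uniform": 192.0})
        m = ph.region_masks()["uniform"]
        att_b = estimate_att(decode(base[m].mean(axis=0), scheme), tis, acq).att
        att_h = estimate_att(decode(hyper[m].mean(axis=0), scheme), tis, acq).att
        assert att_h < att_b
        assert att_h == pytest.approx(192.0, abs=1.0)

    def test_ir_series_refit_recovers_t1(self, acq):
        ph = uniform_phantom(noise_sd=0.0)
        ti = np.array([50.0, 150, 300, 600, 1000, 1500, 2500, 4000])
        vols = simulate_ir(ph, ti, seed=0)
        fit = fit_inversion_recovery(IrSeries(vols[0, 0, 0], ti))
        assert fit.t1_tissue == pytest.approx(1700.0, abs=1.0)
        assert fit.m0_tissue == pytest.approx(1000.0, rel=1e-4)


class TestCohort:
    def test_group_sizes_follow_dropout_narrative(self):
        df = simulate_cohort(seed=0)
        at_12 = df[(df.age_months == 12.0) & (df.endpoint == "cbf")]
        sizes = at_12.groupby("genotype").size().to_dict()
        assert sizes == {"WT": 9, "TG": 7}
        at_3 = df[(df.age_months == 3.0) & (df.endpoint == "cbf")]
        assert at_3.groupby("genotype").size().to_dict() == {"WT": 9, "TG": 8}

    def test_large_draw_medians_match_spec(self):
        spec = CohortSpec(
            n_per_group=10_000,
            params={("WT", "isoflurane"): {"cbf": {3: (155, (143, 159))}}},
            dropouts={},
        )
        df = simulate_cohort(spec, seed=1)
        med, q1, q3 = median_iqr(df["value"])
        assert med == pytest.approx(155.0, rel=0.01)
        # the symmetric generative family matches the IQR *width*
        assert q3 - q1 == pytest.approx(159.0 - 143.0, rel=0.03)

    def test_zero_variance_spec_gives_identical_mice(self):
        spec = CohortSpec(
            n_per_group=5,
            params={("WT", "isoflurane"): {"cbf": {3: (120, (120, 120))}}},
            dropouts={},
        )
        df = simulate_cohort(spec, seed=2)
        assert (df["value"] == 120.0).all()

    def test_deterministic_under_seed(self):
        a = simulate_cohort(seed=9)
        b = simulate_cohort(seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_longitudinal_correlation_positive(self):
        spec = CohortSpec(
            n_per_group=2_000,
            params={("WT", "isoflurane"): {"cbf": {3: (155, (143, 159)),
                                                   6: (121, (112, 124))}}},
            dropouts={},
            correlation=0.5,
        )
        wide = simulate_cohort(spec, seed=3).pivot(
            index="mouse_id", columns="age_months", values="value"
        )
        r = np.corrcoef(wide[3.0], wide[6.0])[0, 1]
        assert r == pytest.approx(0.5, abs=0.06)


class TestLdf:
    def test_attenuated_plateau(self):
        t = np.arange(0, 1260, 7.0)
        cbf_t = np.where((t >= 420) & (t < 840), 130.0, 100.0)
        trace = simulate_ldf(cbf_t, t, attenuation=0.5, noise_sd=0.0)
        norm = ldf_normalize(trace["ldf"].to_numpy(), t)
        plateau = norm[(t >= 600) & (t < 800)].mean()
        assert plateau == pytest.approx(1.15, abs=1e-3)

    def test_attenuation_one_matches_asl_cvr(self):
        t = np.arange(0, 1260, 7.0)
        cbf_t = np.where((t >= 420) & (t < 840), 130.0, 100.0)
        trace = simulate_ldf(cbf_t, t, attenuation=1.0, noise_sd=0.0)
        norm = ldf_normalize(trace["ldf"].to_numpy(), t)
        # filter smears the step into the last baseline sample
        base_mean = (59 + (1 + 1 + 1.3) / 3.0) / 60.0
        assert norm[(t >= 600) & (t < 800)].mean() == pytest.approx(1.30 / base_mean, abs=1e-6)
        assert 1.30 / base_mean == pytest.approx(1.30, abs=3e-3)

    def test_seed_reproducibility(self):
        t = np.arange(0, 700, 7.0)
        p = np.full(t.size, 100.0)
        a = simulate_ldf(p, t, noise_sd=0.05, seed=4)
        b = simulate_ldf(p, t, noise_sd=0.05, seed=4)
        pd.testing.assert_frame_equal(a, b)
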