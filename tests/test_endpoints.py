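import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spherotrack.endpoints import (
    WellSeries,
    classify_invasiveness,
    diameter_ratio,
    fit_dose_response,
    normalize_viability,
    relative_tumor_volume,
    summarize_plate,
    tumor_growth_inhibition,
)
from spherotrack.errors import (
    DegenerateControlError,
    InsufficientDataError,
    InvalidArgumentError,
)
from spherotrack.phantom import (
    PhantomConfig,
    iter_plate_wells,
    simulate_viability_readout,
)


def truth_tables(config, doses, conditions=("normoxia",), n_reps=3,
                 n_days=7):
    """metrics/absorbance/layout frames straight from trajectory truth."""
    m_rows, layout_rows, ab_frames = [], [], []
    for meta, traj in iter_plate_wells(config, doses, conditions, n_reps,
                                       n_days):
        layout_rows.append({k: meta[k] for k in
                            ("well", "cell_line_label", "dose_uM",
                             "condition", "replicate")})
        for day, r, amp in zip(traj.days, traj.radius_um,
                               traj.protrusion_amp):
            d = 2 * r
            S = math.pi * r ** 2
            m_rows.append({
                "well": meta["well"], "day": day, "S": S,
                "P_o": 2 * math.pi * r, "P_e": 2 * math.sqrt(math.pi * S),
                "EPI": amp, "roughness": amp / 2, "d": d,
                "V": (4 / 3) * math.pi * (d / 2) ** 3})
        ab = simulate_viability_readout(traj, config, seed=meta["seed"])
        ab.insert(0, "well", meta["well"])
        ab_frames.append(ab)
    return (pd.DataFrame(m_rows), pd.concat(ab_frames, ignore_index=True),
            pd.DataFrame(layout_rows))


class TestRTVAndTGI:
    def test_no_growth_rtv_one(self):
        assert relative_tumor_volume(5.0, 5.0) == 1.0

    def test_diameter_doubled_rtv_eight(self):
        v1 = (4 / 3) * math.pi * 50.0 ** 3
        v2 = (4 / 3) * math.pi * 100.0 ** 3
        assert relative_tumor_volume(v2, v1) == pytest.approx(8.0, rel=1e-12)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(InvalidArgumentError):
            relative_tumor_volume(0.0, 1.0)
        with pytest.raises(InvalidArgumentError):
            relative_tumor_volume(1.0, -1.0)

    def test_tgi_zero_when_equal(self):
        assert tumor_growth_inhibition(2.0, 2.0) == 0.0

    def test_tgi_75_percent(self):
        assert tumor_growth_inhibition(4.0, 1.0) == pytest.approx(75.0)

    def test_tgi_negative_when_treated_grows_more(self):
        assert tumor_growth_inhibition(2.0, 3.0) == pytest.approx(-50.0)

    def test_tgi_control_nonpositive_rejected(self):
        with pytest.raises(InvalidArgumentError):
            tumor_growth_inhibition(0.0, 1.0)

    def test_tgi_unit_invariance(self):
        # RTV is a ratio, so volumes in mm^3 vs um^3 give identical TGI
        f = 1e-9
        rtv_c = relative_tumor_volume(8e6, 1e6)
        rtv_t = relative_tumor_volume(2e6, 1e6)
        rtv_c2 = relative_tumor_volume(8e6 * f, 1e6 * f)
        rtv_t2 = relative_tumor_volume(2e6 * f, 1e6 * f)
        assert tumor_growth_inhibition(rtv_c, rtv_t) == pytest.approx(
            tumor_growth_inhibition(rtv_c2, rtv_t2), rel=1e-12)

    def test_tgi_from_diameters_identity(self):
        # TGI == 100*(1 - (d7/d1)^3_treat / (d7/d1)^3_ctrl)
        d1c, d7c, d1t, d7t = 100.0, 180.0, 100.0, 120.0
        vol = lambda d: (4 / 3) * math.pi * (d / 2) ** 3
        tgi_v = tumor_growth_inhibition(vol(d7c) / vol(d1c),
                                        vol(d7t) / vol(d1t))
        tgi_d = 100.0 * (1 - (d7t / d1t) ** 3 / (d7c / d1c) ** 3)
        assert tgi_v == pytest.approx(tgi_d, rel=1e-12)


class TestDiameterRatio:
    def series(self, diams, days=None):
        days = days or list(range(1, len(diams) + 1))
        return WellSeries(well_id="w", condition="normoxia", dose_uM=0.0,
                          days=days, diameters_um=list(diams),
                          volumes_um3=[(4 / 3) * math.pi * (d / 2) ** 3
                                       for d in diams])

    def test_constant_series(self):
        s = self.series([200.0] * 7)
        assert diameter_ratio(s) == 1.0

    def test_growth_ratio(self):
        s = self.series([100, 110, 120, 130, 140, 150, 160])
        assert diameter_ratio(s, 7, 1) == pytest.approx(1.6)

    def test_shrinking_less_than_one(self):
        s = self.series([100, 95, 90, 85, 80, 75, 70])
        assert diameter_ratio(s) < 1.0

    def test_missing_day_rejected(self):
        s = self.series([100.0, 110.0], days=[1, 2])
        with pytest.raises(InvalidArgumentError):
            diameter_ratio(s, 7, 1)


class TestNormalizeViability:
    def test_identical_sample_and_control(self):
        pairs = [(0.8, 0.3), (0.82, 0.31)]
        v, _ = normalize_viability(pairs, pairs)
        assert v == pytest.approx(100.0)

    def test_half_signal(self):
        control = [(0.9, 0.3)] * 3
        sample = [(0.6, 0.3)] * 3
        v, sem = normalize_viability(sample, control)
        assert v == pytest.approx(50.0)
        assert sem == 0.0

    def test_blank_subtraction(self):
        blank = [(0.15, 0.05)] * 2
        control = [(0.9 + 0.1, 0.3)] * 3
        sample = [(0.65, 0.3)] * 3
        v, _ = normalize_viability(sample, control, blank)
        assert v == pytest.approx(100.0 * 0.25 / 0.6)

    def test_common_gain_invariance(self):
        rng = np.random.default_rng(0)
        sample = rng.uniform(0.4, 0.6, size=(4, 2))
        sample[:, 1] = 0.2
        control = rng.uniform(0.7, 0.9, size=(4, 2))
        control[:, 1] = 0.2
        v1, _ = normalize_viability(sample - [0.2, 0.2], control - [0.2, 0.2])
        v2, _ = normalize_viability(3.0 * (sample - [0.2, 0.2]),
                                    3.0 * (control - [0.2, 0.2]))
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_degenerate_control(self):
        with pytest.raises(DegenerateControlError):
            normalize_viability([(0.5, 0.3)], [(0.3, 0.3)])


class TestClassifyInvasiveness:
    def test_below_threshold(self):
        assert classify_invasiveness(0.4) == "less-invasive"

    def test_above_threshold(self):
        assert classify_invasiveness(0.6) == "invasive"

    def test_exactly_at_threshold_is_invasive(self):
        assert classify_invasiveness(0.5) == "invasive"

    def test_custom_threshold(self):
        assert classify_invasiveness(0.4, threshold=0.3) == "invasive"

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidArgumentError):
            classify_invasiveness(float("nan"))


def four_pl(dose, bottom, top, ic50, slope):
    return bottom + (top - bottom) / (1 + (np.asarray(dose) / ic50) ** slope)


class TestFitDoseResponse:
    DOSES = np.array([0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1.0, 5.0])

    def test_flat_response_ic50_not_reached(self):
        fit = fit_dose_response(self.DOSES, np.full(8, 95.0))
        assert fit.status == "ic50-not-reached"
        assert fit.params is None

    def test_parameter_recovery(self):
        rng = np.random.default_rng(7)
        viab = four_pl(self.DOSES, 10.0, 100.0, 0.05, 1.0)
        viab = viab + rng.normal(0, 3.0, size=viab.shape)
        fit = fit_dose_response(self.DOSES, viab)
        assert fit.status == "ok"
        assert fit.params["ic50"] == pytest.approx(0.05, rel=0.25)

    def test_anomalous_direction_flagged(self):
        viab = np.array([20.0, 25.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0])
        fit = fit_dose_response(self.DOSES, viab)
        assert fit.anomalous_direction

    def test_too_few_doses(self):
        with pytest.raises(InsufficientDataError):
            fit_dose_response([0.01, 0.1, 1.0], [90.0, 60.0, 30.0])

    def test_vehicle_excluded_from_count(self):
        with pytest.raises(InsufficientDataError):
            fit_dose_response([0.0, 0.0, 0.01, 0.1, 1.0],
                              [100.0, 100.0, 90.0, 60.0, 30.0])

    def test_ci_brackets_estimate(self):
        viab = four_pl(self.DOSES, 10.0, 100.0, 0.05, 1.2)
        fit = fit_dose_response(self.DOSES, viab)
        assert fit.status == "ok"
        lo, hi = fit.ic50_ci
        assert lo <= fit.params["ic50"] <= hi


class TestSummarizePlate:
    DOSES = [0.0, 0.001, 0.01, 0.1, 1.0]

    def test_zero_effect_tgi_near_zero(self):
        cfg = PhantomConfig(drug_emax=0.0, noise_sd=0.0, seed=5)
        m, ab, lay = truth_tables(cfg, self.DOSES)
        tables = summarize_plate(m, ab, lay)
        assert np.allclose(tables["tgi"]["TGI_percent"], 0.0, atol=1e-9)

    def test_tgi_monotone_in_dose(self):
        cfg = PhantomConfig(drug_emax=0.9, drug_ec50_uM=0.02,
                            noise_sd=0.0, seed=5)
        m, ab, lay = truth_tables(cfg, self.DOSES, n_reps=6)
        tgi = summarize_plate(m, ab, lay)["tgi"]
        rho = stats.spearmanr(tgi["dose_uM"], tgi["TGI_percent"]).statistic
        assert rho == pytest.approx(1.0)

    def test_hypoxia_drug_factor_raises_tgi(self):
        cfg = PhantomConfig(drug_emax=0.7, drug_ec50_uM=0.02,
                            hypoxia_drug_factor=1.4, noise_sd=0.0, seed=5)
        m, ab, lay = truth_tables(cfg, self.DOSES,
                                  conditions=("normoxia", "hypoxia"),
                                  n_reps=6)
        tgi = summarize_plate(m, ab, lay)["tgi"]
        piv = tgi.pivot(index="dose_uM", columns="condition",
                        values="TGI_percent")
        assert (piv["hypoxia"] >= piv["normoxia"] - 1e-9).all()

    def test_vehicle_viability_is_100(self):
        cfg = PhantomConfig(noise_sd=0.0, seed=5)
        m, ab, lay = truth_tables(cfg, self.DOSES)
        tc = summarize_plate(m, ab, lay)["timecourse"]
        veh = tc[tc["dose_uM"] == 0.0]
        np.testing.assert_allclose(veh["viability_mean"], 100.0, rtol=1e-9)

    def test_flat_viability_reports_ic50_not_reached(self):
        cfg = PhantomConfig(drug_emax=0.05, noise_sd=0.0, seed=5)
        m, ab, lay = truth_tables(cfg, self.DOSES)
        dr = summarize_plate(m, ab, lay)["dose_response"]
        assert dr.loc[0, "status"] == "ic50-not-reached"

    def test_missing_wells_warn_not_crash(self):
        cfg = PhantomConfig(noise_sd=0.0, seed=5)
        m, ab, lay = truth_tables(cfg, self.DOSES)
        m = m[m["well"] != "W0001"]
        with pytest.warns(UserWarning, match="excluded"):
            tables = summarize_plate(m, ab, lay)
        assert len(tables["tgi"]) > 0

    def test_epi_classification_column(self):
        cfg = PhantomConfig(invasion_rate_per_day=0.12, drug_emax=0.9,
                            drug_ec50_uM=0.02, noise_sd=0.0, seed=5)
        m, ab, lay = truth_tables(cfg, self.DOSES)
        d7 = summarize_plate(m, ab, lay)["day7_summary"]
        # EPI proxy = protrusion amp: 0.12*6 days = 0.72 untreated -> invasive
        assert d7[d7["dose_uM"] == 0.0]["invasiveness"].iloc[0] == "invasive"
        assert d7[d7["dose_uM"] == 1.0]["invasiveness"].iloc[0] == "less-invasive"
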