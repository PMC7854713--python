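"""Ratio series, log-ratio regression, and the age clock."""

import logging
import math

import numpy as np
import pytest

import ednaclock as ec
from ednaclock.core import NotEstimableError, ValidationError
from ednaclock.ratio import LN10, ClockUndefinedError

RNA = ec.GeneTarget("16S_141", "mt", "rRNA", 141, "RNA")
DNA = ec.GeneTarget("16S_141", "mt", "rRNA", 141, "DNA")


def _series(target, copies, times, tank="t1"):
    ms = tuple(
        ec.Measurement(tank, target, float(t), copies_per_ml=c)
        if c is not None
        else ec.Measurement(tank, target, float(t), censored=True)
        for t, c in zip(times, copies)
    )
    return ec.ConcentrationSeries(tank, target, ms, abundance=2, replicate="r1")


class TestBuildRatioSeries:
    def test_pointwise_log10(self):
        num = _series(RNA, [100.0, 10.0], [0, 24])
        den = _series(DNA, [10.0, 10.0], [0, 24])
        (rs,) = ec.build_ratio_series([num, den], "R:D")
        assert rs.points == ((0.0, 1.0), (24.0, 0.0))

    def test_censored_member_drops_the_timepoint(self):
        num = _series(RNA, [100.0, None], [0, 24])
        den = _series(DNA, [10.0, 10.0], [0, 24])
        (rs,) = ec.build_ratio_series([num, den], "R:D")
        assert rs.points == ((0.0, 1.0),)

    def test_identical_series_give_zero_ratio(self):
        num = _series(RNA, [5.0, 2.5, 1.0], [0, 5, 12])
        den = _series(DNA, [5.0, 2.5, 1.0], [0, 5, 12])
        (rs,) = ec.build_ratio_series([num, den], "R:D")
        assert all(r == 0.0 for _, r in rs.points)

    def test_no_common_detection_yields_empty_series(self, caplog):
        num = _series(RNA, [100.0, None], [0, 24])
        den = _series(DNA, [None, 10.0], [0, 24])
        with caplog.at_level(logging.WARNING, logger="ednaclock"):
            (rs,) = ec.build_ratio_series([num, den], "R:D")
        assert rs.points == ()
        assert "no common detections" in caplog.text

    def test_short_long_pairing(self, reference_sim):
        series, _ = reference_sim
        rs = ec.build_ratio_series(series, "S:L")
        pairs = {(s.pair[0].label, s.pair[1].label) for s in rs}
        assert ("16S_141_DNA", "16S_341_DNA") in pairs
        assert ("H2B_75_DNA", "H2B_250_DNA") in pairs


class TestRegressRatio:
    def test_noiseless_slope_is_minus_delta_k_over_ln10(self, noiseless_pair_series):
        series, _ = noiseless_pair_series
        reg = ec.regress_ratio(ec.build_ratio_series(series, "R:D"))
        assert abs(reg.slope - (-(0.0561 - 0.0378) / LN10)) <= 1e-12
        assert reg.r2 > 1 - 1e-12

    def test_equal_decay_constants_give_zero_slope(self, pair_16s):
        (t_rna, _), (t_dna, _) = pair_16s
        eq = ((t_rna, ec.KineticParams(11.0, 0.05)), (t_dna, ec.KineticParams(4.0, 0.05)))
        cfg = ec.SimConfig(
            targets=eq, abundances=(2,), replicates_per_abundance=1,
            timepoints_h=ec.REFERENCE_TIMEPOINTS_H,
        )
        series, _ = ec.simulate_experiment(cfg)
        reg = ec.regress_ratio(ec.build_ratio_series(series, "R:D"))
        assert reg.slope == pytest.approx(0.0, abs=1e-13)

    def test_degenerate_inputs_rejected(self):
        num = _series(RNA, [100.0, 10.0], [0, 24])
        den = _series(DNA, [10.0, 10.0], [0, 24])
        (rs,) = ec.build_ratio_series([num, den], "R:D")
        with pytest.raises(NotEstimableError):
            ec.regress_ratio([rs])  # only two pooled points


class TestEstimateAge:
    def test_worked_example(self):
        est = ec.estimate_age(1.0, 3.0, k_rna=0.0561, k_dna=0.0378)
        assert est.t_hat == pytest.approx(LN10 * 2.0 / 0.0183, rel=1e-12)
        assert est.t_hat == pytest.approx(251.6, abs=0.1)

    def test_fresh_material_and_undefined_clock(self, caplog):
        assert ec.estimate_age(3.0, 3.0, 0.0561, 0.0378).t_hat == 0.0
        with caplog.at_level(logging.WARNING, logger="ednaclock"):
            est = ec.estimate_age(3.2, 3.0, 0.0561, 0.0378)
        assert est.t_hat == 0.0
        assert "fresh material" in caplog.text
        with pytest.raises(ClockUndefinedError):
            ec.estimate_age(1.0, 3.0, 0.03, 0.05)

    def test_monotone_in_ratio_drop_and_delta_k(self):
        ages_by_drop = [
            ec.estimate_age(3.0 - d, 3.0, 0.0561, 0.0378).t_hat
            for d in (0.5, 1.0, 1.5, 2.0)
        ]
        assert ages_by_drop == sorted(ages_by_drop)
        assert ages_by_drop[0] < ages_by_drop[-1]
        ages_by_dk = [
            ec.estimate_age(1.0, 3.0, 0.0378 + dk, 0.0378).t_hat
            for dk in (0.01, 0.02, 0.04)
        ]
        assert ages_by_dk == sorted(ages_by_dk, reverse=True)

    def test_bootstrap_interval_contains_estimate_and_is_seeded(self):
        kw = dict(se_k_rna=0.0025, se_k_dna=0.0025, se_baseline=0.1, seed=4)
        a = ec.estimate_age(1.0, 3.0, 0.0561, 0.0378, **kw)
        b = ec.estimate_age(1.0, 3.0, 0.0561, 0.0378, **kw)
        assert a.ci_h == b.ci_h
        assert a.ci_h[0] <= a.t_hat <= a.ci_h[1]
        assert a.ci_h[0] < a.ci_h[1]

    def test_round_trip_on_noiseless_simulation(self, pair_16s):
        for t_true in (0.0, 37.5, 100.0, 240.0):
            cfg = ec.SimConfig(
                targets=pair_16s, abundances=(2,), replicates_per_abundance=1,
                timepoints_h=(0.0, t_true) if t_true > 0 else (0.0,),
            )
            series, _ = ec.simulate_experiment(cfg)
            by = {s.target.key: s for s in series}
            obs = math.log10(
                by[("16S_141", "RNA")].at_time(t_true).copies_per_ml
                / by[("16S_141", "DNA")].at_time(t_true).copies_per_ml
            )
            base = math.log10(
                by[("16S_141", "RNA")].at_time(0.0).copies_per_ml
                / by[("16S_141", "DNA")].at_time(0.0).copies_per_ml
            )
            est = ec.estimate_age(obs, base, 0.0561, 0.0378)
            assert est.t_hat == pytest.approx(t_true, abs=1e-9)


class TestRatioClockModel:
    def test_fitted_clock_ages_noiseless_observations(self, noiseless_pair_series):
        series, _ = noiseless_pair_series
        rs = ec.build_ratio_series(series, "R:D")
        res = ec.RatioClockModel(rs, k_rna=0.0561, k_dna=0.0378).fit()
        obs_at_100 = res.regression.intercept + res.regression.slope * 100.0
        est = res.estimate_age(obs_at_100)
        assert est.t_hat == pytest.approx(100.0, abs=1e-6)

    def test_summary_mentions_fit_quality(self, noiseless_pair_series):
        series, _ = noiseless_pair_series
        res = ec.RatioClockModel(ec.build_ratio_series(series, "R:D")).fit()
        assert "slope" in res.summary() and "R^2" in res.summary()


class TestAgeRecoveryStudy:
    def test_noiseless_study_is_exact(self, pair_16s):
        cfg = ec.SimConfig(
            targets=pair_16s, abundances=(2, 6, 12), replicates_per_abundance=1,
            timepoints_h=ec.REFERENCE_TIMEPOINTS_H,
        )
        df = ec.age_recovery_study(cfg, sample_times=(12.0, 48.0), reps=3, seed=5)
        assert np.allclose(df["bias_h"], 0.0, atol=1e-9)
        assert np.allclose(df["rmse_h"], 0.0, atol=1e-9)
        assert (df["coverage"] == 1.0).all()

    def test_noisy_study_bias_below_rmse_and_rmse_grows_with_age(self, pair_16s):
        cfg = ec.SimConfig(
            targets=pair_16s, abundances=(2, 6, 12, 24, 48),
            replicates_per_abundance=3, timepoints_h=ec.REFERENCE_TIMEPOINTS_H,
            tank_sd=0.3, noise_sd=0.5,
        )
        df = ec.age_recovery_study(cfg, sample_times=(12.0, 72.0), reps=150, seed=5)
        assert (df["bias_h"].abs() < df["rmse_h"]).all()
        rmse = df.set_index("true_age_h")["rmse_h"]
        assert rmse[72.0] > rmse[12.0]
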