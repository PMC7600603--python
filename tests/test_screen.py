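"""Screen engine: normalization identities, 4PL recovery, the DSS integral
against a numerical oracle, the dual-readout hit rule and the follow-up
IC50/sensitization analyses."""

import numpy as np
import pandas as pd
import pytest

from nrf2screen.screen import (DoseResponseSeries, LogisticFit,
                               differential_dss, dss, dss_from_data,
                               fit_logistic4, ic50_and_fold, normalize_plate,
                               sensitization_analysis, to_series)
from nrf2screen.synthetic import generate_sensitization_table


def series_from_fit(bottom, top, ec50, slope, doses=None, noise=0.0, rng=None,
                    line="WT"):
    doses = np.geomspace(1.0, 10_000.0, 5) if doses is None else np.asarray(doses)
    fit = LogisticFit(bottom, top, ec50, slope, True, 0.0)
    y = fit.predict(doses)
    if noise:
        y = y + rng.normal(0.0, noise, len(doses))
    return DoseResponseSeries("c", line, "CTG", doses, y)


class TestNormalization:
    def test_control_anchors_and_midpoint(self, toy_plate):
        norm, qc = normalize_plate(toy_plate)
        resp = norm.set_index("dose_nM")["response_pct"]
        assert resp.loc[1.0] == pytest.approx(0.0)     # at negative-control mean
        assert resp.loc[10.0] == pytest.approx(50.0)   # halfway
        assert resp.loc[100.0] == pytest.approx(100.0)  # at positive-control mean
        assert qc["z_prime"].iloc[0] == pytest.approx(1.0)  # noiseless controls

    def test_toxicity_orientation_maps_to_same_scale(self, toy_plate):
        ctx = toy_plate.copy()
        ctx["readout"] = "CTX"
        # invert the raw signal orientation: high = dead
        ctx["signal"] = 100.0 - ctx["signal"]
        norm, _ = normalize_plate(ctx)
        resp = norm.set_index("dose_nM")["response_pct"]
        assert resp.loc[1.0] == pytest.approx(0.0)
        assert resp.loc[100.0] == pytest.approx(100.0)

    def test_too_few_controls_rejected(self, toy_plate):
        broken = toy_plate[toy_plate["compound"] != "POS_CTRL"]
        with pytest.raises(ValueError, match="control wells"):
            normalize_plate(broken)

    def test_dead_plate_rejected(self, toy_plate):
        dead = toy_plate.copy()
        dead["signal"] = 42.0
        with pytest.raises(ValueError, match="dead plate"):
            normalize_plate(dead)


class TestLogisticFit:
    def test_noiseless_parameters_recovered(self):
        s = series_from_fit(0.0, 100.0, 100.0, 1.0)
        fit = fit_logistic4(s)
        assert fit.converged and fit.n_params == 4
        assert fit.bottom == pytest.approx(0.0, abs=1e-6)
        assert fit.top == pytest.approx(100.0, rel=1e-6)
        assert fit.ec50 == pytest.approx(100.0, rel=1e-6)
        assert fit.hill_slope == pytest.approx(1.0, rel=1e-6)

    @pytest.mark.parametrize("params", [
        (0.0, 80.0, 30.0, 0.7), (5.0, 110.0, 1000.0, 2.5), (0.0, 50.0, 5.0, 1.2),
    ])
    def test_noiseless_recovery_across_parameter_space(self, params):
        fit = fit_logistic4(series_from_fit(*params))
        assert fit.bottom == pytest.approx(params[0], abs=1e-5)
        assert fit.top == pytest.approx(params[1], rel=1e-5)
        assert fit.ec50 == pytest.approx(params[2], rel=1e-4)
        assert fit.hill_slope == pytest.approx(params[3], rel=1e-4)

    def test_inactive_compound_gets_flat_fit_and_zero_dss(self, rng):
        s = series_from_fit(0.0, 0.0, 100.0, 1.0, noise=1.0, rng=rng)
        fit = fit_logistic4(s)
        metrics = dss(fit, 1.0, 10_000.0)
        assert metrics.dss == 0.0

    def test_noisy_ec50_median_recovery(self):
        # 3%-of-scale response noise on 5-point series, true EC50 = 100 nM
        recovered = []
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            s = series_from_fit(0.0, 100.0, 100.0, 1.0, noise=3.0, rng=rng)
            recovered.append(fit_logistic4(s).ec50)
        assert 70.0 <= np.median(recovered) <= 143.0


class TestDss:
    def test_full_inhibition_scores_100(self):
        flat = LogisticFit(100.0, 100.0, 100.0, 1.0, True, 0.0)
        assert dss(flat, 1.0, 10_000.0).dss == pytest.approx(100.0)

    def test_below_threshold_scores_zero(self):
        weak = LogisticFit(0.0, 8.0, 100.0, 1.0, True, 0.0)
        assert dss(weak, 1.0, 10_000.0).dss == 0.0

    def test_closed_form_matches_numerical_oracle(self, rng):
        xgrid = np.linspace(0.0, 4.0, 100_001)
        for _ in range(200):
            b = rng.uniform(-10, 20)
            t = rng.uniform(b, 120)
            m = rng.uniform(-2, 6)
            s = rng.uniform(0.1, 10)
            fit = LogisticFit(b, t, 10.0 ** m, s, True, 0.0)
            closed = dss(fit, 1.0, 10_000.0).dss
            y = np.clip(fit.predict(10.0 ** xgrid) - 10.0, 0.0, 90.0)
            numeric = 100.0 * np.trapezoid(y, xgrid) / (90.0 * 4.0)
            assert closed == pytest.approx(numeric, rel=1e-6, abs=1e-9)

    def test_monotone_in_top(self):
        vals = [dss(LogisticFit(0.0, top, 100.0, 1.0, True, 0.0),
                    1.0, 10_000.0).dss for top in np.linspace(10, 120, 12)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_vanishes_as_ec50_leaves_range(self):
        far = LogisticFit(0.0, 100.0, 1e9, 1.0, True, 0.0)
        assert dss(far, 1.0, 10_000.0).dss < 0.5

    def test_data_trapezoid_agrees_on_dense_series(self):
        doses = np.geomspace(1.0, 10_000.0, 400)
        fit = LogisticFit(0.0, 100.0, 100.0, 1.0, True, 0.0)
        approx = dss_from_data(doses, fit.predict(doses))
        assert approx == pytest.approx(dss(fit, 1.0, 10_000.0).dss, rel=1e-3)


class TestHitCalling:
    def metrics_frame(self, deltas):
        """Build a metrics table with DSS(WT)=20 and DSS(GOF)=20+delta."""
        rows = []
        for comp, (d_ctg, d_ctx) in deltas.items():
            for readout, d in (("CTG", d_ctg), ("CTX", d_ctx)):
                rows.append(dict(compound=comp, cell_line="WT", readout=readout, dss=20.0))
                rows.append(dict(compound=comp, cell_line="GOF", readout=readout,
                                 dss=20.0 + d))
        return pd.DataFrame(rows)

    def test_dual_readout_rule_is_strict(self):
        res = differential_dss(self.metrics_frame({
            "identical": (0.0, 0.0),
            "one_sided": (6.0, 3.0),
            "both_at_5": (5.0, 5.0),
            "real_hit": (12.0, 9.0),
        })).set_index("compound")
        assert not res.loc["identical", "hit"]
        assert res.loc["identical", "min_delta_dss"] == 0.0
        assert not res.loc["one_sided", "hit"]  # 6 and 3: fails CTX
        assert not res.loc["both_at_5", "hit"]  # ties at 5 are not hits
        assert res.loc["real_hit", "hit"]
        assert res.loc["real_hit", "min_delta_dss"] == pytest.approx(9.0)
        assert res.index[0] == "real_hit"  # ranked first

    def test_shift_of_both_lines_leaves_deltas_unchanged(self):
        base = self.metrics_frame({"a": (7.0, 8.0), "b": (2.0, 9.0)})
        shifted = base.copy()
        shifted["dss"] += 30.0
        a = differential_dss(base)
        b = differential_dss(shifted)
        pd.testing.assert_frame_equal(
            a[["compound", "delta_dss_ctg", "delta_dss_ctx", "hit"]],
            b[["compound", "delta_dss_ctg", "delta_dss_ctx", "hit"]])

    def test_compound_missing_one_line_is_excluded(self, caplog):
        frame = self.metrics_frame({"a": (7.0, 8.0)})
        orphan = pd.DataFrame([dict(compound="orphan", cell_line="WT",
                                    readout=ro, dss=50.0) for ro in ("CTG", "CTX")])
        res = differential_dss(pd.concat([frame, orphan], ignore_index=True))
        assert "orphan" not in set(res["compound"])


class TestIc50:
    def test_tenfold_sensitization_recovered_exactly(self):
        wt = series_from_fit(0.0, 100.0, 320.0, 1.0)
        gof = series_from_fit(0.0, 100.0, 32.0, 1.0, line="GOF")
        ic_wt, ic_gof, fold = ic50_and_fold(wt, gof)
        assert ic_wt == pytest.approx(320.0, rel=1e-6)
        assert ic_gof == pytest.approx(32.0, rel=1e-6)
        assert fold == pytest.approx(10.0, rel=1e-6)

    def test_identical_curves_fold_one(self):
        a = series_from_fit(0.0, 90.0, 150.0, 1.3)
        b = series_from_fit(0.0, 90.0, 150.0, 1.3, line="GOF")
        assert ic50_and_fold(a, b)[2] == pytest.approx(1.0, rel=1e-6)

    def test_submaximal_curve_is_censored(self):
        wt = series_from_fit(0.0, 40.0, 100.0, 1.0)   # tops out at 40%
        gof = series_from_fit(0.0, 100.0, 30.0, 1.0, line="GOF")
        ic_wt, _, fold = ic50_and_fold(wt, gof)
        assert np.isnan(ic_wt) and np.isnan(fold)


class TestSensitization:
    def test_null_generator_keeps_all_arms_near_100(self):
        table = generate_sensitization_table(
            at_alone_drop_pct={80.0: 0.0, 200.0: 0.0},
            combo_drop_pct={80.0: 0.0, 200.0: 0.0},
            noise_sd_pct=2.0, n_replicates=5, seed=1)
        combo, alone = sensitization_analysis(table)
        assert combo["mean_viability_pct"].between(95, 105).all()
        assert (combo.dropna(subset=["p_vs_control"])["p_vs_control"] > 0.05).all()
        np.testing.assert_allclose(alone["viability_pct_vs_dmso"], 100.0, atol=4.0)

    def test_combination_arm_drops_and_is_significant(self):
        table = generate_sensitization_table(noise_sd_pct=2.0, n_replicates=5,
                                             seed=2)
        combo, alone = sensitization_analysis(table)
        ind = combo[combo["inducer"] != "DMSO"]
        assert (ind["p_vs_control"] < 0.01).all()
        dmso = combo[combo["inducer"] == "DMSO"].set_index("at9283_nM")
        for _, row in ind.iterrows():
            assert row["mean_viability_pct"] < dmso.loc[row["at9283_nM"],
                                                        "mean_viability_pct"]
        # with zero inducer toxicity the inducer-alone arms stay near 100%
        np.testing.assert_allclose(alone["viability_pct_vs_dmso"], 100.0, atol=4.0)

    def test_missing_control_arm_rejected(self):
        table = generate_sensitization_table(seed=0)
        broken = table[~((table.inducer == "SFN") & (table.at9283_nM == 0))]
        with pytest.raises(ValueError, match="control arm"):
            sensitization_analysis(broken)


class TestToSeries:
    def test_groups_by_compound_line_readout(self, toy_plate):
        norm, _ = normalize_plate(toy_plate)
        series = to_series(norm)
        assert len(series) == 1
        s = series[0]
        assert s.compound == "drugA" and len(s.doses) == 3
        assert (np.diff(s.doses) > 0).all()
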