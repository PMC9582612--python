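"""Excitation law, its inverse, the Shannon boundary and the transfer fit."""

import numpy as np
import pytest

from conftest import random_safety_params
from stimsafe.safety import (
    CathodalExcitationModel,
    adjusted_r2,
    double_layer_field_ratio,
    electric_field,
    fit_full_model,
    fit_single_factor,
    holdout_transfer,
    ilimit_vs_diameter,
    invert_ilimit,
    predict_velec,
    shannon_limit,
)
from stimsafe.types import SafetyParams, ScalingParams, UnitConvention


def grid_records(p, currents, widths, zs, rng=None, noise=0.0):
    rows = []
    for i in currents:
        for t in widths:
            for z in zs:
                v = predict_velec(p, i, t, z)
                if noise:
                    v *= 1.0 + noise * rng.standard_normal()
                rows.append((i, t, z, v))
    return np.asarray(rows)


CURRENTS = (20e-6, 50e-6, 100e-6, 200e-6, 500e-6)
WIDTHS = (100e-6, 200e-6, 400e-6, 700e-6, 1000e-6)
ZS = (1e3, 5e3, 20e3)


class TestForwardLaw:
    def test_zero_current_gives_zero(self, truth_params):
        assert predict_velec(truth_params, 0.0, 1e-4, 1e3) == 0.0

    def test_constructed_log_identity(self):
        # a = 0.5 and argument e^2 - 1 force V = 1 exactly
        p = SafetyParams(a=0.5, b=np.expm1(2.0), k2=1.0, k4=1.0, k6=1.0,
                         unit_convention=UnitConvention(1.0, 1.0, 1.0))
        assert predict_velec(p, 1.0, 1.0, 1.0) == pytest.approx(1.0, rel=1e-14)

    def test_dual_path_oracle(self, rng):
        for _ in range(50):
            p = random_safety_params(rng)
            i, t, z = rng.uniform(1e-6, 1e-3), rng.uniform(1e-5, 1e-3), rng.uniform(1e2, 1e5)
            # independent re-evaluation written from the formula
            x = p.b * (i / 1e-6) ** p.k2 * (t / 1e-6) ** p.k4 * (z / 1e3) ** p.k6
            assert predict_velec(p, i, t, z) == pytest.approx(p.a * np.log(1 + x), rel=1e-12)

    def test_monotone_in_each_factor(self, truth_params):
        base = predict_velec(truth_params, 1e-4, 2e-4, 5e3)
        assert predict_velec(truth_params, 2e-4, 2e-4, 5e3) > base
        assert predict_velec(truth_params, 1e-4, 4e-4, 5e3) > base
        assert predict_velec(truth_params, 1e-4, 2e-4, 1e4) > base

    def test_negative_inputs_rejected(self, truth_params):
        with pytest.raises(ValueError):
            predict_velec(truth_params, -1e-4, 1e-4, 1e3)


class TestInverse:
    def test_zero_threshold_gives_zero_current(self, truth_params):
        assert invert_ilimit(truth_params, 0.0, 1e-4, 1e3) == 0.0

    def test_identity_composition(self, rng):
        for _ in range(200):
            p = random_safety_params(rng)
            e = float(rng.uniform(0.05, 1.5))
            t, z = float(rng.uniform(5e-5, 1e-3)), float(rng.uniform(5e2, 5e4))
            i = invert_ilimit(p, e, t, z)
            assert predict_velec(p, i, t, z) == pytest.approx(e, rel=1e-9)

    def test_monotone_decreasing_in_width_and_impedance(self, truth_params):
        base = invert_ilimit(truth_params, 0.6, 1e-4, 5e3)
        assert invert_ilimit(truth_params, 0.6, 2e-4, 5e3) < base
        assert invert_ilimit(truth_params, 0.6, 1e-4, 1e4) < base
        assert invert_ilimit(truth_params, 0.8, 1e-4, 5e3) > base

    def test_degenerate_inputs_rejected(self, truth_params):
        with pytest.raises(ValueError):
            invert_ilimit(truth_params, 0.6, 0.0, 1e3)


class TestDiameterLimit:
    SCALING = ScalingParams(alpha=6.3e-4, d1=-1.67)

    def test_equals_literal_substitution(self, truth_params):
        d = 100e-6
        z = self.SCALING.alpha * d**self.SCALING.d1
        assert ilimit_vs_diameter(truth_params, self.SCALING, 0.6, 1e-4, d) == (
            invert_ilimit(truth_params, 0.6, 1e-4, z)
        )

    def test_increasing_in_diameter_for_negative_d1(self, truth_params):
        lims = [
            ilimit_vs_diameter(truth_params, self.SCALING, 0.6, 1e-4, d)
            for d in (30e-6, 100e-6, 400e-6, 1e-3)
        ]
        assert np.all(np.diff(lims) > 0)

    def test_doubling_diameter_scales_by_power_law(self):
        p = SafetyParams(a=0.35, b=1e-5, k2=1.0, k4=0.9, k6=1.0)
        s = ScalingParams(alpha=6.3e-4, d1=-1.67)
        r = ilimit_vs_diameter(p, s, 0.6, 1e-4, 2e-4) / ilimit_vs_diameter(
            p, s, 0.6, 1e-4, 1e-4
        )
        assert r == pytest.approx(2**1.67, rel=1e-9)


class TestShannon:
    def test_worked_example_1mm_100us(self):
        r = shannon_limit(1e-3, 1e-4, k=1.8)
        assert r.area_cm2 == pytest.approx(7.854e-3, rel=1e-3)
        assert r.q_per_phase_uc == pytest.approx(0.704, rel=2e-3)
        assert r.i_limit_a == pytest.approx(7.04e-3, rel=2e-3)
        # defining relation: Q^2 = A * 10^k
        assert r.q_per_phase_uc**2 == pytest.approx(r.area_cm2 * 10**1.8, rel=1e-12)

    def test_doubling_width_halves_current_fixed_charge(self):
        r1, r2 = shannon_limit(1e-3, 1e-4), shannon_limit(1e-3, 2e-4)
        assert r2.i_limit_a == pytest.approx(r1.i_limit_a / 2, rel=1e-12)
        assert r2.q_per_phase_uc == r1.q_per_phase_uc

    def test_density_area_charge_identity(self):
        r = shannon_limit(2e-4, 5e-4)
        assert r.charge_density_uc_cm2 * r.area_cm2 == pytest.approx(
            r.q_per_phase_uc, rel=1e-12
        )


class TestFieldEstimates:
    def test_double_layer_field_is_10_mv_per_cm(self):
        assert electric_field(1.0, 1e-9) == pytest.approx(1e7)  # 10 MV/cm

    def test_spreading_region_field_is_10_kv_per_cm(self):
        assert electric_field(10.0, 10e-6) == pytest.approx(1e4)  # 10 kV/cm

    def test_scale_separation_ratio_is_1000(self):
        assert double_layer_field_ratio() == pytest.approx(1000.0)


class TestSingleFactor:
    def test_noiseless_recovery(self):
        x = np.logspace(1, 2.5, 20)
        v = np.log1p(0.01 * x**1.0)
        sf = fit_single_factor("current", x, v)
        assert sf.k_scale == pytest.approx(0.01, rel=1e-6)
        assert sf.k_exp == pytest.approx(1.0, rel=1e-6)

    def test_all_zero_response_flagged_degenerate(self):
        sf = fit_single_factor("pulse_width", np.logspace(0, 1, 10), np.zeros(10))
        assert sf.degenerate and sf.k_scale == 0.0

    def test_noisy_exponent_recovery(self, rng):
        errs = []
        x = np.logspace(1, 2, 20)
        for _ in range(100):
            v = np.log1p(0.02 * x**0.9) * (1 + 0.01 * rng.standard_normal(20))
            errs.append(fit_single_factor("impedance", x, v).k_exp - 0.9)
        assert np.max(np.abs(errs)) < 0.05


class TestFullModel:
    def test_noiseless_grid_recovery(self, truth_params):
        rec = grid_records(truth_params, CURRENTS, WIDTHS, ZS)
        p = fit_full_model(rec)
        for name in ("a", "b", "k2", "k4", "k6"):
            assert getattr(p, name) == pytest.approx(
                getattr(truth_params, name), rel=1e-3
            ), name

    def test_perfect_data_adjusted_r2_is_one(self, truth_params):
        rec = grid_records(truth_params, CURRENTS, WIDTHS, ZS)
        assert fit_full_model(rec).adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_factor_rejected_by_name(self, truth_params):
        rec = grid_records(truth_params, CURRENTS, WIDTHS, (5e3,))
        with pytest.raises(ValueError, match="impedance"):
            fit_full_model(rec)

    def test_fixed_k6_fits_constant_impedance_design(self, truth_params):
        rec = grid_records(truth_params, CURRENTS, WIDTHS, (5e3,))
        p = fit_full_model(rec, fix_k6=1.0)
        assert p.k2 == pytest.approx(truth_params.k2, rel=1e-3)
        assert p.k4 == pytest.approx(truth_params.k4, rel=1e-3)

    def test_sklearn_interface_round_trip(self, truth_params):
        from sklearn.base import clone

        rec = grid_records(truth_params, CURRENTS, WIDTHS, ZS)
        model = CathodalExcitationModel()
        clone(model)  # params must survive get_params/set_params
        model.fit(rec[:, :3], rec[:, 3])
        assert np.allclose(model.predict(rec[:, :3]), rec[:, 3], atol=1e-8)
        assert model.score(rec[:, :3], rec[:, 3]) == pytest.approx(1.0, abs=1e-9)

    def test_noisy_recovery_within_5pct(self, rng):
        truth = SafetyParams(a=0.35, b=1e-5, k2=1.0, k4=0.9, k6=1.05)
        worst = {k: 0.0 for k in ("a", "b", "k2", "k4", "k6")}
        for _ in range(20):
            rec = grid_records(truth, CURRENTS, WIDTHS, ZS, rng=rng, noise=0.01)
            p = fit_full_model(rec)
            for k in worst:
                worst[k] = max(
                    worst[k], abs(getattr(p, k) - getattr(truth, k)) / getattr(truth, k)
                )
        assert max(worst.values()) < 0.05, worst


class TestHoldoutTransfer:
    def test_recovers_shifted_impedance_exponent(self, rng, truth_params):
        truth_iv = SafetyParams(
            a=truth_params.a, b=truth_params.b, k2=truth_params.k2,
            k4=truth_params.k4, k6=1.08,
        )
        rec = grid_records(truth_iv, CURRENTS[:4], WIDTHS[:4], (3e3, 6e3, 12e3, 25e3),
                           rng=rng, noise=0.01)
        k6, r2, _ = holdout_transfer(truth_params, rec)
        assert k6 == pytest.approx(1.08, abs=0.02)
        assert r2 > 0.99

    def test_identical_records_give_perfect_fit(self, truth_params):
        rec = grid_records(truth_params, CURRENTS[:3], WIDTHS[:3], (3e3, 9e3))
        k6, r2, p_val = holdout_transfer(truth_params, rec)
        assert r2 == pytest.approx(1.0, abs=1e-9)
        assert p_val == 1.0

    def test_refit_beats_frozen_misspecified_exponent(self, rng, truth_params):
        truth_iv = SafetyParams(
            a=truth_params.a, b=truth_params.b, k2=truth_params.k2,
            k4=truth_params.k4, k6=1.3,
        )
        rec = grid_records(truth_iv, CURRENTS[:4], WIDTHS[:4], (3e3, 6e3, 12e3, 25e3),
                           rng=rng, noise=0.005)
        k6, r2_refit, _ = holdout_transfer(truth_params, rec)
        pred_frozen = predict_velec(truth_params, rec[:, 0], rec[:, 1], rec[:, 2])
        v = rec[:, 3]
        r2_frozen = 1 - np.sum((v - pred_frozen) ** 2) / np.sum((v - v.mean()) ** 2)
        assert r2_refit > r2_frozen

    def test_too_few_records_rejected(self, truth_params):
        with pytest.raises(ValueError, match=">= 8"):
            holdout_transfer(truth_params, np.ones((5, 4)))


class TestAdjustedR2:
    def test_perfect_prediction(self):
        y = np.arange(10.0)
        assert adjusted_r2(y, y, 5) == 1.0

    def test_mean_prediction_is_nonpositive(self, rng):
        y = rng.standard_normal(30)
        assert adjusted_r2(y, np.full(30, y.mean()), 3) <= 0

    def test_dual_path_formula(self, rng):
        for _ in range(20):
            y = rng.standard_normal(25)
            pred = y + 0.3 * rng.standard_normal(25)
            got = adjusted_r2(y, pred, 5)
            r2 = 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
            want = 1 - (1 - r2) * (25 - 1) / (25 - 5 - 1)
            assert got == pytest.approx(want, rel=1e-12)

    def test_degenerate_length_rejected(self):
        with pytest.raises(ValueError):
            adjusted_r2(np.ones(5), np.ones(5), 5)
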