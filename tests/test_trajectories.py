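"""Trajectory statistics: θ(t), ω, model fits, AIC ranking, Welch test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fusionstats import (
    EggModel,
    Track,
    angle_series,
    angular_velocity_series,
    displacement_series,
    fit_velocity_models,
    half_sphere_comparison,
    normalize_track,
    pairwise_distance_series,
    rank_models_aic,
)
from fusionstats.trajectories import RegressionModelFit


def make_track(times, positions, obj="paternal", **kw):
    return Track(object_id=obj, times=np.asarray(times, float),
                 positions=np.asarray(positions, float), **kw)


class TestAngleSeries:
    def test_coincident_positions_zero(self, egg):
        t = [0.0, 3.0, 6.0]
        pos = [[0, 0, 30]] * 3
        s = angle_series(make_track(t, pos), make_track(t, pos, obj="maternal"), egg)
        assert s["theta_deg"].to_numpy() == pytest.approx([0.0] * 3)

    def test_antipodal_positions_180(self, egg):
        t = [0.0, 3.0]
        pat = make_track(t, [[0, 0, 30]] * 2)
        mat = make_track(t, [[0, 0, -30]] * 2, obj="maternal")
        s = angle_series(pat, mat, egg)
        assert s["theta_deg"].to_numpy() == pytest.approx([180.0] * 2)

    def test_matches_dot_product_oracle(self, egg, rng):
        t = np.arange(0.0, 30.0, 3.0)
        p = rng.normal(size=(len(t), 3)) * 10 + 20
        m = rng.normal(size=(len(t), 3)) * 10 - 20
        s = angle_series(make_track(t, p), make_track(t, m, obj="maternal"), egg)
        for k in range(len(t)):
            u, v = p[k] - egg.center, m[k] - egg.center
            exp = np.degrees(
                np.arccos(np.clip(np.dot(u, v) / np.linalg.norm(u) / np.linalg.norm(v), -1, 1))
            )
            assert s["theta_deg"].iloc[k] == pytest.approx(exp, abs=1e-9)

    def test_non_overlapping_tracks_error(self, egg):
        pat = make_track([0.0, 3.0], [[0, 0, 30]] * 2)
        mat = make_track([100.0, 103.0], [[0, 0, 30]] * 2, obj="maternal")
        with pytest.raises(ValueError):
            angle_series(pat, mat, egg)

    def test_short_maternal_track_carried_forward(self, egg, caplog):
        pat = make_track([0.0, 3.0, 6.0, 9.0], [[0, 0, 30]] * 4)
        mat = make_track([0.0, 3.0], [[30, 0, 0]] * 2, obj="maternal")
        with caplog.at_level("WARNING"):
            s = angle_series(pat, mat, egg)
        assert len(s) == 4
        assert s["theta_deg"].to_numpy() == pytest.approx([90.0] * 4)
        assert "carried forward" in caplog.text


class TestAngularVelocity:
    def test_constant_theta_zero_omega(self):
        s = pd.DataFrame({"time_min": np.arange(0, 30, 3.0), "theta_deg": 70.0})
        rec = angular_velocity_series(s, fusion_time=0.0)
        assert rec["omega"].to_numpy() == pytest.approx(0.0)

    def test_linear_decrease_sign_convention(self):
        """θ falling 3° per 3-min frame is ω = +1 deg/min (approach)."""
        t = np.arange(0, 30, 3.0)
        s = pd.DataFrame({"time_min": t, "theta_deg": 120.0 - t})
        rec = angular_velocity_series(s, fusion_time=0.0)
        assert rec["omega"].to_numpy() == pytest.approx(1.0)
        assert rec["t"].to_numpy() == pytest.approx(t[:-2])

    def test_reflection_flips_omega_exactly(self):
        t = np.arange(0, 60, 3.0)
        theta = 90 + 30 * np.sin(t / 10)
        s = pd.DataFrame({"time_min": t, "theta_deg": theta})
        s_ref = pd.DataFrame({"time_min": t, "theta_deg": 180.0 - theta})
        a = angular_velocity_series(s, fusion_time=0.0)["omega"].to_numpy()
        b = angular_velocity_series(s_ref, fusion_time=0.0)["omega"].to_numpy()
        assert b == pytest.approx(-a)

    def test_mixed_frame_intervals_use_actual_times(self):
        s = pd.DataFrame({"time_min": [0.0, 2.5, 5.5], "theta_deg": [100.0, 97.0, 89.0]})
        rec = angular_velocity_series(s, fusion_time=0.0)
        assert rec["omega"].iloc[0] == pytest.approx((100.0 - 89.0) / 5.5)

    def test_requires_fusion_time(self):
        s = pd.DataFrame({"time_min": [0.0, 3.0, 6.0], "theta_deg": [1, 2, 3.0]})
        with pytest.raises(ValueError):
            angular_velocity_series(s, fusion_time=None)


class TestTrackTransforms:
    def test_normalize_track(self, egg):
        fusion = egg.surface_point(90.0)
        tr = make_track([0.0, 3.0], [egg.center, fusion])
        norm = normalize_track(tr, fusion, egg)
        assert np.linalg.norm(norm.positions[0]) == pytest.approx(0.0)
        assert np.linalg.norm(norm.positions[1]) == pytest.approx(1.0)

    def test_displacement_series(self):
        v = 2.0  # µm/min straight-line motion
        t = np.arange(0, 30, 3.0)
        tr = make_track(t, np.outer(t, [v, 0, 0]))
        d = displacement_series(tr, origin=[0, 0, 0])
        assert d["displacement_um"].to_numpy() == pytest.approx(v * t)
        assert d.attrs["max_displacement_um"] == pytest.approx(v * t[-1])

    def test_pairwise_distance_and_proximity_flag(self):
        t = np.arange(0, 24, 3.0)
        # approach from 50 µm at 2 µm/min: crosses 30 µm strictly after t=10
        a = make_track(t, np.outer(50 - 2 * t, [1, 0, 0]))
        b = make_track(t, np.zeros((len(t), 3)), obj="maternal")
        d = pairwise_distance_series(a, b)
        assert d["distance_um"].to_numpy() == pytest.approx(50 - 2 * t)
        assert d.attrs["first_proximity_entry_min"] == pytest.approx(12.0)

    def test_constant_offset_never_enters(self):
        t = np.arange(0, 12, 3.0)
        a = make_track(t, np.tile([40.0, 0, 0], (len(t), 1)))
        b = make_track(t, np.zeros((len(t), 3)), obj="maternal")
        d = pairwise_distance_series(a, b)
        assert d["distance_um"].to_numpy() == pytest.approx(40.0)
        assert d.attrs["first_proximity_entry_min"] is None


class TestModelFits:
    def test_exact_interaction_recovery_noiseless(self):
        """ω generated exactly as 0.5 − 0.002·θ·t on a grid is recovered to
        1e-6 and the interaction model has the smallest AIC."""
        theta, t = np.meshgrid(np.linspace(10, 170, 15), np.linspace(0, 90, 15))
        rec = pd.DataFrame(
            {"theta": theta.ravel(), "t": t.ravel(),
             "omega": 0.5 - 0.002 * theta.ravel() * t.ravel()}
        )
        fits = fit_velocity_models(rec)
        inter = fits["interaction"]
        assert inter.coefficients["const"] == pytest.approx(0.5, abs=1e-6)
        assert inter.coefficients["theta"] == pytest.approx(0.0, abs=1e-6)
        assert inter.coefficients["t"] == pytest.approx(0.0, abs=1e-6)
        assert inter.coefficients["theta_t"] == pytest.approx(-0.002, abs=1e-6)
        ranking = rank_models_aic(fits)
        assert ranking["model"].iloc[0] == "interaction"

    def test_pure_noise_does_not_reward_extra_terms(self, rng):
        """On pure-noise data the richer models rarely beat the simpler ones
        by more than 2 AIC (each extra useless term costs 2)."""
        wins = 0
        n_rep = 40
        for _ in range(n_rep):
            rec = pd.DataFrame(
                {
                    "theta": rng.uniform(0, 180, 400),
                    "t": rng.uniform(0, 100, 400),
                    "omega": rng.normal(0, 1, 400),
                }
            )
            fits = fit_velocity_models(rec)
            single_best = min(fits["angle_only"].aic, fits["time_only"].aic)
            multi_best = min(fits["additive"].aic, fits["interaction"].aic)
            wins += multi_best < single_best - 2
        assert wins <= 5  # ~roughly the chance level for a 2-AIC gain

    def test_aic_convention(self, rng):
        rec = pd.DataFrame(
            {"theta": rng.uniform(0, 180, 50), "t": rng.uniform(0, 100, 50),
             "omega": rng.normal(0, 1, 50)}
        )
        f = fit_velocity_models(rec)["additive"]
        n = f.n
        sigma2 = f.rss / n
        ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
        assert f.loglik == pytest.approx(ll)
        assert f.k == 4  # intercept + 2 slopes + error variance
        assert f.aic == pytest.approx(2 * f.k - 2 * ll)

    def test_nested_models_nonincreasing_rss(self, rng):
        rec = pd.DataFrame(
            {"theta": rng.uniform(0, 180, 200), "t": rng.uniform(0, 100, 200),
             "omega": rng.normal(0, 1, 200)}
        )
        fits = fit_velocity_models(rec)
        assert fits["additive"].rss <= fits["angle_only"].rss + 1e-9
        assert fits["additive"].rss <= fits["time_only"].rss + 1e-9
        assert fits["interaction"].rss <= fits["additive"].rss + 1e-9

    def test_rank_deficient_design_flagged(self, rng):
        """Constant θ makes every θ-containing design collinear with the
        intercept: those fits are flagged invalid, and with only one valid
        model left there is nothing to rank."""
        rec = pd.DataFrame(
            {"theta": 90.0, "t": rng.uniform(0, 100, 50),
             "omega": rng.normal(0, 1, 50)}
        )
        fits = fit_velocity_models(rec)
        assert not fits["angle_only"].valid
        assert not fits["additive"].valid
        assert not fits["interaction"].valid
        assert fits["time_only"].valid
        with pytest.raises(ValueError):
            rank_models_aic(fits)

    def test_too_few_records_error(self):
        rec = pd.DataFrame({"theta": [1.0, 2], "t": [0.0, 1], "omega": [0.0, 0]})
        with pytest.raises(ValueError):
            fit_velocity_models(rec)


class TestRanking:
    def _fit(self, model_id, aic, k):
        return RegressionModelFit(
            model_id=model_id, coefficients={}, stderr={}, n=10,
            rss=1.0, loglik=0.0, k=k, aic=aic,
        )

    def test_orders_and_deltas(self):
        fits = {
            "a": self._fit("a", 10.0, 3),
            "b": self._fit("b", 12.0, 4),
            "c": self._fit("c", 8.0, 5),
        }
        r = rank_models_aic(fits)
        assert r["model"].tolist() == ["c", "a", "b"]
        assert r["delta_aic"].tolist() == pytest.approx([0.0, 2.0, 4.0])

    def test_tie_breaks_by_fewer_parameters_then_name(self):
        fits = {
            "x": self._fit("x", 5.0, 4),
            "y": self._fit("y", 5.0, 3),
            "z": self._fit("z", 5.0, 3),
        }
        r = rank_models_aic(fits)
        assert r["model"].tolist() == ["y", "z", "x"]

    def test_all_invalid_error(self):
        bad = RegressionModelFit(
            model_id="a", coefficients={}, stderr={}, n=10,
            rss=float("nan"), loglik=float("nan"), k=3, aic=float("nan"), valid=False,
        )
        with pytest.raises(ValueError):
            rank_models_aic({"a": bad})


class TestHalfSphere:
    def test_identical_groups_t_zero(self):
        rec = pd.DataFrame(
            {"theta": [30, 40, 130, 140.0], "t": 0.0, "omega": [1.0, 2.0, 1.0, 2.0]}
        )
        w = half_sphere_comparison(rec)
        assert w.t_statistic == pytest.approx(0.0)
        assert w.p_value == pytest.approx(1.0)

    def test_shifted_group_matches_welch_formula(self, rng):
        omega_s = rng.normal(5.0, 1.0, 30)
        omega_o = rng.normal(0.0, 2.0, 40)
        rec = pd.DataFrame(
            {
                "theta": np.r_[np.full(30, 45.0), np.full(40, 135.0)],
                "t": 0.0,
                "omega": np.r_[omega_s, omega_o],
            }
        )
        w = half_sphere_comparison(rec)
        # closed-form Welch statistic and Welch-Satterthwaite df
        v1, v2 = omega_s.var(ddof=1) / 30, omega_o.var(ddof=1) / 40
        t_exp = (omega_s.mean() - omega_o.mean()) / np.sqrt(v1 + v2)
        df_exp = (v1 + v2) ** 2 / (v1**2 / 29 + v2**2 / 39)
        p_exp = 2 * stats.t.sf(abs(t_exp), df_exp)
        assert w.t_statistic == pytest.approx(t_exp)
        assert w.df == pytest.approx(df_exp)
        assert w.p_value == pytest.approx(p_exp)
        assert w.p_value < 1e-3

    def test_boundary_90_goes_to_opposite_half(self):
        rec = pd.DataFrame(
            {"theta": [45.0, 46.0, 90.0, 91.0], "t": 0.0, "omega": [1.0, 1, 2, 2]}
        )
        w = half_sphere_comparison(rec)
        assert w.n_spindle == 2 and w.n_opposite == 2

    def test_time_window_filter(self):
        rec = pd.DataFrame(
            {
                "theta": [45.0, 45, 135, 135] * 2,
                "t": [0.0] * 4 + [50.0] * 4,
                "omega": [1.0, 2, 3, 4] * 2,
            }
        )
        w = half_sphere_comparison(rec, window=(0.0, 20.0))
        assert w.n_spindle == 2 and w.n_opposite == 2

    def test_small_group_error(self):
        rec = pd.DataFrame({"theta": [45.0, 135, 136], "t": 0.0, "omega": [1.0, 2, 3]})
        with pytest.raises(ValueError):
            half_sphere_comparison(rec)
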