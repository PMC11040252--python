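"""Aerodynamic model: forces, trim solving, stability derivatives,
synthetic generation and serialization."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import morphglide as mg
from morphglide.model import schedule_aero, trim_residual

from conftest import make_constant_model


class TestAeroForces:
    def test_zero_lift_gives_pure_drag(self):
        m = make_constant_model(CL0=0.0, CLa=5.0, CD0=0.02, k_ind=0.0)
        state = mg.BodyState(U=20.0, W=0.0, Q=0.0, Theta=0.0)
        X, Z, M = mg.aero_forces(state, mg.JointConfig(130, 130), m)
        qS = 0.5 * 1.225 * 20.0**2 * 0.268
        assert X == pytest.approx(-qS * 0.02, rel=1e-12)
        assert Z == pytest.approx(0.0, abs=1e-12)

    def test_pure_lift_at_zero_alpha(self):
        m = make_constant_model(CL0=0.5, CD0=0.0, k_ind=0.0)
        state = mg.BodyState(U=20.0, W=0.0, Q=0.0, Theta=0.0)
        X, Z, M = mg.aero_forces(state, mg.JointConfig(130, 130), m)
        qS = 0.5 * 1.225 * 20.0**2 * 0.268
        assert Z == pytest.approx(-qS * 0.5, rel=1e-12)
        assert X == pytest.approx(0.0, abs=1e-12)

    def test_matches_wind_to_body_rotation_oracle(self):
        # Independent formulation: lift/drag in wind axes rotated into body
        # axes with an explicit rotation matrix.
        m = make_constant_model(CL0=0.3, CLa=5.2, CD0=0.03, k_ind=0.07)
        alpha = math.radians(10.0)
        V = 18.0
        state = mg.BodyState(
            U=V * math.cos(alpha), W=V * math.sin(alpha), Q=0.0, Theta=0.0
        )
        X, Z, M = mg.aero_forces(state, mg.JointConfig(140, 150), m)
        CL = 0.3 + 5.2 * alpha
        CD = 0.03 + 0.07 * CL**2
        qS = 0.5 * 1.225 * V**2 * 0.268
        L, D = qS * CL, qS * CD
        R = np.array(
            [
                [math.cos(alpha), -math.sin(alpha)],
                [math.sin(alpha), math.cos(alpha)],
            ]
        )
        # Wind axes: drag along -x_wind, lift along -z_wind.
        Xw, Zw = R @ np.array([-D, -L])
        assert X == pytest.approx(Xw, abs=1e-12 * max(1, abs(Xw)))
        assert Z == pytest.approx(Zw, abs=1e-12 * abs(Zw))

    def test_negative_speed_rejected(self, constant_model):
        state = mg.BodyState(U=-1.0, W=0.0, Q=0.0, Theta=0.0)
        with pytest.raises(mg.InvalidStateError):
            mg.aero_forces(state, mg.JointConfig(130, 130), constant_model)

    def test_out_of_validity_config_rejected(self, constant_model):
        state = mg.BodyState(U=15.0, W=0.0, Q=0.0, Theta=0.0)
        with pytest.raises(mg.DomainError):
            mg.aero_forces(state, mg.JointConfig(90, 130), constant_model)


class TestSolveTrim:
    def test_forced_moment_zero_alpha(self):
        # Cm0 = -Cma * 5 deg forces the zero-moment angle to 5 deg exactly.
        alpha5 = math.radians(5.0)
        m = make_constant_model(Cm0=0.5 * alpha5, Cma=-0.5)
        trim = mg.solve_trim(mg.JointConfig(130, 140), m)
        assert math.atan2(trim.W0, trim.U0) == pytest.approx(alpha5, abs=1e-12)

    def test_drag_free_level_glide(self):
        m = make_constant_model(Cm0=0.0, Cma=-0.5, CD0=0.0, k_ind=0.0, CL0=0.4)
        trim = mg.solve_trim(mg.JointConfig(130, 140), m)
        # gamma = 0 and V = sqrt(2 m g / (rho S CL)).
        assert trim.Theta0 == pytest.approx(0.0, abs=1e-12)
        V_expected = math.sqrt(
            2 * 1.015 * 9.81 / (1.225 * 0.268 * 0.4)
        )
        assert trim.airspeed == pytest.approx(V_expected, rel=1e-12)

    def test_anchor_speeds(self, model, start_config, end_config):
        assert mg.solve_trim(start_config, model).airspeed == pytest.approx(
            33.0, abs=0.5
        )
        assert mg.solve_trim(end_config, model).airspeed == pytest.approx(
            17.0, abs=0.5
        )

    def test_zero_pitch_rate(self, model):
        trim = mg.solve_trim(mg.JointConfig(140, 150), model)
        assert trim.Q0 == 0.0

    @pytest.mark.parametrize("config", [(125.0, 118.0), (150.0, 160.0)])
    def test_against_grid_search_oracle(self, model, config):
        # Brute-force (alpha, V) grid: at equilibrium the total aerodynamic
        # force magnitude equals weight and the pitch moment vanishes, with
        # Theta then fixed by the force direction.  The grid minimum must
        # land on the closed-form trim.
        cfg = mg.JointConfig(*config)
        trim = mg.solve_trim(cfg, model)
        c = {
            k: float(v)
            for k, v in model.surfaces.evaluate(
                cfg.elbow_deg, cfg.wrist_deg
            ).items()
        }
        p = model.parameters
        W_weight = p.mass_kg * p.gravity_m_s2

        def search(a_lo, a_hi, v_lo, v_hi, n=801):
            A, V = np.meshgrid(
                np.linspace(a_lo, a_hi, n), np.linspace(v_lo, v_hi, n)
            )
            CL = c["CL0"] + c["CLa"] * A
            CD = c["CD0"] + c["k_ind"] * CL**2
            Cm = c["Cm0"] + c["Cma"] * A
            qS = 0.5 * p.air_density_kg_m3 * V**2 * p.ref_area_m2
            X = qS * (CL * np.sin(A) - CD * np.cos(A))
            Z = -qS * (CL * np.cos(A) + CD * np.sin(A))
            resid = (np.hypot(X, Z) - W_weight) ** 2 + (qS * 0.286 * Cm) ** 2
            i, j = np.unravel_index(np.argmin(resid), resid.shape)
            theta = math.atan2(X[i, j], -Z[i, j])
            return A[i, j], V[i, j], theta

        a_lo, a_hi, v_lo, v_hi = -0.2, 0.2, 5.0, 50.0
        for _ in range(4):
            a_star, V_star, theta_star = search(a_lo, a_hi, v_lo, v_hi)
            da, dv = (a_hi - a_lo) / 800, (v_hi - v_lo) / 800
            a_lo, a_hi = a_star - 40 * da, a_star + 40 * da
            v_lo, v_hi = V_star - 40 * dv, V_star + 40 * dv
        assert a_star == pytest.approx(
            math.atan2(trim.W0, trim.U0), abs=1e-4
        )
        assert V_star == pytest.approx(trim.airspeed, abs=1e-3)
        assert theta_star == pytest.approx(trim.Theta0, abs=1e-3)

    def test_no_glide_trim_error(self):
        m = make_constant_model(CL0=-0.5, Cm0=0.0)
        with pytest.raises(mg.NoGlideTrimError):
            mg.solve_trim(mg.JointConfig(130, 140), m)

    def test_alpha_band_error(self):
        alpha20 = math.radians(20.0)
        m = make_constant_model(Cm0=0.5 * alpha20, Cma=-0.5)
        with pytest.raises(mg.TrimOutOfBandError):
            mg.solve_trim(mg.JointConfig(130, 140), m)

    def test_trim_residual_small_on_grid(self, model):
        for e in np.linspace(105, 160, 5):
            for w in np.linspace(105, 179, 5):
                cfg = mg.JointConfig(e, w)
                trim = mg.solve_trim(cfg, model)
                res = trim_residual(trim, cfg, model)
                assert np.max(np.abs(res)) < 1e-6


def _sympy_derivative_oracle(coeffs, params):
    """Analytic chain-rule derivatives of the closed-form force model,
    built symbolically — independent of the finite-difference path."""
    import sympy as sp

    U, W, Q = sp.symbols("U W Q", positive=False)
    p = params
    alpha = sp.atan2(W, U)
    V = sp.sqrt(U**2 + W**2)
    qS = sp.Rational(1, 2) * p.air_density_kg_m3 * V**2 * p.ref_area_m2
    qhat = Q * p.ref_chord_m / (2 * V)
    CL = coeffs["CL0"] + coeffs["CLa"] * alpha + coeffs["CLq"] * qhat
    CD = coeffs["CD0"] + coeffs["k_ind"] * CL**2
    Cm = coeffs["Cm0"] + coeffs["Cma"] * alpha + coeffs["Cmq"] * qhat
    X = qS * (CL * sp.sin(alpha) - CD * sp.cos(alpha))
    Z = -qS * (CL * sp.cos(alpha) + CD * sp.sin(alpha))
    M = qS * p.ref_chord_m * Cm
    syms = (U, W, Q)
    funcs = []
    for F in (X, Z, M):
        funcs.append([sp.lambdify(syms, sp.diff(F, s), "numpy") for s in syms])
    return funcs


class TestStabilityDerivatives:
    def test_pitch_damping_sign(self, model):
        d = mg.stability_derivatives(mg.JointConfig(140, 150), model)
        assert d.Mq < 0

    def test_matches_analytic_oracle(self, model, rng):
        # 10 random configurations here; the full 50-configuration check
        # runs in the acceptance suite.
        for _ in range(10):
            cfg = mg.JointConfig(
                rng.uniform(105, 160), rng.uniform(105, 179)
            )
            trim = mg.solve_trim(cfg, model)
            d = mg.stability_derivatives(cfg, model).as_matrix()
            c = {
                k: float(v)
                for k, v in model.surfaces.evaluate(
                    cfg.elbow_deg, cfg.wrist_deg
                ).items()
            }
            oracle = _sympy_derivative_oracle(c, model.parameters)
            exact = np.array(
                [
                    [f(trim.U0, trim.W0, trim.Q0) for f in row]
                    for row in oracle
                ]
            )
            assert np.allclose(d, exact, rtol=1e-5, atol=1e-8)

    def test_vectorized_matches_scalar(self, model, rng):
        e = rng.uniform(105, 160, 5)
        w = rng.uniform(105, 179, 5)
        trims, derivs, Iyy = schedule_aero(model, e, w)
        for i in range(5):
            cfg = mg.JointConfig(e[i], w[i])
            trim = mg.solve_trim(cfg, model)
            d = mg.stability_derivatives(cfg, model)
            assert np.allclose(trims[i], trim.as_array(), rtol=0, atol=1e-12)
            assert np.allclose(
                derivs[i], d.as_matrix().ravel(), rtol=1e-12, atol=0
            )
            assert Iyy[i] == pytest.approx(model.Iyy(cfg), rel=1e-12)


class TestSyntheticModel:
    def test_same_seed_identical_serialization(self, tmp_path):
        a = tmp_path / "a.json"
        b = tmp_path / "b.json"
        mg.save_model(mg.make_synthetic_model(seed=3), a)
        mg.save_model(mg.make_synthetic_model(seed=3), b)
        assert a.read_bytes() == b.read_bytes()

    def test_different_seeds_differ(self):
        m1 = mg.make_synthetic_model(seed=1)
        m2 = mg.make_synthetic_model(seed=2)
        assert not (m1.surfaces.CD0 == m2.surfaces.CD0)

    def test_iyy_spans_printed_range(self, model):
        e, w = np.meshgrid(
            np.linspace(105, 160, 40), np.linspace(105, 179, 40)
        )
        iyy = model.inertia.Iyy(e, w)
        assert iyy.min() == pytest.approx(0.0047, abs=2e-4)
        assert iyy.max() == pytest.approx(0.0086, abs=2e-4)
        assert np.all(iyy >= 0.0047 - 1e-12)
        assert np.all(iyy <= 0.0086 + 1e-12)

    def test_linearized_stability_on_random_configs(self, model, rng):
        for _ in range(20):
            cfg = mg.JointConfig(
                rng.uniform(105, 160), rng.uniform(105, 179)
            )
            J = mg.linearize(cfg, model)
            assert np.max(np.linalg.eigvals(J).real) < 0

    def test_monotone_trim_speed_along_linear_path(
        self, model, trajectories
    ):
        sch = mg.arc_length_schedule(trajectories["linear"], 12.0)
        V = [
            mg.solve_trim(mg.JointConfig(*c), model).airspeed
            for c in sch.configs[::50]
        ]
        assert np.all(np.diff(V) < 0)

    def test_unknown_preset(self):
        with pytest.raises(mg.GeneratorError):
            mg.make_synthetic_model(seed=0, preset="albatross")

    def test_static_stability_everywhere(self, model):
        e, w = np.meshgrid(
            np.linspace(105, 160, 25), np.linspace(105, 179, 25)
        )
        assert np.all(model.surfaces.Cma(e, w) < 0)
        assert np.all(model.surfaces.CLa(e, w) > 0)
        assert np.all(model.surfaces.CD0(e, w) > 0)
        assert np.all(model.surfaces.k_ind(e, w) >= 0)


class TestSerialization:
    def test_round_trip(self, model, tmp_path, rng):
        path = tmp_path / "model.json"
        mg.save_model(model, path)
        loaded = mg.load_model(path)
        e = rng.uniform(105, 160, 20)
        w = rng.uniform(105, 179, 20)
        for name in ("CL0", "CLa", "Cm0", "Cma", "CD0", "k_ind", "CLq", "Cmq"):
            orig = getattr(model.surfaces, name)(e, w)
            back = getattr(loaded.surfaces, name)(e, w)
            assert np.allclose(orig, back, rtol=0, atol=1e-12)
        assert np.allclose(
            model.inertia.Iyy(e, w), loaded.inertia.Iyy(e, w), atol=1e-15
        )
        assert loaded.elbow_range == model.elbow_range

    def test_missing_surface_rejected(self, model, tmp_path):
        import json

        path = tmp_path / "model.json"
        mg.save_model(model, path)
        raw = json.loads(path.read_text())
        del raw["surfaces"]["Cmq"]
        path.write_text(json.dumps(raw))
        with pytest.raises(mg.ModelFormatError, match="Cmq"):
            mg.load_model(path)

    def test_bad_format_field_rejected(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text('{"format": "something-else"}')
        with pytest.raises(mg.ModelFormatError, match="format"):
            mg.load_model(path)

    def test_hand_written_constant_surface_file(self, tmp_path):
        import json

        surfaces = {
            name: {"e^0 w^0": val}
            for name, val in [
                ("CL0", 0.2), ("CLa", 5.0), ("Cm0", 0.05), ("Cma", -0.5),
                ("CD0", 0.02), ("k_ind", 0.05), ("CLq", 3.0), ("Cmq", -12.0),
            ]
        }
        doc = {
            "format": "morphglide-aero-1",
            "parameters": {
                "mass_kg": 1.015, "gravity_m_s2": 9.81,
                "ref_area_m2": 0.268, "ref_chord_m": 0.286,
                "air_density_kg_m3": 1.225,
            },
            "surfaces": surfaces,
            "inertia": {"Iyy": {"e^0 w^0": 0.006}},
            "validity": {"elbow_deg": [105, 160], "wrist_deg": [105, 179]},
        }
        path = tmp_path / "const.json"
        path.write_text(json.dumps(doc))
        m = mg.load_model(path)
        for e, w in [(110, 120), (150, 170)]:
            c = m.surfaces.evaluate(e, w)
            assert float(c["CL0"]) == 0.2
            assert float(c["Cmq"]) == -12.0
            assert m.Iyy(mg.JointConfig(e, w)) == 0.006


@given(
    mass=st.floats(0.5, 2.0),
    CL=st.floats(0.05, 1.0),
    CD=st.floats(0.005, 0.2),
)
def test_trim_force_balance_property(mass, CL, CD):
    """Wind-axis force balance holds for any (mass, CL, CD): substituting
    the returned trim into the absolute nonlinear EOM gives ~zero."""
    m = make_constant_model(CL0=CL, Cm0=0.0, CD0=CD, k_ind=0.0)
    m = mg.AeroModel(
        parameters=mg.BirdParameters(mass_kg=mass),
        surfaces=m.surfaces,
        inertia=m.inertia,
    )
    cfg = mg.JointConfig(130, 140)
    trim = mg.solve_trim(cfg, m)
    res = trim_residual(trim, cfg, m)
    assert np.max(np.abs(res)) < 1e-9
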