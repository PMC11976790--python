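"""Engine: fields, pair forces, integration, boundaries, noise statistics."""

import numpy as np
import pytest

from microswim import (
    Action,
    Colloid,
    ConcentrationField,
    LangevinEngine,
    SystemParams,
    field_gradient,
    field_value,
    wca_force,
)
from microswim.engine import wca_cutoff

from conftest import CountingForceFunction, make_colloids


# ---------------------------------------------------------------------------
# concentration field
# ---------------------------------------------------------------------------


class TestField:
    def setup_method(self):
        self.fld = ConcentrationField(source=np.array([3.0, 4.0]), c0=2.5, sigma_c=1.5)

    def test_maximum_at_source(self):
        assert field_value(self.fld, self.fld.source) == pytest.approx(2.5)

    def test_decay_to_zero_far_away(self):
        far = self.fld.source + np.array([1e3, 0.0])
        assert field_value(self.fld, far) < 1e-12

    def test_unit_distance_value(self):
        # c0=1, sigma=1, |x - source| = 1 -> exp(-1/2)
        fld = ConcentrationField(source=np.zeros(2), c0=1.0, sigma_c=1.0)
        assert field_value(fld, np.array([1.0, 0.0])) == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_positive_everywhere_and_batch(self):
        xs = np.random.default_rng(0).uniform(-10, 10, size=(50, 2))
        vals = field_value(self.fld, xs)
        assert vals.shape == (50,)
        assert (vals > 0).all()

    def test_gradient_points_to_source(self):
        x = np.array([0.0, 0.0])
        g = field_gradient(self.fld, x)
        to_source = self.fld.source - x
        assert np.dot(g, to_source) > 0

    def test_nonfinite_position_rejected(self):
        with pytest.raises(ValueError):
            field_value(self.fld, np.array([np.nan, 0.0]))


# ---------------------------------------------------------------------------
# WCA pair force
# ---------------------------------------------------------------------------


class TestWCA:
    def test_zero_at_cutoff_and_beyond(self):
        r = np.array([wca_cutoff(1.0), 0.0])
        assert np.allclose(wca_force(r, 1.0, 1.0), 0.0)
        assert np.allclose(wca_force(np.array([5.0, 0.0]), 1.0, 1.0), 0.0)

    def test_magnitude_at_sigma(self):
        # 24*eps*(2*sigma^12/r^13 - sigma^6/r^7) at eps=sigma=r=1 -> 24
        f = wca_force(np.array([1.0, 0.0]), 1.0, 1.0)
        assert np.linalg.norm(f) == pytest.approx(24.0, rel=1e-12)
        assert f[0] > 0  # repulsive, pushes i away from j

    def test_overlap_warning_and_cap(self):
        with pytest.warns(RuntimeWarning, match="capped"):
            f = wca_force(np.array([0.2, 0.0]), 1.0, 1.0)
        with pytest.warns(RuntimeWarning):
            f_deeper = wca_force(np.array([0.1, 0.0]), 1.0, 1.0)
        # both are capped at the 0.5 sigma magnitude
        assert np.linalg.norm(f) == pytest.approx(np.linalg.norm(f_deeper))
        assert np.linalg.norm(f) == pytest.approx(
            24.0 * (2.0 / 0.5**13 - 1.0 / 0.5**7)
        )

    def test_zero_separation_rejected(self):
        with pytest.raises(ValueError):
            wca_force(np.zeros(2), 1.0, 1.0)


# ---------------------------------------------------------------------------
# deterministic stepping
# ---------------------------------------------------------------------------


class TestStep:
    def test_fixed_point_at_zero_temperature(self, simple_params):
        eng = LangevinEngine(make_colloids(4), simple_params)
        before = eng.pos.copy()
        for _ in range(10):
            eng.step([Action() for _ in range(4)])
        assert np.array_equal(eng.pos, before)

    def test_ballistic_displacement(self):
        params = SystemParams(temperature=0.0, gamma_t=2.0, dt=0.01, boundary="open")
        eng = LangevinEngine(make_colloids(1), params)
        eng.step([Action(force=5.0)])
        # displacement = F dt / gamma_t along the director (x axis)
        assert eng.pos[0, 0] == pytest.approx(10.0 + 5.0 * 0.01 / 2.0, abs=1e-14)
        assert eng.pos[0, 1] == pytest.approx(10.0)

    def test_torque_rotates_director(self, simple_params):
        eng = LangevinEngine(make_colloids(1), simple_params)
        eng.step([Action(torque=np.array([0.0, 0.0, 2.0]))])
        theta = np.arctan2(eng.directors[0, 1], eng.directors[0, 0])
        assert theta == pytest.approx(2.0 * 0.01, abs=1e-14)  # ccw for +z torque

    def test_new_direction_overrides_torque(self, simple_params):
        eng = LangevinEngine(make_colloids(1), simple_params)
        target = np.array([0.0, 1.0])
        eng.step([Action(torque=np.array([0.0, 0.0, 5.0]), new_direction=target)])
        assert np.allclose(eng.directors[0], target)

    def test_action_count_mismatch(self, simple_params):
        eng = LangevinEngine(make_colloids(3), simple_params)
        with pytest.raises(ValueError):
            eng.step([Action()])

    def test_director_unit_norm_invariant(self):
        params = SystemParams(temperature=1.0, dt=0.01, boundary="open", seed=5)
        eng = LangevinEngine(make_colloids(20), params)
        acts = [Action(torque=np.array([0.0, 0.0, 3.0]))] * 20
        for _ in range(50):
            eng.step(acts)
        assert np.allclose(np.linalg.norm(eng.directors, axis=1), 1.0, atol=1e-9)

    def test_3d_step_keeps_unit_directors(self):
        params = SystemParams(dimension=3, temperature=0.5, dt=0.01, boundary="open", seed=2)
        cols = [
            Colloid(i, 0, np.array([5.0, 5.0, 5.0 + i]), np.array([0.0, 0.0, 1.0]))
            for i in range(10)
        ]
        eng = LangevinEngine(cols, params)
        for _ in range(20):
            eng.step([Action(force=1.0, torque=np.array([0.5, 0.0, 0.0]))] * 10)
        assert np.allclose(np.linalg.norm(eng.directors, axis=1), 1.0, atol=1e-9)
        assert np.isfinite(eng.pos).all()


# ---------------------------------------------------------------------------
# integrate / get_particle_data contract
# ---------------------------------------------------------------------------


class TestIntegrate:
    def test_zero_slices_keeps_initial_snapshot(self, simple_params):
        eng = LangevinEngine(make_colloids(3), simple_params)
        rec = eng.integrate(CountingForceFunction(), 0, 10)
        assert rec.positions.shape[0] == 1

    def test_loop_accounting(self, simple_params):
        eng = LangevinEngine(make_colloids(2), simple_params)
        ff = CountingForceFunction()
        calls = {"n": 0}
        orig = eng.step

        def counted(actions):
            calls["n"] += 1
            return orig(actions)

        eng.step = counted
        rec = eng.integrate(ff, 5, 10)
        assert ff.calls == 5
        assert calls["n"] == 50
        assert rec.n_slices == 5

    def test_kill_switch_halts_at_firing_slice(self, simple_params):
        eng = LangevinEngine(make_colloids(2), simple_params)
        rec = eng.integrate(CountingForceFunction(kill_at=3), 10, 2)
        assert rec.positions.shape[0] == 3 + 1

    def test_get_particle_data_snapshots(self, simple_params):
        eng = LangevinEngine(make_colloids(7), simple_params)
        data = eng.get_particle_data()
        assert len(data) == 7
        assert [c.id for c in data] == [c.id for c in eng.get_particle_data()]
        data[0].pos += 99.0  # mutating the snapshot must not touch the engine
        assert eng.pos[0, 0] == pytest.approx(10.0)

    def test_single_step_matches_hand_computation(self):
        params = SystemParams(temperature=0.0, gamma_t=1.0, dt=0.1, boundary="open")
        eng = LangevinEngine(make_colloids(2), params)
        expected = eng.pos + 0.1 * 3.0 * eng.directors
        eng.integrate(
            type(
                "FF",
                (),
                {
                    "calc_action": lambda self, c: [Action(force=3.0)] * len(c),
                    "kill_switch": False,
                },
            )(),
            1,
            1,
        )
        got = np.array([c.pos for c in eng.get_particle_data()])
        assert np.allclose(got, expected, atol=1e-14)

    def test_determinism_bit_identical(self):
        def run():
            params = SystemParams(temperature=1.0, dt=0.01, seed=99, boundary="periodic",
                                  box_length=20.0)
            eng = LangevinEngine(make_colloids(10), params)
            return eng.integrate(CountingForceFunction(), 20, 5)

        a, b = run(), run()
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.directors, b.directors)


# ---------------------------------------------------------------------------
# boundaries and noise statistics
# ---------------------------------------------------------------------------


class TestBoundariesAndNoise:
    def test_periodic_positions_inside_box(self):
        params = SystemParams(temperature=2.0, dt=0.05, boundary="periodic", box_length=5.0, seed=1)
        eng = LangevinEngine(make_colloids(50, spacing=0.05), params)
        for _ in range(200):
            eng.step([Action(force=5.0)] * 50)
        assert (eng.pos >= 0).all() and (eng.pos < 5.0).all()

    def test_minimum_image_within_half_diagonal(self):
        params = SystemParams(temperature=1.0, dt=0.05, boundary="periodic", box_length=8.0, seed=3)
        eng = LangevinEngine(make_colloids(20, spacing=0.3), params)
        for _ in range(100):
            eng.step([Action(force=3.0)] * 20)
        rij = eng.pos[:, None, :] - eng.pos[None, :, :]
        rij -= 8.0 * np.round(rij / 8.0)
        dist = np.linalg.norm(rij, axis=-1)
        assert dist.max() <= np.linalg.norm([4.0, 4.0]) + 1e-12

    def test_reflective_positions_inside_box(self):
        params = SystemParams(
            temperature=2.0, dt=0.05, boundary="reflective", box_length=5.0, seed=7
        )
        eng = LangevinEngine(make_colloids(30, spacing=0.1), params)
        for _ in range(200):
            eng.step([Action(force=10.0)] * 30)
        assert (eng.pos >= 0).all() and (eng.pos <= 5.0).all()

    def test_thermal_noise_moments(self):
        # one passive step: displacement / sqrt(2 D dt) should be N(0, I)
        n = 100_000
        params = SystemParams(temperature=1.5, gamma_t=2.0, dt=0.01, boundary="open", seed=11)
        rng = np.random.default_rng(0)
        cols = [Colloid(i, 0, rng.uniform(0, 50, 2), np.array([1.0, 0.0])) for i in range(n)]
        eng = LangevinEngine(cols, params)
        before = eng.pos.copy()
        eng.step([Action()] * n)
        xi = (eng.pos - before) / np.sqrt(2 * 1.5 / 2.0 * 0.01)
        assert np.abs(xi.mean(axis=0)).max() < 4 / np.sqrt(n)
        cov = np.cov(xi.T)
        assert np.allclose(cov, np.eye(2), atol=0.05)

    def test_nan_forces_raise(self):
        params = SystemParams(temperature=0.0, dt=0.01, boundary="open")
        eng = LangevinEngine(make_colloids(1), params)
        eng.external_force = lambda pos, types: np.full_like(pos, np.nan)
        with pytest.raises(FloatingPointError):
            eng.step([Action()])


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"dt": -1.0},
            {"temperature": -0.5},
            {"gamma_t": 0.0},
            {"gamma_r": -2.0},
            {"boundary": "bouncy"},
            {"interaction": "lj"},
            {"dimension": 4},
        ],
    )
    def test_bad_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SystemParams(**kwargs)

    def test_duplicate_ids_rejected(self, simple_params):
        cols = make_colloids(2)
        cols[1].id = cols[0].id
        with pytest.raises(ValueError):
            LangevinEngine(cols, simple_params)
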