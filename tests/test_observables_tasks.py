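"""Observables (sensing) and tasks (rewards, kill switch, composition)."""

import numpy as np
import pytest

from microswim import (
    Action,
    Colloid,
    ConcentrationChange,
    ConcentrationField,
    ConstantTask,
    GradientClimbing,
    LangevinEngine,
    MultiSensing,
    Multitasking,
    NeighborSensing,
    PositionObservable,
    RodRotation,
    SystemParams,
    TimeLimitTask,
)
from microswim.observables import Observable

from conftest import CountingForceFunction


def colloid(i, x, y, ex=1.0, ey=0.0, ptype=0):
    return Colloid(i, ptype, np.array([x, y], float), np.array([ex, ey], float))


@pytest.fixture
def fld():
    return ConcentrationField(source=np.array([0.0, 0.0]), c0=1.0, sigma_c=2.0)


class TestConcentrationChange:
    def test_first_slice_and_stationary_are_zero(self, fld):
        obs = ConcentrationChange(fld, scale=3.0)
        c = [colloid(0, 1.0, 0.0)]
        assert obs.compute_observable(c)[0] == pytest.approx(0.0)  # first slice
        assert obs.compute_observable(c)[0] == pytest.approx(0.0)  # slice 2 on, static

    def test_motion_toward_source_gives_positive_change(self, fld):
        obs = ConcentrationChange(fld, scale=1.0)
        obs.compute_observable([colloid(0, 3.0, 0.0)])
        out = obs.compute_observable([colloid(0, 2.0, 0.0)])
        assert out[0][0] > 0
        away = obs.compute_observable([colloid(0, 4.0, 0.0)])
        assert away[0][0] < 0

    def test_scale_applied(self, fld):
        a, b = ConcentrationChange(fld, scale=1.0), ConcentrationChange(fld, scale=10.0)
        for o in (a, b):
            o.compute_observable([colloid(0, 3.0, 0.0)])
        va = a.compute_observable([colloid(0, 2.0, 0.0)])[0][0]
        vb = b.compute_observable([colloid(0, 2.0, 0.0)])[0][0]
        assert vb == pytest.approx(10 * va)

    def test_reset_clears_history(self, fld):
        obs = ConcentrationChange(fld)
        obs.compute_observable([colloid(0, 3.0, 0.0)])
        obs.reset()
        assert obs.compute_observable([colloid(0, 1.0, 0.0)])[0][0] == pytest.approx(0.0)


class TestNeighborSensing:
    def test_hand_counted_configuration(self):
        # subject at origin; neighbors at r = 1, 2, 3.5, 5 with radius 3
        cols = [
            colloid(0, 0.0, 0.0),
            colloid(1, 1.0, 0.0),
            colloid(2, 0.0, 2.0),
            colloid(3, 3.5, 0.0),
            colloid(4, 0.0, 5.0),
        ]
        obs = NeighborSensing(radius=3.0)
        out = obs.compute_observable([cols[0]], cols)
        assert out[0][0] == 2  # hand count: ids 1 and 2
        assert np.allclose(out[0][1:], np.array([1.0, 2.0]) / 2 / 3.0)

    def test_no_neighbors_gives_zeros(self):
        obs = NeighborSensing(radius=1.0)
        out = obs.compute_observable([colloid(0, 0.0, 0.0)], [colloid(0, 0.0, 0.0)])
        assert np.allclose(out[0], 0.0)

    def test_dimension_constant_across_slices(self):
        obs = NeighborSensing(radius=2.0)
        cols = [colloid(0, 0.0, 0.0), colloid(1, 1.0, 0.0)]
        for _ in range(3):
            out = obs.compute_observable(cols, cols)
            assert all(v.shape == (obs.dimension,) for v in out)


class TestMultiSensing:
    def test_single_observable_identity(self, fld):
        inner = ConcentrationChange(fld)
        multi = MultiSensing([ConcentrationChange(fld)])
        c = [colloid(0, 2.0, 0.0)]
        assert np.allclose(multi.compute_observable(c)[0], inner.compute_observable(c)[0])

    def test_dimensions_sum_and_block_order(self, fld):
        box = np.array([10.0, 10.0])
        multi = MultiSensing([PositionObservable(box), NeighborSensing(radius=2.0)])
        rev = MultiSensing([NeighborSensing(radius=2.0), PositionObservable(box)])
        assert multi.dimension == 2 + 3
        cols = [colloid(0, 4.0, 6.0), colloid(1, 4.5, 6.0)]
        a = multi.compute_observable(cols, cols)[0]
        b = rev.compute_observable(cols, cols)[0]
        assert np.allclose(a[:2], b[3:])  # permuting declaration permutes blocks
        assert np.allclose(a[2:], b[:3])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            MultiSensing([])

    def test_purity_no_mutation(self, fld):
        multi = MultiSensing([ConcentrationChange(fld)])
        cols = [colloid(0, 2.0, 3.0)]
        before = cols[0].pos.copy()
        multi.compute_observable(cols)
        assert np.array_equal(cols[0].pos, before)


class TestGradientClimbing:
    def test_stationary_system_zero_reward(self, fld):
        task = GradientClimbing(fld, scale=2.0)
        c = [colloid(0, 1.0, 1.0)]
        assert np.allclose(task(c), 0.0)
        assert np.allclose(task(c), 0.0)

    def test_up_gradient_positive_down_gradient_clipped(self, fld):
        task = GradientClimbing(fld, scale=1.0)
        task([colloid(0, 3.0, 0.0)])
        assert task([colloid(0, 2.0, 0.0)])[0] > 0
        assert task([colloid(0, 4.0, 0.0)])[0] == 0.0  # clipped negative gain

    def test_signed_variant(self, fld):
        task = GradientClimbing(fld, clip_negative=False)
        task([colloid(0, 2.0, 0.0)])
        assert task([colloid(0, 4.0, 0.0)])[0] < 0

    def test_threshold_latches_kill(self, fld):
        task = GradientClimbing(fld, threshold=0.9)
        task([colloid(0, 5.0, 0.0)])
        assert not task.kill_switch
        task([colloid(0, 0.0, 0.0)])  # at source, c = 1 >= 0.9
        assert task.kill_switch
        task([colloid(0, 5.0, 0.0)])  # latched even after moving away
        assert task.kill_switch


class TestRodRotation:
    def _beads(self, angle, n=3, ptype=1):
        axis = np.array([np.cos(angle), np.sin(angle)])
        return [
            Colloid(100 + k, ptype, (k - 1) * axis, axis.copy()) for k in range(n)
        ]

    def test_rotation_reward_finite_difference(self):
        task = RodRotation(rod_type=1, scale=1.0, slice_dt=1.0)
        pushers = [colloid(0, 5.0, 5.0)]
        assert task(pushers, pushers + self._beads(0.0))[0] == 0.0  # first slice
        r = task(pushers, pushers + self._beads(0.1))
        assert r[0] == pytest.approx(0.1, abs=1e-12)

    def test_sense_flips_sign(self):
        task = RodRotation(rod_type=1, sense=-1, slice_dt=1.0)
        pushers = [colloid(0, 5.0, 5.0)]
        task(pushers, pushers + self._beads(0.0))
        assert task(pushers, pushers + self._beads(0.2))[0] == pytest.approx(-0.2)

    def test_angle_wraps_on_nearest_branch(self):
        task = RodRotation(rod_type=1, slice_dt=1.0)
        pushers = [colloid(0, 5.0, 5.0)]
        task(pushers, pushers + self._beads(np.pi - 0.05))
        r = task(pushers, pushers + self._beads(-np.pi + 0.05))
        assert r[0] == pytest.approx(0.1, abs=1e-9)

    def test_missing_rod_raises(self):
        task = RodRotation(rod_type=1)
        with pytest.raises(ValueError):
            task([colloid(0, 0.0, 0.0)], [colloid(0, 0.0, 0.0)])


class TestKillSwitch:
    def test_time_condition_before_and_after_limit(self):
        task = TimeLimitTask(limit=3)
        c = [colloid(0, 0.0, 0.0)]
        task(c)
        task(c)
        assert not task.kill_switch
        task(c)
        assert task.kill_switch

    def test_engine_records_exactly_k_slices(self, simple_params):
        # latched switch at slice k -> k recorded slices after start
        k = 4
        ff = CountingForceFunction(kill_at=k)
        eng = LangevinEngine(
            [colloid(0, 10.0, 10.0), colloid(1, 14.0, 10.0)], simple_params
        )
        rec = eng.integrate(ff, 10, 3)
        assert rec.n_slices == k


class TestMultitasking:
    def test_single_task_identity(self, fld):
        c = [colloid(0, 2.0, 0.0)]
        single = ConstantTask(1.25)
        combo = Multitasking([ConstantTask(1.25)])
        assert np.allclose(combo(c), single(c))

    def test_task_plus_negation_cancels(self):
        c = [colloid(0, 0.0, 0.0), colloid(1, 1.0, 0.0)]
        combo = Multitasking([ConstantTask(0.7), ConstantTask(-0.7)])
        assert np.allclose(combo(c), 0.0)

    def test_sums_match_hand_computation(self):
        c = [colloid(0, 0.0, 0.0)]
        combo = Multitasking([ConstantTask(0.5), ConstantTask(2.0), ConstantTask(-0.25)])
        assert combo(c)[0] == pytest.approx(2.25)

    def test_composite_kill_is_monotone_or(self):
        t1, t2 = TimeLimitTask(limit=2), ConstantTask(0.0)
        combo = Multitasking([t1, t2])
        c = [colloid(0, 0.0, 0.0)]
        combo(c)
        assert not combo.kill_switch
        combo(c)
        assert combo.kill_switch
        t1._kill = False  # even if the part clears, the composite stays latched
        assert combo.kill_switch

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            Multitasking([])


class TestObservablePurity:
    def test_observables_do_not_mutate_colloids(self, fld):
        cols = [colloid(0, 1.0, 2.0), colloid(1, 3.0, 4.0)]
        snapshots = [(c.pos.copy(), c.director.copy()) for c in cols]
        for obs in (
            ConcentrationChange(fld),
            NeighborSensing(radius=5.0),
            PositionObservable(np.array([10.0, 10.0])),
        ):
            obs.compute_observable(cols, cols)
        for c, (p, d) in zip(cols, snapshots):
            assert np.array_equal(c.pos, p) and np.array_equal(c.director, d)

    def test_base_class_is_abstract(self):
        with pytest.raises(NotImplementedError):
            Observable().compute_observable([])
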