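import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cssaflow import (
    AgeGrid,
    BirthSchedule,
    PopulationWeights,
    StateDistribution,
    TransitionSchedule,
    ValidationError,
    newborn_state,
    overall_proportion,
    project,
    project_scalar,
    project_step,
    transition_matrix,
)

probs = st.floats(0.0, 1.0, allow_nan=False)


class TestTransitionMatrix:
    def test_no_flow_is_identity(self):
        assert np.array_equal(transition_matrix(0.0, 0.0), np.eye(2))

    def test_reference_entries(self):
        # entries for the 20-29 band of the packaged schedule
        A = transition_matrix(0.0015, 0.2103)
        assert np.allclose(A, [[0.7897, 0.0015], [0.2103, 0.9985]])

    @given(probs, probs)
    @settings(derandomize=True, max_examples=100)
    def test_column_stochastic_and_conserving(self, p, q):
        A = transition_matrix(p, q)
        assert np.allclose(A.sum(axis=0), 1.0, atol=1e-12)
        assert np.all((A >= 0) & (A <= 1))
        x = 0.37
        out = A @ np.array([x, 1 - x])
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            transition_matrix(1.5, 0.1)


class TestProjectScalar:
    def test_hand_iterated_recursion(self):
        # x1 = (1-q)*0 + p*1 = 0.2; x2 = (1-q)*x1 + p*(1-x1) = 0.7*0.2 + 0.2*0.8 = 0.30
        traj = project_scalar(0.0, p=0.2, q=0.3, steps=2)
        assert np.allclose(traj, [0.0, 0.2, 0.30], atol=1e-15)

    def test_zero_steps_returns_start(self):
        assert np.array_equal(project_scalar(0.4, 0.1, 0.2, 0), [0.4])

    def test_absorbing_when_no_exit(self):
        assert np.all(project_scalar(1.0, p=0.1, q=0.0, steps=5) == 1.0)

    @given(st.floats(0.01, 1.0), st.floats(0.01, 1.0))
    @settings(derandomize=True, max_examples=50)
    def test_fixed_point_is_stationary(self, p, q):
        fp = p / (p + q)
        traj = project_scalar(fp, p, q, steps=20)
        assert np.max(np.abs(traj - fp)) < 1e-12


class TestNewbornState:
    def test_constant_state_in_both_modes(self, synth):
        ts, bs, pw, _ = synth
        x = StateDistribution(np.full(60, 0.3), ts.grid)
        assert newborn_state(x, bs, pw, "literal") == pytest.approx(0.3)
        assert newborn_state(x, bs, pw, "weighted") == pytest.approx(0.3)

    def test_single_age_mothers(self):
        grid = AgeGrid(60)
        b = np.zeros(60)
        b[30] = 0.08
        bs = BirthSchedule(b, grid)
        x = np.full(60, 0.1)
        x[30] = 0.4
        assert newborn_state(StateDistribution(x, grid), bs) == pytest.approx(0.4)

    def test_literal_vs_weighted_modes(self):
        # b(20)=b(30)=0.1, w(20)=0.7, w(30)=0.3, x(20)=0, x(30)=1
        grid = AgeGrid(31)
        b = np.zeros(31)
        b[20] = b[30] = 0.1
        bs = BirthSchedule(b, grid, fertile_range=(15, 30))
        w = np.zeros(31)
        w[20], w[30] = 0.7, 0.3
        pw = PopulationWeights(w, grid)
        x = np.zeros(31)
        x[30] = 1.0
        st_ = StateDistribution(x, grid)
        assert newborn_state(st_, bs, pw, "literal") == pytest.approx(0.5)
        assert newborn_state(st_, bs, pw, "weighted") == pytest.approx(0.3)

    def test_all_zero_births_rejected(self):
        grid = AgeGrid(60)
        bs = BirthSchedule(np.zeros(60), grid)
        x = StateDistribution(np.full(60, 0.2), grid)
        with pytest.raises(ValidationError, match="newborn composition undefined"):
            newborn_state(x, bs)


class TestProjectStep:
    def test_empty_system_stays_empty_without_entry(self, synth):
        ts, bs, pw, _ = synth
        ts0 = TransitionSchedule(np.zeros(60), ts.q, ts.grid)
        x = StateDistribution(np.zeros(60), ts.grid)
        out = project_step(x, ts0, bs, pw)
        assert np.all(out.x == 0.0)

    def test_full_system_stays_full_without_exit(self, synth):
        ts, bs, pw, _ = synth
        ts1 = TransitionSchedule(ts.p, np.zeros(60), ts.grid)
        x = StateDistribution(np.ones(60), ts.grid)
        out = project_step(x, ts1, bs, pw)
        assert np.all(out.x == 1.0)

    def test_three_age_toy_by_hand(self, toy3):
        grid, ts, bs, x = toy3
        out = project_step(x, ts, bs)
        # age 1: (1-0.3)*0.2 + 0.1*0.8 = 0.22 ; age 2: (1-0.2)*0.5 + 0.2*0.5 = 0.5
        # age 0: newborns inherit x(1) = 0.5 (b supported on age 1 only)
        assert out.x == pytest.approx([0.5, 0.22, 0.5], abs=1e-15)
        assert out.time_label == x.time_label + 1

    def test_grid_mismatch_rejected(self, synth, toy3):
        ts, bs, pw, x0 = synth
        _, ts3, _, _ = toy3
        with pytest.raises(ValidationError, match="grid"):
            project_step(x0, ts3, bs, pw)

    def test_homogeneous_fixed_point_preserved(self):
        """With age-constant p, q the scalar fixed point is held at every age."""
        grid = AgeGrid(60)
        p, q = 0.04, 0.16
        fp = p / (p + q)
        ts = TransitionSchedule(np.full(60, p), np.full(60, q), grid)
        b = np.zeros(60)
        b[15:50] = 0.03
        bs = BirthSchedule(b, grid)
        x = StateDistribution(np.full(60, fp), grid)
        out = project_step(x, ts, bs)
        assert np.max(np.abs(out.x - fp)) < 1e-12


class TestOverallProportion:
    def test_constant_state_gives_constant(self, synth):
        ts, _, pw, _ = synth
        x = StateDistribution(np.full(60, 0.25), ts.grid)
        assert overall_proportion(x, pw) == pytest.approx(0.25, abs=1e-12)

    def test_point_mass_weights_pick_one_age(self):
        grid = AgeGrid(10)
        w = np.zeros(10)
        w[7] = 1.0
        pw = PopulationWeights(w, grid)
        x = StateDistribution(np.linspace(0, 0.9, 10), grid)
        assert overall_proportion(x, pw) == pytest.approx(x.x[7])

    def test_two_age_dot_product(self):
        grid = AgeGrid(2)
        x = StateDistribution([0.1, 0.3], grid)
        pw = PopulationWeights([0.25, 0.75], grid)
        assert overall_proportion(x, pw) == pytest.approx(0.25, abs=1e-15)

    def test_bounded_by_state_range(self, synth):
        ts, _, pw, x0 = synth
        X = overall_proportion(x0, pw)
        assert x0.x.min() <= X <= x0.x.max()


class TestProject:
    def test_horizon_zero_returns_initial_state(self, synth):
        ts, bs, pw, x0 = synth
        res = project(x0, ts, bs, pw, horizon=0)
        assert len(res.states) == 1
        assert res.overall[0] == pytest.approx(overall_proportion(x0, pw))

    def test_two_steps_equal_step_composed_twice(self, synth):
        ts, bs, pw, x0 = synth
        res = project(x0, ts, bs, pw, horizon=2)
        manual = project_step(project_step(x0, ts, bs, pw), ts, bs, pw)
        assert np.array_equal(res.states[2].x, manual.x)

    def test_overall_consistent_with_states(self, synth):
        ts, bs, pw, x0 = synth
        res = project(x0, ts, bs, pw, horizon=5)
        for st_, X in zip(res.states, res.overall):
            assert X == pytest.approx(overall_proportion(st_, pw), abs=1e-15)

    def test_to_frame_shape(self, synth):
        ts, bs, pw, x0 = synth
        df = project(x0, ts, bs, pw, horizon=3).to_frame()
        assert list(df.columns) == ["period", "age", "x", "overall_X"]
        assert len(df) == 4 * 60

    @given(age=st.integers(0, 58), bump=st.floats(0.01, 0.5))
    @settings(derandomize=True, max_examples=30)
    def test_monotone_coupling_in_q(self, synth, age, bump):
        """Raising one exit probability never raises next-period X."""
        ts, bs, pw, x0 = synth
        X_base = project(x0, ts, bs, pw, 1).overall[-1]
        q2 = ts.q.copy()
        q2[age] = min(1.0, q2[age] + bump)
        ts2 = TransitionSchedule(ts.p, q2, ts.grid)
        assert project(x0, ts2, bs, pw, 1).overall[-1] <= X_base + 1e-15

    @given(age=st.integers(0, 58), bump=st.floats(0.01, 0.5))
    @settings(derandomize=True, max_examples=30)
    def test_monotone_coupling_in_p(self, synth, age, bump):
        """Raising one entry probability never lowers next-period X."""
        ts, bs, pw, x0 = synth
        X_base = project(x0, ts, bs, pw, 1).overall[-1]
        p2 = ts.p.copy()
        p2[age] = min(1.0, p2[age] + bump)
        ts2 = TransitionSchedule(p2, ts.q, ts.grid)
        assert project(x0, ts2, bs, pw, 1).overall[-1] >= X_base - 1e-15
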