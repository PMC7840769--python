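"""Run classification, propensity, lifetimes, and potential fitting."""

import numpy as np
import pandas as pd
import pytest

import endtrack as et
from endtrack.metrics import PotentialFitError
from endtrack.simulate import ScenarioSpec, Trajectory


def synthetic_trajectory(t, x, x_s, params=None):
    params = params or et.RatchetParams(D=4e4, U0=10.0, V_Z=25.0)
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    x_s = np.asarray(x_s, dtype=float)
    return Trajectory(
        t=t, x=x, x_S=x_s, x_G=x_s + (params.N_fil - 1) * params.L0,
        bound=np.ones_like(t, dtype=bool), params=params,
        scenario=ScenarioSpec(), seed=0, first_escape=np.nan, censored=True,
    )


class TestClassifyEndTracking:
    def test_perfect_tracking_is_one_run(self):
        t = np.arange(0, 10.05, 0.05)
        x = 25.0 * t
        tr = synthetic_trajectory(t, x, x)
        flag, runs = et.classify_end_tracking(tr)
        assert flag
        assert runs.n == 1
        assert runs.durations[0] == pytest.approx(10.0, abs=0.1)
        assert runs.speeds[0] == pytest.approx(25.0, rel=0.01)

    def test_run_ends_when_gap_exceeds_limit(self):
        # enzyme stalls while the end advances 150 nm: the run terminates
        # once the 100 nm distance criterion is violated
        t = np.arange(0, 20.05, 0.05)
        x_s = 25.0 * t
        x = np.where(t <= 6.0, 25.0 * t, 150.0)
        tr = synthetic_trajectory(t, x, x_s)
        flag, runs = et.classify_end_tracking(tr)
        assert flag
        assert runs.n == 1
        # the run cannot extend past the instant the gap reaches 100 nm
        assert runs.durations[0] <= 10.0 + 0.1

    def test_short_trajectory_not_persistent(self):
        t = np.arange(0, 2.05, 0.05)
        x = 25.0 * t
        tr = synthetic_trajectory(t, x, x)
        flag, _ = et.classify_end_tracking(tr)
        assert not flag

    def test_backtrack_breaks_run(self):
        # 30 nm of backward motion ends the unidirectional run even while
        # the enzyme stays within 100 nm of the end
        t = np.arange(0, 12.0, 1.0)
        x_s = 25.0 * t
        x = 25.0 * t
        x[6:] = x[5] - 30.0 + 24.0 * (t[6:] - t[6])  # drop then resume
        tr = synthetic_trajectory(t, x, np.minimum(x_s, x + 90))
        flag, runs = et.classify_end_tracking(tr)
        assert runs.n <= 1
        if runs.n == 1:
            assert runs.durations[0] <= 5.5

    def test_stalled_enzyme_fails_follow_fraction(self):
        # enzyme stays within the window briefly but advances far less
        # than the end: not "following"
        t = np.arange(0, 5.0, 1.0)
        x_s = 25.0 * t
        x = 2.0 * t
        tr = synthetic_trajectory(t, x, x_s)
        flag, _ = et.classify_end_tracking(tr)
        assert not flag


class TestPropensity:
    def test_trivial_fractions(self):
        t = np.arange(0, 10.05, 0.05)
        good = synthetic_trajectory(t, 25 * t, 25 * t)
        bad = synthetic_trajectory(t, np.zeros_like(t), 25 * t)
        assert et.propensity([good, good]) == 1.0
        assert et.propensity([bad, bad]) == 0.0
        assert et.propensity([good, bad]) == 0.5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            et.propensity([])

    def test_relative_propensity_normalised(self):
        rel = et.relative_propensity([10, 5, 5])
        assert rel.sum() == pytest.approx(1.0)
        assert rel[0] == pytest.approx(0.5)


class TestPhaseDiagram:
    def test_degenerate_single_cell(self):
        fixed = et.RatchetParams(D=4e4, U0=10.0, V_Z=25.0, t_max=6.0, seed=1)
        pd_ = et.phase_diagram(("U0", [10.0]), ("V_Z", [25.0]), fixed, n_traj=2)
        assert pd_.propensity.shape == (1, 1)
        assert 0.0 <= pd_.propensity[0, 0] <= 1.0

    def test_empty_grid_rejected(self):
        fixed = et.RatchetParams(D=4e4, U0=10.0, V_Z=25.0)
        with pytest.raises(ValueError):
            et.phase_diagram(("U0", []), ("V_Z", [25.0]), fixed)

    def test_frame_round_trip(self):
        pd_ = et.PhaseDiagram("D", np.array([1.0, 2.0]), "U0", np.array([3.0]),
                              np.array([[0.1], [0.9]]))
        df = pd_.to_frame()
        assert df.loc[2.0, 3.0] == 0.9
        assert pd_.above_threshold()[1, 0]


class TestBoundLifetime:
    def test_first_passage_matches_free_diffusion_oracle(self):
        # U0 = 0, V_Z = 0: escape >100 nm beyond either end of a static
        # 245 nm filament from a uniform subunit start. Closed form for an
        # interval [-100, 345]: E[T | start d] = (d+100)(345-d)/(2D),
        # averaged over the 50 subunit centers.
        D = 1e4
        p = et.RatchetParams(D=D, U0=0.0, V_Z=0.0, t_max=60.0, dt=1e-3, seed=9)
        trajs = et.simulate_ensemble(
            p, ScenarioSpec(init_mode="mid_filament"), n_traj=4000,
            record_every=10**6,
        )
        times = [et.bound_lifetime(tr)[0] for tr in trajs]
        d = np.arange(50) * 5.0
        oracle = np.mean((d + 100.0) * (345.0 - d) / (2 * D))
        assert np.mean(times) == pytest.approx(oracle, rel=0.05)

    def test_deeper_well_lives_longer(self):
        base = et.RatchetParams(D=1e4, U0=0.0, V_Z=0.0, t_max=30.0, dt=1e-3, seed=2)
        shallow = et.simulate_ensemble(
            base, ScenarioSpec(init_mode="mid_filament"), n_traj=40,
            record_every=10**6)
        deep_p = et.RatchetParams(D=1e4, U0=12.0, V_Z=0.0, t_max=30.0,
                                  dt=et.choose_dt(1e4, 12.0, 0.0), seed=2)
        deep = et.simulate_ensemble(
            deep_p, ScenarioSpec(init_mode="mid_filament"), n_traj=10,
            record_every=10**6)
        mean_shallow = np.mean([et.bound_lifetime(t)[0] for t in shallow])
        mean_deep = np.mean([et.bound_lifetime(t)[0] for t in deep])
        assert mean_deep > 3 * mean_shallow

    def test_censoring_flagged(self):
        p = et.RatchetParams(D=1e4, U0=12.0, V_Z=0.0, t_max=0.5,
                             dt=et.choose_dt(1e4, 12.0, 0.0), seed=4)
        tr = et.simulate_trajectory(p, ScenarioSpec(init_mode="mid_filament"),
                                    record_every=10**6)
        lt, censored = et.bound_lifetime(tr)
        assert censored and lt == pytest.approx(0.5)
        stats = et.mean_bound_lifetime([tr])
        assert stats["censored_fraction"] == 1.0


class TestFitBindingPotential:
    def test_recovers_generating_depth(self, rng):
        # self-consistency: data generated from the model's own activity
        # curve at U0 = 9 with 10% noise brackets 9
        D = 0.041e6
        vz = np.array([8.0, 12.0, 16.0, 20.0, 25.0])
        life = np.array([et.model_bound_lifetime(v, D, 9.0) for v in vz])
        act = (life[0] / life) * (1 + 0.1 * rng.standard_normal(vz.size))
        lo, hi = et.fit_binding_potential(np.column_stack([vz, act]), D)
        assert lo <= 9.0 <= hi

    def test_flat_data_with_fast_diffusion_is_wide(self):
        D = 0.05e6
        vz = np.array([8.0, 12.0, 16.0, 20.0, 25.0])
        act = np.ones_like(vz)
        lo, hi = et.fit_binding_potential(np.column_stack([vz, act]), D)
        assert hi - lo > 2.0  # weak identifiability: broad bracket

    def test_unfittable_data_reports_failure(self):
        vz = np.array([8.0, 12.0, 16.0, 20.0])
        act = np.array([1.0, 10.0, 0.1, 20.0])
        with pytest.raises(PotentialFitError) as err:
            et.fit_binding_potential(np.column_stack([vz, act]), 0.04e6)
        assert err.value.residuals is not None

    def test_requires_three_points(self):
        with pytest.raises(ValueError):
            et.fit_binding_potential(np.array([[8.0, 1.0], [25.0, 0.5]]), 0.04e6)
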