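"""Bound-state segmentation, dwell extraction, KM survival and rate fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _util import apparent_rate
from smresidence.kinetics import (
    BoundStateClassifier,
    DegenerateInputError,
    DwellRecord,
    FitResult,
    ResidenceTimeFitter,
    SurvivalCurve,
    _empirical_survival,
    bleach_floor,
    bound_fraction,
    classify_states,
    compare_rates,
    extract_dwells,
    fit_koff,
    km_survival,
    mle_koff,
)
from smresidence.locio import filter_precision
from smresidence.simulate import SimConfig, simulate_condition
from smresidence.tracking import Trajectory, link_trajectories


def traj_from_xy(x, y):
    x = np.asarray(x, dtype=float)
    return Trajectory(id=0, frames=np.arange(len(x)), x=x, y=np.asarray(y, dtype=float))


# ---------------------------------------------------------------------------
# segmentation


class TestClassifyStates:
    def test_static_trajectory_all_bound(self):
        t = traj_from_xy(np.zeros(12), np.zeros(12))
        assert classify_states(t, 5, 220.0).all()

    def test_large_steps_all_free(self):
        t = traj_from_xy(np.arange(12) * 1000.0, np.zeros(12))
        assert not classify_states(t, 5, 220.0).any()

    def test_short_trajectory_labelled_free(self):
        t = traj_from_xy(np.zeros(3), np.zeros(3))
        assert not classify_states(t, 5, 220.0).any()

    def test_assume_bound_flag(self):
        t = traj_from_xy(np.arange(4) * 1000.0, np.zeros(4))
        assert classify_states(t, assume_bound=True).all()

    def test_mixed_trajectory_segmented(self):
        # 10 static frames, then 10 frames of 1 µm steps
        x = np.concatenate([np.zeros(10), np.arange(1, 11) * 1000.0])
        t = traj_from_xy(x, np.zeros(20))
        lab = classify_states(t, 5, 220.0)
        assert lab[:9].all()
        assert not lab[12:].any()

    def test_agreement_with_ground_truth_states(self, sim_20ms):
        cfg, table, truth = sim_20ms
        trajs = link_trajectories(filter_precision(table, 40.0))
        agree = total = 0
        for tr in trajs:
            lab = classify_states(tr, 5, 220.0)
            for k in range(tr.n_frames):
                state = truth.molecules[int(tr.molecule_id[k])].state_at_frame(
                    int(tr.frames[k]), cfg.frame_interval
                )
                if state is None:
                    continue
                agree += lab[k] == (state == "bound")
                total += 1
        assert total > 5000
        assert agree / total >= 0.95


class TestBoundFraction:
    def test_simple_ratio(self):
        t = traj_from_xy(np.zeros(10), np.zeros(10))
        labels = [np.array([True] * 4 + [False] * 6)]
        assert bound_fraction([t], labels) == pytest.approx(0.4)

    def test_all_free_is_zero(self):
        t = traj_from_xy(np.zeros(5), np.zeros(5))
        assert bound_fraction([t], [np.zeros(5, dtype=bool)]) == 0.0

    def test_no_frames_undefined(self):
        assert np.isnan(bound_fraction([], []))

    def test_estimates_equilibrium_occupancy(self):
        # frame-weighted bound share ~ k_on / (k_on + k_off); a very wide
        # axial slice removes the defocus loss that otherwise depletes
        # free-state frames from the detected sample
        cfg = SimConfig(
            n_molecules=400, seed=31, k_off=0.5, k_on=0.5, k_bleach=0.5,
            frame_interval=0.02, n_frames=3000, sigma_loc=25.0,
            axial_halfwidth=1e6,
        )
        table, _ = simulate_condition(cfg)
        trajs = link_trajectories(filter_precision(table, 40.0))
        labels = [classify_states(t, 5, 220.0) for t in trajs]
        bf = bound_fraction(trajs, labels)
        expected = cfg.k_on / (cfg.k_on + cfg.k_off)
        assert abs(bf - expected) < 0.07


# ---------------------------------------------------------------------------
# dwell extraction


class TestExtractDwells:
    def run(self, pattern, dt=0.5):
        lab = np.array([c == "B" for c in pattern])
        t = traj_from_xy(np.zeros(len(lab)), np.zeros(len(lab)))
        return extract_dwells([t], [lab], dt)

    def test_full_bound_run(self):
        dwells = self.run("BBBBB")
        assert len(dwells) == 1
        assert dwells[0].duration_s == pytest.approx(2.0)

    def test_two_separate_runs(self):
        dwells = self.run("BBFFBB")
        assert [d.duration_s for d in dwells] == [pytest.approx(0.5)] * 2

    def test_single_frame_runs_discarded(self):
        assert self.run("FBF") == []
        assert self.run("BFBFB") == []

    def test_fixed_cell_dwells_match_track_durations(self):
        cfg = SimConfig(n_molecules=80, seed=6, k_bleach=0.05, fixed_cell=True, n_frames=600)
        table, _ = simulate_condition(cfg)
        trajs = link_trajectories(filter_precision(table, 40.0))
        labels = [np.ones(t.n_frames, dtype=bool) for t in trajs]
        dwells = extract_dwells(trajs, labels, cfg.frame_interval)
        expected = sorted(
            t.duration(cfg.frame_interval) for t in trajs if t.n_frames >= 2
        )
        assert sorted(d.duration_s for d in dwells) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# survival estimation


class TestKMSurvival:
    def test_worked_example(self):
        curve = km_survival([2.0, 3.0, 5.0], t_min=1.5)
        # shifted times 0.5, 1.5, 3.5; no censoring -> empirical survival
        np.testing.assert_allclose(curve.times, [0.0, 0.5, 1.5, 3.5])
        np.testing.assert_allclose(curve.survival, [1.0, 2 / 3, 1 / 3, 0.0])
        assert curve.survival[0] == 1.0

    def test_short_dwells_filtered(self):
        curve = km_survival([1.0, 2.0, 4.0], t_min=1.5)
        assert curve.n == 2
        np.testing.assert_allclose(curve.times, [0.0, 0.5, 2.5])

    def test_insufficient_dwells_error(self):
        with pytest.raises(ValueError, match="insufficient"):
            km_survival([1.0, 1.2, 2.0], t_min=1.5)

    def test_accepts_dwell_records(self):
        dwells = [DwellRecord(0, 0.0, 2.0), DwellRecord(1, 1.0, 3.0)]
        curve = km_survival(dwells, t_min=1.5)
        assert curve.n == 2

    @settings(deadline=None, max_examples=30)
    @given(
        st.lists(st.floats(min_value=1.6, max_value=50.0), min_size=2, max_size=80),
    )
    def test_km_equals_empirical_survival_without_censoring(self, durations):
        # with every termination an event, the product-limit estimate
        # collapses to the plain empirical survival function
        curve = km_survival(durations, t_min=1.5)
        shifted = np.asarray(durations) - 1.5
        ts, surv, _ = _empirical_survival(shifted)
        ref_t = np.concatenate(([0.0], ts))
        ref_s = np.concatenate(([1.0], surv))
        np.testing.assert_allclose(curve.times, ref_t, atol=1e-12)
        np.testing.assert_allclose(curve.survival, ref_s, atol=1e-12)

    @settings(deadline=None, max_examples=25)
    @given(
        st.lists(st.floats(min_value=1.5, max_value=30.0), min_size=2, max_size=60),
        st.floats(min_value=0.5, max_value=2.0),
    )
    def test_survival_curve_invariants(self, durations, t_min):
        durations = [d + t_min for d in durations]
        curve = km_survival(durations, t_min=t_min)
        assert curve.survival[0] == 1.0
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert np.all((curve.survival >= 0) & (curve.survival <= 1))
        assert np.all(np.diff(curve.n_at_risk) <= 0)

    def test_km_tracks_true_exponential_within_greenwood_band(self):
        # large-sample check of the estimator against the closed form
        rng = np.random.default_rng(42)
        k, t_min, n = 0.3, 1.5, 10_000
        durations = t_min + rng.exponential(1.0 / k, size=n)
        curve = km_survival(durations, t_min=t_min)
        t = curve.times[1:]
        s = curve.survival[1:]
        true = np.exp(-k * t)
        # Greenwood variance for the no-censoring case: S^2 * (1-S)/(n*S)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(s * (1 - s) / n)
        ok = np.abs(s - true) <= 1.96 * np.maximum(se, 1e-12)
        assert ok.mean() >= 0.90


# ---------------------------------------------------------------------------
# rate fitting


def curve_from_model(k=0.5, t_max=10.0, dt=0.5):
    t = np.arange(0.0, t_max + dt / 2, dt)
    s = np.exp(-k * t)
    return SurvivalCurve(
        times=t, survival=s, n_at_risk=np.arange(len(t), 0, -1),
        t_min=1.5, durations=np.linspace(0.1, 10, 50),
    )


class TestFitKoff:
    def test_exact_recovery_from_noiseless_curve(self):
        fit = fit_koff(curve_from_model(0.5), bootstrap_reps=10, seed=0)
        assert abs(fit.k_off_app - 0.5) / 0.5 < 1e-6

    def test_rate_halves_when_durations_double(self):
        rng = np.random.default_rng(1)
        d = 1.5 + rng.exponential(5.0, size=400)
        k1 = fit_koff(km_survival(d, 1.5), bootstrap_reps=10, seed=0).k_off_app
        k2 = fit_koff(km_survival(2 * d, 3.0), bootstrap_reps=10, seed=0).k_off_app
        assert k2 == pytest.approx(k1 / 2, rel=1e-9)

    def test_non_decaying_curve_rejected(self):
        curve = SurvivalCurve(
            times=np.array([0.0, 1.0, 2.0, 3.0]),
            survival=np.ones(4),
            n_at_risk=np.array([4, 4, 4, 4]),
            t_min=1.5,
            durations=np.full(4, 2.0),
        )
        with pytest.raises(DegenerateInputError):
            fit_koff(curve, bootstrap_reps=10, seed=0)

    def test_too_few_event_times_rejected(self):
        curve = km_survival([2.0, 2.0, 3.0], t_min=1.5)
        with pytest.raises(ValueError):
            fit_koff(curve, bootstrap_reps=10, seed=0)

    def test_cis_contain_point_estimate_and_are_nested(self):
        rng = np.random.default_rng(2)
        d = 1.5 + rng.exponential(10.0, size=500)
        fit = fit_koff(km_survival(d, 1.5), bootstrap_reps=300, seed=3)
        assert fit.ci95[0] <= fit.k_off_app <= fit.ci95[1]
        assert fit.ci99[0] <= fit.ci95[0] and fit.ci95[1] <= fit.ci99[1]

    def test_bootstrap_seeded(self):
        rng = np.random.default_rng(4)
        d = 1.5 + rng.exponential(8.0, size=200)
        curve = km_survival(d, 1.5)
        f1 = fit_koff(curve, bootstrap_reps=100, seed=9)
        f2 = fit_koff(curve, bootstrap_reps=100, seed=9)
        assert f1.ci95 == f2.ci95 and f1.ci99 == f2.ci99


class TestMLE:
    def test_closed_form(self):
        assert mle_koff([2.5, 3.5], 1.5) == pytest.approx(2.0 / 3.0)

    def test_single_dwell(self):
        assert mle_koff([2.5], 1.5) == pytest.approx(1.0)

    def test_no_qualifying_dwells(self):
        with pytest.raises(ValueError):
            mle_koff([0.5, 1.0], 1.5)

    def test_agrees_with_nls_fit_at_large_n(self):
        rng = np.random.default_rng(7)
        d = 1.5 + rng.exponential(1.0 / 0.08, size=1000)
        k_fit = fit_koff(km_survival(d, 1.5), bootstrap_reps=10, seed=0).k_off_app
        k_mle = mle_koff(d, 1.5)
        assert abs(k_fit - k_mle) / k_mle < 0.05


def fit_result(k, lo99, hi99, lo95=None, hi95=None):
    lo95 = lo99 if lo95 is None else lo95
    hi95 = hi99 if hi95 is None else hi95
    return FitResult(k_off_app=k, ci95=(lo95, hi95), ci99=(lo99, hi99),
                     n_dwells=100, rss=0.0, bootstrap_reps=100)


class TestComparisons:
    def test_identical_fits_not_significant(self):
        a = fit_result(0.05, 0.04, 0.06)
        assert compare_rates(a, a).significant is False

    def test_disjoint_ci99_significant(self):
        a = fit_result(0.03, 0.02, 0.04)
        b = fit_result(0.06, 0.05, 0.07)
        cmp = compare_rates(a, b)
        assert cmp.significant and cmp.direction == "a_lower"

    def test_touching_intervals_not_significant(self):
        a = fit_result(0.03, 0.02, 0.05)
        b = fit_result(0.06, 0.05, 0.07)
        assert compare_rates(a, b).significant is False

    def test_bleach_floor_is_ci95_upper(self):
        fit = fit_result(0.021, 0.017, 0.025, 0.018, 0.024)
        assert bleach_floor(fit) == 0.024
        live = fit_result(0.020, 0.018, 0.022)
        assert live.k_off_app <= bleach_floor(fit)  # bleaching-limited


# ---------------------------------------------------------------------------
# recovery properties on simulated data


def test_rate_recovery_monotone_in_true_koff():
    # median fitted apparent rate over seeds tracks k_off + k_bleach and
    # increases strictly with the simulated dissociation rate
    k_bleach = 0.02
    medians = []
    for k_off in (0.02, 0.05, 0.10):
        fits = []
        for seed in range(5):
            cfg = SimConfig(
                n_molecules=600, seed=1000 + 97 * seed + int(k_off * 1e4),
                k_off=k_off, k_bleach=k_bleach, frame_interval=0.5, n_frames=3000,
            )
            fits.append(apparent_rate(cfg, bootstrap_reps=10).k_off_app)
        med = float(np.median(fits))
        medians.append(med)
        assert abs(med - (k_off + k_bleach)) / (k_off + k_bleach) < 0.10
    assert medians[0] < medians[1] < medians[2]


def test_bootstrap_ci_covers_true_rate_in_fixed_cells():
    # fixed cells: the only termination process is bleaching, so the true
    # apparent rate is k_bleach exactly; nominal 95% intervals should
    # cover it in most seeded runs
    k_bleach = 0.02
    covered = 0
    n_runs = 40
    for seed in range(n_runs):
        cfg = SimConfig(
            n_molecules=150, seed=5000 + seed, k_off=0.0, fixed_cell=True,
            k_bleach=k_bleach, frame_interval=0.5, n_frames=2000,
        )
        fit = apparent_rate(cfg, bootstrap_reps=200, fit_seed=seed)
        covered += fit.ci95[0] <= k_bleach <= fit.ci95[1]
    assert covered / n_runs >= 0.85


def test_estimator_facades():
    rng = np.random.default_rng(11)
    d = 1.5 + rng.exponential(10.0, size=300)
    est = ResidenceTimeFitter(t_min=1.5, bootstrap_reps=50, seed=2).fit(d)
    assert est.k_off_app_ == pytest.approx(0.1, rel=0.2)
    assert est.ci95_[0] <= est.k_off_app_ <= est.ci95_[1]
    s = est.predict([0.0, 5.0])
    assert s[0] == 1.0 and 0 < s[1] < 1

    clf = BoundStateClassifier(assume_bound=True)
    t = traj_from_xy(np.zeros(5), np.zeros(5))
    labels = clf.fit_transform([t])
    assert labels[0].all() and clf.bound_fraction_ == 1.0
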