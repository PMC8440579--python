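"""HMM segmentation, Bayesian order selection and event filtering."""

import numpy as np
import pytest

from conftest import make_two_level_trace
from smlife import simkit
from smlife.dwell import (
    DwellEvent,
    extract_events,
    filter_events,
    fit_hmm,
    select_model,
)


def path_from_fit(fit):
    return np.asarray(fit.state_path)


class TestFitHmm:
    def test_noiseless_square_wave_recovered_exactly(self):
        x = np.tile([0.0] * 10 + [1000.0] * 10, 12)
        fit = fit_hmm(x, 2)
        assert fit.state_means == pytest.approx([0.0, 1000.0], abs=1e-6)
        np.testing.assert_array_equal(path_from_fit(fit), (x > 500).astype(int))

    def test_constant_trace_single_state_mean(self):
        x = np.full(100, 321.5)
        fit = fit_hmm(x, 1)
        assert fit.state_means[0] == pytest.approx(321.5, abs=1e-9)

    def test_constant_trace_multi_state_flagged_collapsed(self):
        fit = fit_hmm(np.full(100, 5.0), 2)
        assert fit.collapsed

    def test_noisy_two_level_matches_threshold_oracle(self):
        rng = np.random.default_rng(11)
        x, truth = make_two_level_trace(rng, 480, 800.0, 20.0, [(100, 140), (300, 320)])
        fit = fit_hmm(x, 2)
        oracle = (x > 400).astype(int)  # threshold at midpoint, separation 40 sigma
        agreement = (path_from_fit(fit) == oracle).mean()
        assert agreement >= 0.99

    def test_transition_rows_stochastic_and_means_sorted(self):
        rng = np.random.default_rng(12)
        x, _ = make_two_level_trace(rng, 300, 700.0, 30.0, [(50, 120)])
        fit = fit_hmm(x, 3)
        np.testing.assert_allclose(fit.transition_matrix.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.diff(fit.state_means) >= 0)

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            fit_hmm(np.zeros(3), 2)

    def test_agrees_with_reference_em_implementation(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(13)
        x, _ = make_two_level_trace(rng, 400, 800.0, 25.0, [(100, 160), (250, 270)])
        ours = fit_hmm(x, 2)
        ref = hmmlearn.GaussianHMM(
            n_components=2, covariance_type="diag", n_iter=200, tol=1e-5, random_state=0
        ).fit(x.reshape(-1, 1))
        ref_means = np.sort(ref.means_.ravel())
        assert ours.state_means == pytest.approx(ref_means, abs=2.0)
        assert ours.log_likelihood == pytest.approx(ref.score(x.reshape(-1, 1)), abs=2.0)


class TestModelSelection:
    def test_constant_noisy_trace_selects_one_state(self):
        rng = np.random.default_rng(20)
        fit, _ = select_model(rng.normal(100.0, 20.0, 300), seed=1)
        assert fit.n_states == 1

    def test_two_level_trace_selects_two_states(self):
        rng = np.random.default_rng(21)
        x, _ = make_two_level_trace(rng, 300, 800.0, 20.0, [(80, 140)])
        fit, evidences = select_model(x, seed=1)
        assert fit.n_states == 2
        assert evidences[2] > evidences[1] and evidences[2] > evidences[3]

    def test_three_level_overlap_selects_at_least_three(self):
        rng = np.random.default_rng(22)
        x = np.concatenate(
            [np.zeros(80), np.full(60, 800.0), np.full(60, 1600.0), np.full(60, 800.0), np.zeros(80)]
        ) + rng.normal(0, 20.0, 340)
        fit, _ = select_model(x, seed=1)
        assert fit.n_states >= 3


class TestExtractEvents:
    def _fit(self, path, means=(0.0, 800.0)):
        """Hand-built two-state fit for event-extraction tests."""
        from smlife.dwell import HmmFit

        path = np.asarray(path, dtype=np.int8)
        return HmmFit(
            n_states=2,
            state_means=np.array(means, dtype=float),
            state_sds=np.array([10.0, 10.0]),
            transition_matrix=np.array([[0.9, 0.1], [0.1, 0.9]]),
            startprob=np.array([0.5, 0.5]),
            state_path=path,
            log_likelihood=0.0,
            evidence=0.0,
            converged=True,
        )

    def test_interior_run_uncensored(self):
        evs = extract_events(self._fit([0, 0, 0, 1, 1, 1, 0, 0, 0]), 0.5)
        assert len(evs) == 1
        e = evs[0]
        assert (e.start_frame, e.end_frame, e.duration_s) == (3, 6, 1.5)
        assert not e.censored

    def test_run_at_start_left_censored(self):
        evs = extract_events(self._fit([1, 1, 1, 0, 0, 0]), 0.5)
        assert evs[0].left_censored and not evs[0].right_censored

    def test_separation_below_60_counts_discards_trace(self):
        evs = extract_events(self._fit([0, 0, 1, 1, 0, 0], means=(100.0, 150.0)), 0.5)
        assert evs == []

    def test_events_defined_on_higher_mean_state(self):
        # mostly-bright trace: the fluorescent state is the majority state
        evs = extract_events(self._fit([1, 1, 1, 1, 0, 1, 1, 1]), 0.5)
        assert len(evs) == 2
        assert evs[0].end_frame == 4 and evs[1].start_frame == 5


class TestFilterEvents:
    def _event(self, dur_s, start=10, censored=False, tid=0):
        frames = int(round(dur_s / 0.5))
        return DwellEvent(
            start_frame=start,
            end_frame=start + frames,
            duration_s=dur_s,
            left_censored=censored,
            right_censored=False,
            trace_id=tid,
        )

    def test_short_event_dropped_boundary_kept(self):
        accepted, tally = filter_events({0: [self._event(1.5), self._event(2.0, start=40)]})
        assert [e.duration_s for e in accepted] == [2.0]
        assert tally["dropped_short"] == 1

    def test_censored_events_dropped(self):
        accepted, tally = filter_events({0: [self._event(3.0, censored=True)]})
        assert accepted == [] and tally["dropped_censored"] == 1

    def test_three_event_trace_excluded_entirely(self):
        events = [self._event(3.0, start=10 + 20 * i) for i in range(3)]
        accepted, tally = filter_events({0: events})
        assert accepted == [] and tally["dropped_too_many_events"] == 3

    def test_censored_events_do_not_count_toward_limit(self):
        events = [
            self._event(3.0, start=0, censored=True),
            self._event(3.0, start=30),
            self._event(3.0, start=60),
        ]
        accepted, _ = filter_events({0: events})
        assert len(accepted) == 2


class TestSyntheticRoundTrip:
    def test_zero_noise_traces_recover_manifest_dwells(self, noise_free, acq_halfsec):
        for seed, (bind, dwl) in enumerate([(5.0, 4.0), (10.0, 2.5), (3.25, 7.0)]):
            values, _ = simkit.render_trace(bind, dwl, acq_halfsec, noise_free, seed=seed)
            fit = fit_hmm(values, 2)
            evs = extract_events(fit, 0.5)
            accepted, _ = filter_events({0: evs})
            assert len(accepted) == 1
            # duration matches the true dwell to the nearest whole frame
            assert abs(accepted[0].duration_s - dwl) <= 0.5
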