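"""Gamma-emission HMM: training, selection, decoding, summaries."""

import itertools

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist

from sptstates.linking import StepTrace
from sptstates import states

from conftest import sample_gamma_hmm


PI3 = np.array([0.35, 0.58, 0.07])
A3 = np.array(
    [[0.86, 0.12, 0.02], [0.07, 0.90, 0.03], [0.10, 0.18, 0.72]]
)
SHAPES3 = np.array([3.0, 3.0, 3.0])
SCALES3 = np.array([0.010, 0.020, 0.055])


class TestForwardBackward:
    def test_likelihood_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        pi = np.array([0.6, 0.4])
        A = np.array([[0.8, 0.2], [0.3, 0.7]])
        shapes = np.array([2.0, 5.0])
        scales = np.array([0.02, 0.05])
        r = rng.gamma(2.0, 0.04, size=7)
        traces = [StepTrace(0, r[:4], 0.081), StepTrace(1, r[4:], 0.081)]
        R, lens = states._pack(traces)
        ll, post, xi, g0 = states._forward_backward(R, lens, pi, A, shapes, scales)

        def brute(robs):
            tot = 0.0
            for path in itertools.product(range(2), repeat=len(robs)):
                p = pi[path[0]] * gamma_dist.pdf(robs[0], shapes[path[0]],
                                                 scale=scales[path[0]])
                for t in range(1, len(robs)):
                    p *= A[path[t - 1], path[t]] * gamma_dist.pdf(
                        robs[t], shapes[path[t]], scale=scales[path[t]]
                    )
                tot += p
            return np.log(tot)

        expected = brute(r[:4]) + brute(r[4:])
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_posteriors_sum_to_one_per_step(self):
        rng = np.random.default_rng(6)
        traces = [StepTrace(i, rng.gamma(2.0, 0.05, rng.integers(2, 30)), 0.081)
                  for i in range(20)]
        R, lens = states._pack(traces)
        pi = np.array([0.5, 0.5])
        A = np.array([[0.9, 0.1], [0.2, 0.8]])
        _, post, _, _ = states._forward_backward(
            R, lens, pi, A, np.array([2.0, 4.0]), np.array([0.03, 0.08])
        )
        for i, tr in enumerate(traces):
            assert np.allclose(post[i, : len(tr.r)].sum(axis=1), 1.0, atol=1e-10)


class TestFitHMM:
    def test_single_state_emission_recovery(self):
        rng = np.random.default_rng(7)
        traces = [StepTrace(i, rng.gamma(2.5, 0.04, 100), 0.081) for i in range(100)]
        model = states.fit_hmm(traces, 1, seed=0)
        assert abs(model.emissions[0].shape - 2.5) / 2.5 < 0.10
        assert abs(model.emissions[0].scale - 0.04) / 0.04 < 0.10

    def test_two_state_transition_recovery(self):
        rng = np.random.default_rng(8)
        pi = np.array([0.5, 0.5])
        A = np.array([[0.95, 0.05], [0.10, 0.90]])
        traces, _ = sample_gamma_hmm(
            1500, 70, pi, A, np.array([3.0, 3.0]), np.array([0.01, 0.08]), rng
        )
        assert sum(len(t.r) for t in traces) > 1e5
        model = states.fit_hmm(traces, 2, seed=0)
        fitted = model.transition_matrix
        assert abs(fitted[0, 1] - 0.05) / 0.05 < 0.20
        assert abs(fitted[1, 0] - 0.10) / 0.10 < 0.20

    def test_trace_order_invariance(self):
        rng = np.random.default_rng(9)
        traces, _ = sample_gamma_hmm(50, 40, PI3, A3, SHAPES3, SCALES3, rng)
        m1 = states.fit_hmm(traces, 2, seed=0)
        m2 = states.fit_hmm(traces[::-1], 2, seed=0)
        assert np.allclose(m1.transition_matrix, m2.transition_matrix, atol=1e-8)
        assert np.allclose(
            [e.shape for e in m1.emissions], [e.shape for e in m2.emissions],
            atol=1e-8,
        )

    def test_loglik_monotone(self):
        rng = np.random.default_rng(10)
        traces, _ = sample_gamma_hmm(100, 40, PI3, A3, SHAPES3, SCALES3, rng)
        model = states.fit_hmm(traces, 3, seed=0)
        assert np.all(np.diff(model.ll_history) > -1e-6)

    def test_states_sorted_by_mean_step(self):
        rng = np.random.default_rng(11)
        traces, _ = sample_gamma_hmm(200, 40, PI3, A3, SHAPES3, SCALES3, rng)
        model = states.fit_hmm(traces, 3, seed=0)
        means = model.state_means
        assert np.all(np.diff(means) > 0)

    def test_bic_formula(self):
        rng = np.random.default_rng(12)
        traces = [StepTrace(i, rng.gamma(2.0, 0.05, 30), 0.081) for i in range(20)]
        model = states.fit_hmm(traces, 2, seed=0)
        n_obs = sum(len(t.r) for t in traces)
        expected = -2 * model.log_likelihood + model.n_params * np.log(n_obs)
        assert model.bic == pytest.approx(expected, rel=1e-12)
        assert model.n_params == 2 * 2 + 2 * 1 + 1


class TestSelectNStates:
    def test_one_state_data_selects_one(self):
        rng = np.random.default_rng(13)
        traces = [StepTrace(i, rng.gamma(3.0, 0.03, 60), 0.081) for i in range(150)]
        best, table = states.select_n_states(traces, seed=0)
        assert best.n_states == 1
        assert len(table) == 4

    def test_three_state_gamma_hmm_selects_three(self):
        rng = np.random.default_rng(14)
        traces, _ = sample_gamma_hmm(800, 60, PI3, A3, SHAPES3, SCALES3, rng)
        best, _ = states.select_n_states(traces, seed=0)
        assert best.n_states == 3

    def test_duplicate_state_data_selects_smaller_model(self):
        # two states with identical emissions and symmetric switching are
        # statistically one state
        rng = np.random.default_rng(15)
        pi = np.array([0.5, 0.5])
        A = np.array([[0.9, 0.1], [0.1, 0.9]])
        traces, _ = sample_gamma_hmm(
            300, 50, pi, A, np.array([3.0, 3.0]), np.array([0.02, 0.02]), rng
        )
        best, _ = states.select_n_states(traces, candidates=(1, 2), seed=0)
        assert best.n_states == 1


class TestViterbi:
    def test_one_state_model_single_segment(self):
        rng = np.random.default_rng(16)
        traces = [StepTrace(0, rng.gamma(2.0, 0.05, 40), 0.081)]
        model = states.fit_hmm(traces, 1, seed=0)
        seg = states.viterbi(model, traces[0])
        assert len(seg.segments) == 1
        assert seg.segments[0].duration == pytest.approx(40 * 0.081)

    def test_separated_emissions_exact_decoding(self):
        rng = np.random.default_rng(17)
        pi = np.array([0.5, 0.5])
        A = np.array([[0.9, 0.1], [0.1, 0.9]])
        shapes = np.array([20.0, 20.0])
        scales = np.array([0.002, 0.02])  # 10x separated means, tight
        traces, paths = sample_gamma_hmm(60, 60, pi, A, shapes, scales, rng)
        model = states.fit_hmm(traces, 2, seed=0)
        correct = total = 0
        for tr, truth in zip(traces, paths):
            seg = states.viterbi(model, tr)
            correct += int(np.sum(seg.states == truth))
            total += len(truth)
        assert correct / total > 0.995

    def test_decoding_deterministic(self, default_traces):
        model = states.fit_hmm(default_traces[:100], 2, seed=0, max_iter=50)
        a = states.viterbi(model, default_traces[0])
        b = states.viterbi(model, default_traces[0])
        assert np.array_equal(a.states, b.states)

    def test_segment_durations_cover_trace(self):
        rng = np.random.default_rng(18)
        traces, _ = sample_gamma_hmm(30, 50, PI3, A3, SHAPES3, SCALES3, rng)
        model = states.fit_hmm(traces, 3, seed=0, max_iter=100)
        for tr in traces:
            seg = states.viterbi(model, tr)
            assert sum(s.n_steps for s in seg.segments) == len(tr.r)
            assert all(s.n_steps > 0 for s in seg.segments)


class TestOccupancy:
    def test_single_state_occupancy(self):
        rng = np.random.default_rng(19)
        traces = [StepTrace(i, rng.gamma(2.0, 0.05, 30), 0.081) for i in range(10)]
        model = states.fit_hmm(traces, 1, seed=0)
        segs = states.segment_all(model, traces)
        occ = states.occupancy(segs, 3)
        assert np.allclose(occ, [1.0, 0.0, 0.0])

    def test_symmetric_two_state_occupancy(self):
        rng = np.random.default_rng(20)
        pi = np.array([0.5, 0.5])
        A = np.array([[0.9, 0.1], [0.1, 0.9]])
        traces, _ = sample_gamma_hmm(
            600, 60, pi, A, np.array([10.0, 10.0]), np.array([0.004, 0.02]), rng
        )
        model = states.fit_hmm(traces, 2, seed=0)
        occ = states.occupancy(states.segment_all(model, traces), 2)
        n_eff = sum(len(t.r) for t in traces) / 20
        assert abs(occ[0] - 0.5) < 3 * 0.5 / np.sqrt(n_eff)

    def test_occupancy_sums_to_one(self, default_traces):
        model = states.fit_hmm(default_traces[:150], 3, seed=0, max_iter=100)
        occ = states.occupancy(states.segment_all(model, default_traces[:150]), 3)
        assert occ.sum() == pytest.approx(1.0)


class TestIdealizedHistogram:
    def test_three_delta_means_recovered_within_bin_width(self):
        rng = np.random.default_rng(21)
        traces, _ = sample_gamma_hmm(400, 50, PI3, A3, SHAPES3, SCALES3, rng)
        model = states.fit_hmm(traces, 3, seed=0)
        segs = states.segment_all(model, traces)
        hist = states.idealized_step_histogram(segs, bins=60)
        assert hist.fit_ok
        binw = hist.edges[1] - hist.edges[0]
        for m_fit, m_state in zip(hist.gauss_means, model.state_means):
            assert abs(m_fit - m_state) < binw

    def test_single_state_input_flagged_degenerate(self):
        rng = np.random.default_rng(22)
        traces = [StepTrace(i, rng.gamma(2.0, 0.05, 30), 0.081) for i in range(10)]
        model = states.fit_hmm(traces, 1, seed=0)
        segs = states.segment_all(model, traces)
        hist = states.idealized_step_histogram(segs)
        assert not hist.fit_ok
        assert hist.density is not None


def test_cross_check_transition_recovery_against_hmmlearn():
    """Independent cross-check: a Gaussian HMM on log-steps (hmmlearn) and
    the gamma HMM agree on the recovered transition structure."""
    hmmlearn = pytest.importorskip("hmmlearn.hmm")
    rng = np.random.default_rng(23)
    pi = np.array([0.5, 0.5])
    A = np.array([[0.92, 0.08], [0.15, 0.85]])
    traces, _ = sample_gamma_hmm(
        400, 60, pi, A, np.array([4.0, 4.0]), np.array([0.008, 0.06]), rng
    )
    model = states.fit_hmm(traces, 2, seed=0)

    X = np.concatenate([np.log(tr.r) for tr in traces])[:, None]
    lengths = [len(tr.r) for tr in traces]
    gh = hmmlearn.GaussianHMM(
        n_components=2, covariance_type="diag", n_iter=200, random_state=0
    )
    gh.fit(X, lengths)
    order = np.argsort(gh.means_.ravel())
    A_ref = gh.transmat_[np.ix_(order, order)]
    assert np.allclose(model.transition_matrix, A_ref, atol=0.03)


def test_per_trace_fits_return_one_model_each():
    rng = np.random.default_rng(24)
    traces = [StepTrace(i, rng.gamma(3.0, 0.02, 120), 0.081) for i in range(3)]
    models = states.fit_hmm_per_trace(traces, 1, seed=0)
    assert len(models) == 3
    for m in models:
        assert abs(m.emissions[0].mean - 0.06) / 0.06 < 0.2
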