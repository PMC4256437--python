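"""State-space model: densities, likelihood, MCMC mechanics, decoding."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from grazetrack import (
    MCMCConfig,
    SSMParams,
    SimConfig,
    StateEmission,
    fit_ssm,
    gelman_rubin,
    hmm_loglik,
    simulate_track,
    weibull_pdf,
    wrapped_cauchy_pdf,
)
from grazetrack.ssm import (
    STEP_FLOOR_M,
    decode_states,
    modal_states,
    posterior_to_frame,
)


class TestWrappedCauchy:
    def test_uniform_limit(self):
        assert wrapped_cauchy_pdf(1.234, mu=0.0, rho=0.0) == pytest.approx(1 / (2 * math.pi))

    def test_mode_closed_form(self):
        # (1+rho)/((1-rho) 2 pi) at theta = mu
        assert wrapped_cauchy_pdf(0.7, mu=0.7, rho=0.5) == pytest.approx(3 / (2 * math.pi))

    @pytest.mark.parametrize("mu,rho", [(0.0, 0.3), (1.2, 0.8), (-2.0, 0.0)])
    def test_normalization(self, mu, rho):
        val, _ = integrate.quad(lambda t: wrapped_cauchy_pdf(t, mu, rho), -math.pi, math.pi)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_matches_scipy(self):
        theta = np.linspace(-3, 3, 7)
        mine = wrapped_cauchy_pdf(theta, mu=0.4, rho=0.6)
        ref = stats.wrapcauchy.pdf(np.mod(theta - 0.4, 2 * math.pi), 0.6)
        np.testing.assert_allclose(mine, ref, rtol=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            wrapped_cauchy_pdf(0.0, 0.0, 1.0)


class TestWeibull:
    def test_exponential_limit_at_zero(self):
        assert weibull_pdf(0.0, shape=1.0, scale=1.0) == pytest.approx(1.0)

    def test_plug_in(self):
        assert weibull_pdf(1.0, shape=2.0, scale=1.0) == pytest.approx(2.0 * math.exp(-1.0))

    def test_normalization(self):
        val, _ = integrate.quad(lambda d: weibull_pdf(d, 1.5, 3.0), 0, np.inf)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_matches_scipy(self):
        d = np.linspace(0.01, 10, 9)
        np.testing.assert_allclose(
            weibull_pdf(d, 1.7, 2.3), stats.weibull_min.pdf(d, 1.7, scale=2.3), rtol=1e-12
        )

    def test_domain_error(self):
        with pytest.raises(ValueError):
            weibull_pdf(1.0, shape=-1.0, scale=1.0)


def _params(q=None, initial=None, seed=0):
    rng = np.random.default_rng(seed)
    ems = tuple(
        StateEmission(rng.uniform(0.6, 3.0), rng.uniform(0.5, 8.0), rng.uniform(-3, 3), rng.uniform(0, 0.9))
        for _ in range(3)
    )
    q = q if q is not None else rng.dirichlet(np.ones(3), size=3)
    initial = initial if initial is not None else rng.dirichlet(np.ones(3))
    return SSMParams(ems, q, initial)


class TestHmmLoglik:
    def test_degenerate_chain_is_single_state_sum(self):
        p = _params(q=np.eye(3), initial=np.array([1.0, 0.0, 0.0]))
        rng = np.random.default_rng(1)
        steps = rng.weibull(1.5, 12) * 2
        angles = rng.uniform(-np.pi, np.pi, 12)
        angles[0] = np.nan
        e = p.emissions[0]
        expected = sum(
            math.log(weibull_pdf(max(d, STEP_FLOOR_M), e.shape, e.scale))
            + (math.log(wrapped_cauchy_pdf(a, e.mu, e.rho)) if np.isfinite(a) else -math.log(2 * math.pi))
            for d, a in zip(steps, angles)
        )
        assert hmm_loglik(steps, angles, p) == pytest.approx(expected)

    def test_relabeling_invariance(self):
        p = _params(seed=3)
        rng = np.random.default_rng(4)
        steps = rng.weibull(1.2, 30) * 3
        angles = rng.uniform(-np.pi, np.pi, 30)
        base = hmm_loglik(steps, angles, p)
        perm = np.array([2, 0, 1])
        p2 = SSMParams(
            tuple(p.emissions[i] for i in perm),
            p.transition[np.ix_(perm, perm)],
            p.initial[perm],
        )
        assert hmm_loglik(steps, angles, p2) == pytest.approx(base)

    def test_nonfinite_emission_identified(self):
        p = _params(seed=5)
        steps = np.array([1.0, np.inf, 2.0])
        angles = np.array([np.nan, 0.1, 0.2])
        with pytest.raises(ValueError, match="index 1"):
            hmm_loglik(steps, angles, p)

    def test_misaligned_inputs(self):
        with pytest.raises(ValueError):
            hmm_loglik(np.ones(5), np.ones(4), _params())


class TestGelmanRubin:
    def test_identical_chains_unity(self):
        c = np.random.default_rng(0).normal(size=500)
        # with B = 0 the statistic is sqrt((n-1)/n), i.e. 1 up to O(1/n)
        assert gelman_rubin(np.stack([c, c, c])) == pytest.approx(1.0, abs=2e-3)

    def test_separated_chains_match_direct_formula(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 500), rng.normal(10, 1, 500)
        traces = np.stack([a, b])
        n = 500
        w = 0.5 * (a.var(ddof=1) + b.var(ddof=1))
        b_over_n = np.var([a.mean(), b.mean()], ddof=1)
        expected = math.sqrt(((n - 1) / n * w + b_over_n) / w)
        assert gelman_rubin(traces) == pytest.approx(expected)
        assert gelman_rubin(traces) > 3

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        traces = rng.normal(size=(3, 400)) + np.array([[0.0], [0.3], [-0.2]])
        assert gelman_rubin(5.0 * traces - 7.0) == pytest.approx(gelman_rubin(traces))

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.ones((2, 100)))


class TestModalDecoding:
    def test_counting(self):
        # 700 draws of state 0, 500 of state 1, 300 of state 2 at one position
        draws = np.repeat([0, 1, 2], [700, 500, 300])[:, None]
        assert modal_states(draws)[0] == 0

    def test_tie_breaks_to_lowest_state(self):
        draws = np.array([[0], [2], [2], [0]])
        assert modal_states(draws)[0] == 0

    def test_unanimous(self):
        draws = np.full((50, 4), 2)
        assert (modal_states(draws) == 2).all()


def _quick_cfg(n_iter=120, burn_in=40, n_chains=2):
    return MCMCConfig(n_chains=n_chains, n_iter=n_iter, burn_in=burn_in)


@pytest.fixture(scope="module")
def clean_sim():
    return simulate_track(SimConfig(n_positions=600, seed=5, gps_noise_sigma=0.0))


class TestFitSsm:
    def test_deterministic_under_seed(self, clean_sim):
        a = fit_ssm(clean_sim.track, mcmc=_quick_cfg(), seed=9)
        b = fit_ssm(clean_sim.track, mcmc=_quick_cfg(), seed=9)
        np.testing.assert_array_equal(a.scale, b.scale)
        np.testing.assert_array_equal(a.states, b.states)

    def test_kept_draw_count_default_schedule(self, clean_sim):
        post = fit_ssm(clean_sim.track, seed=1)
        assert post.n_draws == 1500  # 3 chains x 500 kept iterations

    def test_states_ordered_by_mean_step(self, clean_sim):
        post = fit_ssm(clean_sim.track, mcmc=_quick_cfg(), seed=2)
        k = post.flat("shape")
        lam = post.flat("scale")
        mean_steps = lam * np.vectorize(lambda kk: math.gamma(1 + 1 / kk))(k)
        assert (np.diff(mean_steps, axis=1) >= -1e-12).all()

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            fit_ssm((np.ones(10), np.full(10, 0.1)), seed=0)

    def test_decode_shapes_and_labels(self, clean_sim):
        post = fit_ssm(clean_sim.track, mcmc=_quick_cfg(), seed=3)
        result = decode_states(post)[clean_sim.track.sequence_id]
        assert len(result) == len(clean_sim.track)
        assert set(result.labels) <= {"resting", "grazing", "walking"}

    def test_posterior_frame_export(self, clean_sim):
        post = fit_ssm(clean_sim.track, mcmc=_quick_cfg(), seed=4)
        frame = posterior_to_frame(post)
        assert len(frame) == post.n_draws
        assert "scale_walking" in frame.columns and "q_grazing_grazing" in frame.columns

    def test_decoding_degrades_with_overlap(self):
        # shrink the kinematic contrast between states; accuracy must fall
        accs = []
        for contrast in (1.0, 0.45, 0.18):
            speeds = tuple(0.06 * (s / 0.06) ** contrast for s in (0.04, 0.06, 0.41))
            cfg = SimConfig(
                n_positions=900,
                seed=11,
                gps_noise_sigma=0.0,
                emissions=tuple(
                    StateEmission(1.5, sp * 20.0 / math.gamma(1 + 1 / 1.5), 0.0, r)
                    for sp, r in zip(speeds, (0.1, 0.4, 0.8))
                ),
            )
            sim = simulate_track(cfg)
            post = fit_ssm(sim.track, mcmc=_quick_cfg(200, 60), seed=13)
            dec = decode_states(post)[sim.track.sequence_id]
            accs.append(np.mean(dec.labels == sim.track.labels))
        assert accs[0] > accs[1] > accs[2]


def test_ssm_params_validation():
    ems = tuple(StateEmission(1.5, s) for s in (1.0, 2.0, 3.0))
    with pytest.raises(ValueError):
        SSMParams(ems, np.full((3, 3), 0.4))  # rows do not sum to 1
    with pytest.raises(ValueError):
        StateEmission(1.5, 2.0, 0.0, 1.0)  # rho = 1 not allowed
    with pytest.raises(ValueError):
        StateEmission(-1.0, 2.0)
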