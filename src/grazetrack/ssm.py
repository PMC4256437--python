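"""3-state switching random-walk state-space model for step/turn data.

The observed movement path is modeled as a mixture of three random walks
with fixed switching probabilities between them: a latent first-order
Markov chain selects, at every fix interval, one of three behavioral
states, and each state emits a step length from its own Weibull
distribution (shape k, scale λ, meters) and a turning angle from its own
wrapped Cauchy distribution (mean direction μ, concentration ρ).  States
are identified by their mean step length λ·Γ(1+1/k), ascending:
resting < grazing < walking.

Inference is Bayesian, by a blocked MCMC sampler:

* latent states by forward-filtering backward-sampling (FFBS) given the
  current parameters,
* each row of the switching matrix from its conjugate Dirichlet
  posterior given the sampled transition counts (uniform prior),
* emission parameters by random-walk Metropolis — wide Gamma(0.01, 0.01)
  priors for the Weibull shape and scale, uniform priors for μ and ρ —
  with proposal scales adapted during burn-in to a 20–50% acceptance
  rate.

Label switching is resolved after every iteration by reordering states by
mean step length.  The default schedule keeps 500 iterations from each of
3 chains after a burn-in of 200; convergence is assessed with the
Gelman-Rubin potential scale reduction factor.  The per-position decoded
state is the most frequent state of that position across all kept draws.

Numerical conventions: step lengths are floored at 0.01 m before Weibull
evaluation (densities with k < 1 diverge at zero), and undefined turning
angles (zero-length steps, the first move of a track) contribute a
uniform 1/2π angle density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from math import gamma as _gamma_fn
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .classify import PredictionResult
from .metrics import step_lengths, turning_angles
from .tracks import TrackSequence

__all__ = [
    "STATE_NAMES",
    "StateEmission",
    "SSMParams",
    "SSMPriors",
    "MCMCConfig",
    "PosteriorSample",
    "wrapped_cauchy_pdf",
    "weibull_pdf",
    "steps_and_turns",
    "hmm_loglik",
    "fit_ssm",
    "gelman_rubin",
    "modal_states",
    "decode_states",
    "decode_track",
    "posterior_to_frame",
]

#: Behavioral states in ascending order of mean step length.
STATE_NAMES = ("resting", "grazing", "walking")

#: Step lengths are clipped to this floor [m] before Weibull evaluation.
STEP_FLOOR_M = 0.01

_LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class StateEmission:
    """Emission distributions of one behavioral state.

    Weibull(shape, scale) step lengths [m per interval] and wrapped
    Cauchy(mu, rho) turning angles [rad].
    """

    shape: float
    scale: float
    mu: float = 0.0
    rho: float = 0.0

    def __post_init__(self):
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError("Weibull shape and scale must be positive")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("wrapped Cauchy rho must be in [0, 1)")
        if not (-math.pi < self.mu <= math.pi):
            raise ValueError("mu must be in (-pi, pi]")

    @property
    def mean_step(self) -> float:
        """Mean step length λ·Γ(1 + 1/k) [m]."""
        return self.scale * _gamma_fn(1.0 + 1.0 / self.shape)


@dataclass(frozen=True)
class SSMParams:
    """Full parameter set: three state emissions, switching matrix, initial law.

    The switching matrix rows must be probability vectors.  Fitted
    posteriors always order states by ascending mean step (resting <
    grazing < walking); arbitrary orders are allowed here so that
    likelihoods can be evaluated under any labeling.
    """

    emissions: tuple[StateEmission, StateEmission, StateEmission]
    transition: np.ndarray
    initial: np.ndarray = field(default_factory=lambda: np.full(3, 1.0 / 3.0))

    def __post_init__(self):
        q = np.asarray(self.transition, dtype=float)
        p0 = np.asarray(self.initial, dtype=float)
        if q.shape != (3, 3) or p0.shape != (3,):
            raise ValueError("transition must be 3x3 and initial length-3")
        if (q < 0).any() or (p0 < 0).any():
            raise ValueError("probabilities must be non-negative")
        if np.abs(q.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValueError("each transition row must sum to 1 within 1e-12")
        if abs(p0.sum() - 1.0) > 1e-9:
            raise ValueError("initial distribution must sum to 1")
        object.__setattr__(self, "emissions", tuple(self.emissions))
        object.__setattr__(self, "transition", q)
        object.__setattr__(self, "initial", p0)
        if len(self.emissions) != 3:
            raise ValueError("exactly three state emissions required")

    @property
    def mean_steps(self) -> np.ndarray:
        return np.array([e.mean_step for e in self.emissions])


@dataclass(frozen=True)
class SSMPriors:
    """Vague priors: Gamma(shape, rate) on Weibull k and λ, uniform on μ
    (over (−π, π]) and ρ (over [0, 1)), Dirichlet(alpha,...) per Q row."""

    gamma_shape: float = 0.01
    gamma_rate: float = 0.01
    dirichlet_alpha: float = 1.0


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler schedule; the default keeps 3 × 500 draws after burn-in."""

    n_chains: int = 3
    n_iter: int = 700
    burn_in: int = 200
    fix_mu: bool = False

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")


# ---------------------------------------------------------------------------
# densities


def wrapped_cauchy_pdf(theta, mu: float, rho: float):
    """Wrapped Cauchy density on (−π, π].

    f(θ) = (1 − ρ²) / (2π (1 + ρ² − 2ρ cos(θ − μ))); ρ = 0 is the
    circular uniform 1/2π.
    """
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must be in [0, 1)")
    theta = np.asarray(theta, dtype=float)
    dens = (1.0 - rho**2) / (2.0 * np.pi * (1.0 + rho**2 - 2.0 * rho * np.cos(theta - mu)))
    return dens if dens.ndim else float(dens)


def weibull_pdf(d, shape: float, scale: float):
    """Weibull density (k/λ)(d/λ)^{k−1} exp(−(d/λ)^k) for d ≥ 0."""
    if not (shape > 0 and scale > 0):
        raise ValueError("Weibull shape and scale must be positive")
    d = np.asarray(d, dtype=float)
    z = d / scale
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = np.where(
            d < 0, 0.0, (shape / scale) * z ** (shape - 1.0) * np.exp(-(z**shape))
        )
    return dens if dens.ndim else float(dens)


def steps_and_turns(track: TrackSequence) -> tuple[np.ndarray, np.ndarray]:
    """Observation arrays for the SSM: one (step, turn) pair per move.

    Move ``i`` goes from position ``i`` to ``i+1``; its turning angle is
    the signed direction change at position ``i`` (NaN for the first move
    and at zero-length steps).
    """
    d = step_lengths(track)
    theta = turning_angles(track, signed=True)[:-1]
    return d, theta


def _emission_logdens(
    d: np.ndarray, theta: np.ndarray, k: np.ndarray, lam: np.ndarray, mu: np.ndarray, rho: np.ndarray
) -> np.ndarray:
    """(T, 3) log emission densities; NaN angles get the uniform 1/2π."""
    dl = d[:, None] / lam[None, :]
    with np.errstate(invalid="ignore", over="ignore"):
        logb = np.log(k / lam)[None, :] + (k - 1.0)[None, :] * np.log(dl) - dl ** k[None, :]
    ang = np.where(np.isfinite(theta), theta, 0.0)[:, None]
    wc = (
        np.log1p(-(rho**2))[None, :]
        - _LOG_2PI
        - np.log(1.0 + (rho**2)[None, :] - 2.0 * rho[None, :] * np.cos(ang - mu[None, :]))
    )
    logb += np.where(np.isfinite(theta)[:, None], wc, -_LOG_2PI)
    return logb


# ---------------------------------------------------------------------------
# forward algorithm / FFBS kernels


@njit(cache=False)
def _forward_kernel(b, q, init):
    """Scaled forward recursion; returns log of the scaled likelihood."""
    t_len, n_states = b.shape
    alpha = init * b[0]
    s = alpha.sum()
    ll = np.log(s)
    alpha = alpha / s
    for t in range(1, t_len):
        new = np.zeros(n_states)
        for j in range(n_states):
            acc = 0.0
            for i in range(n_states):
                acc += alpha[i] * q[i, j]
            new[j] = acc * b[t, j]
        s = new.sum()
        ll += np.log(s)
        alpha = new / s
    return ll


@njit(cache=False)
def _ffbs_kernel(b, q, init, u):
    """Forward-filtering backward-sampling of one latent state path."""
    t_len, n_states = b.shape
    alphas = np.empty((t_len, n_states))
    alpha = init * b[0]
    alpha = alpha / alpha.sum()
    alphas[0] = alpha
    for t in range(1, t_len):
        new = np.zeros(n_states)
        for j in range(n_states):
            acc = 0.0
            for i in range(n_states):
                acc += alpha[i] * q[i, j]
            new[j] = acc * b[t, j]
        alpha = new / new.sum()
        alphas[t] = alpha
    states = np.empty(t_len, dtype=np.int64)
    r = u[t_len - 1]
    acc = 0.0
    states[t_len - 1] = n_states - 1
    for j in range(n_states):
        acc += alphas[t_len - 1, j]
        if r <= acc:
            states[t_len - 1] = j
            break
    for t in range(t_len - 2, -1, -1):
        wsum = 0.0
        w = np.empty(n_states)
        for j in range(n_states):
            w[j] = alphas[t, j] * q[j, states[t + 1]]
            wsum += w[j]
        r = u[t] * wsum
        acc = 0.0
        states[t] = n_states - 1
        for j in range(n_states):
            acc += w[j]
            if r <= acc:
                states[t] = j
                break
    return states


def _scaled_b(logb: np.ndarray) -> tuple[np.ndarray, float]:
    bad = ~np.isfinite(logb).all(axis=1)
    if bad.any():
        raise ValueError(f"non-finite emission density at observation index {int(np.flatnonzero(bad)[0])}")
    c = logb.max(axis=1)
    return np.exp(logb - c[:, None]), float(c.sum())


def hmm_loglik(steps: np.ndarray, angles: np.ndarray, params: SSMParams) -> float:
    """Marginal log-likelihood of a step/turn sequence under the SSM.

    Sums over all latent state paths with the scaled forward recursion;
    equals brute-force path enumeration on short sequences.
    """
    steps = np.asarray(steps, dtype=float)
    angles = np.asarray(angles, dtype=float)
    if steps.shape != angles.shape:
        raise ValueError("steps and angles must be aligned")
    k = np.array([e.shape for e in params.emissions])
    lam = np.array([e.scale for e in params.emissions])
    mu = np.array([e.mu for e in params.emissions])
    rho = np.array([e.rho for e in params.emissions])
    logb = _emission_logdens(np.maximum(steps, STEP_FLOOR_M), angles, k, lam, mu, rho)
    b, corr = _scaled_b(logb)
    return float(_forward_kernel(b, np.asarray(params.transition), np.asarray(params.initial))) + corr


# ---------------------------------------------------------------------------
# posterior container


@dataclass
class PosteriorSample:
    """Kept MCMC draws, organised as (chains, draws-per-chain, ...).

    ``states`` holds the latent state draw per observation (move), with
    observations of all fitted sequences concatenated in ``sequence_slices``
    order.  ``rhat`` maps parameter names to Gelman-Rubin statistics.
    """

    shape: np.ndarray
    scale: np.ndarray
    mu: np.ndarray
    rho: np.ndarray
    transition: np.ndarray
    states: np.ndarray
    sequence_slices: tuple[tuple[str, int, int], ...]
    burn_in: int
    rhat: dict[str, float] = field(default_factory=dict)
    state_names: tuple[str, ...] = STATE_NAMES

    @property
    def n_chains(self) -> int:
        return self.shape.shape[0]

    @property
    def n_draws(self) -> int:
        """Total kept draws across chains."""
        return self.shape.shape[0] * self.shape.shape[1]

    @property
    def converged(self) -> bool:
        """All Gelman-Rubin statistics at or below 1.1."""
        return bool(self.rhat) and max(self.rhat.values()) <= 1.1

    def flat(self, name: str) -> np.ndarray:
        """Draws of one parameter family pooled over chains."""
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    def mean_params(self) -> SSMParams:
        """Posterior-mean parameter set (states stay mean-step ordered)."""
        k, lam = self.flat("shape").mean(axis=0), self.flat("scale").mean(axis=0)
        mus = self.flat("mu")
        mu = np.arctan2(np.sin(mus).mean(axis=0), np.cos(mus).mean(axis=0))  # circular mean
        rho = self.flat("rho").mean(axis=0)
        q = self.flat("transition").mean(axis=0)
        q = q / q.sum(axis=1, keepdims=True)
        emissions = tuple(
            StateEmission(k[j], lam[j], float(mu[j]), min(rho[j], 1 - 1e-12)) for j in range(3)
        )
        return SSMParams(emissions, q)


def gelman_rubin(traces: np.ndarray) -> float:
    """Potential scale reduction factor for one scalar parameter.

    ``traces`` is (n_chains, n_draws).  R̂ = sqrt((W(n−1)/n + B/n) / W)
    with W the mean within-chain variance and B/n the variance of the
    chain means.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    n = traces.shape[1]
    w = traces.var(axis=1, ddof=1).mean()
    if w == 0:
        raise ValueError("zero within-chain variance; R-hat undefined")
    b_over_n = traces.mean(axis=1).var(ddof=1)
    return float(np.sqrt(((n - 1) / n * w + b_over_n) / w))


def _compute_rhat(post: PosteriorSample) -> dict[str, float]:
    out: dict[str, float] = {}
    for fam in ("shape", "scale", "mu", "rho"):
        arr = getattr(post, fam)
        for j, name in enumerate(post.state_names):
            out[f"{fam}[{name}]"] = gelman_rubin(arr[:, :, j])
    for i in range(3):
        for j in range(3):
            out[f"q[{post.state_names[i]},{post.state_names[j]}]"] = gelman_rubin(
                post.transition[:, :, i, j]
            )
    return out


# ---------------------------------------------------------------------------
# MCMC


def _as_observations(data) -> list[tuple[str, np.ndarray, np.ndarray]]:
    if isinstance(data, TrackSequence):
        data = [data]
    elif isinstance(data, tuple) and len(data) == 2 and not isinstance(data[0], TrackSequence):
        data = [data]
    obs = []
    for i, item in enumerate(data):
        if isinstance(item, TrackSequence):
            d, theta = steps_and_turns(item)
            obs.append((item.sequence_id, d, theta))
        else:
            d, theta = item
            obs.append((str(i), np.asarray(d, float), np.asarray(theta, float)))
    return obs


def _wc_loglik(theta: np.ndarray, mu: float, rho: float) -> float:
    return float(
        theta.size * (math.log1p(-(rho**2)) - _LOG_2PI)
        - np.log(1.0 + rho**2 - 2.0 * rho * np.cos(theta - mu)).sum()
    )


def _weib_loglik(d: np.ndarray, sum_logd: float, k: float, lam: float) -> float:
    return float(
        d.size * (math.log(k) - k * math.log(lam)) + (k - 1.0) * sum_logd - ((d / lam) ** k).sum()
    )


def _wrap_angle(a: float) -> float:
    a = (a + math.pi) % (2.0 * math.pi) - math.pi
    return math.pi if a == -math.pi else a


def fit_ssm(
    data,
    priors: SSMPriors | None = None,
    mcmc: MCMCConfig | None = None,
    seed: int = 0,
) -> PosteriorSample:
    """Fit the 3-state switching random-walk model by MCMC.

    Parameters
    ----------
    data : TrackSequence, list of TrackSequence, or (steps, angles) pair(s)
        One or more observation sequences.  Multiple sequences share
        parameters; the latent chain restarts at each sequence start.
    priors : SSMPriors, optional
    mcmc : MCMCConfig, optional
        Default: 3 chains × 700 iterations, 200 burn-in (1500 kept draws).
    seed : int
        Master seed; chain c uses an rng seeded from (seed, c).

    Returns
    -------
    PosteriorSample
        With Gelman-Rubin statistics in ``rhat``; non-convergence
        (any R̂ > 1.1) is flagged via ``converged``, not fatal.
    """
    priors = priors or SSMPriors()
    cfg = mcmc or MCMCConfig()
    obs = _as_observations(data)
    total = sum(d.size for _, d, _ in obs)
    if total < 50:
        raise ValueError("need at least 50 observations (positions) to fit the SSM")
    slices = []
    start = 0
    for sid, d, _ in obs:
        slices.append((sid, start, start + d.size))
        start += d.size
    d_all = np.concatenate([np.maximum(d, STEP_FLOOR_M) for _, d, _ in obs])
    th_all = np.concatenate([t for _, _, t in obs])
    log_d_all = np.log(d_all)
    init_dist = np.full(3, 1.0 / 3.0)
    kept = cfg.n_iter - cfg.burn_in

    n_chains = cfg.n_chains
    shape_out = np.empty((n_chains, kept, 3))
    scale_out = np.empty((n_chains, kept, 3))
    mu_out = np.empty((n_chains, kept, 3))
    rho_out = np.empty((n_chains, kept, 3))
    q_out = np.empty((n_chains, kept, 3, 3))
    z_out = np.empty((n_chains, kept, total), dtype=np.int8)

    param_names = ("k", "lam", "mu", "rho")
    for chain in range(n_chains):
        rng = np.random.default_rng([seed, chain])
        # data-driven start, jittered per chain
        lam = np.quantile(d_all, [0.25, 0.60, 0.95]) * np.exp(0.1 * rng.standard_normal(3))
        lam = np.maximum(np.sort(lam), STEP_FLOOR_M)
        k = np.full(3, 1.3) * np.exp(0.05 * rng.standard_normal(3))
        mu = np.zeros(3)
        rho = np.clip(0.3 + 0.1 * rng.uniform(-1, 1, 3), 0.01, 0.95)
        q = np.full((3, 3), 0.1)
        np.fill_diagonal(q, 0.8)
        step_sizes = {("k", j): 0.2 for j in range(3)}
        step_sizes.update({("lam", j): 0.2 for j in range(3)})
        step_sizes.update({("mu", j): 0.3 for j in range(3)})
        step_sizes.update({("rho", j): 0.1 for j in range(3)})
        acc = {key: 0 for key in step_sizes}
        tries = {key: 0 for key in step_sizes}

        for it in range(cfg.n_iter):
            # (i) latent states by FFBS, per sequence
            z_parts = []
            for _, d_seq, th_seq in obs:
                logb = _emission_logdens(np.maximum(d_seq, STEP_FLOOR_M), th_seq, k, lam, mu, rho)
                b, _ = _scaled_b(logb)
                z_parts.append(_ffbs_kernel(b, q, init_dist, rng.random(d_seq.size)))
            z = np.concatenate(z_parts)

            # (ii) switching matrix rows from conjugate Dirichlet posterior
            counts = np.zeros((3, 3))
            for z_seq in z_parts:
                np.add.at(counts, (z_seq[:-1], z_seq[1:]), 1)
            for row in range(3):
                q[row] = rng.dirichlet(priors.dirichlet_alpha + counts[row])

            # (iii) emission parameters by random-walk Metropolis
            for j in range(3):
                mask = z == j
                if not mask.any():
                    continue
                d_j = d_all[mask]
                sum_logd = log_d_all[mask].sum()
                th_j = th_all[mask]
                th_j = th_j[np.isfinite(th_j)]

                # Weibull shape: log-scale random walk, Gamma prior
                prop = k[j] * math.exp(step_sizes[("k", j)] * rng.standard_normal())
                tries[("k", j)] += 1
                logr = (
                    _weib_loglik(d_j, sum_logd, prop, lam[j])
                    - _weib_loglik(d_j, sum_logd, k[j], lam[j])
                    + priors.gamma_shape * (math.log(prop) - math.log(k[j]))
                    - priors.gamma_rate * (prop - k[j])
                )
                if math.log(rng.random()) < logr:
                    k[j] = prop
                    acc[("k", j)] += 1

                # Weibull scale
                prop = lam[j] * math.exp(step_sizes[("lam", j)] * rng.standard_normal())
                tries[("lam", j)] += 1
                logr = (
                    _weib_loglik(d_j, sum_logd, k[j], prop)
                    - _weib_loglik(d_j, sum_logd, k[j], lam[j])
                    + priors.gamma_shape * (math.log(prop) - math.log(lam[j]))
                    - priors.gamma_rate * (prop - lam[j])
                )
                if math.log(rng.random()) < logr:
                    lam[j] = prop
                    acc[("lam", j)] += 1

                if th_j.size:
                    if not cfg.fix_mu:
                        prop = _wrap_angle(mu[j] + step_sizes[("mu", j)] * rng.standard_normal())
                        tries[("mu", j)] += 1
                        if math.log(rng.random()) < _wc_loglik(th_j, prop, rho[j]) - _wc_loglik(
                            th_j, mu[j], rho[j]
                        ):
                            mu[j] = prop
                            acc[("mu", j)] += 1
                    prop = rho[j] + step_sizes[("rho", j)] * rng.standard_normal()
                    tries[("rho", j)] += 1
                    if 0.0 <= prop < 1.0 and math.log(rng.random()) < _wc_loglik(
                        th_j, mu[j], prop
                    ) - _wc_loglik(th_j, mu[j], rho[j]):
                        rho[j] = prop
                        acc[("rho", j)] += 1

            # label switching: keep states ordered by mean step length
            means = lam * np.array([_gamma_fn(1.0 + 1.0 / kj) for kj in k])
            order = np.argsort(means, kind="stable")
            if not np.array_equal(order, np.arange(3)):
                inv = np.argsort(order)
                k, lam, mu, rho = k[order], lam[order], mu[order], rho[order]
                q = q[np.ix_(order, order)]
                z = inv[z]

            # proposal adaptation towards 20-50% acceptance (burn-in only)
            if it < cfg.burn_in and (it + 1) % 50 == 0:
                for key in step_sizes:
                    if tries[key] == 0:
                        continue
                    rate = acc[key] / tries[key]
                    if rate < 0.2:
                        step_sizes[key] *= 0.7
                    elif rate > 0.5:
                        step_sizes[key] *= 1.5
                    acc[key] = 0
                    tries[key] = 0

            if it >= cfg.burn_in:
                keep = it - cfg.burn_in
                shape_out[chain, keep] = k
                scale_out[chain, keep] = lam
                mu_out[chain, keep] = mu
                rho_out[chain, keep] = rho
                q_out[chain, keep] = q
                z_out[chain, keep] = z

    post = PosteriorSample(
        shape=shape_out,
        scale=scale_out,
        mu=mu_out,
        rho=rho_out,
        transition=q_out,
        states=z_out,
        sequence_slices=tuple(slices),
        burn_in=cfg.burn_in,
    )
    if n_chains >= 2:
        post.rhat = _compute_rhat(post)
    return post


# ---------------------------------------------------------------------------
# decoding


def modal_states(draws: np.ndarray) -> np.ndarray:
    """Most frequent state per column of an (n_draws, T) draw matrix.

    Ties resolve to the lowest state index.
    """
    draws = np.asarray(draws)
    counts = np.stack([(draws == s).sum(axis=0) for s in range(3)])
    return counts.argmax(axis=0)


def _moves_to_positions(move_states: np.ndarray) -> np.ndarray:
    # move i arrives at position i+1; position 0 inherits the first move's state
    return np.concatenate([[move_states[0]], move_states])


def decode_states(posterior: PosteriorSample) -> dict[str, PredictionResult]:
    """Modal-state decoding of every fitted sequence.

    For each position the most frequent state across all kept draws is
    taken as the predicted behavior (ties → lowest-index state, i.e. the
    slower behavior).  Returns one PredictionResult per fitted sequence,
    with per-*position* labels (one more than the number of moves).
    """
    flat = posterior.flat("states")
    modal = modal_states(flat)
    out = {}
    for sid, start, stop in posterior.sequence_slices:
        labels = np.array(
            [posterior.state_names[s] for s in _moves_to_positions(modal[start:stop])], dtype=object
        )
        out[sid] = PredictionResult(labels, "H", sid)
    return out


def decode_track(
    posterior: PosteriorSample,
    track: TrackSequence,
    seed: int = 0,
    thin: int = 5,
) -> PredictionResult:
    """Decode a sequence that was not part of the fit.

    Every ``thin``-th kept draw's parameters are used to sample a latent
    path for the new sequence by FFBS; the per-position modal state over
    those paths is returned.  This is the held-out prediction rule for
    the state-space model in cross-validation.
    """
    d, theta = steps_and_turns(track)
    d = np.maximum(d, STEP_FLOOR_M)
    rng = np.random.default_rng(seed)
    ks, lams = posterior.flat("shape"), posterior.flat("scale")
    mus, rhos = posterior.flat("mu"), posterior.flat("rho")
    qs = posterior.flat("transition")
    init_dist = np.full(3, 1.0 / 3.0)
    paths = []
    for idx in range(0, ks.shape[0], max(int(thin), 1)):
        logb = _emission_logdens(d, theta, ks[idx], lams[idx], mus[idx], rhos[idx])
        b, _ = _scaled_b(logb)
        paths.append(_ffbs_kernel(b, qs[idx], init_dist, rng.random(d.size)))
    modal = modal_states(np.stack(paths))
    labels = np.array([posterior.state_names[s] for s in _moves_to_positions(modal)], dtype=object)
    return PredictionResult(labels, "H", track.sequence_id)


def posterior_to_frame(posterior: PosteriorSample) -> pd.DataFrame:
    """One row per kept draw (chain-major) with all scalar parameters.

    Suitable for tab-separated export and external diagnostics.
    """
    rows = {}
    n_chains, kept = posterior.shape.shape[:2]
    rows["chain"] = np.repeat(np.arange(n_chains), kept)
    rows["iteration"] = np.tile(np.arange(kept) + posterior.burn_in, n_chains)
    for fam in ("shape", "scale", "mu", "rho"):
        arr = posterior.flat(fam)
        for j, name in enumerate(posterior.state_names):
            rows[f"{fam}_{name}"] = arr[:, j]
    q = posterior.flat("transition")
    for i, a in enumerate(posterior.state_names):
        for j, b in enumerate(posterior.state_names):
            rows[f"q_{a}_{b}"] = q[:, i, j]
    return pd.DataFrame(rows)
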