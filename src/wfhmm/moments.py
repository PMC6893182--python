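"""Approximate Wright-Fisher moments and fixation probabilities.

Exact WF moments under selection have no closed form, but a second-order
Taylor expansion of the fitness function ``f`` around the current mean yields
a cheap per-generation recursion for the approximate mean and variance::

    mu_{t+1}     = f(mu_t) + f''(mu_t)/2 * sigma2_t
    sigma2_{t+1} = mu~(1 - mu~)/N + (1 - 1/N) f'(mu_t)^2 sigma2_t

with ``mu~ = f(mu_t) + f''(mu_t)/2 * sigma2_t`` and ``N`` the haploid size.
Under neutrality ``f`` is the identity (affine), the expansion is exact and
the recursion reproduces the classical drift variance
``x0(1-x0)(1 - (1-1/N)^t)`` to machine precision.

The Beta-with-spikes construction additionally tracks the loss/fixation
masses ``p0_t``/``p1_t`` through a per-generation recursion: the distribution
conditional on non-fixation is matched to a Beta(a*, b*), and the probability
of absorbing in the next generation is a ratio of Beta functions,

    p0_{t+1} = p0_t + (1 - p0_t - p1_t) B(a*, b* + N)/B(a*, b*),

(symmetrically for ``p1``), evaluated via log-gamma differences.  For a Beta
random variable X this ratio equals E[(1-X)^N], i.e. the chance of drawing
zero copies in the next binomial resampling round, so the recursion is the
natural moment-matched analogue of WF absorption.

All functions are vectorised over their frequency arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln

from .wright_fisher import PopulationParams, fitness, fitness_derivatives

# Feasibility clamps used wherever Beta parameters are formed.  The variance
# floor keeps the Beta shape parameters below ~1e7 so that betaln differences
# retain ~1e-8 absolute accuracy; it is NOT applied inside the plain moment
# recursion, where genuinely tiny variances (e.g. one generation at Ne=1e4)
# must survive untouched.
MEAN_EPS = 1e-9
VAR_FLOOR = 1e-8
VAR_CAP = 1.0 - 1e-6
DEGENERATE_EPS = 1e-12


class DegenerateStateError(ValueError):
    """Conditional moments are undefined: essentially all mass is fixed."""


class InfeasibleMomentsError(ValueError):
    """(mean, variance) outside the feasible region of a [0,1] distribution."""


@dataclass(frozen=True)
class MomentState:
    """Approximate WF state after ``t`` generations (arrays or scalars)."""

    mu: np.ndarray
    var: np.ndarray
    p0: np.ndarray
    p1: np.ndarray
    t: int


@dataclass(frozen=True)
class ConditionalMoments:
    """Mean/variance of the frequency conditional on non-fixation."""

    m_star: np.ndarray
    z2_star: np.ndarray


def _taylor_step(mu, var, params: PopulationParams):
    N = params.Ne
    fmu = fitness(mu, params)
    f1, f2 = fitness_derivatives(mu, params)
    mu_next = fmu + 0.5 * f2 * var
    mu_next = np.clip(mu_next, 0.0, 1.0)
    var_next = mu_next * (1.0 - mu_next) / N + (1.0 - 1.0 / N) * f1**2 * var
    var_next = np.clip(var_next, 0.0, mu_next * (1.0 - mu_next))
    return mu_next, var_next


def propagate_moments(mu0, var0, params: PopulationParams, t: int) -> MomentState:
    """Advance the Taylor moment recursion ``t`` generations.

    The mean is clamped to [0, 1] and the variance to the feasible band
    ``[0, mu(1-mu)]`` after each step; no variance floor is applied here.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    mu = np.asarray(mu0, dtype=float).copy()
    var = np.asarray(var0, dtype=float).copy()
    for _ in range(int(t)):
        mu, var = _taylor_step(mu, var, params)
    zeros = np.zeros_like(mu)
    return MomentState(mu=mu, var=var, p0=zeros, p1=zeros.copy(), t=int(t))


def conditional_moments(mu, var, p0, p1, eps: float = DEGENERATE_EPS,
                        clamp: bool = True) -> ConditionalMoments:
    """Moments of the frequency conditional on segregating (not fixed).

    ``m* = (m - p1)/(1 - p0 - p1)`` and
    ``z2* = (z2 + m^2 - p1)/(1 - p0 - p1) - m*^2``.  With ``clamp=True``
    (default) the result is pushed into the open feasibility region required
    by Beta matching; raw formula values are available with ``clamp=False``.
    """
    mu = np.asarray(mu, dtype=float)
    var = np.asarray(var, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    alive = 1.0 - p0 - p1
    if np.any(alive <= eps):
        raise DegenerateStateError("1 - p0 - p1 below threshold; state is fully fixed")
    m_star = (mu - p1) / alive
    z2_star = (var + mu**2 - p1) / alive - m_star**2
    if clamp:
        m_star = np.clip(m_star, MEAN_EPS, 1.0 - MEAN_EPS)
        z2_star = np.clip(z2_star, VAR_FLOOR, VAR_CAP * m_star * (1.0 - m_star))
    return ConditionalMoments(m_star=m_star, z2_star=z2_star)


def beta_params(m, z2):
    """Shape parameters of the Beta distribution with mean ``m``, variance ``z2``.

    ``a = m (m(1-m)/z2 - 1)``, ``b = (1-m)(m(1-m)/z2 - 1)``; requires
    ``0 < m < 1`` and ``0 < z2 < m(1-m)``.
    """
    m = np.asarray(m, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if np.any(m <= 0) or np.any(m >= 1):
        raise InfeasibleMomentsError(f"mean must lie in (0,1), got {m}")
    if np.any(z2 <= 0) or np.any(z2 >= m * (1.0 - m)):
        raise InfeasibleMomentsError(
            "variance must lie in (0, m(1-m)); clamp the moments first"
        )
    r = m * (1.0 - m) / z2 - 1.0
    a = m * r
    b = (1.0 - m) * r
    if a.ndim == 0:
        return float(a), float(b)
    return a, b


def _spike_increments(a, b, N):
    """log-space Beta-function ratios B(a,b+N)/B(a,b) and B(a+N,b)/B(a,b)."""
    lab = betaln(a, b)
    inc0 = np.exp(betaln(a, b + N) - lab)
    inc1 = np.exp(betaln(a + N, b) - lab)
    return inc0, inc1


def propagate_spikes(mu0, var0, params: PopulationParams, t: int) -> MomentState:
    """Jointly advance moments and loss/fixation masses ``t`` generations.

    Each generation: form conditional moments of the current state, match a
    Beta(a*, b*), add the Beta-function-ratio absorption increments to
    ``p0``/``p1``, then advance the (absolute) Taylor moment recursion.
    Degenerate starting points (mu0 in {0,1} with var0=0) become immediate
    point masses; states whose segregating mass falls below threshold are
    frozen.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    N = params.Ne
    mu = np.atleast_1d(np.asarray(mu0, dtype=float)).copy()
    var = np.atleast_1d(np.asarray(var0, dtype=float)).copy()
    scalar = np.asarray(mu0).ndim == 0
    p0 = np.zeros_like(mu)
    p1 = np.zeros_like(mu)
    lost = (mu <= 0.0) & (var == 0.0)
    fixed = (mu >= 1.0) & (var == 0.0)
    p0[lost] = 1.0
    p1[fixed] = 1.0
    for _ in range(int(t)):
        alive = 1.0 - p0 - p1
        act = alive > DEGENERATE_EPS
        if not np.any(act):
            break
        m_star = (mu[act] - p1[act]) / alive[act]
        z2_star = (var[act] + mu[act] ** 2 - p1[act]) / alive[act] - m_star**2
        m_star = np.clip(m_star, MEAN_EPS, 1.0 - MEAN_EPS)
        z2_star = np.clip(z2_star, VAR_FLOOR, VAR_CAP * m_star * (1.0 - m_star))
        r = m_star * (1.0 - m_star) / z2_star - 1.0
        a = m_star * r
        b = (1.0 - m_star) * r
        inc0, inc1 = _spike_increments(a, b, N)
        p0[act] = p0[act] + alive[act] * inc0
        p1[act] = p1[act] + alive[act] * inc1
        # absolute moment recursion (selection acts on the full distribution)
        mu_a, var_a = _taylor_step(mu[act], var[act], params)
        mu[act] = mu_a
        var[act] = var_a
    over = p0 + p1 > 1.0
    if np.any(over):  # guard against rounding at near-total absorption
        scale = 1.0 / (p0[over] + p1[over])
        p0[over] *= scale
        p1[over] *= scale
    if scalar:
        return MomentState(mu=float(mu[0]), var=float(var[0]),
                           p0=float(p0[0]), p1=float(p1[0]), t=int(t))
    return MomentState(mu=mu, var=var, p0=p0, p1=p1, t=int(t))
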