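"""Exact Wright-Fisher transition machinery.

The Wright-Fisher (WF) model describes the evolution of the frequency of a
biallelic variant in a panmictic population of ``Ne`` haploids with
non-overlapping generations.  Under diploid selection the genotype fitnesses
are 1, 1+sh and 1+s (reference homozygote, heterozygote, alternative
homozygote), and the frequency performs a Markov chain on the lattice
``{0, 1/Ne, ..., 1}`` whose one-generation row from state ``i/Ne`` is
``Binomial(Ne, f(i/Ne))``, where ``f`` is the deterministic post-selection
frequency.  Mutation is not modelled, so 0 and 1 are absorbing.

This module provides the exact machinery -- fitness function with analytic
derivatives, one-step matrix, multi-generation matrices by matrix power, and
exact moments/absorption masses -- used both as a transition model in its own
right (for small ``Ne``) and as the reference oracle for the parametric
approximations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special


class FitnessDomainError(ValueError):
    """Raised when the fitness denominator is non-positive."""


@dataclass(frozen=True)
class PopulationParams:
    """Population-genetic parameters.

    Parameters
    ----------
    Ne : int
        Haploid effective population size (>= 2).
    s : float
        Selection coefficient of the alternative homozygote (>= -1).
    h : float
        Dominance coefficient; 0.5 gives additive (genic) selection.
    """

    Ne: int
    s: float = 0.0
    h: float = 0.5

    def __post_init__(self) -> None:
        if int(self.Ne) != self.Ne or self.Ne < 2:
            raise ValueError(f"Ne must be an integer >= 2, got {self.Ne}")
        if self.s < -1:
            raise ValueError(f"s must be >= -1, got {self.s}")


@dataclass(frozen=True)
class WFTransitionMatrix:
    """Row-stochastic transition matrix over the lattice {0, 1/Ne, ..., 1}."""

    Ne: int
    dt: int
    probs: np.ndarray

    @property
    def lattice(self) -> np.ndarray:
        return np.arange(self.Ne + 1) / self.Ne


def _fitness_parts(x, s, h):
    num = x * (1.0 + s * h + s * (1.0 - h) * x)
    den = 1.0 + 2.0 * s * h * x + s * (1.0 - 2.0 * h) * x * x
    return num, den


def fitness(x, params: PopulationParams):
    """Deterministic post-selection frequency ``f(x)``.

    ``f(x) = x (1 + sh + s(1-h)x) / (1 + 2shx + s(1-2h)x^2)``; fixed points at
    0 and 1.  Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    num, den = _fitness_parts(x, params.s, params.h)
    if np.any(np.asarray(den) <= 0):
        bad = np.atleast_1d(x)[np.atleast_1d(den) <= 0]
        raise FitnessDomainError(
            f"fitness denominator non-positive at x={bad.tolist()} "
            f"(s={params.s}, h={params.h})"
        )
    out = num / den
    return out if out.ndim else float(out)


def fitness_derivatives(x, params: PopulationParams):
    """Exact first and second derivatives of the fitness function.

    ``f`` is a rational function N(x)/D(x); the derivatives are closed-form
    quotient-rule expressions, not numerical differences.
    """
    x = np.asarray(x, dtype=float)
    s, h = params.s, params.h
    num, den = _fitness_parts(x, s, h)
    if np.any(np.asarray(den) <= 0):
        bad = np.atleast_1d(x)[np.atleast_1d(den) <= 0]
        raise FitnessDomainError(
            f"fitness denominator non-positive at x={bad.tolist()} (s={s}, h={h})"
        )
    dn = (1.0 + s * h) + 2.0 * s * (1.0 - h) * x
    d2n = 2.0 * s * (1.0 - h)
    dd = 2.0 * s * h + 2.0 * s * (1.0 - 2.0 * h) * x
    d2d = 2.0 * s * (1.0 - 2.0 * h)
    g = dn * den - num * dd          # numerator of f'
    f1 = g / den**2
    f2 = (d2n * den - num * d2d) / den**2 - 2.0 * dd * g / den**3
    if f1.ndim == 0:
        return float(f1), float(f2)
    return f1, f2


def one_step_matrix(params: PopulationParams) -> WFTransitionMatrix:
    """One-generation WF transition matrix.

    Row ``i`` holds Binomial(Ne, f(i/Ne)) probabilities, computed in log
    space so that large ``Ne`` does not underflow; rows 0 and Ne are exact
    point masses (absorbing boundaries, no mutation).
    """
    Ne = int(params.Ne)
    i = np.arange(Ne + 1)
    p = np.clip(np.asarray(fitness(i / Ne, params)), 0.0, 1.0)
    j = i
    logc = (
        special.gammaln(Ne + 1)
        - special.gammaln(j + 1.0)
        - special.gammaln(Ne - j + 1.0)
    )
    interior = (p > 0) & (p < 1)
    probs = np.zeros((Ne + 1, Ne + 1))
    if np.any(interior):
        pi = p[interior][:, None]
        logrow = logc[None, :] + j[None, :] * np.log(pi) + (Ne - j)[None, :] * np.log1p(-pi)
        probs[interior] = np.exp(logrow)
    probs[p == 0.0, 0] = 1.0
    probs[p == 1.0, Ne] = 1.0
    # remove residual rounding so row sums are exactly 1
    probs /= probs.sum(axis=1, keepdims=True)
    return WFTransitionMatrix(Ne=Ne, dt=1, probs=probs)


def transition(params: PopulationParams, dt: int) -> WFTransitionMatrix:
    """WF transition over ``dt`` generations: the one-step matrix to the power dt."""
    if int(dt) != dt or dt < 1:
        raise ValueError(f"dt must be a positive integer, got {dt}")
    one = one_step_matrix(params)
    probs = np.linalg.matrix_power(one.probs, int(dt))
    return WFTransitionMatrix(Ne=one.Ne, dt=int(dt), probs=probs)


def _lattice_index(x0: float, Ne: int) -> int:
    i = x0 * Ne
    irounded = int(round(i))
    if abs(i - irounded) > 1e-9:
        raise ValueError(f"x0={x0} is not on the 1/{Ne} lattice")
    return irounded


def exact_moments(x0: float, params: PopulationParams, t: int):
    """Exact mean, variance and absorption masses after ``t`` generations.

    Computed from the row of the ``t``-generation transition matrix started at
    the lattice point ``x0 = i/Ne``.  Returns ``(mean, variance, p0, p1)``
    where ``p0``/``p1`` are the probabilities of loss/fixation.
    """
    Ne = params.Ne
    idx = _lattice_index(x0, Ne)
    if t == 0:
        return float(x0), 0.0, float(x0 == 0.0), float(x0 == 1.0)
    row = transition(params, t).probs[idx]
    lattice = np.arange(Ne + 1) / Ne
    mean = float(row @ lattice)
    var = float(row @ lattice**2 - mean**2)
    return mean, max(var, 0.0), float(row[0]), float(row[-1])
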