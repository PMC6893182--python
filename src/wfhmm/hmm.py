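"""Forward-algorithm likelihood, profiles over s, MLE and likelihood-ratio test.

The hidden Markov model: the hidden allele frequency ``X_k`` at sampling date
``t_k`` follows one of the transition kernels of :mod:`wfhmm.kernels`; the
observed count ``Y_k`` of alternative alleles among ``n_k`` sampled is
Binomial(n_k, X_k); the initial frequency has a uniform prior on [0,1].  The
forward recursion propagates a mass vector over the frequency grid (atoms at
the endpoints share the vector with the continuous part), rescaling at each
date and accumulating the log normaliser, so the log-likelihood never
underflows.

Selection inference evaluates the log-likelihood on a grid of ``Nes`` values
(600 points on [-100, 300] by default, adjusted so that 0 is a grid point),
takes the maximum-likelihood estimate ``s_hat`` and forms the
likelihood-ratio statistic ``lambda = 2(l(s_hat) - l(0))``, whose null
distribution is asymptotically chi-squared with one degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .kernels import DEFAULT_GRID, FrequencyGrid, kernel_matrix
from .wright_fisher import PopulationParams

__all__ = [
    "TimeSeries", "PriorSpec", "LikelihoodProfile", "default_nes_grid",
    "emission", "forward_loglik", "likelihood_profile", "profile_batch",
    "is_one_step_fixation", "detection_outcome",
]

# floor that keeps s strictly above -1 (the fitness function has a removable
# singularity at s=-1, h=1/2, x=1 that floating point cannot cancel)
S_MIN = -1.0 + 1e-6


@dataclass(frozen=True)
class TimeSeries:
    """One locus's sampling dates (generations), sample sizes and counts."""

    locus_id: str
    dates: np.ndarray
    sizes: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "dates", np.asarray(self.dates, dtype=int))
        object.__setattr__(self, "sizes", np.asarray(self.sizes, dtype=int))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=int))
        if not (len(self.dates) == len(self.sizes) == len(self.counts)):
            raise ValueError(f"{self.locus_id}: dates/sizes/counts lengths differ")
        if len(self.dates) < 1:
            raise ValueError(f"{self.locus_id}: need at least one sampling date")
        if np.any(np.diff(self.dates) <= 0):
            raise ValueError(f"{self.locus_id}: dates must be strictly increasing")
        if np.any(self.sizes < 1):
            raise ValueError(f"{self.locus_id}: sample sizes must be >= 1")
        if np.any((self.counts < 0) | (self.counts > self.sizes)):
            raise ValueError(f"{self.locus_id}: counts must satisfy 0 <= y <= n")

    @property
    def n_dates(self) -> int:
        return len(self.dates)


@dataclass(frozen=True)
class PriorSpec:
    """Initial-frequency prior discretised as masses on the grid."""

    kind: str
    weights: np.ndarray

    @classmethod
    def uniform(cls, points: np.ndarray) -> "PriorSpec":
        # trapezoid weights of the flat density: endpoints get half-weight,
        # no extra atoms at 0/1
        d = np.diff(points)
        w = np.zeros_like(points, dtype=float)
        w[:-1] += d / 2.0
        w[1:] += d / 2.0
        return cls(kind="uniform", weights=w / w.sum())


@dataclass(frozen=True)
class LikelihoodProfile:
    """Log-likelihood over the s grid with the derived test quantities."""

    locus_id: str
    s_values: np.ndarray
    loglik: np.ndarray
    s_hat: float
    loglik0: float
    loglik_mle: float
    lam: float
    pvalue: float


def default_nes_grid(n: int = 600, lo: float = -100.0, hi: float = 300.0) -> np.ndarray:
    """Nes grid: ``n`` evenly spaced values with the nearest one snapped to 0."""
    g = np.linspace(lo, hi, n)
    g[np.argmin(np.abs(g))] = 0.0
    return g


def emission(x, n: int, y: int):
    """Binomial emission probability P(Y=y | X=x) with the 0^0=1 convention."""
    if y < 0 or y > n:
        raise ValueError(f"count y={y} outside [0, n={n}]")
    x = np.asarray(x, dtype=float)
    out = _emission_matrix(np.atleast_1d(x), np.array([n]), np.array([y]))[0]
    return float(out[0]) if x.ndim == 0 else out


def _emission_matrix(xs: np.ndarray, n: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Binomial pmf of per-locus (n, y) over the grid: shape (len(n), len(xs))."""
    xs = np.asarray(xs, dtype=float)[None, :]
    n = np.asarray(n, dtype=float)[:, None]
    y = np.asarray(y, dtype=float)[:, None]
    logc = gammaln(n + 1.0) - gammaln(y + 1.0) - gammaln(n - y + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = logc + y * np.log(xs) + (n - y) * np.log1p(-xs)
    out = np.exp(lp)
    # 0^0 = 1 conventions at the boundaries
    out = np.where((xs == 0.0) & (y == 0.0), 1.0, out)
    out = np.where((xs == 0.0) & (y > 0.0), 0.0, out)
    out = np.where((xs == 1.0) & (y == n), 1.0, out)
    out = np.where((xs == 1.0) & (y < n), 0.0, out)
    return out


def _forward_batch(dts, Elist, model, params, grid_points, prior, grid=None):
    """Vectorised forward pass for loci sharing one date design.

    ``Elist`` holds one (L, G) emission matrix per date; returns (L,) log-liks.
    """
    W = prior[None, :] * Elist[0]
    c = W.sum(axis=1)
    dead = c <= 0.0
    with np.errstate(divide="ignore"):
        ll = np.where(dead, -np.inf, np.log(np.where(dead, 1.0, c)))
    W = W / np.where(dead, 1.0, c)[:, None]
    mats = {}
    for k, dt in enumerate(dts, start=1):
        if dt not in mats:
            mats[dt] = kernel_matrix(model, params, int(dt), grid)
        W = (W @ mats[dt]) * Elist[k]
        c = W.sum(axis=1)
        dead = c <= 0.0
        if np.any(dead):
            ll[dead] = -np.inf
            W[dead] = prior
            c = np.where(dead, 1.0, c)
        ll += np.where(np.isneginf(ll), 0.0, np.log(c))
        W /= c[:, None]
    return ll


def _prepare(model: str, Ne: int, grid: FrequencyGrid | None):
    if model == "WF":
        points = np.arange(Ne + 1) / Ne
        return points, None
    grid = grid or DEFAULT_GRID
    return grid.points, grid


def forward_loglik(ts: TimeSeries, model: str, params: PopulationParams,
                   grid: FrequencyGrid | None = None,
                   prior: PriorSpec | None = None) -> float:
    """Log-likelihood of one locus under a given transition model and s."""
    points, grid = _prepare(model, params.Ne, grid)
    prior_w = (prior.weights if prior is not None
               else PriorSpec.uniform(points).weights)
    Elist = [_emission_matrix(points, ts.sizes[k:k + 1], ts.counts[k:k + 1])
             for k in range(ts.n_dates)]
    dts = np.diff(ts.dates)
    return float(_forward_batch(dts, Elist, model, params, points, prior_w, grid)[0])


def _profiles_for_group(dates, sizes, counts, model, Ne, h, nes_grid, grid,
                        locus_ids):
    """Likelihood profiles for loci sharing one sampling-date design."""
    points, grid = _prepare(model, Ne, grid)
    prior_w = PriorSpec.uniform(points).weights
    K = len(dates)
    Elist = [_emission_matrix(points, sizes[:, k], counts[:, k]) for k in range(K)]
    dts = np.diff(dates)
    L = sizes.shape[0]
    S = len(nes_grid)
    LL = np.empty((L, S))
    for j, nes in enumerate(nes_grid):
        s = max(nes / Ne, S_MIN)
        params = PopulationParams(Ne=Ne, s=s, h=h)
        LL[:, j] = _forward_batch(dts, Elist, model, params, points, prior_w, grid)
    s_values = np.maximum(np.asarray(nes_grid, dtype=float) / Ne, S_MIN)
    iz = int(np.flatnonzero(np.asarray(nes_grid) == 0.0)[0])
    best = LL.max(axis=1)
    tie = np.where(LL >= best[:, None] - 0.0, np.abs(s_values)[None, :], np.inf)
    jstar = tie.argmin(axis=1)
    out = []
    for i in range(L):
        lmle = float(LL[i, jstar[i]])
        l0 = float(LL[i, iz])
        lam = max(2.0 * (lmle - l0), 0.0)
        out.append(LikelihoodProfile(
            locus_id=locus_ids[i], s_values=s_values, loglik=LL[i],
            s_hat=float(s_values[jstar[i]]), loglik0=l0, loglik_mle=lmle,
            lam=lam, pvalue=float(stats.chi2.sf(lam, df=1)),
        ))
    return out


def likelihood_profile(ts: TimeSeries, model: str, Ne: int, h: float = 0.5,
                       nes_grid: np.ndarray | None = None,
                       grid: FrequencyGrid | None = None) -> LikelihoodProfile:
    """Likelihood profile, MLE and LRT p-value for a single locus."""
    return profile_batch([ts], model, Ne, h=h, nes_grid=nes_grid, grid=grid)[0]


def profile_batch(ts_list, model: str, Ne: int, h: float = 0.5,
                  nes_grid: np.ndarray | None = None,
                  grid: FrequencyGrid | None = None) -> list[LikelihoodProfile]:
    """Likelihood profiles for many loci.

    Loci sharing a sampling-date design are processed together so that each
    transition matrix is built once per (s, dt) and reused; this is what makes
    genome scans and large simulation studies tractable.
    """
    if nes_grid is None:
        nes_grid = default_nes_grid()
    nes_grid = np.asarray(nes_grid, dtype=float)
    if not np.any(nes_grid == 0.0):
        raise ValueError("the Nes grid must contain 0 (required by the LRT)")
    groups: dict[tuple, list[int]] = {}
    for i, ts in enumerate(ts_list):
        groups.setdefault(tuple(ts.dates.tolist()), []).append(i)
    results: list[LikelihoodProfile | None] = [None] * len(list(ts_list))
    for dates_key, idxs in groups.items():
        dates = np.asarray(dates_key)
        sizes = np.stack([ts_list[i].sizes for i in idxs])
        counts = np.stack([ts_list[i].counts for i in idxs])
        ids = [ts_list[i].locus_id for i in idxs]
        profs = _profiles_for_group(dates, sizes, counts, model, Ne, h,
                                    nes_grid, grid, ids)
        for i, p in zip(idxs, profs):
            results[i] = p
    return results


def is_one_step_fixation(ts: TimeSeries) -> bool:
    """True when the observed frequency fixes (or is lost) from date 2 onward.

    Such trajectories make the likelihood monotone in s (the MLE escapes to
    an edge of the domain) and are excluded before testing.
    """
    if ts.n_dates < 2:
        return False
    tail_counts = ts.counts[1:]
    tail_sizes = ts.sizes[1:]
    return bool(np.all(tail_counts == 0) or np.all(tail_counts == tail_sizes))


def detection_outcome(profile: LikelihoodProfile, alpha: float = 0.05) -> str:
    """Classify a test result when the true s is known to be non-negative.

    A significant result with a negative ``s_hat`` points at the wrong allele
    and is counted as ``wrong_sign``, not as a detection.
    """
    if profile.pvalue <= alpha:
        if profile.s_hat > 0:
            return "detected"
        if profile.s_hat < 0:
            return "wrong_sign"
    return "not_detected"
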