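"""Wright-Fisher trajectory simulator and binomial sampling scheme.

Generates the evaluation datasets used throughout: frequency trajectories
under the exact WF process (binomial resampling of ``Ne`` haploids each
generation, absorbing at 0 and 1), partial observations (``n_k`` alleles
sampled binomially at each date), and complete simulation studies that apply
the one-step-fixation filter and run the likelihood-ratio test per replicate.

The default scenario mirrors the standard design of time-series selection
experiments: 30 alleles sampled at 10 evenly spaced dates over a total span
``T``, with starting frequency 0.1 or 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hmm import TimeSeries, detection_outcome, is_one_step_fixation, profile_batch
from .kernels import FrequencyGrid
from .wright_fisher import PopulationParams, fitness


@dataclass(frozen=True)
class Scenario:
    """A simulation design: population parameters plus the sampling scheme."""

    Ne: int
    s: float = 0.0
    h: float = 0.5
    x0: float = 0.5
    T: int = 45
    n_dates: int = 10
    n_per_date: int = 30
    reps: int = 100
    seed: int = 0

    @property
    def dates(self) -> np.ndarray:
        """n_dates evenly spaced integer dates from 0 to T."""
        d = np.round(np.linspace(0, self.T, self.n_dates)).astype(int)
        if len(np.unique(d)) != len(d):
            raise ValueError("T too small for n_dates distinct integer dates")
        return d

    @property
    def params(self) -> PopulationParams:
        return PopulationParams(Ne=self.Ne, s=self.s, h=self.h)


def _snap_to_lattice(x0: float, Ne: int) -> int:
    return int(round(x0 * Ne))


def simulate_trajectories(scenario: Scenario, rng: np.random.Generator) -> np.ndarray:
    """Simulate ``reps`` WF frequency paths; shape (reps, T+1)."""
    Ne = scenario.Ne
    params = scenario.params
    counts = np.full(scenario.reps, _snap_to_lattice(scenario.x0, Ne), dtype=np.int64)
    out = np.empty((scenario.reps, scenario.T + 1))
    out[:, 0] = counts / Ne
    for t in range(scenario.T):
        p = np.clip(fitness(counts / Ne, params), 0.0, 1.0)
        counts = rng.binomial(Ne, p)
        out[:, t + 1] = counts / Ne
    return out


def simulate_trajectory(scenario: Scenario, seed: int | None = None) -> np.ndarray:
    """One WF frequency path of length T+1 (X(0) = x0 snapped to the lattice)."""
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    one = Scenario(**{**scenario.__dict__, "reps": 1})
    return simulate_trajectories(one, rng)[0]


def sample_observations(path: np.ndarray, dates, sizes,
                        seed_or_rng) -> TimeSeries:
    """Binomially sample allele counts from a frequency path at given dates."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    dates = np.asarray(dates, dtype=int)
    sizes = np.asarray(sizes, dtype=int)
    if np.any(dates >= len(path)) or np.any(dates < 0):
        raise ValueError("sampling dates outside the simulated path")
    y = rng.binomial(sizes, path[dates])
    return TimeSeries(locus_id="sim", dates=dates, sizes=sizes, counts=y)


def simulate_dataset(scenario: Scenario, rng: np.random.Generator):
    """Trajectories plus their sampled observations, as batch arrays.

    Returns ``(paths, counts)`` with counts of shape (reps, n_dates).
    """
    paths = simulate_trajectories(scenario, rng)
    dates = scenario.dates
    sizes = np.full(len(dates), scenario.n_per_date, dtype=int)
    counts = rng.binomial(sizes[None, :], paths[:, dates])
    return paths, counts


def run_study(scenario: Scenario, model: str = "BwS", alpha: float = 0.05,
              nes_grid: np.ndarray | None = None,
              grid: FrequencyGrid | None = None,
              Ne_inference: int | None = None) -> pd.DataFrame:
    """Simulate a scenario and run the LRT on every replicate.

    One-step-fixation replicates are excluded from testing but kept in the
    table with their exclusion flag, so exclusion fractions can be reported.
    ``Ne_inference`` lets the analysis assume a different Ne than the
    simulator used (defaults to the true one).  Fully reproducible from
    ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed)
    _, counts = simulate_dataset(scenario, rng)
    dates = scenario.dates
    sizes = np.full(len(dates), scenario.n_per_date, dtype=int)
    ts_list = [TimeSeries(locus_id=f"rep{i}", dates=dates, sizes=sizes,
                          counts=counts[i]) for i in range(scenario.reps)]
    keep = [not is_one_step_fixation(ts) for ts in ts_list]
    kept = [ts for ts, k in zip(ts_list, keep) if k]
    profiles = profile_batch(kept, model, Ne_inference or scenario.Ne,
                             h=scenario.h, nes_grid=nes_grid, grid=grid)
    prof_iter = iter(profiles)
    rows = []
    for i, (ts, k) in enumerate(zip(ts_list, keep)):
        if not k:
            rows.append(dict(rep=i, excluded=True, s_hat=np.nan, loglik0=np.nan,
                             loglik_mle=np.nan, **{"lambda": np.nan},
                             pvalue=np.nan, outcome="excluded"))
            continue
        p = next(prof_iter)
        rows.append(dict(rep=i, excluded=False, s_hat=p.s_hat, loglik0=p.loglik0,
                         loglik_mle=p.loglik_mle, **{"lambda": p.lam},
                         pvalue=p.pvalue, outcome=detection_outcome(p, alpha)))
    df = pd.DataFrame(rows)
    df.attrs["scenario"] = scenario
    df.attrs["model"] = model
    return df
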