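"""HMM transition kernels on a frequency grid.

Five interchangeable models for the distribution of the hidden allele
frequency after ``dt`` generations, started from frequency ``x``:

``WF``
    exact Wright-Fisher matrix power (discrete row over the 1/Ne lattice);
``Ga``
    Normal(m, z2) restricted to [0,1] and rescaled (truncated Gaussian);
``NG``
    Nicholson Gaussian: Normal density on (0,1), with the out-of-range mass
    moved to atoms at 0 and 1;
``Be``
    Beta(a, b) matched to the absolute moments;
``BwS``
    Beta with spikes: atoms ``p0``/``p1`` at 0 and 1 from the absorption
    recursion plus a conditional Beta(a*, b*) carrying the rest of the mass.

The moments (m, z2) come from the Taylor recursion in :mod:`wfhmm.moments`
(or may be supplied externally, e.g. exact WF moments).

Quadrature convention: the forward algorithm works with probability *masses*
at the grid points.  The continuous part of a kernel is assigned per grid
cell by exact CDF differences at the half-interval edges (the cell of an
endpoint receives its half-cell mass plus any atom), which conserves total
mass exactly and stays finite even when the Beta density diverges at a
boundary.  On a uniform grid this agrees with the trapezoidal rule to the
same order in the grid spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.special import betainc, ndtr

from .moments import (
    MEAN_EPS,
    VAR_CAP,
    VAR_FLOOR,
    propagate_moments,
    propagate_spikes,
)
from .wright_fisher import PopulationParams, transition

MODELS = ("WF", "Ga", "NG", "Be", "BwS")

#: variance below which a continuous kernel collapses to a point mass
POINT_MASS_VAR = 1e-12


class FrequencyGrid:
    """Strictly increasing frequency grid on [0,1] with trapezoid weights.

    ``weights`` are the trapezoidal quadrature weights (they sum to 1);
    ``edges`` are the half-interval cell boundaries used to convert a
    continuous density into per-point masses.
    """

    def __init__(self, points) -> None:
        points = np.asarray(points, dtype=float)
        if points.ndim != 1 or points.size < 3:
            raise ValueError("grid needs at least 3 points")
        if np.any(np.diff(points) <= 0):
            raise ValueError("grid points must be strictly increasing")
        if points[0] != 0.0 or points[-1] != 1.0:
            raise ValueError("grid must span [0,1] inclusive")
        self.points = points
        d = np.diff(points)
        w = np.zeros_like(points)
        w[:-1] += d / 2.0
        w[1:] += d / 2.0
        self.weights = w
        self.edges = np.concatenate(([0.0], (points[:-1] + points[1:]) / 2.0, [1.0]))

    @classmethod
    def uniform(cls, n: int = 129) -> "FrequencyGrid":
        """The default integration grid: ``n`` evenly spaced points on [0,1]."""
        return cls(np.linspace(0.0, 1.0, n))

    def __len__(self) -> int:
        return self.points.size


DEFAULT_GRID = FrequencyGrid.uniform(129)


@dataclass
class TransitionKernel:
    """One transition distribution: atoms at 0/1 plus a continuous part.

    ``family`` is ``("beta", a, b)`` or ``("normal", m, sd)`` (the normal is
    implicitly restricted to [0,1]; ``cont_weight`` is the mass it carries).
    ``atom`` holds an optional interior/degenerate point mass.  For the WF
    model ``discrete`` holds the exact lattice row and the other fields are
    unused.
    """

    model: str
    source: float
    dt: int
    grid: FrequencyGrid
    spike0: float = 0.0
    spike1: float = 0.0
    cont_weight: float = 0.0
    family: tuple | None = None
    atom: tuple | None = None
    discrete: np.ndarray | None = None
    lattice: np.ndarray | None = None

    @classmethod
    def point(cls, loc: float, grid: FrequencyGrid | None = None,
              model: str = "point") -> "TransitionKernel":
        return cls(model=model, source=loc, dt=0, grid=grid or DEFAULT_GRID,
                   atom=(float(loc), 1.0))

    @cached_property
    def masses(self) -> np.ndarray:
        """Probability masses at the grid points (lattice row for WF)."""
        if self.discrete is not None:
            return self.discrete
        g = self.grid
        out = np.zeros(len(g))
        if self.cont_weight > 0.0:
            F = _cont_cdf(self.family, g.edges)
            out += self.cont_weight * np.diff(F)
        out[0] += self.spike0
        out[-1] += self.spike1
        if self.atom is not None:
            loc, mass = self.atom
            out[int(np.argmin(np.abs(g.points - loc)))] += mass
        return out

    @property
    def density(self) -> np.ndarray:
        """Continuous-part density estimate at the grid points (masses/weights)."""
        d = self.masses.astype(float).copy()
        d[0] -= self.spike0
        d[-1] -= self.spike1
        return d / self.grid.weights

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())


def _cont_cdf(family: tuple, q) -> np.ndarray:
    """CDF of the (normalised) continuous part, evaluated at q in [0,1]."""
    kind = family[0]
    q = np.clip(np.asarray(q, dtype=float), 0.0, 1.0)
    if kind == "beta":
        _, a, b = family
        return betainc(a, b, q)
    if kind == "normal":
        _, m, sd = family
        lo = ndtr((0.0 - m) / sd)
        hi = ndtr((1.0 - m) / sd)
        return (ndtr((q - m) / sd) - lo) / (hi - lo)
    raise ValueError(f"unknown family {family!r}")


def _components(model: str, xs, params: PopulationParams, dt: int,
                moments: tuple | None = None):
    """Per-source kernel components, vectorised over starting frequencies.

    Returns arrays ``(spike0, spike1, cont_weight, par1, par2, point)`` where
    ``(par1, par2)`` are (a, b) for Beta-family models and (m, sd) for the
    Gaussian ones, and ``point`` is a point-mass location (NaN when absent).
    ``moments`` optionally supplies externally computed ``(m, v, p0, p1)``
    arrays (e.g. exact WF moments) in place of the Taylor recursion.
    """
    xs = np.atleast_1d(np.asarray(xs, dtype=float))
    n = xs.size
    if moments is not None:
        m, v, p0, p1 = (np.broadcast_to(np.asarray(a, dtype=float), (n,)).copy()
                        for a in moments)
    elif model == "BwS":
        st = propagate_spikes(xs, np.zeros(n), params, dt)
        m, v, p0, p1 = (np.atleast_1d(a) for a in (st.mu, st.var, st.p0, st.p1))
    else:
        st = propagate_moments(xs, np.zeros(n), params, dt)
        m, v = st.mu, st.var
        p0 = np.zeros(n)
        p1 = np.zeros(n)

    spike0 = np.zeros(n)
    spike1 = np.zeros(n)
    cw = np.zeros(n)
    par1 = np.full(n, np.nan)
    par2 = np.full(n, np.nan)
    point = np.full(n, np.nan)

    if model == "BwS":
        alive = 1.0 - p0 - p1
        spike0, spike1 = p0.copy(), p1.copy()
        seg = alive > 1e-12
        # conditional moments of the segregating part
        ms = np.clip((m[seg] - p1[seg]) / alive[seg], MEAN_EPS, 1.0 - MEAN_EPS)
        z2 = (v[seg] + m[seg] ** 2 - p1[seg]) / alive[seg] - ms**2
        z2 = np.clip(z2, VAR_FLOOR, VAR_CAP * ms * (1.0 - ms))
        r = ms * (1.0 - ms) / z2 - 1.0
        par1[seg] = ms * r
        par2[seg] = (1.0 - ms) * r
        cw[seg] = alive[seg]
        dead = ~seg
        if np.any(dead):  # fully absorbed: renormalise the two spikes
            tot = spike0[dead] + spike1[dead]
            spike0[dead] /= tot
            spike1[dead] /= tot
    elif model in ("Ga", "NG"):
        ok = v > POINT_MASS_VAR
        sd = np.sqrt(np.maximum(v, POINT_MASS_VAR))
        if model == "Ga":
            cw[ok] = 1.0
        else:
            lo = ndtr((0.0 - m[ok]) / sd[ok])
            hi = ndtr((1.0 - m[ok]) / sd[ok])
            spike0[ok] = lo
            spike1[ok] = 1.0 - hi
            cw[ok] = hi - lo
        par1[ok] = m[ok]
        par2[ok] = sd[ok]
        point[~ok] = np.clip(m[~ok], 0.0, 1.0)
    elif model == "Be":
        ok = v > POINT_MASS_VAR
        mc = np.clip(m[ok], MEAN_EPS, 1.0 - MEAN_EPS)
        z2 = np.clip(v[ok], VAR_FLOOR / 1e4, VAR_CAP * mc * (1.0 - mc))
        r = mc * (1.0 - mc) / z2 - 1.0
        par1[ok] = mc * r
        par2[ok] = (1.0 - mc) * r
        cw[ok] = 1.0
        point[~ok] = np.clip(m[~ok], 0.0, 1.0)
    else:
        raise ValueError(f"unknown parametric model {model!r}")
    return spike0, spike1, cw, par1, par2, point


def build_kernel(model: str, x: float, params: PopulationParams, dt: int,
                 grid: FrequencyGrid | None = None,
                 moments: tuple | None = None) -> TransitionKernel:
    """Transition kernel from a single starting frequency ``x``."""
    return build_kernels(model, [x], params, dt, grid=grid, moments=moments)[0]


def build_kernels(model: str, xs, params: PopulationParams, dt: int,
                  grid: FrequencyGrid | None = None,
                  moments: tuple | None = None) -> list[TransitionKernel]:
    """Transition kernels from several starting frequencies (vectorised)."""
    grid = grid or DEFAULT_GRID
    if dt < 1:
        raise ValueError("dt must be >= 1")
    xs = np.atleast_1d(np.asarray(xs, dtype=float))
    if np.any((xs < 0) | (xs > 1)):
        raise ValueError("starting frequencies must lie in [0,1]")
    if model == "WF":
        tm = transition(params, dt)
        lattice = tm.lattice
        out = []
        for x in xs:
            i = int(round(x * params.Ne))
            out.append(TransitionKernel(model="WF", source=float(x), dt=int(dt),
                                        grid=grid, discrete=tm.probs[i],
                                        lattice=lattice))
        return out
    sp0, sp1, cw, p1a, p2a, point = _components(model, xs, params, dt, moments)
    fam = "beta" if model in ("Be", "BwS") else "normal"
    out = []
    for k, x in enumerate(xs):
        if not np.isnan(point[k]):
            w = 1.0 - sp0[k] - sp1[k]
            s0, s1, at = float(sp0[k]), float(sp1[k]), (float(point[k]), float(w))
            if at[0] == 0.0:  # boundary point masses are reported as spikes
                s0, at = s0 + w, None
            elif at[0] == 1.0:
                s1, at = s1 + w, None
            out.append(TransitionKernel(model=model, source=float(x), dt=int(dt),
                                        grid=grid, spike0=s0, spike1=s1,
                                        atom=at))
        else:
            out.append(TransitionKernel(model=model, source=float(x), dt=int(dt),
                                        grid=grid, spike0=float(sp0[k]),
                                        spike1=float(sp1[k]),
                                        cont_weight=float(cw[k]),
                                        family=(fam, float(p1a[k]), float(p2a[k]))))
    return out


def kernel_matrix(model: str, params: PopulationParams, dt: int,
                  grid: FrequencyGrid | None = None,
                  moments: tuple | None = None) -> np.ndarray:
    """Row-stochastic mass matrix over the grid, one row per source point.

    For ``WF`` this is the exact lattice matrix (the caller's grid must be
    the lattice); for the parametric models row ``i`` holds the cell masses
    of the kernel started at ``grid.points[i]``.  Built once per
    ``(model, params, dt)`` and reused across loci by the forward algorithm.
    """
    if model == "WF":
        return transition(params, dt).probs
    grid = grid or DEFAULT_GRID
    xs = grid.points
    sp0, sp1, cw, p1a, p2a, point = _components(model, xs, params, dt, moments)
    G = len(grid)
    M = np.zeros((G, G))
    cont = np.isnan(point) & (cw > 0.0)
    if np.any(cont):
        if model in ("Be", "BwS"):
            F = betainc(p1a[cont][:, None], p2a[cont][:, None],
                        grid.edges[None, :])
        else:
            m = p1a[cont][:, None]
            sd = p2a[cont][:, None]
            lo = ndtr((0.0 - m) / sd)
            hi = ndtr((1.0 - m) / sd)
            F = (ndtr((grid.edges[None, :] - m) / sd) - lo) / (hi - lo)
        M[cont] = cw[cont][:, None] * np.diff(F, axis=1)
    M[:, 0] += sp0
    M[:, -1] += sp1
    pm = ~np.isnan(point)
    if np.any(pm):
        idx = np.abs(point[pm][:, None] - grid.points[None, :]).argmin(axis=1)
        rows = np.flatnonzero(pm)
        M[rows, idx] += 1.0 - sp0[pm] - sp1[pm]
    # kill tiny negative rounding and renormalise exactly
    np.clip(M, 0.0, None, out=M)
    M /= M.sum(axis=1, keepdims=True)
    return M


def kernel_cdf(kernel: TransitionKernel, q):
    """Right-continuous CDF of a kernel, vectorised over ``q``."""
    q = np.asarray(q, dtype=float)
    if kernel.discrete is not None:
        cum = np.concatenate(([0.0], np.cumsum(kernel.discrete)))
        idx = np.searchsorted(kernel.lattice, q, side="right")
        out = cum[idx]
    else:
        out = np.where(q >= 0.0, kernel.spike0, 0.0)
        if kernel.cont_weight > 0.0:
            out = out + kernel.cont_weight * np.where(
                q >= 0.0, _cont_cdf(kernel.family, q), 0.0)
        if kernel.atom is not None:
            loc, mass = kernel.atom
            out = out + np.where(q >= loc, mass, 0.0)
        out = out + np.where(q >= 1.0, kernel.spike1, 0.0)
    return out if out.ndim else float(out)


def kernel_atoms(kernel: TransitionKernel):
    """Locations and masses of all atoms of a kernel."""
    if kernel.discrete is not None:
        return kernel.lattice, kernel.discrete
    locs = [0.0, 1.0]
    masses = [kernel.spike0, kernel.spike1]
    if kernel.atom is not None:
        locs.append(kernel.atom[0])
        masses.append(kernel.atom[1])
    locs = np.asarray(locs)
    masses = np.asarray(masses)
    uniq, inv = np.unique(locs, return_inverse=True)
    agg = np.zeros_like(uniq)
    np.add.at(agg, inv, masses)
    return uniq, agg
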