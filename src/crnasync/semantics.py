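"""The three simulation semantics for a CRS.

* deterministic: concentrations follow the mass-action rate equations
  dPhi/dt = sum_tau v_tau * k_tau * prod_i Phi_i^{r_i,tau};
* stochastic: molecule counts follow the continuous-time Markov chain with
  propensities alpha_tau(x) = k_tau (prod_i r_i!) / N^{|r|-1} prod_i C(x_i, r_i)
  and transition rates N * alpha_tau, sampled exactly with the Gillespie
  direct method;
* linear noise approximation (LNA): counts are Y = N*Phi + sqrt(N)*Z with Z
  a zero-mean Gaussian process whose covariance obeys
  dC/dt = J C + C J^T + W, C(0) = 0, where J is the Jacobian of the drift
  and W = sum_tau v v^T k prod Phi^r is the diffusion matrix.

Injection schedules are piecewise network redefinitions: each engine runs
to the event time, extends the reaction set, and continues from the state
it reached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .core import CRS, CRNError, InjectionEvent, Reaction

__all__ = [
    "drift",
    "jacobian",
    "diffusion",
    "propensity",
    "simulate_ode",
    "simulate_ssa",
    "simulate_lna",
    "mean_over_paths",
    "DeterministicTrajectory",
    "StochasticPath",
    "GaussianTrajectory",
]

_RTOL = 1e-8
_ATOL = 1e-10


# ---------------------------------------------------------------------------
# compiled reaction view
# ---------------------------------------------------------------------------


class _Compiled:
    """Index arrays for fast vectorized rate evaluation."""

    def __init__(self, crs: CRS, reactions: Sequence[Reaction] | None = None):
        self.crs = crs
        rxns = list(reactions if reactions is not None else crs.reactions)
        self.reactions = rxns
        n = len(crs.species)
        m = len(rxns)
        self.V = np.zeros((m, n))
        self.k = np.zeros(m)
        # reactant structure: order 1 -> (a, -1); order 2 distinct -> (a, b);
        # order 2 paired -> (a, a) flagged
        self.a = np.zeros(m, dtype=int)
        self.b = np.zeros(m, dtype=int)
        self.kind = np.zeros(m, dtype=int)  # 0 uni, 1 bi-distinct, 2 bi-paired
        for j, rxn in enumerate(rxns):
            self.k[j] = rxn.rate
            for name, d in rxn.net().items():
                self.V[j, crs.index(name)] = d
            r = [(crs.index(nm), c) for nm, c in rxn.reactants]
            if rxn.order == 1:
                self.a[j] = r[0][0]
                self.b[j] = -1
                self.kind[j] = 0
            elif len(r) == 1:  # A + A
                self.a[j] = self.b[j] = r[0][0]
                self.kind[j] = 2
            else:
                self.a[j], self.b[j] = r[0][0], r[1][0]
                self.kind[j] = 1

    def conc_rates(self, phi: np.ndarray) -> np.ndarray:
        """Mass-action concentration-scale reaction rates k * prod phi^r."""
        rates = self.k.copy()
        rates *= phi[self.a]
        bi = self.kind > 0
        rates[bi] *= phi[self.b[bi]]
        return rates

    def drift(self, phi: np.ndarray) -> np.ndarray:
        return self.conc_rates(phi) @ self.V

    def jacobian(self, phi: np.ndarray) -> np.ndarray:
        n = self.V.shape[1]
        J = np.zeros((n, n))
        for j in range(len(self.k)):
            kj, a, b = self.k[j], self.a[j], self.b[j]
            v = self.V[j]
            if self.kind[j] == 0:
                J[:, a] += v * kj
            elif self.kind[j] == 2:
                J[:, a] += v * (2.0 * kj * phi[a])
            else:
                J[:, a] += v * (kj * phi[b])
                J[:, b] += v * (kj * phi[a])
        return J

    def diffusion(self, phi: np.ndarray) -> np.ndarray:
        rates = self.conc_rates(phi)
        return (self.V.T * rates) @ self.V

    def jump_rates(self, x: np.ndarray, N: float) -> np.ndarray:
        """CTMC transition rates N * alpha_tau(x) for integer state x."""
        rates = self.k.copy()
        uni = self.kind == 0
        dis = self.kind == 1
        par = self.kind == 2
        xa = x[self.a]
        # N*alpha: the 1/N of the bi-molecular propensity cancels against N
        rates[uni] *= N * xa[uni]
        rates[dis] *= xa[dis] * x[self.b[dis]]
        rates[par] *= xa[par] * (xa[par] - 1)
        np.maximum(rates, 0.0, out=rates)
        return rates


def drift(crs: CRS, phi: np.ndarray) -> np.ndarray:
    """Deterministic drift F(phi) of the rate equations."""
    phi = np.asarray(phi, dtype=float)
    if phi.shape != (len(crs.species),):
        raise CRNError("phi has wrong dimension")
    return _Compiled(crs).drift(phi)


def jacobian(crs: CRS, phi: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the drift at phi."""
    phi = np.asarray(phi, dtype=float)
    if phi.shape != (len(crs.species),):
        raise CRNError("phi has wrong dimension")
    return _Compiled(crs).jacobian(phi)


def diffusion(crs: CRS, phi: np.ndarray) -> np.ndarray:
    """LNA diffusion matrix W(phi) = sum_tau v v^T k prod phi^r (symmetric PSD)."""
    phi = np.asarray(phi, dtype=float)
    if phi.shape != (len(crs.species),):
        raise CRNError("phi has wrong dimension")
    return _Compiled(crs).diffusion(phi)


def propensity(rxn: Reaction, x, N: float = 1.0) -> float:
    """Stochastic propensity alpha_tau(x) under mass-action kinetics.

    ``x`` maps species names to integer counts (missing names count 0).
    Insufficient reactants give 0.  The CTMC transition rate is
    ``N * propensity(...)``.
    """
    coeff = rxn.rate
    for _, c in rxn.reactants:
        coeff *= math.factorial(c)
    coeff /= N ** (rxn.order - 1)
    for name, c in rxn.reactants:
        coeff *= math.comb(int(x.get(name, 0)), c)
    return float(coeff)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


@dataclass
class DeterministicTrajectory:
    """Solution of the rate equations on a time grid (count scale, x = N*Phi)."""

    times: np.ndarray
    values: np.ndarray  # shape (n_species, n_times)
    species: list[str]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[self.species.index(name)]

    def at(self, t: float) -> dict[str, float]:
        return {s: float(np.interp(t, self.times, self[s])) for s in self.species}

    def value(self, name: str, t: float) -> float:
        return float(np.interp(t, self.times, self[name]))

    def sd(self, name: str, t: float) -> float:  # deterministic semantics: SD = 0
        return 0.0


@dataclass
class StochasticPath:
    """Exact jump path of the CTMC: states are integer configurations."""

    jump_times: np.ndarray  # includes t=0
    states: np.ndarray  # shape (n_jumps+1, n_species)
    species: list[str]
    seed: object
    horizon: float

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self.species.index(name)]

    def value(self, name: str, t: float) -> float:
        i = int(np.searchsorted(self.jump_times, t, side="right")) - 1
        return float(self.states[max(i, 0), self.species.index(name)])

    def sd(self, name: str, t: float) -> float:
        return 0.0

    def on_grid(self, grid: np.ndarray) -> np.ndarray:
        """Piecewise-constant sample on a grid, shape (n_species, len(grid))."""
        idx = np.clip(np.searchsorted(self.jump_times, grid, side="right") - 1, 0, None)
        return self.states[idx].T.astype(float)

    @property
    def n_jumps(self) -> int:
        return len(self.jump_times) - 1


@dataclass
class GaussianTrajectory:
    """LNA solution: mean E[Y(t)] = N*Phi(t) and covariance C[Y(t)] = N*C[Z(t)]."""

    times: np.ndarray
    mean: np.ndarray  # (n_species, n_times)
    cov: np.ndarray  # (n_times, n_species, n_species)
    species: list[str]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.mean[self.species.index(name)]

    def value(self, name: str, t: float) -> float:
        return float(np.interp(t, self.times, self[name]))

    def sd_series(self, name: str) -> np.ndarray:
        i = self.species.index(name)
        var = self.cov[:, i, i]
        if np.any(var < -1e-9):
            raise CRNError(f"negative variance for {name}: {var.min()}")
        return np.sqrt(np.clip(var, 0.0, None))

    def sd(self, name: str, t: float) -> float:
        return float(np.interp(t, self.times, self.sd_series(name)))


# ---------------------------------------------------------------------------
# engines
# ---------------------------------------------------------------------------


def _segments(horizon: float, schedule: Sequence[InjectionEvent] | None):
    """Yield (t_start, t_end, events_to_add_at_start) covering [0, horizon]."""
    events = sorted(schedule or [], key=lambda e: e.time)
    times = [e.time for e in events if 0.0 < e.time < horizon]
    bounds = [0.0, *dict.fromkeys(times), horizon]
    segs = []
    for i in range(len(bounds) - 1):
        at_start = [e for e in events if (e.time == bounds[i] and i > 0) or (i == 0 and e.time <= 0.0)]
        segs.append((bounds[i], bounds[i + 1], at_start))
    return segs


def simulate_ode(
    crs: CRS,
    horizon: float,
    grid: np.ndarray | None = None,
    schedule: Sequence[InjectionEvent] | None = None,
    rtol: float = _RTOL,
    atol: float = _ATOL,
) -> DeterministicTrajectory:
    """Integrate the deterministic rate equations to ``horizon`` seconds.

    Returns counts (``N * Phi``).  Injections extend the reaction set at
    their event times (piecewise integration).  Uses an adaptive explicit
    Runge-Kutta scheme; these networks are non-stiff at this scale.
    """
    if horizon <= 0:
        raise CRNError("horizon must be positive")
    if grid is None:
        grid = np.linspace(0.0, horizon, 501)
    grid = np.asarray(grid, dtype=float)
    reactions = list(crs.reactions)
    phi = crs.z0.copy()
    out = np.empty((len(crs.species), len(grid)))
    for t0, t1, events in _segments(horizon, schedule):
        for e in events:
            reactions.extend(e.added_reactions)
        comp = _Compiled(crs, reactions)
        mask = (grid >= t0) & (grid <= t1)
        t_eval = np.unique(np.concatenate([grid[mask], [t0, t1]]))
        sol = solve_ivp(
            lambda t, y: comp.drift(np.maximum(y, 0.0)),
            (t0, t1),
            phi,
            method="RK45",
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:  # pragma: no cover
            raise CRNError(f"ODE solver failed on [{t0}, {t1}]: {sol.message}")
        for tt, yy in zip(sol.t, sol.y.T):
            hits = np.nonzero(mask & np.isclose(grid, tt))[0]
            out[:, hits] = yy[:, None]
        phi = sol.y[:, -1]
    return DeterministicTrajectory(grid, out * crs.N, crs.names)


def _as_seed(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    return np.random.Generator(np.random.PCG64(seed))


def simulate_ssa(
    crs: CRS,
    horizon: float,
    seed,
    schedule: Sequence[InjectionEvent] | None = None,
    max_jumps: int = 2_000_000,
) -> StochasticPath:
    """Exact CTMC sample path via the Gillespie direct method.

    Reactions are scanned in declaration order with cumulative-sum
    inversion; two independent uniforms drive each jump.  Fixed seeds give
    bitwise-reproducible paths.  Absorbing states hold to the next event
    or to the horizon.
    """
    if horizon <= 0:
        raise CRNError("horizon must be positive")
    rng = _as_seed(seed)
    x = np.round(crs.x0).astype(np.int64)
    t = 0.0
    times = [0.0]
    states = [x.copy()]
    reactions = list(crs.reactions)
    n_jumps = 0
    for t0, t1, events in _segments(horizon, schedule):
        if events:
            reactions = list(reactions) + [r for e in events for r in e.added_reactions]
        comp = _Compiled(crs, reactions)
        Vint = comp.V.astype(np.int64)
        t = t0
        while True:
            rates = comp.jump_rates(x, crs.N)
            total = rates.sum()
            if total <= 0.0:
                break  # absorbing: hold state to segment end
            u1, u2 = rng.random(2)
            t_next = t - math.log(u1) / total
            if t_next > t1:
                break
            t = t_next
            j = int(np.searchsorted(np.cumsum(rates), u2 * total, side="right"))
            j = min(j, len(rates) - 1)
            x = x + Vint[j]
            times.append(t)
            states.append(x.copy())
            n_jumps += 1
            if n_jumps >= max_jumps:  # pragma: no cover
                raise CRNError("SSA exceeded max_jumps")
    return StochasticPath(np.array(times), np.array(states), crs.names, seed, horizon)


def simulate_lna(
    crs: CRS,
    horizon: float,
    grid: np.ndarray | None = None,
    schedule: Sequence[InjectionEvent] | None = None,
    rtol: float = _RTOL,
    atol: float = _ATOL,
) -> GaussianTrajectory:
    """Linear noise approximation: jointly integrates mean and covariance.

    The covariance is symmetrized each evaluation; a diagonal entry below
    -1e-9 raises, smaller negatives clamp to zero when standard deviations
    are read out.
    """
    if horizon <= 0:
        raise CRNError("horizon must be positive")
    if grid is None:
        grid = np.linspace(0.0, horizon, 501)
    grid = np.asarray(grid, dtype=float)
    n = len(crs.species)
    reactions = list(crs.reactions)
    y = np.concatenate([crs.z0, np.zeros(n * n)])
    mean = np.empty((n, len(grid)))
    cov = np.empty((len(grid), n, n))

    for t0, t1, events in _segments(horizon, schedule):
        for e in events:
            reactions.extend(e.added_reactions)
        comp = _Compiled(crs, reactions)

        def rhs(t, state):
            phi = np.maximum(state[:n], 0.0)
            C = state[n:].reshape(n, n)
            C = 0.5 * (C + C.T)
            J = comp.jacobian(phi)
            dC = J @ C + C @ J.T + comp.diffusion(phi)
            return np.concatenate([comp.drift(phi), dC.ravel()])

        mask = (grid >= t0) & (grid <= t1)
        t_eval = np.unique(np.concatenate([grid[mask], [t0, t1]]))
        sol = solve_ivp(rhs, (t0, t1), y, method="RK45", t_eval=t_eval, rtol=rtol, atol=atol)
        if not sol.success:  # pragma: no cover
            raise CRNError(f"LNA solver failed on [{t0}, {t1}]: {sol.message}")
        for tt, yy in zip(sol.t, sol.y.T):
            hits = np.nonzero(mask & np.isclose(grid, tt))[0]
            if len(hits):
                C = yy[n:].reshape(n, n)
                mean[:, hits] = (crs.N * yy[:n])[:, None]
                cov[hits] = crs.N * 0.5 * (C + C.T)
        y = sol.y[:, -1]
    return GaussianTrajectory(grid, mean, cov, crs.names)


def path_seed(master_seed: int, i: int) -> np.random.SeedSequence:
    """Per-path seed: ``SeedSequence(master).spawn``-style counter scheme.

    Path ``i`` of a family uses ``SeedSequence(entropy=master, spawn_key=(i,))``,
    so a master seed reproduces the whole family and paths are independent.
    """
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(i,))


def mean_over_paths(
    crs: CRS,
    horizon: float,
    grid: np.ndarray | None = None,
    n_paths: int = 20,
    seed: int = 0,
    schedule: Sequence[InjectionEvent] | None = None,
):
    """Pointwise empirical mean +/- standard error over ``n_paths`` SSA paths.

    Returns ``(grid, mean, se)`` with mean/se of shape (n_species, len(grid)).
    """
    if n_paths < 1:
        raise CRNError("n_paths must be >= 1")
    if grid is None:
        grid = np.linspace(0.0, horizon, 201)
    grid = np.asarray(grid, dtype=float)
    samples = np.empty((n_paths, len(crs.species), len(grid)))
    for i in range(n_paths):
        path = simulate_ssa(crs, horizon, path_seed(seed, i), schedule=schedule)
        samples[i] = path.on_grid(grid)
    mean = samples.mean(axis=0)
    if n_paths > 1:
        se = samples.std(axis=0, ddof=1) / math.sqrt(n_paths)
    else:
        se = np.zeros_like(mean)
    return grid, mean, se
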