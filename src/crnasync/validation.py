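"""Dual-rail threshold logic, truth-table sweeps and temporal properties.

A high rail is *correct* when its mean exceeds ``0.8 * max - 1 SD`` and a
low rail when its mean is below ``0.2 * max + 1 SD``, where ``max`` is the
rail's maximum achievable population (its conserved pool total) and the
standard deviation is zero under the deterministic semantics.  Temporal
properties are threshold atoms combined with time-bounded until /
eventually / globally, estimated as the fraction of sampled SSA paths that
satisfy the formula.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import CRS, CRNError, DualRailCircuit, conserved_totals, rail_group_total
from .semantics import (
    DeterministicTrajectory,
    GaussianTrajectory,
    StochasticPath,
    path_seed,
    simulate_lna,
    simulate_ode,
    simulate_ssa,
)

__all__ = [
    "ThresholdPolicy",
    "is_high",
    "is_low",
    "signal_value",
    "first_passage",
    "first_passage_time",
    "sweep_truth_table",
    "TruthTableReport",
    "Atom",
    "TemporalProperty",
    "parse_property",
    "estimate_property",
    "PropertyEstimate",
]


@dataclass(frozen=True)
class ThresholdPolicy:
    """Dual-rail correctness thresholds (fractions of the rail maximum)."""

    hi_fraction: float = 0.8
    lo_fraction: float = 0.2
    sd_multiplier: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.lo_fraction < self.hi_fraction < 1.0):
            raise CRNError("thresholds must satisfy 0 < lo < hi < 1")


DEFAULT_POLICY = ThresholdPolicy()


def _mean_sd(traj, species: str, t: float) -> tuple[float, float]:
    return traj.value(species, t), traj.sd(species, t)


def is_high(
    traj, rail: str, t: float, rail_max: float, policy: ThresholdPolicy = DEFAULT_POLICY
) -> bool:
    """mean > hi_fraction * rail_max - sd_multiplier * SD."""
    mean, sd = _mean_sd(traj, rail, t)
    return mean > policy.hi_fraction * rail_max - policy.sd_multiplier * sd


def is_low(
    traj, rail: str, t: float, rail_max: float, policy: ThresholdPolicy = DEFAULT_POLICY
) -> bool:
    """mean < lo_fraction * rail_max + sd_multiplier * SD."""
    mean, sd = _mean_sd(traj, rail, t)
    return mean < policy.lo_fraction * rail_max + policy.sd_multiplier * sd


def signal_value(
    traj,
    rail_pair: tuple[str, str],
    t: float,
    rail_maxes: tuple[float, float],
    policy: ThresholdPolicy = DEFAULT_POLICY,
) -> int | None:
    """Boolean value of a dual-rail signal: 1, 0, or None when undefined.

    1 requires the high rail high *and* the low rail low; 0 the mirror;
    anything else (including both rails high) is surfaced as None.
    """
    hi, lo = rail_pair
    mhi, mlo = rail_maxes
    hi_high = is_high(traj, hi, t, mhi, policy)
    lo_low = is_low(traj, lo, t, mlo, policy)
    lo_high = is_high(traj, lo, t, mlo, policy)
    hi_low = is_low(traj, hi, t, mhi, policy)
    if hi_high and lo_low:
        return 1
    if lo_high and hi_low:
        return 0
    return None


def first_passage_time(traj, species: str, level: float) -> float | None:
    """Earliest grid time at which the species first reaches the level."""
    series = traj[species]
    if isinstance(traj, StochasticPath):
        times = traj.jump_times
    else:
        times = traj.times
    idx = np.nonzero(series >= level)[0]
    return float(times[idx[0]]) if len(idx) else None


def first_passage(
    traj, species: str, level: float, direction: str = "above"
) -> float | None:
    """Earliest grid time where the threshold holds *and keeps holding*.

    The debounced crossing: the predicate must be true from the returned
    time through the end of the trajectory.  Returns None if never.
    """
    series = traj[species]
    ok = series >= level if direction == "above" else series <= level
    if not ok[-1]:
        return None
    # last index where the predicate fails, +1 is the debounced crossing
    bad = np.nonzero(~ok)[0]
    idx = 0 if len(bad) == 0 else int(bad[-1]) + 1
    return float(traj.times[idx])


# ---------------------------------------------------------------------------
# truth-table sweeps
# ---------------------------------------------------------------------------


@dataclass
class TruthTableReport:
    circuit: str
    rows: list[dict]
    ok: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"truth table for {self.circuit}: {'PASS' if self.ok else 'FAIL'}"]
        for row in self.rows:
            lines.append(
                f"  {row['inputs']} -> {row['observed']} (expected {row['expected']})"
                + ("" if row["ok"] else "  <-- mismatch")
            )
        return "\n".join(lines)


def _rail_maxes(circuit: DualRailCircuit, amplitude: float) -> dict[str, float]:
    groups = conserved_totals(circuit.crs, max_weighted_species=0)
    maxes = {}
    for base in circuit.outputs:
        hi, lo = circuit.rail(base)
        maxes[hi] = rail_group_total(circuit.crs, hi, groups)
        maxes[lo] = rail_group_total(circuit.crs, lo, groups)
    return maxes


def sweep_truth_table(
    circuit: DualRailCircuit,
    semantics: str = "ode",
    horizon: float = 5.0,
    policy: ThresholdPolicy = DEFAULT_POLICY,
    amplitude: float = 10.0,
    seed: int = 0,
    contract=None,
) -> TruthTableReport:
    """Simulate a circuit against every Boolean input assignment.

    For each assignment the input rails are set at ``amplitude``, the
    circuit simulated under the chosen semantics and each output signal
    thresholded at the horizon.  Mismatches against the circuit's declared
    contract are flagged; undefined outputs are reported, never coerced.
    """
    contract = contract or circuit.contract
    if contract is None:
        raise CRNError("circuit declares no behavioural contract")
    rows = []
    ok = True
    for bits in itertools.product((0, 1), repeat=len(circuit.inputs)):
        assignment = dict(zip(circuit.inputs, bits))
        inst = circuit.with_input_assignment(assignment, amplitude=amplitude)
        maxes = _rail_maxes(inst, amplitude)
        if semantics == "ode":
            traj = simulate_ode(inst.crs, horizon)
        elif semantics == "lna":
            traj = simulate_lna(inst.crs, horizon)
        elif semantics == "ssa":
            traj = simulate_ssa(inst.crs, horizon, seed=path_seed(seed, hash(bits) % 997))
        else:
            raise CRNError(f"unknown semantics {semantics!r}")
        observed = {}
        for base in circuit.outputs:
            hi, lo = circuit.rail(base)
            observed[base] = signal_value(
                traj, (hi, lo), horizon, (maxes[hi], maxes[lo]), policy
            )
        expected = dict(contract(assignment))
        row_ok = all(
            expected[k] is None or observed.get(k) == expected[k] for k in expected
        )
        ok = ok and row_ok
        rows.append(
            {"inputs": assignment, "observed": observed, "expected": expected, "ok": row_ok}
        )
    return TruthTableReport(circuit.name, rows, ok)


# ---------------------------------------------------------------------------
# temporal properties over SSA paths
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Atom:
    """Threshold predicate over one species: ``species cmp level``."""

    species: str
    comparator: str  # < <= > >=
    level: float

    def __post_init__(self):
        if self.comparator not in ("<", "<=", ">", ">="):
            raise CRNError(f"unknown comparator {self.comparator!r}")
        if self.level < 0:
            raise CRNError("threshold level must be non-negative")

    def holds(self, value: float) -> bool:
        return {
            "<": value < self.level,
            "<=": value <= self.level,
            ">": value > self.level,
            ">=": value >= self.level,
        }[self.comparator]


@dataclass(frozen=True)
class TemporalProperty:
    """Time-bounded path formula over threshold atoms.

    ``form`` is one of ``until`` (phi1 U[t1,t2] phi2), ``eventually``
    (F[t1,t2] phi2) and ``globally`` (G[t1,t2] phi2); ``eventually`` is
    ``true U[t1,t2] phi2``.
    """

    form: str
    phi2: Atom | None
    phi1: Atom | None = None
    window: tuple[float, float] = (0.0, 10.0)
    n_paths: int = 20

    def __post_init__(self):
        t1, t2 = self.window
        if not (0 <= t1 <= t2):
            raise CRNError("property window must satisfy 0 <= t1 <= t2")
        if self.form not in ("until", "eventually", "globally"):
            raise CRNError(f"unknown property form {self.form!r}")
        if self.form == "until" and t1 == t2 and self.phi1 is not None:
            raise CRNError("vacuous bounded until: t1 == t2")

    def holds_on(self, path: StochasticPath) -> bool:
        """Evaluate on the exact jump path (no grid aliasing)."""
        t1, t2 = self.window
        times = path.jump_times
        states = path.states
        idx = {s: i for i, s in enumerate(path.species)}

        def atom_holds(atom: Atom | None, k: int) -> bool:
            if atom is None:
                return True
            return atom.holds(float(states[k, idx[atom.species]]))

        n = len(times)
        if self.form == "globally":
            for k in range(n):
                start = times[k]
                end = times[k + 1] if k + 1 < n else max(path.horizon, t2)
                if start > t2:
                    break
                if end > t1 and start <= t2 and not atom_holds(self.phi2, k):
                    # interval [start, end) intersects [t1, t2]
                    if max(start, t1) <= min(end, t2):
                        return False
            return True
        # until / eventually: find earliest t in [t1, t2] with phi2, phi1 before
        for k in range(n):
            start = times[k]
            end = times[k + 1] if k + 1 < n else max(path.horizon, t2) + 1.0
            if start > t2:
                break
            if atom_holds(self.phi2, k) and end > t1:
                # phi1 held on all complete earlier intervals; if the witness
                # time t1 falls inside this interval, phi1 must hold here too
                # on [start, t1) unless the interval begins at/after t1
                if start >= t1 or atom_holds(self.phi1, k):
                    return True
            if not atom_holds(self.phi1, k):
                return False
        return False


_ATOM_RE = re.compile(r"\(?\s*([A-Za-z_][A-Za-z0-9_.]*)\s*(<=|>=|<|>)\s*([0-9.]+)\s*\)?")
_UNTIL_RE = re.compile(
    r"^P\[\s*(?P<a1>.+?)\s*U\[\s*(?P<t1>[0-9.]+)\s*,\s*(?P<t2>[0-9.]+)\s*\]\s*(?P<a2>.+?)\s*\]$"
)
_FG_RE = re.compile(
    r"^P\[\s*(?P<op>[FG])\[\s*(?P<t1>[0-9.]+)\s*,\s*(?P<t2>[0-9.]+)\s*\]\s*(?P<a>.+?)\s*\]$"
)


def _parse_atom(text: str) -> Atom | None:
    text = text.strip()
    if text.lower() in ("true", "(true)"):
        return None
    m = _ATOM_RE.fullmatch(text)
    if not m:
        raise CRNError(f"cannot parse atom {text!r}")
    return Atom(m.group(1), m.group(2), float(m.group(3)))


def parse_property(text: str, n_paths: int = 20) -> TemporalProperty:
    """Parse the property mini-language.

    Examples: ``P[ (Bhi < 8) U[0,3] (Ahi > 8) ]``, ``P[ F[0,10] Chi > 8 ]``,
    ``P[ G[0,5] Zhi >= 8 ]``.
    """
    text = text.strip()
    m = _FG_RE.match(text)
    if m:
        form = "eventually" if m.group("op") == "F" else "globally"
        return TemporalProperty(
            form, _parse_atom(m.group("a")),
            window=(float(m.group("t1")), float(m.group("t2"))), n_paths=n_paths,
        )
    m = _UNTIL_RE.match(text)
    if m:
        return TemporalProperty(
            "until", _parse_atom(m.group("a2")), _parse_atom(m.group("a1")),
            window=(float(m.group("t1")), float(m.group("t2"))), n_paths=n_paths,
        )
    raise CRNError(f"cannot parse property {text!r}")


@dataclass
class PropertyEstimate:
    estimate: float
    ci: tuple[float, float]
    n_paths: int
    seed: int
    successes: int = 0

    def as_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "ci": list(self.ci),
            "n_paths": self.n_paths,
            "seed": self.seed,
        }


def estimate_property(
    crs: CRS,
    prop: TemporalProperty,
    seed: int = 0,
    horizon: float | None = None,
    schedule=None,
) -> PropertyEstimate:
    """Monte-Carlo estimate of P(path formula) over seeded SSA paths.

    Returns the satisfaction fraction with a 95% Clopper-Pearson interval.
    """
    if prop.n_paths < 1:
        raise CRNError("n_paths must be >= 1")
    horizon = horizon if horizon is not None else prop.window[1]
    hits = 0
    for i in range(prop.n_paths):
        path = simulate_ssa(crs, horizon, seed=path_seed(seed, i), schedule=schedule)
        if prop.holds_on(path):
            hits += 1
    n = prop.n_paths
    alpha = 0.05
    lo = stats.beta.ppf(alpha / 2, hits, n - hits + 1) if hits > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, hits + 1, n - hits) if hits < n else 1.0
    return PropertyEstimate(hits / n, (float(lo), float(hi)), n, seed, hits)
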