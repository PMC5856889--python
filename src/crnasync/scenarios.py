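"""Scenario registry: the reference experiments, self-contained.

Each scenario names a component, its initial assignment, optional signal
injections and a simulation semantics/horizon, together with checks that
report the measured quantities.  ``run_scenario`` simulates, writes the
trajectory CSV and returns the check report; re-running with the same seed
reproduces SSA outputs bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from . import components as comp
from .core import DualRailCircuit, InjectionEvent, Reaction
from .io import write_trajectory_csv
from .semantics import simulate_lna, simulate_ode, simulate_ssa
from .validation import first_passage, first_passage_time

__all__ = ["Scenario", "SCENARIOS", "run_scenario"]

AMP = comp.AMPLITUDE


@dataclass
class Scenario:
    id: str
    description: str
    build: Callable[[], DualRailCircuit]
    initial: dict[str, float]
    semantics: str = "ode"
    horizon: float = 2.0
    injections: list[InjectionEvent] = field(default_factory=list)
    checks: Callable[[object], dict] | None = None

    def circuit(self) -> DualRailCircuit:
        circ = self.build()
        return circ.with_initial(self.initial)

    def simulate(self, seed: int = 0):
        crs = self.circuit().crs
        if self.semantics == "ode":
            return simulate_ode(crs, self.horizon, schedule=self.injections)
        if self.semantics == "lna":
            return simulate_lna(crs, self.horizon, schedule=self.injections)
        if self.semantics == "ssa":
            return simulate_ssa(crs, self.horizon, seed=seed, schedule=self.injections)
        raise ValueError(f"unknown semantics {self.semantics!r}")


def _neutral_am(initial_output=1):
    return comp.build_dual_rail_am(initial_output=initial_output)


def _check_values(**targets):
    """Check helper: targets map '<species>@<time>' to (expected, tol)."""

    def run(traj):
        report = {}
        ok = True
        for key, (expected, tol) in targets.items():
            sp, t = key.split("@")
            val = traj.value(sp, float(t))
            good = abs(val - expected) <= tol
            ok = ok and good
            report[key] = {"measured": val, "expected": expected, "ok": good}
        report["ok"] = ok
        return report

    return run


SCENARIOS: dict[str, Scenario] = {}


def _register(s: Scenario):
    SCENARIOS[s.id] = s


_register(Scenario(
    "motif", "motif propagates X=1 to Y within 0.4 s",
    comp.build_motif, {"Xhi": AMP, "Ylo": AMP}, "ode", 1.0,
    checks=_check_values(**{"Yhi@0.4": (10.0, 0.5)}),
))
_register(Scenario(
    "am-consensus", "dual-rail AM converges to Z=0 on both-low inputs",
    lambda: _neutral_am(1), {"Xlo": AMP, "Ylo": AMP}, "ode", 1.0,
    checks=_check_values(**{"Zlo@0.5": (10.0, 0.5)}),
))
_register(Scenario(
    "am-mixed-failure", "single-AM C-element candidate fails on mixed input (the design flaw)",
    lambda: _neutral_am(1), {"Xlo": AMP, "Yhi": AMP}, "lna", 1.0,
    checks=_check_values(**{"Zhi@0.3": (6.0, 0.5), "lam@0.3": (4.0, 0.5)}),
))
_register(Scenario(
    "c-element-boost", "weak inputs boosted to full output by the C-element",
    lambda: comp.build_c_element(initial_output=None),
    {"Xhi": 6.0, "Yhi": 4.0}, "lna", 2.0,
    checks=_check_values(**{"Zhi@2": (10.0, 0.5)}),
))
_register(Scenario(
    "c-element-hold", "C-element holds its output on mixed input",
    lambda: comp.build_c_element(initial_output=1),
    {"Xlo": AMP, "Yhi": AMP}, "ode", 2.0,
    checks=lambda traj: {
        "Zhi_min": float(np.min(traj["Zhi"])),
        "ok": bool(np.min(traj["Zhi"]) > AMP - 0.5),
    },
))
_register(Scenario(
    "c-element-flip-low", "C-element flips to 0 on both-low inputs within 1 s",
    lambda: comp.build_c_element(initial_output=1),
    {"Xlo": AMP, "Ylo": AMP}, "ode", 2.0,
    checks=_check_values(**{"Zlo@1": (10.0, 0.5)}),
))
_register(Scenario(
    "c-element-flip-high", "C-element flips to 1 on both-high inputs within 1 s",
    lambda: comp.build_c_element(initial_output=0),
    {"Xhi": AMP, "Yhi": AMP}, "lna", 2.0,
    checks=_check_values(**{"Zhi@1": (10.0, 0.5)}),
))
_register(Scenario(
    "latch-simple", "simple latch follows input X=1",
    lambda: comp.build_latch("simple"), {"Xhi": AMP, "Ylo": AMP}, "ode", 1.0,
    checks=_check_values(**{"Yhi@0.5": (10.0, 0.5)}),
))
_register(Scenario(
    "latch-reset", "reset latch follows input X=1",
    lambda: comp.build_latch("with_reset"), {"Xhi": AMP, "Ylo": AMP}, "ode", 1.0,
    checks=_check_values(**{"Yhi@1": (10.0, 0.5)}),
))
_register(Scenario(
    "arbiter", "arbiter promotes the present input to full output",
    lambda: comp.build_arbiter(initial_output=None),
    {"Xhi": 5.0}, "lna", 1.0,
    checks=_check_values(**{"Yhi@0.4": (10.0, 0.5)}),
))
_register(Scenario(
    "and-timing", "AND gate output rises by 0.8 s on both-high inputs",
    lambda: comp.build_gate("AND"), {"Xhi": AMP, "Yhi": AMP}, "ode", 3.0,
    checks=lambda traj: {
        "t_cross": first_passage(traj, "Zhi", 8.0),
        "ok": first_passage(traj, "Zhi", 8.0) is not None
        and abs(first_passage(traj, "Zhi", 8.0) - 0.8) <= 0.2,
    },
))
for _bits in [(0, 0), (1, 0), (0, 1), (1, 1)]:
    _x, _y = _bits
    _register(Scenario(
        f"xor-{_x}{_y}", f"XOR gate validation on input ({_x},{_y})",
        lambda: comp.build_gate("XOR"),
        {
            ("Xhi" if _x else "Xlo"): AMP,
            ("Yhi" if _y else "Ylo"): AMP,
        },
        "lna", 2.0,
        checks=(lambda x, y: _check_values(
            **{("Zhi@2" if x ^ y else "Zlo@2"): (10.0, 0.5)}
        ))(_x, _y),
    ))


def _pipeline_injection(t: float = 1.0):
    return InjectionEvent.make(t, [Reaction.make(["Reqhi"], ["Reqlo"])])


_register(Scenario(
    "pipeline-wave", "pipeline propagates Req=1 wave, then responds to Req=0 at 1 s",
    lambda: comp.build_pipeline(3), {"Reqhi": AMP}, "ode", 2.0,
    injections=[_pipeline_injection(1.0)],
    checks=lambda traj: {
        "Alo@2": traj.value("Alo", 2.0),
        "Blo@2": traj.value("Blo", 2.0),
        "Clo@2": traj.value("Clo", 2.0),
        "ok": min(traj.value(s, 2.0) for s in ("Alo", "Blo", "Clo")) > 9.5,
    },
))
_register(Scenario(
    "queue-wave", "queue latches show the staggered rise-then-fall wave",
    lambda: comp.build_queue(3), {"Reqhi": AMP, "Amhi": AMP}, "ode", 4.0,
    injections=[InjectionEvent.make(1.5, [Reaction.make(["Amhi"], ["Amlo"])])],
    checks=lambda traj: {
        "t_Ams_up": first_passage_time(traj, "Amshi", 8.0),
        "t_Bms_up": first_passage_time(traj, "Bmshi", 8.0),
        "Ams_final": traj.value("Amshi", 4.0),
        "ok": first_passage_time(traj, "Amshi", 8.0) is not None
        and first_passage_time(traj, "Bmshi", 8.0) is not None
        and first_passage_time(traj, "Amshi", 8.0)
        < first_passage_time(traj, "Bmshi", 8.0),
    },
))
_register(Scenario(
    "adder-worked-example", "ripple-carry adder: (0,1)+(1,1)+(1,1), sums 1,0,1, carry 1",
    lambda: comp.stage_adder_inputs(
        comp.build_ripple_carry_adder(3), [(0, 1), (1, 1), (1, 1)]
    ),
    {"Reqhi": AMP}, "ode", 10.0,
    checks=lambda traj: {
        "Asum_hi": traj.value("Asumhi", 10.0),
        "Bsum_lo": traj.value("Bsumlo", 10.0),
        "Csum_hi": traj.value("Csumhi", 10.0),
        "Carry_hi": traj.value("Carryhi", 10.0),
        "ok": traj.value("Asumhi", 10.0) > 7.5
        and traj.value("Bsumlo", 10.0) > 7.5
        and traj.value("Csumhi", 10.0) > 7.5
        and traj.value("Carryhi", 10.0) > 7.5,
    },
))


def run_scenario(scenario_id: str, out_dir=None, seed: int = 0, **overrides) -> dict:
    """Run a registered scenario; write CSV when ``out_dir`` given.

    Returns ``{"id", "description", "seed", "checks"}``; check failures are
    reported, never raised.
    """
    if scenario_id not in SCENARIOS:
        raise KeyError(f"unknown scenario {scenario_id!r}")
    sc = SCENARIOS[scenario_id]
    if overrides:
        sc = Scenario(**{**sc.__dict__, **overrides})
    traj = sc.simulate(seed=seed)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_trajectory_csv(traj, out_dir / f"{scenario_id}.csv")
    report = {"id": sc.id, "description": sc.description, "seed": seed}
    report["checks"] = sc.checks(traj) if sc.checks else {}
    return report
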