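"""Builders for the asynchronous-logic circuit designs.

All components are built from bi-molecular catalytic reactions
``X + Y -> X + Z`` (written here as "X catalyses Y -> Z") with unit rates.
Signals are dual-rail pairs at an amplitude of 10 molecules; undecided
state lives in internal ``lam`` pools.  Every reaction is 2-reactant /
2-product, so each component's output pool conserves its total count.

The key building block is the Approximate Majority (AM) network, which
drives a population to consensus through an undecided intermediary.  In
the dual-rail AM the two inputs gate the two halves of each conversion:
``X`` gates the rail -> lam step and ``Y`` the lam -> rail step, and the
output rails self-amplify.  Composing two AM stages yields a Muller
C-element whose output moves only when both inputs agree.
"""

from __future__ import annotations

from typing import Callable, Mapping

from .core import (
    CRS,
    Connection,
    CRNError,
    DualRailCircuit,
    Port,
    Reaction,
    compose,
    compose_series,
)

__all__ = [
    "build_motif",
    "build_am",
    "build_dual_rail_am",
    "build_arbiter",
    "build_c_element",
    "build_latch",
    "build_fork",
    "build_join",
    "build_gate",
    "build_pipeline",
    "build_queue",
    "build_full_adder",
    "build_ripple_carry_adder",
    "build_lambda_sink",
    "COMPONENTS",
    "AMPLITUDE",
]

AMPLITUDE = 10.0  # molecules per rail in every experiment of the study


def _cat(catalyst: str, substrate: str, product: str) -> Reaction:
    return Reaction.make([catalyst, substrate], [catalyst, product])


def build_motif() -> DualRailCircuit:
    """Two-reaction dual-rail motif: X drives Y to copy its Boolean value."""
    rxns = [_cat("Xhi", "Ylo", "Yhi"), _cat("Xlo", "Yhi", "Ylo")]
    crs = CRS.from_reactions(rxns, init={"Ylo": AMPLITUDE})
    circ = DualRailCircuit(crs, inputs=["X"], outputs=["Y"], name="motif")
    circ.contract = lambda a: {"Y": a.get("X")}
    return circ


def build_am() -> CRS:
    """Single-rail Approximate Majority: 3 species, 4 reactions.

    X and Y convert each other into the undecided lam, and recruit lam to
    their own side; the initial majority wins.
    """
    rxns = [
        _cat("X", "Y", "lam"),
        _cat("Y", "X", "lam"),
        _cat("X", "lam", "X"),
        _cat("Y", "lam", "Y"),
    ]
    return CRS.from_reactions(rxns)


def _am_core(
    hi_first, hi_second, lo_first, lo_second,
    zhi: str, zlo: str, lam: str,
) -> list[Reaction]:
    """Dual-rail AM over an output pair with split-step input gating.

    ``hi_first`` gates ``zlo -> lam`` and ``hi_second`` gates
    ``lam -> zhi`` (mirror for the low side); the output rails catalyse
    both steps of their own conversion, giving AM self-amplification.
    Each gating argument may be a single catalyst name or a list of
    alternative catalysts (catalysis is additive, so listing several
    species wire-ORs the gate).
    """
    def as_list(x):
        return [x] if isinstance(x, str) else list(x)

    rxns = []
    for c in as_list(hi_first):
        rxns.append(_cat(c, zlo, lam))
    for c in as_list(hi_second):
        rxns.append(_cat(c, lam, zhi))
    for c in as_list(lo_first):
        rxns.append(_cat(c, zhi, lam))
    for c in as_list(lo_second):
        rxns.append(_cat(c, lam, zlo))
    rxns += [
        _cat(zhi, zlo, lam), _cat(zhi, lam, zhi),
        _cat(zlo, zhi, lam), _cat(zlo, lam, zlo),
    ]
    return rxns


def build_dual_rail_am(initial_output: int | None = 1) -> DualRailCircuit:
    """Dual-rail AM with inputs X, Y and output Z (the single-AM C-element candidate).

    The X rails gate the rail -> lam steps and the Y rails the lam -> rail
    steps.  ``initial_output`` places the conserved output pool (total 10)
    on Z_hi (1), Z_lo (0) or lam (None).
    """
    rxns = _am_core("Xhi", "Yhi", "Xlo", "Ylo", "Zhi", "Zlo", "lam")
    init = {_out_species("Z", "lam", initial_output): AMPLITUDE}
    crs = CRS.from_reactions(rxns, init=init)
    return DualRailCircuit(crs, inputs=["X", "Y"], outputs=["Z"], name="dual_rail_am")


def _out_species(base: str, lam: str, state: int | None) -> str:
    if state == 1:
        return f"{base}hi"
    if state == 0:
        return f"{base}lo"
    return lam


def build_arbiter(initial_output: int | None = None) -> DualRailCircuit:
    """Two-input AM arbiter: output Y follows whichever X rail dominates.

    Same AM core with a single input pair gating both conversion steps.
    Starts in the neutral lam state by default.
    """
    rxns = _am_core("Xhi", "Xhi", "Xlo", "Xlo", "Yhi", "Ylo", "lam")
    init = {_out_species("Y", "lam", initial_output): AMPLITUDE}
    crs = CRS.from_reactions(rxns, init=init)
    return DualRailCircuit(crs, inputs=["X"], outputs=["Y"], name="arbiter")


def build_c_element(initial_output: int | None = 1) -> DualRailCircuit:
    """Muller C-element: two AM stages in series.

    Stage 1 is the dual-rail AM over (X, Y) with output pair (W_hi, W_lo)
    and intermediary lam1; stage 2 is an arbiter-style AM amplifying W into
    the output Z with intermediary lam2.  The internal chain is initialised
    consistently with the declared output state, i.e. the configuration the
    element holds after stabilising at that output.
    """
    am = build_dual_rail_am(initial_output=None).with_initial({"lam": 0})
    arb = build_arbiter(initial_output=None).with_initial({"lam": 0})
    circ = compose(
        [("am", am), ("amp", arb)],
        [Connection(Port("am", "Z"), Port("amp", "X"))],
        expose_inputs=[(Port("am", "X"), "X"), (Port("am", "Y"), "Y")],
        expose_outputs=[(Port("amp", "Y"), "Z")],
        name="c_element",
        rename={"am.lam": "lam1", "amp.lam": "lam2"},
    )
    # wired pair lam1hi/lam1lo is the W pair; rename for readability
    ren = {"lam1hi": "Whi", "lam1lo": "Wlo"}
    crs = circ.crs
    crs = CRS.from_reactions(
        [r.rename(ren) for r in crs.reactions],
        init={ren.get(n, n): c for n, c in zip(crs.names, crs.x0) if c},
        N=crs.N,
        extra_species=[ren.get(n, n) for n in crs.names],
    )
    circ = DualRailCircuit(crs, inputs=["X", "Y"], outputs=["Z"], name="c_element")
    stage1 = _out_species("W", "lam1", initial_output)
    stage2 = _out_species("Z", "lam2", initial_output)
    circ = circ.with_initial({stage1: AMPLITUDE, stage2: AMPLITUDE})
    circ.contract = lambda a: {
        "Z": a.get("X") if a.get("X") == a.get("Y") else None
    }
    return circ


def build_latch(kind: str = "simple") -> DualRailCircuit:
    """Latch storing one bit.

    ``simple``: the motif plus output feedback (each rail catalyses the
    conversion of the other into itself), so the stored value persists
    when the input is withdrawn.

    ``with_reset``: lam-centred design with inputs X and R.  X gates both
    steps of the conversion chain through the neutral state lam; R_hi
    returns both output rails to lam (neutral); the output rails
    self-amplify.  The neutral state means neither rail is populated, so
    downstream components are not triggered.
    """
    if kind == "simple":
        rxns = [
            _cat("Xhi", "Ylo", "Yhi"), _cat("Xlo", "Yhi", "Ylo"),
            _cat("Yhi", "Ylo", "Yhi"), _cat("Ylo", "Yhi", "Ylo"),
        ]
        crs = CRS.from_reactions(rxns, init={"Ylo": AMPLITUDE})
        circ = DualRailCircuit(crs, inputs=["X"], outputs=["Y"], name="latch_simple")
    elif kind == "with_reset":
        rxns = _am_core("Xhi", "Xhi", "Xlo", "Xlo", "Yhi", "Ylo", "lam") + [
            _cat("Rhi", "Yhi", "lam"), _cat("Rhi", "Ylo", "lam"),
        ]
        crs = CRS.from_reactions(rxns, init={"Ylo": AMPLITUDE}, extra_species=["Rlo"])
        circ = DualRailCircuit(crs, inputs=["X", "R"], outputs=["Y"], name="latch_reset")
        # an active reset dominates: the stored value returns to neutral lam
        circ.contract = lambda a: {"Y": None if a.get("R") == 1 else a.get("X")}
        return circ
    else:
        raise CRNError(f"unknown latch kind {kind!r}")
    circ.contract = lambda a: {"Y": a.get("X")}
    return circ


def build_fork() -> DualRailCircuit:
    """Fork: one input X split into outputs Y1, Y2 via two parallel motifs.

    Catalysis is non-consuming, so under deterministic semantics both
    branches move identically: the CRN analogue of an isochronous fork.
    """
    rxns = [
        _cat("Xhi", "Y1lo", "Y1hi"), _cat("Xlo", "Y1hi", "Y1lo"),
        _cat("Xhi", "Y2lo", "Y2hi"), _cat("Xlo", "Y2hi", "Y2lo"),
    ]
    crs = CRS.from_reactions(rxns, init={"Y1lo": AMPLITUDE, "Y2lo": AMPLITUDE})
    circ = DualRailCircuit(crs, inputs=["X"], outputs=["Y1", "Y2"], name="fork")
    circ.contract = lambda a: {"Y1": a.get("X"), "Y2": a.get("X")}
    return circ


def build_join() -> DualRailCircuit:
    """Join: output Y rises only when both X1 and X2 agree (synchronisation).

    Each polarity is a two-step chain whose steps are gated by the two
    inputs in turn, so a single input cannot complete the conversion.
    """
    rxns = [
        _cat("X1hi", "ah", "bh"), _cat("X2hi", "bh", "Yhi"),
        _cat("X1lo", "al", "bl"), _cat("X2lo", "bl", "Ylo"),
        # opposite-rail cleanup keeps the outputs exclusive when re-used
        _cat("Yhi", "Ylo", "al"), _cat("Ylo", "Yhi", "ah"),
    ]
    crs = CRS.from_reactions(rxns, init={"ah": AMPLITUDE, "al": AMPLITUDE})
    circ = DualRailCircuit(crs, inputs=["X1", "X2"], outputs=["Y"], name="join")
    circ.contract = lambda a: {
        "Y": a.get("X1") if a.get("X1") == a.get("X2") else None
    }
    return circ


# ---------------------------------------------------------------------------
# logic gates
# ---------------------------------------------------------------------------


def _conj_ladder(lit1: str, lit2: str, src: str, mid: str, rail: str) -> list[Reaction]:
    """Two-step ladder src ->(lit2) mid ->(lit1) rail requiring both literals."""
    return [_cat(lit2, src, mid), _cat(lit1, mid, rail)]


def _gate_two_sided(
    conj: tuple[str, str], conj_rail: str, conj_src: str, conj_mid: str,
    disj: tuple[str, str], disj_rail: str, disj_pool: str,
) -> list[Reaction]:
    """Gate with a conjunction ladder on one rail and a disjunction pool on the other.

    The conjunction rail suppresses the disjunction rail back into its
    pool; the disjunction rail knocks the conjunction rail down to the
    ladder bottom and un-climbs the intermediate.
    """
    lit1, lit2 = conj
    d1, d2 = disj
    return [
        *_conj_ladder(lit1, lit2, conj_src, conj_mid, conj_rail),
        _cat(d1, disj_pool, disj_rail), _cat(d2, disj_pool, disj_rail),
        _cat(conj_rail, disj_rail, disj_pool),
        _cat(disj_rail, conj_rail, conj_src), _cat(disj_rail, conj_mid, conj_src),
    ]


def _xor_branch(lit1: str, lit2: str, src: str, mid_a: str, mid_b: str, rail: str) -> list[Reaction]:
    """One XOR minterm: the shared source pool drains through both catalysis
    orders of the two literals, with output self-catalysis on the second step."""
    return [
        _cat(lit1, src, mid_a), _cat(lit2, mid_a, rail), _cat(rail, mid_a, rail),
        _cat(lit2, src, mid_b), _cat(lit1, mid_b, rail), _cat(rail, mid_b, rail),
    ]


_GATE_TRUTH: dict[str, Callable[[int, int], int]] = {
    "AND": lambda x, y: x & y,
    "OR": lambda x, y: x | y,
    "NAND": lambda x, y: 1 - (x & y),
    "NOR": lambda x, y: 1 - (x | y),
    "XOR": lambda x, y: x ^ y,
}


def build_gate(kind: str) -> DualRailCircuit:
    """Dual-rail logic gate over inputs X, Y (NOT: input X only), output Z.

    NOT is the crossed motif.  AND/OR/NAND/NOR pair a two-step conjunction
    ladder (for the rail whose minterm is a conjunction of input literals)
    with a single catalysis pool for the other rail, plus mutual
    suppression.  XOR uses one shared source pool per output rail, drained
    through the two minterm branches of that rail.
    """
    kind = kind.upper()
    if kind == "NOT":
        rxns = [_cat("Xhi", "Yhi", "Ylo"), _cat("Xlo", "Ylo", "Yhi")]
        crs = CRS.from_reactions(rxns, init={"Ylo": AMPLITUDE})
        circ = DualRailCircuit(crs, inputs=["X"], outputs=["Y"], name="gate_not")
        circ.contract = lambda a: {
            "Y": None if a.get("X") is None else 1 - a["X"]
        }
        return circ

    if kind == "AND":
        # ladder lam2 ->(Yhi) lam1 ->(Xhi) Zhi; pool lam3 ->(Xlo|Ylo) Zlo
        rxns = _gate_two_sided(
            ("Xhi", "Yhi"), "Zhi", "lam2", "lam1",
            ("Xlo", "Ylo"), "Zlo", "lam3",
        )
        init = {"lam2": AMPLITUDE, "Zlo": AMPLITUDE}
    elif kind == "NAND":
        rxns = _gate_two_sided(
            ("Xhi", "Yhi"), "Zlo", "lam2", "lam1",
            ("Xlo", "Ylo"), "Zhi", "lam3",
        )
        init = {"lam2": AMPLITUDE, "Zhi": AMPLITUDE}
    elif kind == "OR":
        rxns = _gate_two_sided(
            ("Xlo", "Ylo"), "Zlo", "lam2", "lam1",
            ("Xhi", "Yhi"), "Zhi", "lam3",
        )
        init = {"lam2": AMPLITUDE, "lam3": AMPLITUDE}
    elif kind == "NOR":
        rxns = _gate_two_sided(
            ("Xlo", "Ylo"), "Zhi", "lam2", "lam1",
            ("Xhi", "Yhi"), "Zlo", "lam3",
        )
        init = {"lam2": AMPLITUDE, "lam3": AMPLITUDE}
    elif kind == "XOR":
        rxns = [
            *_xor_branch("Xhi", "Ylo", "lam1", "lam1a", "lam1b", "Zhi"),
            *_xor_branch("Xlo", "Yhi", "lam1", "lam1c", "lam1d", "Zhi"),
            *_xor_branch("Xhi", "Yhi", "lam2", "lam2a", "lam2b", "Zlo"),
            *_xor_branch("Xlo", "Ylo", "lam2", "lam2c", "lam2d", "Zlo"),
            # mutual suppression: each rail returns the other to its source
            # pool, so the gate re-evaluates when its inputs change
            _cat("Zhi", "Zlo", "lam2"), _cat("Zlo", "Zhi", "lam1"),
        ]
        init = {"lam1": AMPLITUDE, "lam2": AMPLITUDE}
    else:
        raise CRNError(f"unknown gate kind {kind!r}")
    crs = CRS.from_reactions(rxns, init=init)
    circ = DualRailCircuit(crs, inputs=["X", "Y"], outputs=["Z"], name=f"gate_{kind.lower()}")
    truth = _GATE_TRUTH[kind]
    circ.contract = lambda a: {
        "Z": None if a.get("X") is None or a.get("Y") is None else truth(a["X"], a["Y"])
    }
    return circ


# ---------------------------------------------------------------------------
# pipeline, queue, adder, lambda sink
# ---------------------------------------------------------------------------


def _c_element_reactions(
    trigger: tuple[str, str], guard,
    w: tuple[str, str], lam1: str,
    z: tuple[str, str], lam2: str,
) -> list[Reaction]:
    """C-element reaction list over explicit species names (for wiring nets).

    ``trigger`` gates the lam -> rail steps of the first AM stage (so its
    signal alone can lift a neutral element), ``guard`` the rail -> lam
    steps (so a disagreeing guard holds the element in the mixed state
    that the second AM stage filters out).  ``guard`` rails may be lists
    of alternative catalysts.
    """
    rxns = _am_core(guard[0], trigger[0], guard[1], trigger[1], w[0], w[1], lam1)
    rxns += _am_core(w[0], w[0], w[1], w[1], z[0], z[1], lam2)
    return rxns


_STAGE_NAMES = "ABCDEFGH"


def build_pipeline(n_stages: int = 3) -> DualRailCircuit:
    """Muller C-pipeline: ``n_stages`` C-elements linked by forks with
    inverted feedback.

    Stage i is triggered by a fork branch of the previous stage's output
    (stage 1: the Req rails directly) and guarded by the *inverted* other
    fork branch of the next stage's output, so a stage may only change
    after its predecessor has and while its successor disagrees.  The
    inversion is a rail crossing (dual-rail NOT is a wire swap); the fork
    branches are single-input AM pools of their own, so each inter-stage
    link adds a real conversion delay and the stage outputs rise well
    separated.  All pools start in the neutral lam state: no stage outputs
    a value until driven.

    The last stage's guard is its own inverted fork branch, wire-ORed with
    the inverted acknowledge rails: with Acc absent the stage follows its
    predecessor (the open-ended experiment); a driven Acc gates it like
    any other stage.
    """
    if n_stages < 1:
        raise CRNError("n_stages must be >= 1")
    if n_stages > len(_STAGE_NAMES):
        raise CRNError(f"at most {len(_STAGE_NAMES)} stages supported")
    stages = [_STAGE_NAMES[i] for i in range(n_stages)]
    rxns: list[Reaction] = []
    init: dict[str, float] = {}

    def fork_branch(src: str, branch: str):
        """Single-input AM pool copying the source signal onto the branch."""
        rxns.extend(
            _am_core(
                f"{src}hi", f"{src}hi", f"{src}lo", f"{src}lo",
                f"{branch}hi", f"{branch}lo", f"lam{branch}",
            )
        )
        init[f"lam{branch}"] = AMPLITUDE

    for i, s in enumerate(stages):
        if i == 0:
            prev = ("Reqhi", "Reqlo")
        else:  # forward fork branch of the previous stage's output
            fork_branch(stages[i - 1], f"F{stages[i-1]}")
            prev = (f"F{stages[i-1]}hi", f"F{stages[i-1]}lo")
        # feedback fork branch of this stage's own output (used inverted by
        # the predecessor, and by the stage itself when it is the last one)
        fork_branch(s, f"G{s}")
        if i == n_stages - 1:
            guard = ([f"G{s}lo", "Acclo"], [f"G{s}hi", "Acchi"])
        else:
            guard = (f"G{stages[i+1]}lo", f"G{stages[i+1]}hi")
        rxns += _c_element_reactions(
            prev, guard,
            (f"W{s}hi", f"W{s}lo"), f"lamW{s}",
            (f"{s}hi", f"{s}lo"), f"lamZ{s}",
        )
        init[f"lamW{s}"] = AMPLITUDE
        init[f"lamZ{s}"] = AMPLITUDE
    crs = CRS.from_reactions(
        rxns, init=init, extra_species=["Reqhi", "Reqlo", "Acchi", "Acclo"]
    )
    return DualRailCircuit(
        crs, inputs=["Req", "Acc"], outputs=list(stages), name=f"pipeline{n_stages}"
    )


def build_queue(n_stages: int = 3) -> DualRailCircuit:
    """Asynchronous queue: the C-pipeline gating one reset latch per stage.

    All latches read the shared data rails Am; the stage-i control species
    (the high rail of C-element output i) gates the load of the staged
    value into latch i, whose output is ``<stage>ms`` (Ams, Bms, ...).
    The data rails preload a staging pool; the output rail can only rise
    once the control species is present.  R resets every latch to neutral.
    """
    pipe = build_pipeline(n_stages)
    stages = pipe.outputs
    rxns = list(pipe.crs.reactions)
    init = {n: c for n, c in zip(pipe.crs.names, pipe.crs.x0) if c}
    for s in stages:
        out, lam = f"{s}ms", f"lamL{s}"
        nu_hi, nu_lo = f"nu{s}hi", f"nu{s}lo"
        ctrl = f"{s}hi"
        rxns += [
            _cat("Amhi", lam, nu_hi), _cat(ctrl, nu_hi, f"{out}hi"),
            _cat("Amlo", lam, nu_lo), _cat(ctrl, nu_lo, f"{out}lo"),
            _cat("Amlo", f"{out}hi", lam), _cat("Amhi", f"{out}lo", lam),
            _cat("Rhi", f"{out}hi", lam), _cat("Rhi", f"{out}lo", lam),
        ]
        init[lam] = AMPLITUDE
    crs = CRS.from_reactions(
        rxns, init=init,
        extra_species=["Reqhi", "Reqlo", "Acchi", "Acclo", "Amhi", "Amlo", "Rhi", "Rlo"],
    )
    return DualRailCircuit(
        crs,
        inputs=["Req", "Acc", "Am", "R"],
        outputs=[f"{s}ms" for s in stages],
        name=f"queue{n_stages}",
    )


def build_full_adder() -> DualRailCircuit:
    """Full adder from gate instances: Sum = A xor B xor Cin,
    Cout = (A and B) or ((A xor B) and Cin)."""
    inst = [
        ("xor1", build_gate("XOR")),
        ("xor2", build_gate("XOR")),
        ("and1", build_gate("AND")),
        ("and2", build_gate("AND")),
        ("or1", build_gate("OR")),
    ]
    conns = [
        Connection(Port("xor1", "Z"), Port("xor2", "X")),
        Connection(Port("xor1", "Z"), Port("and2", "X")),
        Connection(Port("and1", "Z"), Port("or1", "X")),
        Connection(Port("and2", "Z"), Port("or1", "Y")),
    ]
    expose_in = [
        (Port("xor1", "X"), "A"), (Port("and1", "X"), "A"),
        (Port("xor1", "Y"), "B"), (Port("and1", "Y"), "B"),
        (Port("xor2", "Y"), "Cin"), (Port("and2", "Y"), "Cin"),
    ]
    # exposing two ports under one name shares the rail species (fan-out is free)
    circ = compose(
        inst,
        conns,
        expose_inputs=expose_in,
        expose_outputs=[(Port("xor2", "Z"), "Sum"), (Port("or1", "Z"), "Cout")],
        name="full_adder",
    )

    def contract(a):
        if any(a.get(k) is None for k in ("A", "B", "Cin")):
            return {"Sum": None, "Cout": None}
        s = a["A"] + a["B"] + a["Cin"]
        return {"Sum": s % 2, "Cout": int(s >= 2)}

    circ.contract = contract
    return circ


def build_ripple_carry_adder(n_bits: int = 3) -> DualRailCircuit:
    """Ripple-carry adder, control-interleaved with a Muller C-pipeline.

    Bit i has input signals ``<stage>a`` and ``<stage>b`` (stages A, B, C,
    ...).  The assigned input rails are preloaded into staging pools and
    released onto the adder's input rails only when the pipeline stage's
    control species (its C-element high output rail) is present, so each
    sum is produced only in its pipeline stage.  The carry of each adder
    (``<stage>carry``) feeds the next adder's carry-in; ``Cin0`` seeds the
    first.  Outputs are the per-stage sums and the final carry.
    """
    if n_bits < 1:
        raise CRNError("n_bits must be >= 1")
    pipe = build_pipeline(n_bits)
    stages = pipe.outputs
    instances: list[tuple[str, DualRailCircuit]] = [("pipe", pipe)]
    conns: list[Connection] = []
    expose_in = [(Port("pipe", "Req"), "Req"), (Port("pipe", "Acc"), "Acc")]
    expose_out = []
    prev_carry: Port | None = None
    for i, s in enumerate(stages):
        adder = build_full_adder()
        instances.append((f"fa{s}", adder))
        expose_in += [
            (Port(f"fa{s}", "A"), f"{s}a"),
            (Port(f"fa{s}", "B"), f"{s}b"),
        ]
        if prev_carry is None:
            expose_in.append((Port(f"fa{s}", "Cin"), "Cin0"))
        else:
            conns.append(Connection(prev_carry, Port(f"fa{s}", "Cin")))
        prev_carry = Port(f"fa{s}", "Cout")
        expose_out.append((Port(f"fa{s}", "Sum"), f"{s}sum"))
    expose_out.append((prev_carry, "Carry"))
    expose_out += [(Port("pipe", s), s) for s in stages]
    circ = compose(
        instances, conns,
        expose_inputs=expose_in, expose_outputs=expose_out,
        name=f"ripple_carry{n_bits}",
    )
    # staged input release: <stage>a/<stage>b rails are driven from staging
    # pools gated by the stage control species
    rxns = list(circ.crs.reactions)
    init = {n: c for n, c in zip(circ.crs.names, circ.crs.x0) if c}
    extra = list(circ.crs.names)
    for s in stages:
        for sig in (f"{s}a", f"{s}b"):
            for rail in ("hi", "lo"):
                staged = f"stg_{sig}{rail}"
                rxns.append(_cat(f"{s}hi", staged, f"{sig}{rail}"))
                extra.append(staged)
    crs = CRS.from_reactions(rxns, init=init, extra_species=extra)
    out = DualRailCircuit(
        crs, inputs=circ.inputs, outputs=circ.outputs, name=circ.name
    )
    return out


def stage_adder_inputs(circuit: DualRailCircuit, bits: list[tuple[int, int]],
                       amplitude: float = AMPLITUDE) -> DualRailCircuit:
    """Preload the staged input pools of a ripple-carry adder.

    ``bits[i]`` is the (a, b) input pair of stage i; the carry-in of stage
    0 is set to 0 (Cin0 low rail).  Returns a circuit ready to run once
    Req_hi is raised.
    """
    stages = [o for o in circuit.outputs if len(o) == 1]
    if len(bits) != len(stages):
        raise CRNError(f"expected {len(stages)} bit pairs")
    counts: dict[str, float] = {"Cin0lo": amplitude}
    for (a, b), s in zip(bits, stages):
        counts[f"stg_{s}a{'hi' if a else 'lo'}"] = amplitude
        counts[f"stg_{s}b{'hi' if b else 'lo'}"] = amplitude
    return circuit.with_initial(counts)


def build_lambda_sink() -> DualRailCircuit:
    """Sink CRN: lam absorbs the output rails unless an input rail is present.

    With no input and non-zero lam, all of Y converts to lam; with zero lam
    and no input the network deadlocks (nothing can move).
    """
    rxns = [
        _cat("Xhi", "lam", "Yhi"),
        _cat("Xlo", "lam", "Ylo"),
        _cat("lam", "Yhi", "lam"),
        _cat("lam", "Ylo", "lam"),
    ]
    crs = CRS.from_reactions(rxns, init={"lam": 5.0})
    return DualRailCircuit(crs, inputs=["X"], outputs=["Y"], name="lambda_sink")


COMPONENTS: dict[str, Callable[[], DualRailCircuit | CRS]] = {
    "motif": build_motif,
    "am": build_am,
    "dual_rail_am": build_dual_rail_am,
    "arbiter": build_arbiter,
    "c_element": build_c_element,
    "latch_simple": lambda: build_latch("simple"),
    "latch_reset": lambda: build_latch("with_reset"),
    "fork": build_fork,
    "join": build_join,
    "gate_not": lambda: build_gate("NOT"),
    "gate_and": lambda: build_gate("AND"),
    "gate_or": lambda: build_gate("OR"),
    "gate_nand": lambda: build_gate("NAND"),
    "gate_nor": lambda: build_gate("NOR"),
    "gate_xor": lambda: build_gate("XOR"),
    "pipeline": build_pipeline,
    "queue": build_queue,
    "full_adder": build_full_adder,
    "ripple_carry_adder": build_ripple_carry_adder,
    "lambda_sink": build_lambda_sink,
}
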