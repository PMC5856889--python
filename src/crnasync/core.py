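"""Core data model for chemical reaction networks (CRNs).

A CRN is a finite set of species together with uni- or bi-molecular
mass-action reactions.  A chemical reaction system (CRS) additionally fixes
an initial configuration (integer molecule counts) and a volumetric factor
``N`` relating counts to concentrations (``z = x / N``).  All circuit designs
in this package are built from bi-molecular *catalytic* reactions
``X + Y -> X + Z`` with uniform unit rates, so every design conserves the
total molecule count of each of its internal pools.

Boolean signals use dual-rail encoding: a signal ``X`` is the species pair
``Xhi`` / ``Xlo``; the signal is 1 when the high rail is populated and the
low rail empty, 0 for the mirror image, and undefined otherwise.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Species",
    "Reaction",
    "CRS",
    "DualRailCircuit",
    "InjectionEvent",
    "CRNError",
    "ParseError",
    "parse_crn",
    "serialize_crn",
    "net_change",
    "conserved_totals",
    "rail_group_total",
    "compose",
    "compose_series",
    "add_injection",
    "Connection",
    "Port",
]


class CRNError(ValueError):
    """Raised for ill-formed networks or invalid operations on them."""


class ParseError(CRNError):
    """Raised for syntax errors in reaction-format documents."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class Species:
    """A chemical species; rails come in ``hi``/``lo`` pairs sharing a base name."""

    name: str
    role: str = "internal"  # input_rail | output_rail | internal


@dataclass(frozen=True)
class Reaction:
    """A mass-action reaction (r, p, k).

    ``reactants`` and ``products`` map species names to stoichiometric
    counts.  Only uni-molecular (one reactant) and bi-molecular (two
    reactants, possibly the same species twice) reactions are allowed.
    The net change ``p - r`` is always derived, never stored.
    """

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate: float = 1.0

    def __post_init__(self):
        for side, label in ((self.reactants, "reactant"), (self.products, "product")):
            for name, count in side:
                if count <= 0:
                    raise CRNError(f"non-positive {label} count for {name}")
        if not (1 <= self.order <= 2):
            raise CRNError(
                f"reaction must be uni- or bi-molecular, got {self.order} reactants"
            )
        if self.rate <= 0:
            raise CRNError(f"reaction rate must be positive, got {self.rate}")

    @staticmethod
    def make(
        reactants: Mapping[str, int] | Sequence[str],
        products: Mapping[str, int] | Sequence[str],
        rate: float = 1.0,
    ) -> "Reaction":
        def norm(side) -> tuple[tuple[str, int], ...]:
            if isinstance(side, Mapping):
                return tuple((k, int(v)) for k, v in side.items())
            counts: dict[str, int] = {}
            for name in side:
                counts[name] = counts.get(name, 0) + 1
            return tuple(counts.items())

        return Reaction(norm(reactants), norm(products), float(rate))

    @property
    def order(self) -> int:
        return sum(c for _, c in self.reactants)

    @property
    def species(self) -> set[str]:
        return {n for n, _ in self.reactants} | {n for n, _ in self.products}

    def net(self) -> dict[str, int]:
        """Net change p - r per species (zero entries dropped)."""
        delta: dict[str, int] = {}
        for name, c in self.products:
            delta[name] = delta.get(name, 0) + c
        for name, c in self.reactants:
            delta[name] = delta.get(name, 0) - c
        return {k: v for k, v in delta.items() if v != 0}

    def rename(self, mapping: Mapping[str, str]) -> "Reaction":
        def m(side):
            out: dict[str, int] = {}
            for name, c in side:
                new = mapping.get(name, name)
                out[new] = out.get(new, 0) + c
            return tuple(out.items())

        return Reaction(m(self.reactants), m(self.products), self.rate)

    def __str__(self) -> str:
        def side(s):
            parts = []
            for name, c in s:
                parts.extend([name] * c)
            return " + ".join(parts)

        return f"{side(self.reactants)} ->{{{self.rate:g}}} {side(self.products)}"


def net_change(rxn: Reaction) -> dict[str, int]:
    """Net change vector of a reaction, as a species -> integer mapping."""
    return rxn.net()


def _cat(catalyst: str, substrate: str, product: str, rate: float = 1.0) -> Reaction:
    """Catalytic bi-molecular reaction ``catalyst + substrate -> catalyst + product``."""
    return Reaction.make([catalyst, substrate], [catalyst, product], rate)


@dataclass
class CRS:
    """A chemical reaction system: species (ordered), reactions, x0, N.

    Species order is first-appearance order and fixes every vector layout
    (ODE state, SSA scan order, CSV columns).
    """

    species: list[Species]
    reactions: list[Reaction]
    x0: np.ndarray
    N: float = 1.0

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise CRNError("duplicate species names")
        self.x0 = np.asarray(self.x0, dtype=float)
        if self.x0.shape != (len(self.species),):
            raise CRNError("x0 must have one entry per species")
        if np.any(self.x0 < 0):
            raise CRNError("negative initial counts")
        if self.N <= 0:
            raise CRNError("volumetric factor N must be positive")
        declared = set(names)
        for rxn in self.reactions:
            missing = rxn.species - declared
            if missing:
                raise CRNError(f"reaction references undeclared species {sorted(missing)}")
        self._index = {n: i for i, n in enumerate(names)}

    # -- views ---------------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [s.name for s in self.species]

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise CRNError(f"unknown species {name!r}") from None

    @property
    def z0(self) -> np.ndarray:
        """Initial concentrations x0 / N."""
        return self.x0 / self.N

    def count(self, name: str) -> float:
        return float(self.x0[self.index(name)])

    def net_matrix(self) -> np.ndarray:
        """Stoichiometric net-change matrix, shape (n_reactions, n_species)."""
        V = np.zeros((len(self.reactions), len(self.species)), dtype=int)
        for j, rxn in enumerate(self.reactions):
            for name, d in rxn.net().items():
                V[j, self.index(name)] = d
        return V

    def reactant_matrix(self) -> np.ndarray:
        R = np.zeros((len(self.reactions), len(self.species)), dtype=int)
        for j, rxn in enumerate(self.reactions):
            for name, c in rxn.reactants:
                R[j, self.index(name)] = c
        return R

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def from_reactions(
        reactions: Iterable[Reaction],
        init: Mapping[str, float] | None = None,
        N: float = 1.0,
        roles: Mapping[str, str] | None = None,
        extra_species: Sequence[str] = (),
    ) -> "CRS":
        """Build a CRS with species in first-appearance order.

        Appearance order scans reactions in order (reactants before
        products); ``extra_species`` appends species not touched by any
        reaction (e.g. isolated pools).
        """
        order: list[str] = []
        seen: set[str] = set()

        def see(name: str):
            if name not in seen:
                seen.add(name)
                order.append(name)

        for rxn in reactions:
            for name, _ in rxn.reactants:
                see(name)
            for name, _ in rxn.products:
                see(name)
        for name in extra_species:
            see(name)
        init = dict(init or {})
        unknown = set(init) - seen
        if unknown:
            raise CRNError(f"initial counts for undeclared species {sorted(unknown)}")
        roles = roles or {}
        species = [Species(n, roles.get(n, "internal")) for n in order]
        x0 = np.array([float(init.get(n, 0.0)) for n in order])
        return CRS(species, list(reactions), x0, N)

    def with_initial(self, counts: Mapping[str, float], reset: bool = False) -> "CRS":
        """Copy with updated initial counts (``reset`` zeroes the rest first)."""
        x0 = np.zeros_like(self.x0) if reset else self.x0.copy()
        for name, v in counts.items():
            x0[self.index(name)] = v
        return replace(self, x0=x0)


@dataclass(frozen=True)
class InjectionEvent:
    """Reactions added to the network at a given time (signal-change injection).

    Simulation engines treat a schedule of events as a piecewise network
    definition: run to the event time, extend the reaction set, continue
    from the reached state.
    """

    time: float
    added_reactions: tuple[Reaction, ...]

    def __post_init__(self):
        if self.time < 0:
            raise CRNError("injection event time must be non-negative")

    @staticmethod
    def make(time: float, reactions: Iterable[Reaction]) -> "InjectionEvent":
        return InjectionEvent(float(time), tuple(reactions))


def add_injection(
    crs: CRS, event: InjectionEvent, schedule: Sequence[InjectionEvent] = ()
) -> tuple[CRS, list[InjectionEvent]]:
    """Attach an injection event to a CRS, returning (crs, sorted schedule).

    Event reactions may only reference species already declared in the CRS.
    """
    declared = set(crs.names)
    for rxn in event.added_reactions:
        missing = rxn.species - declared
        if missing:
            raise CRNError(f"injection references unknown species {sorted(missing)}")
    events = sorted([*schedule, event], key=lambda e: e.time)
    return crs, events


# ---------------------------------------------------------------------------
# Reaction-format parsing / serialization
# ---------------------------------------------------------------------------

_IDENT = r"[A-Za-z_][A-Za-z0-9_.]*"
_NUM = r"[0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?"
_INIT_RE = re.compile(rf"^init\s+({_IDENT})\s+(-?\d+)$")
_SIDE_RE = re.compile(rf"^{_IDENT}(?:\s*\+\s*{_IDENT})*$")
_ARROW_RE = re.compile(
    rf"^(?P<lhs>.+?)\s*(?P<arrow><->|->)\s*(?:\{{(?P<rates>[^}}]*)\}})?\s*(?P<rhs>.+)$"
)


def _parse_side(text: str, lineno: int) -> list[str]:
    text = text.strip()
    if not _SIDE_RE.match(text):
        raise ParseError(f"cannot parse species list {text!r}", lineno)
    return [s.strip() for s in text.split("+")]


def parse_crn(text: str, N: float = 1.0) -> CRS:
    """Parse a reaction-format document into a CRS.

    Grammar (one statement per line, ``#`` starts a comment)::

        init <species> <integer>
        <S> [+ <S>] ->{<rate>} <S> [+ <S>]
        <S> [+ <S>] <->{<k1>,<k2>} <S> [+ <S>]    # expands to two reactions

    Unspecified rates default to 1; unspecified initial counts default to 0.
    Species appear in first-appearance order scanning statements top to
    bottom.
    """
    order: list[str] = []
    seen: set[str] = set()
    init: dict[str, int] = {}
    reactions: list[Reaction] = []

    def see(name: str):
        if name not in seen:
            seen.add(name)
            order.append(name)

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _INIT_RE.match(line)
        if m:
            name, count = m.group(1), int(m.group(2))
            if count < 0:
                raise ParseError(f"negative initial count for {name}", lineno)
            see(name)
            init[name] = count
            continue
        m = _ARROW_RE.match(line)
        if not m:
            raise ParseError(f"cannot parse statement {line!r}", lineno)
        lhs = _parse_side(m.group("lhs"), lineno)
        rhs = _parse_side(m.group("rhs"), lineno)
        rates_txt = m.group("rates")
        if rates_txt is None:
            rates = []
        else:
            rates = [r.strip() for r in rates_txt.split(",") if r.strip()]
        for r in rates:
            if not re.fullmatch(_NUM, r):
                raise ParseError(f"invalid rate {r!r}", lineno)
        if len(lhs) > 2:
            raise ParseError(
                f"{len(lhs)} reactants: only uni- and bi-molecular reactions allowed",
                lineno,
            )
        for name in lhs + rhs:
            see(name)
        if m.group("arrow") == "->":
            if len(rates) > 1:
                raise ParseError("irreversible reaction takes a single rate", lineno)
            k = float(rates[0]) if rates else 1.0
            reactions.append(Reaction.make(lhs, rhs, k))
        else:
            if len(rhs) > 2:
                raise ParseError(
                    "reversible reaction with more than 2 products cannot be reversed",
                    lineno,
                )
            if len(rates) > 2:
                raise ParseError("reversible reaction takes at most two rates", lineno)
            k1 = float(rates[0]) if len(rates) >= 1 else 1.0
            k2 = float(rates[1]) if len(rates) >= 2 else 1.0
            reactions.append(Reaction.make(lhs, rhs, k1))
            reactions.append(Reaction.make(rhs, lhs, k2))
    if not reactions:
        raise ParseError("no reactions in document")
    species = [Species(n) for n in order]
    x0 = np.array([float(init.get(n, 0)) for n in order])
    return CRS(species, reactions, x0, N)


def serialize_crn(crs: CRS) -> str:
    """Canonical reaction-format document for a CRS.

    Every species gets an ``init`` line (zero counts included) so that
    ``parse_crn(serialize_crn(crs))`` preserves species order exactly.
    """
    lines = [f"init {name} {int(round(count))}" for name, count in zip(crs.names, crs.x0)]
    lines += [str(rxn) for rxn in crs.reactions]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Conservation analysis
# ---------------------------------------------------------------------------


def conserved_totals(crs: CRS, max_weighted_species: int = 12) -> list[dict[str, int]]:
    """Integer-weight species combinations invariant under every reaction.

    Returns weight vectors ``w >= 0`` (as species -> weight dicts) with
    ``w . net(tau) = 0`` for all reactions.  Unit-weight groups are found
    structurally: species never changed by any reaction are singleton
    groups, and each connected component of the conversion graph whose net
    change sums to zero in every reaction is a unit group.  For small
    networks (``<= max_weighted_species`` species) the exact rational null
    space is additionally searched for non-negative integer vectors.
    """
    V = crs.net_matrix()
    n = len(crs.species)
    names = crs.names
    groups: list[dict[str, int]] = []

    changed = np.any(V != 0, axis=0)
    for i in range(n):
        if not changed[i]:
            groups.append({names[i]: 1})

    # connected components of species co-occurring in some net-change vector
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for row in V:
        touched = np.nonzero(row)[0]
        for i in touched[1:]:
            union(touched[0], i)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        if changed[i]:
            comps.setdefault(find(i), []).append(i)
    for members in comps.values():
        if all(int(V[j, members].sum()) == 0 for j in range(V.shape[0])):
            groups.append({names[i]: 1 for i in members})

    if n <= max_weighted_species:
        try:
            import sympy

            ns = sympy.Matrix(V).nullspace()
            for vec in ns:
                denom = sympy.lcm([sympy.fraction(x)[1] for x in vec]) if vec else 1
                ints = [int(x * denom) for x in vec]
                g = int(np.gcd.reduce([abs(v) for v in ints if v != 0] or [1]))
                ints = [int(v) // g for v in ints]
                if all(v >= 0 for v in ints) and any(v > 0 for v in ints):
                    d = {names[i]: ints[i] for i in range(n) if ints[i] > 0}
                    if d not in groups:
                        groups.append(d)
        except Exception:  # pragma: no cover - sympy optional at run time
            pass
    return groups


def rail_group_total(crs: CRS, rail: str, groups: list[dict[str, int]] | None = None) -> float:
    """Maximum achievable population of a rail: its conserved group's initial total.

    Uses the smallest unit-weight conserved group containing ``rail``.
    Raises if the rail belongs to no conserved group (unbounded species).
    """
    if groups is None:
        groups = conserved_totals(crs)
    candidates = [g for g in groups if rail in g and all(w == 1 for w in g.values())]
    if not candidates:
        raise CRNError(f"species {rail!r} belongs to no conserved unit group")
    group = min(candidates, key=len)
    return float(sum(crs.count(s) for s in group))


# ---------------------------------------------------------------------------
# Dual-rail circuits and composition
# ---------------------------------------------------------------------------


@dataclass
class DualRailCircuit:
    """A CRS with declared dual-rail input/output ports.

    ``inputs`` and ``outputs`` are signal base names; the rails are the
    species ``<base>hi`` and ``<base>lo``.  ``internals`` lists species that
    are neither input nor output rails.  ``contract``, when present, maps a
    Boolean input assignment to the expected Boolean output assignment at
    convergence (``None`` for "unchanged"/undefined).
    """

    crs: CRS
    inputs: list[str]
    outputs: list[str]
    name: str = "circuit"
    contract: Callable[[Mapping[str, int]], Mapping[str, int | None]] | None = field(
        default=None, repr=False
    )

    def __post_init__(self):
        declared = set(self.crs.names)
        for base in [*self.inputs, *self.outputs]:
            for sp in (f"{base}hi", f"{base}lo"):
                if sp not in declared:
                    raise CRNError(f"rail species {sp!r} not declared in CRS")
        port_rails = set()
        for base in [*self.inputs, *self.outputs]:
            port_rails.update({f"{base}hi", f"{base}lo"})
        self.internals = [n for n in self.crs.names if n not in port_rails]

    def rail(self, base: str) -> tuple[str, str]:
        return f"{base}hi", f"{base}lo"

    def with_input_assignment(
        self, assignment: Mapping[str, int | None], amplitude: float = 10.0
    ) -> "DualRailCircuit":
        """Copy with input rails set from a Boolean assignment.

        ``1`` populates the high rail at ``amplitude``, ``0`` the low rail,
        ``None`` leaves both rails empty (absent signal).  Unmentioned
        inputs are left untouched.
        """
        counts: dict[str, float] = {}
        for base, bit in assignment.items():
            if base not in self.inputs:
                raise CRNError(f"unknown input signal {base!r}")
            hi, lo = self.rail(base)
            counts[hi] = amplitude if bit == 1 else 0.0
            counts[lo] = amplitude if bit == 0 else 0.0
        return replace(self, crs=self.crs.with_initial(counts))

    def with_initial(self, counts: Mapping[str, float]) -> "DualRailCircuit":
        return replace(self, crs=self.crs.with_initial(counts))


@dataclass(frozen=True)
class Port:
    instance: str
    signal: str


@dataclass(frozen=True)
class Connection:
    src: Port
    dst: Port
    crossed: bool = False  # dual-rail inversion: hi wires to lo and vice versa


def compose(
    instances: Sequence[tuple[str, DualRailCircuit]],
    connections: Sequence[Connection] = (),
    expose_inputs: Sequence[tuple[Port, str]] = (),
    expose_outputs: Sequence[tuple[Port, str]] = (),
    name: str = "composite",
    rename: Mapping[str, str] | None = None,
    extra_initial: Mapping[str, float] | None = None,
) -> DualRailCircuit:
    """Netlist composition of dual-rail circuits.

    Connected ports are unified onto shared net species; wired pairs that
    are not exposed become internal ``lam<k>hi``/``lam<k>lo`` pairs (fresh
    running index), inverted nets swap rails.  Non-port species are prefixed
    ``<instance>.`` and may be renamed afterwards via ``rename``.  Initial
    counts landing on the same net species are summed.
    """
    inst_map = dict(instances)
    if len(inst_map) != len(instances):
        raise CRNError("duplicate instance names")

    for conn in connections:
        if conn.src.instance not in inst_map or conn.dst.instance not in inst_map:
            raise CRNError("connection references unknown instance")
        if conn.src.signal not in inst_map[conn.src.instance].outputs:
            raise CRNError(
                f"dangling wiring reference: {conn.src.signal!r} is not an output of "
                f"{conn.src.instance!r}"
            )
        if conn.dst.signal not in inst_map[conn.dst.instance].inputs:
            raise CRNError(
                f"dangling wiring reference: {conn.dst.signal!r} is not an input of "
                f"{conn.dst.instance!r}"
            )

    # union-find over ports with parity (crossed connections flip polarity)
    parent: dict[Port, Port] = {}
    parity: dict[Port, int] = {}

    def find(p: Port) -> tuple[Port, int]:
        if p not in parent:
            parent[p], parity[p] = p, 0
        if parent[p] == p:
            return p, parity[p]
        root, par = find(parent[p])
        parent[p], parity[p] = root, (parity[p] + par) % 2
        return parent[p], parity[p]

    def union(a: Port, b: Port, flip: int):
        ra, pa = find(a)
        rb, pb = find(b)
        if ra == rb:
            if (pa + pb) % 2 != flip % 2:
                raise CRNError("inconsistent rail polarity in wiring")
            return
        parent[ra] = rb
        parity[ra] = (pa + pb + flip) % 2

    all_ports = [
        Port(inst, sig)
        for inst, circ in instances
        for sig in [*circ.inputs, *circ.outputs]
    ]
    for p in all_ports:
        find(p)
    for conn in connections:
        union(conn.src, conn.dst, 1 if conn.crossed else 0)

    # assign net names
    net_name: dict[Port, str] = {}
    net_parity_ref: dict[Port, int] = {}
    for port, ext in [*expose_inputs, *expose_outputs]:
        root, par = find(port)
        if root in net_name and net_name[root] != ext:
            raise CRNError(f"net exposed under two names: {net_name[root]}, {ext}")
        net_name[root] = ext
        net_parity_ref[root] = par
    k = 0
    for p in all_ports:
        root, _ = find(p)
        if root not in net_name:
            k += 1
            net_name[root] = f"lam{k}"
            net_parity_ref[root] = 0

    # species mapping per instance
    rename = dict(rename or {})
    species_map: dict[str, dict[str, str]] = {}
    for inst, circ in instances:
        m: dict[str, str] = {}
        for sig in [*circ.inputs, *circ.outputs]:
            root, par = find(Port(inst, sig))
            base = net_name[root]
            flipped = (par + net_parity_ref[root]) % 2 == 1
            m[f"{sig}hi"] = f"{base}lo" if flipped else f"{base}hi"
            m[f"{sig}lo"] = f"{base}hi" if flipped else f"{base}lo"
        for sp in circ.internals:
            m[sp] = rename.get(f"{inst}.{sp}", f"{inst}.{sp}")
        species_map[inst] = m

    reactions: list[Reaction] = []
    init: dict[str, float] = {}
    for inst, circ in instances:
        m = species_map[inst]
        for rxn in circ.crs.reactions:
            reactions.append(rxn.rename(m))
        for sp, cnt in zip(circ.crs.names, circ.crs.x0):
            if cnt:
                tgt = m[sp]
                init[tgt] = init.get(tgt, 0.0) + float(cnt)
    for sp, cnt in (extra_initial or {}).items():
        init[sp] = init.get(sp, 0.0) + float(cnt)

    in_names = list(dict.fromkeys(ext for _, ext in expose_inputs))
    out_names = list(dict.fromkeys(ext for _, ext in expose_outputs))
    # exposed rails must exist even if no reaction touches them
    extra = []
    for base in [*in_names, *out_names]:
        extra.extend([f"{base}hi", f"{base}lo"])
    crs = CRS.from_reactions(reactions, init=init, N=instances[0][1].crs.N, extra_species=extra)
    return DualRailCircuit(crs, inputs=in_names, outputs=out_names, name=name)


def compose_series(
    first: DualRailCircuit,
    second: DualRailCircuit,
    wiring: Mapping[str, str],
    crossed: Iterable[str] = (),
    names: tuple[str, str] = ("s1", "s2"),
    name: str | None = None,
) -> DualRailCircuit:
    """Series composition: some outputs of ``first`` drive inputs of ``second``.

    ``wiring`` maps output signal names of ``first`` to input signal names
    of ``second``; wired pairs become internal ``lam<k>`` rails.  Signals in
    ``crossed`` are wired with dual-rail inversion (hi to lo), which is a
    free NOT.  The composite's inputs are the inputs of ``first`` (plus any
    unwired inputs of ``second``); its outputs are the outputs of ``second``
    (plus unwired outputs of ``first``).
    """
    if len(set(wiring.values())) != len(wiring):
        raise CRNError("wiring must be one-to-one")
    crossed = set(crossed)
    if not crossed <= set(wiring):
        raise CRNError("crossed flags must reference wired signals")
    n1, n2 = names
    conns = [
        Connection(Port(n1, src), Port(n2, dst), crossed=src in crossed)
        for src, dst in wiring.items()
    ]
    expose_in = [(Port(n1, s), s) for s in first.inputs]
    expose_in += [(Port(n2, s), s) for s in second.inputs if s not in set(wiring.values())]
    expose_out = [(Port(n2, s), s) for s in second.outputs]
    expose_out += [(Port(n1, s), s) for s in first.outputs if s not in wiring]
    return compose(
        [(n1, first), (n2, second)],
        conns,
        expose_inputs=expose_in,
        expose_outputs=expose_out,
        name=name or f"{first.name}>>{second.name}",
    )
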