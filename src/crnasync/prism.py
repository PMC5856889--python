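"""Export a CRS as a PRISM CTMC model.

One bounded integer variable per species, one guarded command per
reaction.  Each command's rate expression equals the CTMC transition rate
``N * alpha_tau(x)`` of the stochastic semantics: ``k*A`` for A -> ...,
``k*A*B`` for A + B -> ..., ``k*A*(A-1)`` for A + A -> ... (at N = 1).
Species and reaction order follow declaration order, so exports are
deterministic.
"""

from __future__ import annotations

from .core import CRS, CRNError, Reaction, conserved_totals, rail_group_total

__all__ = ["export_prism"]


def _sanitize(name: str) -> str:
    return name.replace(".", "_")


def _rate_expression(rxn: Reaction) -> str:
    k = rxn.rate
    prefix = "" if k == 1.0 else f"{k:g}*"
    r = list(rxn.reactants)
    if rxn.order == 1:
        return f"{prefix}{_sanitize(r[0][0])}"
    if len(r) == 1:  # A + A
        a = _sanitize(r[0][0])
        return f"{prefix}{a}*({a}-1)"
    a, b = _sanitize(r[0][0]), _sanitize(r[1][0])
    return f"{prefix}{a}*{b}"


def _guard(rxn: Reaction, bounds: dict[str, int]) -> str:
    clauses = []
    for name, c in rxn.reactants:
        clauses.append(f"{_sanitize(name)}>={c}")
    for name, d in rxn.net().items():
        if d > 0:
            clauses.append(f"{_sanitize(name)}<={bounds[name] - d}")
    return " & ".join(clauses) if clauses else "true"


def export_prism(crs: CRS, bounds: dict[str, int] | None = None) -> str:
    """Render a CRS as a PRISM ``ctmc`` model document.

    ``bounds`` caps each variable; missing bounds are taken from the
    species' conserved pool total.  A species in no conserved pool and
    without an explicit bound is an error (its counts are unbounded).
    """
    if crs.N != 1.0:
        raise CRNError("PRISM export assumes N = 1 (counts == concentrations)")
    bounds = dict(bounds or {})
    groups = conserved_totals(crs, max_weighted_species=0)
    for sp in crs.names:
        if sp in bounds:
            continue
        try:
            bounds[sp] = int(round(rail_group_total(crs, sp, groups)))
        except CRNError:
            raise CRNError(f"missing bound for unconserved species {sp!r}") from None
    lines = ["ctmc", "", "module crn"]
    for sp, x0 in zip(crs.names, crs.x0):
        lines.append(
            f"  {_sanitize(sp)} : [0..{bounds[sp]}] init {int(round(x0))};"
        )
    lines.append("")
    for rxn in crs.reactions:
        updates = [
            f"({_sanitize(name)}'={_sanitize(name)}{d:+d})" for name, d in sorted(rxn.net().items())
        ]
        update = " & ".join(updates) if updates else "true"
        lines.append(f"  [] {_guard(rxn, bounds)} -> {_rate_expression(rxn)} : {update};")
    lines.append("endmodule")
    return "\n".join(lines) + "\n"
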