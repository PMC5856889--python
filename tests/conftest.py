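import numpy as np
import pytest

import crnasync as ca


@pytest.fixture
def motif():
    return ca.build_motif().with_initial({"Xhi": 10, "Ylo": 10})


@pytest.fixture
def dual_rail_am_lowlow():
    return ca.build_dual_rail_am(initial_output=1).with_input_assignment({"X": 0, "Y": 0})


@pytest.fixture
def dual_rail_am_mixed():
    """The reference failure-mode configuration: X=0, Y=1, output high."""
    return ca.build_dual_rail_am(initial_output=1).with_input_assignment({"X": 0, "Y": 1})


def canonical_internal_names(circuit: ca.DualRailCircuit):
    """Rename non-port species to n1, n2, ... in appearance order (for
    structural comparison of composites up to internal renaming)."""
    mapping = {}
    k = 0
    ports = set()
    for base in [*circuit.inputs, *circuit.outputs]:
        ports.update(circuit.rail(base))
    for name in circuit.crs.names:
        if name not in ports:
            k += 1
            mapping[name] = f"n{k}"
    rxns = frozenset(
        (r.rename(mapping).reactants, r.rename(mapping).products, r.rate)
        for r in circuit.crs.reactions
    )
    init = {
        mapping.get(n, n): c for n, c in zip(circuit.crs.names, circuit.crs.x0) if c
    }
    return rxns, init


@pytest.fixture
def canonicalize():
    return canonical_internal_names
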