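# crnasync

Chemical reaction network (CRN) designs for **asynchronous logic circuits**,
with the simulation and validation machinery needed to certify them.

Molecular computers built from CRNs usually emulate *synchronous* logic and
therefore need a chemical clock, which is hard to realize. Asynchronous
design replaces the clock with handshaking, and its cornerstone — the Muller
C-element — can be built from a strikingly small chemical system: the
Approximate Majority (AM) population protocol

```
X + Y  -> X + λ        Y + X  -> Y + λ
X + λ  -> X + X        Y + λ  -> Y + Y
```

which drives two competing populations to a fast, bistable consensus through
an undecided intermediary λ. This package provides:

* **Components** (`crnasync.components`): the dual-rail AM, a two-stage
  AM-based Muller C-element, latches (simple and with reset), an arbiter,
  fork/join control flow, the six dual-rail logic gates (NOT, AND, OR, NAND,
  NOR, XOR), a Muller C-pipeline, an asynchronous queue, and a 3-bit
  ripple-carry adder — every reaction bi-molecular, catalytic
  (`X + Y -> X + Z`) and with unit rate.
* **Semantics** (`crnasync.semantics`): deterministic mass-action ODEs
  `dΦ/dt = Σ_τ υ_τ k_τ Π Φ^r_τ`; the exact stochastic semantics (CTMC with
  propensities `α_τ(x) = k_τ (Π r_i!)/N^{|r|−1} Π C(x_i, r_i)`, sampled with
  the Gillespie direct method); and the linear noise approximation
  (`dC/dt = JC + CJᵀ + W`, mean ≡ N·Φ).
* **Validation** (`crnasync.validation`): dual-rail threshold logic
  (high ⇔ mean > 0.8·max − 1SD, low ⇔ mean < 0.2·max + 1SD), truth-table
  sweeps over all Boolean input assignments, debounced first-passage times,
  and Monte-Carlo estimation of time-bounded temporal properties
  (`P[ (Bhi < 8) U[0,3] (Ahi > 8) ]`) over seeded SSA paths.
* **Interface** (`crnasync.cli`, `crnasync.prism`, `crnasync.scenarios`): a
  plain-text reaction format with parser/serializer, trajectory CSVs, PRISM
  CTMC model export, a registry of ready-made experiment scenarios, and the
  `crnasync` command-line tool.

## Worked example

Build the dual-rail AM (the naive one-stage C-element candidate), drive it
with the *disagreeing* inputs X = 0, Y = 1 from a stored output of 1, and
watch it fail — then see the two-stage C-element hold:

```python
import crnasync as ca

am = ca.build_dual_rail_am(initial_output=1).with_input_assignment({"X": 0, "Y": 1})
traj = ca.simulate_lna(am.crs, 1.0)
print(round(traj.value("Zhi", 0.3), 2), round(traj.value("lam", 0.3), 2))
# 6.18 3.82   <- Z_hi stuck at ~6 molecules, below the 8-molecule bar

c = ca.build_c_element(initial_output=1).with_input_assignment({"X": 0, "Y": 1})
traj = ca.simulate_ode(c.crs, 2.0)
print(float(traj["Zhi"].min()))
# 10.0        <- the second AM stage amplifies the majority: output unmoved
```

The mixed steady state is analytic: with both drives at 10 molecules the
held rail settles at `(√500 − 10)/2 ≈ 6.18` with `λ ≈ 3.82` — exactly what
the simulation shows, and the reason a single AM stage is not a C-element.

From the shell:

```sh
crnasync component emit c_element        # reaction-format document
crnasync validate gate_xor               # truth-table sweep (PASS/FAIL)
crnasync scenario pipeline-wave --out-dir out/   # pipeline experiment + CSV
crnasync property pipeline 'P[ F[0,10] Chi > 8 ]' --set Reqhi=10
```

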