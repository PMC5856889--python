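# Methods

## Model

A chemical reaction network is a finite species set Λ with reactions
τ = (r_τ, p_τ, k_τ); a chemical reaction system adds an integer initial
configuration x₀ and a volumetric factor N relating counts to
concentrations (z = x/N). Everything shipped here uses **bi-molecular
catalytic reactions** `X + Y -> X + Z` with **uniform rate k = 1** and
**N = 1**, so counts and concentrations coincide and every design's
internal pools conserve their totals (all reactions are 2→2). Time is in
seconds of model time under this rate convention; all printed times in the
package's documentation presuppose it.

Boolean signals are dual-rail: signal X is the species pair (X_hi, X_lo),
with 1 ⇔ the high rail populated, 0 ⇔ the low rail populated, and an
optional neutral state in which the signal's conserved pool sits in an
internal λ species. Correctness is thresholded: a high rail is correct
when its mean exceeds `0.8·max − sd_multiplier·SD`, a low rail when its
mean is below `0.2·max + sd_multiplier·SD`, where `max` is the rail's
**conserved-pool total at t = 0** (well-defined before any simulation; the
pools differ per rail for the ladder gates) and SD is zero under the
deterministic semantics, the LNA standard deviation otherwise.
`sd_multiplier` defaults to 1.

## Semantics

* **Deterministic**: `dΦ/dt = Σ_τ υ_τ · k_τ Π_i Φ_i^{r_τ,i}`, integrated
  with an adaptive explicit Runge–Kutta scheme (rtol 1e−8, atol 1e−10);
  the networks are non-stiff at populations of tens of molecules with
  k = 1.
* **Stochastic**: the CTMC with propensity
  `α_τ(x) = k_τ (Π_i r_{i,τ}!)/N^{|r_τ|−1} Π_i C(x(λ_i), r_{i,τ})` and
  transition rate `N·α_τ`. Paths are sampled exactly with the Gillespie
  direct method: reactions scanned in declaration order, cumulative-sum
  inversion, two uniforms per jump. A fixed seed is bitwise reproducible;
  a family of paths derives per-path seeds as
  `SeedSequence(entropy=master, spawn_key=(i,))`. Absorbing states hold to
  the horizon.
* **LNA**: Y = N·Φ + √N·Z with `dC[Z]/dt = J C + C Jᵀ + W`, `C[Z(0)] = 0`,
  `W = Σ_τ υ_τ υ_τᵀ k_τ Π Φ^r`. Mean and covariance are integrated
  jointly; the covariance is symmetrized inside the right-hand side, and a
  diagonal entry below −1e−9 raises while smaller negatives clamp to zero
  when standard deviations are read. The LNA mean coincides with the ODE
  solution to < 1e−6 on every shipped component (tested).

Signal changes are modelled as **piecewise network redefinition**: an
injection event at time t adds reactions (e.g. `Req_hi -> Req_lo`, k = 1);
each engine integrates/simulates to t, extends the reaction set and
continues from the reached state. Rates never vary in time.

## Component transcriptions

The circuit designs are documented diagrammatically in the design literature; the
reaction lists here were fixed so that every *textual* description and
every *printed* measurement agree. The decisions that required judgement:

* **Dual-rail AM (one-stage C-element candidate).** The inputs gate the
  two halves of each conversion: X_hi catalyses `Z_lo -> λ` and Y_hi
  catalyses `λ -> Z_hi` (mirror for the low rails), and each output rail
  catalyses both steps of its own conversion (self-amplification); 8
  reactions. This is the only split of "input catalyses an intermediary
  species λ … over two reactions" we found that reproduces the reference
  mixed-input failure state, which is analytic here: with drive
  populations of 10, `Z_hi → (√500−10)/2 ≈ 6.18` and `λ → 3.82` with
  Z_lo ≡ 0 (the alternative transcription in which every input gates both
  steps gives 3.9/3.3 and breaks the C-element hold after composition).
* **C-element.** Two AM stages in series: the dual-rail AM over (X, Y)
  produces an internal pair W amplified by a single-input (arbiter-style)
  AM into Z. The internal chain initializes consistently with the declared
  output (output 1 ⇒ W_hi and Z_hi full; 0 ⇒ the mirror; neutral ⇒ both λ
  pools full) — the configuration the element would hold after stabilising
  there. Because the wrong-side rail of W stays exactly 0 on mixed inputs,
  the second stage pins the output: the "unchanged" rows hold with zero
  deviation in the deterministic semantics.
* **Gates.** AND/OR/NAND/NOR pair a two-step conversion ladder
  (`λ2 ->(input₁) λ1 ->(input₂) rail`) on the rail whose minterm is a
  conjunction with a one-step pool on the disjunction rail, plus mutual
  suppression; the suppressing rail sends its opponent to the ladder
  *bottom* (the literal reading of the design description), which is what makes
  the AND gate's output cross its threshold at 0.78 s rather than 0.63 s.
  Ladder intermediates start empty; sources and disjunction pools start at
  10. XOR uses one shared source pool per output rail drained through both
  catalysis orders of its two minterms with output self-catalysis on the
  second step, plus mutual suppression; four *separate* branch pools would
  make each rail's conserved group total 20 while a single branch delivers
  only 10 molecules, so the 0.8·max threshold could never be met.
* **Pipeline.** n C-elements; stage i is *triggered* by a fork branch of
  stage i−1's output (stage 1: Req directly) and *guarded* by the inverted
  fork branch of stage i+1's output. Triggers gate the λ→rail steps (a
  lone request can lift a neutral element), guards the rail→λ steps (a
  disagreeing successor holds the element in the mixed state the second AM
  stage filters out). Fork branches are single-input AM pools of their
  own — real components, not wires — which separates the stage outputs
  enough that the rise ordering A, B, C holds in ≥ 19/20 stochastic paths.
  Inversion is a rail crossing (dual-rail NOT is a wire swap). The **last
  stage's guard is its own inverted fork branch, wire-ORed with the
  inverted Acc rails**: a strict C-element guarded only by an absent
  acknowledge could never propagate a falling wave, yet the open-ended
  experiment (only Req driven) must; with Acc driven the stage is gated
  like any other.
* **Queue.** The pipeline plus one reset latch per stage, all reading the
  shared data rails Am. The data preloads a staging pool
  (`Am_hi` cat `λ -> ν⁺`); only the stage control species (the C-element's
  high output rail) converts staged molecules onto the latch output, so a
  latch can never fire before its stage. The opposite data rail drains the
  latch output back to λ (overwrite), and R_hi resets to neutral.
* **Full adder / ripple-carry adder.** Sum = XOR(XOR(A,B), Cin),
  Cout = OR(AND(A,B), AND(XOR(A,B), Cin)) — the textbook decomposition
  (a carry needs two conjunctions; no three-gate OR/OR/AND carry exists).
  The ripple-carry adder interleaves three adders with the 3-stage
  pipeline: each bit's input rails are released from staging pools by its
  stage control, and each carry feeds the next adder's carry-in.
  Late-arriving carries overwrite stale gate outputs via the suppression
  arcs.

## Known deviations and limitations

* **Latch at 0.2 s.** No uniform-rate design moves 10 molecules across an
  output pool in 0.2 s from a cold start: a one-step catalytic drive at
  catalyst population 10 gives exactly `10(1−e^{−2}) ≈ 8.65` molecules at
  0.2 s (the simple latch; measured), and any λ-centred two-step design is
  slower (≈ 5.8). The package reports the computed value.
* **Pipeline falling wave at 2 s.** With the k = 1 injection
  `Req_hi -> Req_lo` at t = 1 s the request converts with a 0.69 s
  half-life, and each stage flip costs ~0.4 s (two sequential AM
  conversions), so the low rails complete at ≈ 3 s, not 2 s; the orderings
  and terminal values hold. While the request is mid-conversion both its
  rails are populated (an ill-defined dual-rail value) and the residual
  high rail can transiently re-seed the self-amplifying AM stages: the
  deterministic trajectories glitch once before settling. An instantaneous
  request swap gives a monotone wave (tested).
* The ODE semantics treats a fractional residue of a rail as an active
  catalyst; thresholded conclusions are therefore read at stated times,
  not at exact fixed points (several pools converge only asymptotically).
* `conserved_totals` finds unit-weight pools structurally and searches the
  exact rational null space for weighted vectors only on small networks;
  for the shipped components all rail pools are unit-weight.
* The PRISM export covers the CTMC model (bounded variables from conserved
  pools, command rates = `N·α_τ`); invoking PRISM itself, CME transient
  solution and uniformization are out of scope, as are tau-leaping, hybrid
  semantics and moment closures beyond the LNA.

## Problem sizes

Everything is desk-scale by construction: the largest shipped network is
the staged 3-bit ripple-carry adder (≈ 170 species, ≈ 280 reactions),
simulated to 10 s of model time in well under a second; Monte-Carlo
estimates use 20 paths (the validation default; 200 for engine
cross-checks in the tests). The full test suite runs in a few seconds.
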