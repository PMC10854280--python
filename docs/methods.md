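# Methods

## Model and scope

The package works with *synchronous* Boolean networks: `n` ordered variables,
one update function each, all updated simultaneously, so the dynamics is a
deterministic map `F : {0,1}^n → {0,1}^n` whose functional graph has
out-degree one.  Asynchronous and stochastic update schemes, ODE semantics,
and sampling-based attractor detection are out of scope.  Update functions
are stored as truth tables over their own ordered input lists; expressions
are parsed once, tabulated, and arity-reduced to essential inputs (inputs
whose toggling never changes the output are dropped, with an audit record on
the function).  Bit order is fixed throughout: the first variable is the
leftmost character of a state string and the most significant bit of a state
index.

## Attractors and enumeration limits

Attractors are found by exhaustive traversal of the functional graph:
integer-encoded states, a compiled per-variable successor, and path-marking
cycle detection, `O(2^n)` time and memory.  Exhaustive routines refuse above
a configurable cap (default `n = 24`) and point the caller to the modular
route.  Attractor representation is canonical — the lexicographically
smallest rotation of the state sequence first, attractor lists sorted by
(length, first state) — so all outputs are deterministic.

## Decomposition and compositional dynamics

Modules are the restrictions of the network to the strongly connected
components of its wiring diagram (computed with networkx).  A cross-module
input `x` becomes an external parameter deterministically named `e_<x>`
(collision-checked against existing names).  Modules are numbered along a
topological order of the quotient DAG, ties broken by smallest original
variable index.  The semidirect product substitutes coupled upstream
variables back for the externals; decompose-then-recompose is truth-table
exact.

Driven (non-autonomous) dynamics: a module under a periodic drive `g(t)` of
period `p` is analyzed on the product space of drive phase and module state
(`p · 2^m` nodes, again out-degree one).  Each product cycle projects to a
periodic orbit of module states, which is reduced to its minimal period —
necessary because a driven module may revisit a state within one period.
Direct sums are assembled by aligning a downstream attractor against the
upstream drive at every cyclic shift and keeping each consistent alignment;
a steady state on either side admits exactly one alignment, while coupling
two genuine cycles can legitimately yield several composed attractors (one
per relative phase), all of which are returned rather than an arbitrary
selection.  `modular_attractors` folds this along the topological order and
is validated in the test suite against whole-network enumeration.

## Control operators and assembly

Edge control pins one input of one target rule to a constant (deletion 0,
constant expression 1) while keeping the input listed — it becomes
non-essential, which is how decoupling is verified.  Node control replaces a
rule by constant 0 (knock-out), constant 1 (constant expression), or its
negation; negation is rejected by default as biologically impractical and
can be re-enabled by flag.  Within one rule, edge controls are applied
before node controls; node controls dominate either way, so the order is a
convention, not a semantic choice.

`assemble_modular_control` walks the modules in topological order.  At each
step it *checks* (never assumes) that the given module control stabilizes
the driven module at the given target, requires a steady state on one side
of the coupling — falling back to verifying that the driven periodic orbit
is unique, the condition that replaces the steady-state requirement for
non-autonomous stabilization — and finally re-verifies the assembled claim
by whole-network enumeration whenever the network fits the cap, raising
rather than passing silently on any discrepancy.

Module-level control search is deliberately plain: breadth-first over
control-set cardinality, node candidates before edge candidates, both in
variable-index order, so the returned family of minimal stabilizing sets is
reproducible and superset-free.  A target may be an attractor the control
itself creates; stabilization is always judged on the controlled network.
Stable-motif, feedback-vertex-set, trap-space and algebraic search methods
are out of scope; the exhaustive search stands in for them at module scale.

## Canalizing layers

The layer decomposition strips, each round, every variable that canalizes
the current function, then restricts to the branch where none received its
canalizing input.  Variables of one round provably share one canalized
output; consecutive outputs alternate, so the additive constant `q` equals
the first layer's output and `b_i = q + i - 1 (mod 2)`.  The core polynomial
is the final non-canalizing remainder, sign-corrected by the nesting parity
(`pC = F_final + r - 1 + q` over GF(2)); for a nested canalizing function it
is the constant 1.  Two degenerate conventions fix uniqueness: a function of
a single essential variable takes the orientation with output 0 (forcing
`q = 0`), and a trailing singleton layer over core 1 cannot occur (it would
merge into the layer above — the generator rejects such requested
structures).  Layer extraction is exponential in arity, which is acceptable
because curated biological rules have small arity; a hard cap of 16 inputs
is enforced with a clear error, and constant functions are rejected with a
distinct error type.  `reconstruct` tabulates the extended monomial form
back; the round-trip identity is the executable uniqueness check.

## Exclusion from the control search

Phenotypes are marker variables with required values; an attractor matches
only if every its state agrees — an oscillating marker never matches.  Two
exclusion routes are reported:

* **Reachability**: a module with no quotient-DAG path to any marker module
  cannot influence the phenotype.  Soundness is tested as equality of the
  *sets* of observable marker patterns (minimal-period, rotation-canonical
  marker sequences of attractors) before and after deleting the module; the
  multiset version of this statement is false, since a deleted module with
  several attractors collapses several product attractors into one.
* **Decoupling**: for a quotient edge `i → j`, each bridging node's rule is
  layer-decomposed and every regulator tagged with its source module and
  layer; `ℓ` is the most dominant layer holding an upstream regulator
  (`r + 1` if they only appear in the core).  If upstream regulators occupy
  layer 1, pinning such a regulator's edge to its canalizing input is
  proposed (edge route, preferred: fewest assumptions); otherwise any
  non-upstream variable in a layer more dominant than `ℓ` yields a
  node-control proposal.  Every proposal is verified on the truth table: the
  controlled bridging rule must be non-essential in all upstream regulators.
  Multiple bridging nodes are handled by applying the procedure per node;
  a strict single-bridge reading is not enforced.

`excludable_modules` additionally requires that no *other* successor of the
excluded module can reach a marker module: cutting only the direct bridges
into `j` must sever all influence on the phenotype.  This is slightly
stronger than the bare chain condition (every path from `i` to a marker
module passes through `j`) and closes a gap that condition alone leaves open
when influence re-enters `j` through an intermediate module.

## Synthetic data generator

`generate_modular_network` emulates the structure of curated regulatory
models: prescribed module sizes with an internal directed cycle per module
(guaranteeing strong connectivity) plus random chords (probability 0.25),
at least one cross-module input per requested quotient edge, in-degrees
capped at 5, and rules drawn from the nested canalizing family that
dominates published biological models (a uniform-random family is available
for contrast; its rules are resampled until essential in every designed
input, so the realized wiring always equals the design).  All draws come
from one numpy generator and are bit-reproducible per seed.  What the
generator does *not* emulate: the long-tailed in-degree distributions,
autoregulation patterns and rule redundancy of real curated models — so
passing property suites demonstrates correctness of the algorithms under
the stated structural assumptions, not biological fidelity of any particular
random instance.  Property suites run at module sizes 2–4 (networks of 4–8
variables, fifty to a hundred instances), where exhaustive oracles are exact
and fast.

## Known limitations

* All global verification is exhaustive; beyond the cap only the modular
  route is available, and a network whose largest module exceeds the cap
  cannot be analyzed exactly.
* The exhaustive module search optimizes cardinality only and enumerates
  `O(candidates^k)` combinations; it is intended for modules of a handful of
  variables, matching the decomposition use-case.
* The 16-node T-LGL leukemia model referenced in the documentation is not
  redistributed (only its DISC rule is public in the source analysis);
  `load_tlgl` accepts a user-supplied rule file and the exclusion pipeline
  applies unchanged.
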