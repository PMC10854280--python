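# boolmod

Modular decomposition, canalization analysis, and phenotype control of
synchronous Boolean network models of gene regulation.

## The problem

A synchronous Boolean network on variables `x1, …, xn` is a map
`F = (f1, …, fn) : {0,1}^n → {0,1}^n`; every variable is updated at once, and
the long-run behaviour is captured by the *attractors* — the minimal sets
`C` with `F(C) = C`.  In models of intracellular regulation the attractors
correspond to cell phenotypes, and the practical question is *phenotype
control*: which gene knock-outs, constant expressions, or interaction
blockings (node and edge controls) force the network into a single desired
attractor?  Exhaustive search over all `2^n` states and all control
combinations collapses quickly; this package makes the problem tractable by
exploiting two structural features that real regulatory networks exhibit:

**Modularity.**  The wiring diagram (an edge `xi → xj` whenever `fj` depends
essentially on `xi`) splits into strongly connected components.  Restricting
`F` to each component gives a *module* — a smaller Boolean network whose
cross-module inputs become external parameters — and the network is the
iterated semidirect product `F = F1 ⋊ F2 ⋊ ⋯` of its modules along the
acyclic quotient graph.  Attractors compose: every attractor of `F` is a
direct sum `C1 ⊕ C2` of an upstream attractor and an attractor of the
downstream module driven by it, and — the key control result — if `μ1`
stabilizes `F1` at `C1` and `μ2` stabilizes the driven `F2` at `C2`, with at
least one of them a steady state, then `μ = (μ1, μ2)` stabilizes `F` at
`C1 ⊕ C2`.  Controls can therefore be found one module at a time.

**Canalization.**  Almost all update rules in published biological models
are (nested) canalizing: some input value alone decides the output.  Every
non-constant Boolean function has a unique stratification

    f = M1 ( M2 ( ⋯ ( Mr · pC + 1 ) ⋯ ) + 1 ) + q        (over GF(2))

into layers `Mi = Π (xij + aij)` of decreasing dominance with core
polynomial `pC` and layer structure `(k1, …, kr)`.  If the inputs a
downstream *bridging node* receives from an upstream module never occupy its
most dominant layer, fixing a more dominant variable to its canalizing input
*decouples* the modules; if they do occupy it, a single edge control pinning
that input does.  Either way the upstream module drops out of the control
search entirely, as do modules with no path to the phenotype markers.

## Worked example

Models are plain-text rule files (`target, expression` with `!`, `&`, `|`):

```
x1, x2
x2, x1
x3, x2 & x4
x4, x3
```

```
$ boolmod attractors toy.bnet
variables: x1 x2 x3 x4
{0000}  (steady state)
{1100}  (steady state)
{1111}  (steady state)
{0100,1000}  (cycle of length 2)
{0101,1010}  (cycle of length 2)
{1101,1110}  (cycle of length 2)
```

Six attractors; suppose the goal is to force `1111`.  The network is
decomposable —

```
$ boolmod decompose toy.bnet
module 0: x1 x2
module 1: x3 x4 (externals: e_x2)
edge: 0 -> 1  via {'x2': 'e_x2'}
```

— so minimal controls exist module by module, and exhaustive search over
edge controls confirms the assembled pairs:

```
$ boolmod control-search toy.bnet --target 1111 --kinds edge
minimal control sets of size 2 stabilizing 1111:
  {x1->1 x2, x3->1 x4}
  {x1->1 x2, x4->1 x3}
  {x2->1 x1, x3->1 x4}
  {x2->1 x1, x4->1 x3}
```

`x1->1 x2` means "constantly express the interaction x1 → x2" (pin the input
`x1` to 1 inside the rule of `x2`).  One control per module suffices: the
first stabilizes the upstream module at the steady state `11`, the second
stabilizes the driven downstream module at `11`, and by the modular
assembly theorem their union leaves `{1111}` as the only attractor of the
full network — which the output above verifies by enumeration.

Canalizing structure is reported per rule; on the death-receptor rule of the
T-LGL leukemia model:

```
$ boolmod layers -e "Ceramide | (Fas & !FLIP)"
f: structure (1, 2), depth 3, NCF=True
  layer 1: {Ceramide:1} -> 1
  layer 2: {Fas:0, FLIP:1} -> 0
  core: 1
```

`Ceramide = 1` alone forces the output to 1 (layer 1); failing that, `Fas=0`
or `FLIP=1` forces 0.  Since Ceramide belongs to the upstream module and
occupies the most dominant layer, constantly expressing the single edge
Ceramide → DISC decouples the two modules — the upstream module never needs
to be searched (`boolmod exclude` automates this argument, together with the
reachability exclusion of modules that cannot influence the markers).

The same operations are available as a library (`boolmod.attractors`,
`decompose`, `modular_attractors`, `search_module_control`,
`assemble_modular_control`, `layer_decomposition`, `excludable_modules`,
`generate_modular_network`, …); see `docs/methods.md` for the model
assumptions and numerical conventions.

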