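# Methods

This note records the modeling semantics, numerical choices, and the open
design decisions behind boolpath, in the order the pipeline runs.

## Process-description → activity-flow translation

A process-description (PD) graph holds species (with compartment,
active/inactive and receptor flags, and state modifications) and reactions
of type `state_transition`, `association`, or `transport`, each with
reactants, products, and signed modifiers. Four rewriting rules reduce the
mechanism to causal influences; they are applied in the fixed order
1→2→3→4 and iterated to a fixpoint (cap: 10·|reactions| sweeps, error
beyond it):

1. receptor–ligand association: the receptor reactant is dropped
   (receptor availability is treated as given);
2. protein–protein association: all reactants are dropped and the
   reaction's modifiers act directly on the complex product;
3. an inactive species participating in exactly one reaction is dropped
   (it only encodes the pre-activation form);
4. a transport reaction whose reactant and product share a biomolecule
   name (different compartments) is collapsed onto the product, with
   every other reaction touching the reactant re-linked.

Receptor identification is an explicit per-species flag in the exchange
format: the glyph classes a diagram editor would supply are out of scope,
and an explicit flag is auditable. Rule 4 requires matching display
names; species without names never merge.

**Logic inference.** Each producing reaction contributes the AND of its
remaining reactants and positive modifiers; contributions are OR-ed over
producing reactions; negative modifiers veto. The default combinator is
dominant inhibition — `target = (OR of routes) AND NOT (OR of all
negative modifiers)` — because that is what the canonical published
single-route example (activating complex + counteracting enzyme) shows,
and a published general combinator does not exist. This is the single
most consequential modeling choice in the translation; the per-route
alternative (`inhibitor_mode="or"`, each route vetoed only by its own
inhibitors) is implemented and tested, and whether reactants of
non-association reactions should always be AND-ed is likewise left as a
documented choice rather than guessed. A produced species whose
regulators all vanish in reduction degrades to a free input with a
warning.

## Topology

Centralities are computed on the directed regulator→target graph,
unweighted and unnormalized, endpoints excluded (`s ≠ v ≠ t`) — the
standard convention. Raw counts rather than [0,1] normalization because
practitioners compare these magnitudes across models of very different
size where the count scale itself is informative. Betweenness delegates
to networkx (Brandes); stress is computed in-repo from all-pairs BFS
distance and path-count matrices via
`g_st(v) = σ(s,v)·σ(v,t)` iff `d(s,v)+d(v,t) = d(s,t)`. An `undirected`
flag symmetrizes first; directed is the default. Feedback loops are SCCs
of size ≥ 2 plus self-loop singletons. `top_quantile` defaults to the top
quartile of the *nonzero* score distribution, ties included — zero-score
nodes (sources/sinks) would otherwise dominate the quantile.

## Dynamics

States are 0/1 tuples in node order, packed as integers (node i = bit i)
for state-space work. Synchronous update recomputes every node at once;
asynchronous recomputes one. Synchronous state-transition graphs keep
self-loops (fixed points visible as loops); asynchronous ones omit them,
so steady states are exactly the sink states. Full STG enumeration is
capped at 20 nodes by default; beyond that a reachable-set build from
given initial states is required.

**Stochastic engine.** The network runs as a continuous-time Markov
chain: in state `s`, each node with `B_i(s) ≠ s_i` may flip, with
propensity equal to its up-rate (flip to 1) or down-rate (flip to 0);
the jump time is exponential in the summed propensity (Gillespie). Both
rates default to 1.0 per node: no rate data exists in the intended use
case, and unit rates make one time unit ≈ one expected update per
eligible node. Graded activity levels from data tables are mapped to
*initial ON-probabilities*, not to rates — rates change path statistics,
initial conditions only the starting mixture, and the latter is what a
bounded activity level (e.g. 0.84 on [0,1]) actually measures.
Unspecified initial conditions are independent Bernoulli(0.5) per node.
ON-probabilities are tallied at the right edge of each time bin from the
held state; standard errors are binomial `sqrt(p(1−p)/m)`. Every
estimate records its seed.

The probabilistic-update view (per-node conditional probabilities given
parents) is realized deterministically: θ_i puts probability 1 on
`B_i`'s output. A per-function noise parameter was considered and left
out of scope; nothing downstream consumes it.

## Attractor search

Five strategies, cross-checked in the test suite:

* **Exhaustive synchronous** (cap 24 nodes, chunked vectorized successor
  table): walks the functional graph, labels every state, exact basin
  sizes that provably sum to 2^n.
* **SAT fixed points**: `x_i ↔ B_i(x)` Tseitin-encoded; models enumerated
  with blocking clauses. The bundled solver is a plain DPLL with unit
  propagation (DIMACS in/out, so any external solver can be dropped in);
  the encodings here propagate almost fully from the free inputs, so
  branching is light even at a few hundred variables.
* **SAT bounded cycles**: L-step unrolling with pairwise-distinct states;
  found cycles are blocked in all rotations. No loop-length schedule is
  imposed; L is a caller/CLI parameter.
* **Decomposition**: SCC condensation in topological order; block-local
  attractors under frozen upstream values, composed across blocks over
  all relative phases. Composition freezes each upstream block at the
  first state of its local attractor, so candidates needing time-varying
  upstream context are wrong — every candidate therefore carries a
  `verified` flag from a direct synchronous check on the full network,
  and unverified candidates are exactly the spurious ones. This
  approximation error is inherent to the strategy, not a defect to fix.
* **Heuristic**: synchronous iteration from sampled starts with Brent
  cycle detection; a lower bound on the attractor set.
* **Asynchronous random walk**: uniform eligible-node walks; walks that
  stall seed a bounded forward exploration (default 4096 states) whose
  terminal SCCs are reported and certified closed; cap overflow yields an
  explicitly uncertified candidate.

Cycles are canonicalized to the lexicographically smallest rotation, so
deduplication and report ordering are deterministic.

## Perturbation sensitivity

Knockout/overexpression replaces one node's function by constant 0/1.
Attractor landscapes are compared as the **union of attractor states with
the perturbed coordinate projected out**: the published distance
definitions presume one attractor on each side and say nothing about
multi-attractor landscapes or the clamped coordinate; union + projection
is the simplest semantics under which both distances are well-defined and
under which clamping a node to a value it already holds everywhere is
exactly a null perturbation. `d_sim` is implemented exactly as the
Jaccard form (a similarity, 1 = unchanged) and also reported as
`1 − d_sim` under the name `dissimilarity`; the headline scalar is
`d_id`, the distance anchored on the unperturbed reference. Both are
always reported, since which one a published sensitivity column contains
is not decidable from its description.

Prioritization min–max normalizes betweenness and `d_id` over the node
set, averages them, ranks descending, and reports the intersection of the
top-q sets of each criterion separately (q default 0.25).

## Synthetic networks

`random_network` is the classic N-K-p ensemble: per-node in-degree ~
Poisson(k) truncated to the candidate pool, regulators sampled without
replacement, truth tables ON with bias p (default 0.5, the standard
unbiased ensemble). Constant truth tables are redrawn (bounded at 64
attempts) so sampled regulators stay effective; at extreme biases the
constant stands. `pathway_like` builds layered input→signaling→phenotype
topologies at three scales — small 65 nodes/86 edges, medium 167/196,
large 391/436, the node/edge ranges typical of curated pathway models —
with every non-input node anchored to an earlier regulator (so all
phenotypes are reachable from inputs), activation:inhibition sampled 3:1,
OR-of-activators AND-NOT-inhibitors functions, and feedback edges closing
backbone ancestor chains at medium/large scale.

What a green test on these fixtures establishes: the algorithms are
correct on networks with realistic size, sparsity, layering, and feedback
structure. What it does not establish: behavior on real curated maps,
whose logic is not sampled from any ensemble (hub in-degrees beyond the
Poisson tail, coordinated inhibition, compartment structure) — hence the
translation and I/O layers are tested on explicit hand-built fragments
as well.

## Pipeline

A run executes load → topology → attractors → perturbation → simulate,
writing TSV/JSON reports plus a manifest with the seed, a config hash,
and a SHA-256 per output; `verify` re-hashes a bundle. The global seed
fans out as `seed·1000 + stage_index`, so a single stage re-run
reproduces its slice of a full run. Stochastic stages are exactly
reproducible given the seed (PCG64 with integer-only sampling paths).

## Known limitations

* Binary logic only; multi-level species are a hard error, not coerced.
* The SBML-qual reader supports one transition per target and math over
  and/or/not/eq at levels 0/1 — the subset the writer emits; mixed-level
  function-term lists with ordered-term semantics are rejected rather
  than misread.
* The DPLL solver is adequate for the encodings produced here, not a
  general-purpose CDCL solver; pathological dense networks may need an
  external DIMACS solver.
* Decomposition is deliberately approximate (see above); its unverified
  candidates must not be read as predictions.
* The SIF relation vocabulary (`activates`/`inhibits`/`interacts`) is a
  package choice; downstream tools expecting other tokens need a remap.
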