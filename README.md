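# boolpath

Boolean modeling of signaling-pathway maps: translate mechanistic
process-description diagrams into logical models, score their topology,
enumerate attractors by several strategies, simulate them as continuous-time
Markov chains, and prioritize intervention targets by combining centrality
with perturbation sensitivity.

## Who this is for

Systems biologists who curate pathway diagrams (e.g. disease maps of
neurodegeneration pathways such as autophagy regulation or dopamine
signaling) and want executable Boolean models out of them: which stable
molecular configurations (attractors) the pathway supports, how a knockout
or overexpression reshapes them, and which molecules are worth perturbing.

## The model

A Boolean network is a set of nodes `x_1..x_n` with one update function
per node. Synchronously, `x_i(t+1) = B_i(x(t))` for all nodes at once;
asynchronously one node is recomputed at a time. Attractors are terminal
sets of states: fixed points (`B(x) = x`), synchronous cycles, or terminal
strongly connected components of the asynchronous state-transition graph.

Key quantities:

* **Betweenness centrality** `C_B(v) = Σ_{s≠v≠t} σ(s,t|v)/σ(s,t)` and
  **stress centrality** `C_S(v) = Σ_{s≠v≠t} g_st(v)`, over ordered node
  pairs of the directed regulator→target graph, unnormalized
  (`σ(s,t)` = number of shortest s→t paths, `σ(s,t|v)`/`g_st(v)` = those
  through `v`).
* **Fixed points via SAT**: the constraint `⋀_i (x_i ↔ B_i(x))` is
  Tseitin-encoded to CNF and all models enumerated with blocking clauses;
  bounded-length synchronous cycles use the unrolled encoding
  `x^{t+1} = B(x^t)`, `x^L = x^0`, states pairwise distinct.
* **Stochastic simulation**: the network is run as a continuous-time
  Markov chain — every node whose function disagrees with its value flips
  with its up- or down-rate; Gillespie sampling over many trajectories
  estimates per-node ON-probabilities over time.
* **Perturbation sensitivity**: for a knockout (clamp 0) or
  overexpression (clamp 1), compare unperturbed and perturbed
  attractor-state sets `A, A'` (union over attractors, perturbed
  coordinate projected out) with the Jaccard similarity
  `d_sim = |A∩A'| / |A∪A'|` and the identity distance
  `d_id = 1 − |A∩A'| / |A|`. Targets are ranked by the mean of min–max
  normalized betweenness and `d_id`.

## Formats

* **Rule text** — one `target, expression` line per node with `&`, `|`,
  `!` and parentheses; a node whose expression is its own name is a free
  input; `#` comments allowed.
* **SBML-qual** — SBML Level 3 qualitative models, binary levels only.
* **SIF** — tab-separated `source relation target` with relations
  `activates` / `inhibits` / `interacts` (the vocabulary is this
  package's choice; see `docs/methods.md`).
* **PD exchange text** — a minimal block format for process-description
  species and reactions (reactants/products/signed modifiers), reduced to
  an activity-flow Boolean network by four rewriting rules.

## Worked example

The built-in `cascade_phenotype` motif is a two-input signaling cascade
with two phenotype read-outs:

```text
growth_factor, growth_factor
stress, stress
kinase1, growth_factor
kinase2, kinase1 & !stress
tf, kinase2 | stress
autophagy, tf & !stress
neuron_death, stress & !kinase2
```

Simulating three input scenarios
(`python -c` over `boolpath.pipeline.scenario_table`, or
`boolpath run cfg.yaml`; seed 1, 2000 trajectories, horizon 30):

```text
  scenario  autophagy  autophagy_se  neuron_death  neuron_death_se
  baseline      0.251      0.009695         0.505          0.01118
 stress_on      0.000      0.000000         1.000          0.00000
protective      1.000      0.000000         0.000          0.00000
```

With both inputs free (`baseline`) the chain settles into a mixture of the
four input combinations, so autophagy is ON in about a quarter of runs and
neuron death in about half; clamping `stress` ON makes neuron death
certain and abolishes autophagy; clamping `growth_factor` ON with `stress`
OFF saturates the protective arm. The standard-error columns are
Monte-Carlo binomial errors at 2000 trajectories.

Knockout sensitivity combined with centrality
(`boolpath perturb ... --priority-out`):

```text
         node  betweenness  sensitivity  priority  rank
      kinase2          6.0         0.25  0.750000     1
      kinase1          4.0         0.25  0.583333     2
growth_factor          0.0         0.50  0.500000     3
       stress          0.0         0.50  0.500000     4
           tf          3.0         0.25  0.500000     5
    autophagy          0.0         0.00  0.000000     6
 neuron_death          0.0         0.00  0.000000     7
```

`kinase2` ranks first: it is the most central relay and its knockout
erases a quarter of the attractor states. The inputs are maximally
sensitive (`d_id = 0.5` — clamping a free input halves the landscape) but
carry no betweenness; the phenotype sinks drop out entirely once their
own coordinate is projected from the comparison.

## Command line

```sh
boolpath generate --scale small --seed 1 --out-prefix pw   # synthetic pathway
boolpath topology pw.rules                                 # centrality TSV
boolpath attractors pw.rules --method sat+async            # attractor JSON
boolpath perturb pw.rules --modes knockout                 # sensitivity TSV
boolpath simulate pw.rules --max-time 20                   # trajectory TSV
boolpath translate diagram.pd --out-rules model.rules      # PD → rules
boolpath run config.yaml && boolpath verify <outdir>       # full pipeline
```

## Acceptance script

`python scripts/acceptance.py --seed <int> --out results/acceptance.json`
generates a seeded 65-node pathway-like network, runs the full pipeline —
topology, SAT+asynchronous attractor search, all-single-node knockout and
overexpression sensitivity, and three clamped-input simulation scenarios —
verifies the report bundle against its manifest hashes, and writes the
target report to `--out`.
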