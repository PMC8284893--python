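# Methods

## Model class and update semantics

A Boolean system is an ordered set of N named variables with one update
function f_i each, evolved by stochastic asynchronous update: at every step
one variable, chosen at random with any fixed positive probability,
recomputes its value. The state transition graph (STG) places a change-edge
x → y whenever y differs from x in exactly one coordinate i and
f_i(x) = y_i. Self-loops (updates that change nothing) are not stored, and
no probabilities are attached to edges: the attractors — terminal strongly
connected components of the STG — depend only on the topology, which is
invariant to the choice of positive update probabilities. All higher-level
machinery is validated against this brute-force oracle on small systems.

Update functions are held in a dual representation: the parsed syntax tree
(kept for display and round-tripping of rule files) and a canonical truth
table over the function's referenced inputs, stored as an integer bit
vector. All algebra (restriction, composition, negation, equality) happens
on tables; tables over more than 20 inputs are refused (`ArityError`), which
callers treat as a signal to degrade to bounds rather than materialize
megabyte tables. Table primitives switch to vectorized numpy code above 8
inputs.

## Parity, time reversal, and their invariants

Parity maps f_i to f'_i(X) = ¬f_i(¬X); the STG of the image is the original
STG under the bit-flip bijection, and the transform is an involution on
truth tables. Time reversal maps f_i to f_i⁻(X) = ¬f_i(X with X_i := ¬X_i);
its STG is the forward STG with every change-edge reversed, it is an
involution up to truth-table equality, and its fixed points coincide with
the in-degree-zero states of the forward STG. These three laws are enforced
as property tests over random ensembles.

One definitional choice deserves a note: at the raw STG level, "source
state" means in-degree zero among change-edges, and the fixed-point/source
duality with the time reversal is exact in those terms. At the analysis
level (`garden_of_eden_spaces`), an isolated fixed point — no incoming *and*
no outgoing change-edge — is not reported as a Garden-of-Eden state, because
the implicit self-transition of asynchronous update makes such a state
reachable from itself forever. Under this convention a pure identity system
has no Garden-of-Eden states, while a constant source node does.

## The parity-expanded network

Each variable contributes the contradictory virtual-node pair (i,1), (i,0),
updating by F_(i,1) = f_i and F_(i,0) = ¬f_i (the two parity layers). For
every prime implicant of F_J — computed per function by Quine–McCluskey
over its referenced inputs, returning the full Blake canonical set, with
deterministic ordering — a hyperedge joins the implicant's literals to J.
Hyperedges with two or more parents are rendered through composite AND-gate
nodes, but network equality is defined on hyperedges; composite identifiers
are cosmetic. Conventions for degenerate rules: a constant-1 function gets
a single empty-parent hyperedge (its virtual node is unconditionally
driven), a constant-0 function gets none. Soundness (every hyperedge's
active parents force the child's value) and completeness (every forced
value is witnessed by a hyperedge) are property-tested state by state.

## Stable motifs and their enumeration

A stable module is a non-empty consistent sourceless virtual-node set:
every member has a hyperedge with all parents inside the set. Modules fix
trap spaces; a stable motif is a minimal module (hence strongly connected).
Enumeration exploits the fact that every motif equals the closure of any of
its members under a choice of one supporting hyperedge per member: a
depth-first search over hyperedge choices from each virtual node, pruning
any branch whose committed set already contains a previously found module
(such a branch cannot end minimal), yields all motifs. The search is
restricted to entities on interaction-graph cycles (motif entities are
strongly connected) plus constant-function entities, whose singletons are
motifs by the tautology-edge convention. A branch budget and an optional
wall-clock deadline cap pathological cases; exhaustion flags the result
incomplete instead of failing. An independent exponential-time subset-scan
oracle exists for tests.

Maximal stable modules — the minimal trap spaces, whose count lower-bounds
the attractor count — are obtained as the deduplicated fixed sets of the
commitment recursion's leaves (commit a motif, percolate, repeat until no
motif remains), cross-checked against the subset-scan oracle.

## Influence: LDOI, exact DOI, drivers, self-negation

The logical domain of influence LDOI(S) is computed by percolation: pin the
values of S, repeatedly partially evaluate update functions, and collect
every virtual node whose function becomes constant. Pinned members whose
own function percolates to the opposite value are recorded as
*self-negation evidence* and never added. Only the downstream cone of the
pinned and constant variables is visited, which makes the 2N single-node
percolations behind the driver set Δ cheap even at N = 256.

The exact domain of influence DOI(S) — defined through the attractors of
the S-pinned dynamics — is implemented only at oracle scale (brute-force
attractors of the restricted system) and is used in tests to verify
LDOI ⊆ DOI, attractor confinement for singleton sources, and the soundness
of the percolation-based self-negation verdict. The production self-negation
test is the percolation one: sound but incomplete, and every result records
which method produced it.

## Succession diagrams and attractor identification

The diagram's nodes are unions of committed motif vertex sets, deduplicated,
so all commitment orders reaching the same union merge; the fixed values of
a node are the percolation closure of its union, and nodes whose closures
coincide share their residual analysis through a cache. At every node with
remaining motifs the terminal restriction space of the residual is built
(the per-node placement follows from treating each reduced system as a
system in its own right); motif-avoidant attractors are searched inside it;
each motif spawns a child node. Nodes with motif-free residuals carry the
residual's attractors (all complex, since a fixed point always contains a
motif); fully fixed nodes carry point attractors. Attractors are
deduplicated globally by their state sets.

The restriction space is materialized compactly: the literals of ¬Δ and of
their LDOIs are pinned, the residual of the pinned subspace (never more
than `space_bits` free variables, default 2^18 states) is enumerated, the
F_I constraints and the exclusions (motif trap spaces; self-negating
reverse-motif spaces) are applied vectorized, and states in which a pinned
variable wants to flip are flagged as escaping. Terminal SCCs are computed
with scipy's sparse strongly-connected-components on the in-space
transition graph; a component counts only if no member escapes and no edge
leaves it, which is exact for attractors confined to the space — the
confinement theorem guarantees exactly that, so no reachability closure
beyond the space is required. Two shortcuts follow the theory: if ¬Δ
contains a contradictory pair, or percolating it contradicts itself, the
space is empty and no motif-avoidant attractor can exist.

When the space has too many free variables to enumerate, terminality is
tested through the deletion projection of the residual: point attractors
project bijectively and complex attractors map onto at least one projected
complex attractor, so a projection without complex attractors proves the
absence of motif-avoidant attractors; and because motif activity in
attractors is preserved by the projection, a projection whose complex
attractors all fix the surviving literals of some motif also proves it.
A motif-free residual with exactly one projected attractor, complex, has
exactly one attractor — counted exactly but reported *unresolved* (its
member states are not enumerated; `AttractorReport.unresolved` and the
`fully_resolved` flag make the distinction machine-readable). This
projection-based terminality logic was validated against the brute-force
oracle on thousands of random systems with the enumeration path disabled.

If any stage exceeds its budget the report degrades to bounds: the lower
bound is the number of attractors actually established (at least the
trivial 1), the upper bound is the attractor count of the fully projected
system when obtainable, and otherwise the caller applies the per-size
ensemble fallback of 10% above the most attractor-rich network of the same
size.

## Deletion projection

Non-self-regulating variables (syntactic test on the simplified function)
are deleted by substituting their update function into their targets';
variables with constant functions go first. The projection map records the
deletion order and definitions; representative-state lifting percolates a
projected state back through the definitions in reverse order. An arity cap
(14 inputs inside the pipeline) blocks substitutions that would blow up
truth tables; blocked variables invalidate the bound rather than silently
degrade it. Order independence of the map holds among feasible orders (an
order is infeasible when an earlier deletion makes a later target
self-regulating) and is property-tested.

## The Kauffman ensemble study

The generator draws, per node, K distinct regulators uniformly without
replacement (self-inputs allowed by default — the convention is not forced
by the model definition; a flag switches to self-exclusion) and a quenched
truth table with independent Bernoulli(p) entries. Degenerate functions are
kept as generated; no repair. Everything is reproducible from a single
seed: per-network seeds are drawn from one generator stream, and the
structural, bias, and determinism contracts are tested.

The desk-scale study uses N ∈ {2, 4, …, 256} with 100 networks per size at
the critical point K=2, p=0.5, under per-network budgets (50k motif
branches, 2^17-state searches, 512 succession nodes, 5 s wall clock — the
wall-clock cap is the operational criterion for an "unusually difficult"
network). Roughly 95% of networks are enumerated exactly (never below ~75%
per size at N=256); the rest contribute bounds. The scaling fit
⟨A⟩ = a + bN^c uses nonlinear least squares on per-size means — exact
counts only for the headline curve, lower/upper bounds for the companion
curves — with bounded multistart initialization (the three parameters trade
off strongly when c is small) and a bootstrap over networks within each
size (1000 resamples by default, percentile 95% CI; samples are sorted
within size so the procedure is invariant to input order). A caveat that
the bootstrap intervals make explicit: with the largest size at N = 256 the
sum-of-squares profile is nearly flat in c, so the three parameters trade
off along a ridge and the exponent estimate is right-skewed and strongly
seed-dependent (typical values fall between roughly 0.1 and 0.3, with
occasional degenerate fits at small b and large c). The ridge only closes
with the cluster-scale sizes (N ≥ 4096) that the budgets deliberately do
not reach; at desk scale the reported c should be read together with its
bootstrap interval, not as a point value. Excluding
budget-exceeded networks from the exact curve biases large-N means slightly
downward (hard networks tend to be attractor-rich); the lower-bound curve,
which uses every network, serves as the cross-check.

## What the synthetic data does and does not show

The random-ensemble tests exercise exactly the generative model above:
independent quenched logic, fixed in-degree, no topological correlations.
Real regulatory networks have broad degree distributions, canalizing and
composed logic, and autoregulation conventions that this ensemble does not
emulate, so passing tests certify the algorithms and the critical-ensemble
scaling claim, not behavior on any particular biological model. The
packaged tristable switch is likewise a synthetic stand-in constructed by
seeded search to exhibit a prescribed repertoire (three point attractors,
three Garden-of-Eden states found as fixed points of the time reversal);
it demonstrates the machinery on a phase-switch-like decision structure
without reproducing any published model's biology. The other small fixtures
are classic minimal circuits (toggle switch, decision cascade, slave
variable) reconstructed from qualitative descriptions.

## Known limitations

- Motif enumeration is worst-case exponential; the budget/incompleteness
  mechanism makes this explicit rather than fast.
- The LDOI-based self-negation verdict can answer "not self-negating" for
  sets the exact DOI test would refute; exclusion lists built from it are
  therefore conservative (never exclude too much — soundness is preserved).
- Succession diagrams over many independent motifs grow exponentially in
  the number of motifs; the node budget truncates such diagrams and the
  result degrades to bounds.
- `unresolved` attractors carry no state enumeration, only existence and
  trap-space provenance.
- The ensemble study's exact-curve exclusion bias is quantified only
  indirectly (through the lower-bound curve), not corrected.
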