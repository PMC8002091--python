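# Methods

## The two-layered model

A compound is modelled hydrogen-suppressed: a simple connected graph with
element labels `α(v)` from a finite table Λ and bond multiplicities
`β(e) ∈ {1,2,3}`, subject to the valence condition
`β_G(v) = Σ_{uv∈E} β(uv) ≤ val(α(v))`.  Implicit hydrogens are the
hydro-degree `val(α(v)) − β_G(v)`.  The default element table is C:4, N:3,
O:2, S:2, Cl:1 with `mass* = ⌊10·mass⌋` (C 120, N 140, O 159, S 320,
Cl 354); both valences and masses are user-overridable, since divalent
sulfur is a modelling choice, not a law.  Elements are totally ordered
lexicographically by symbol; the order only orients configuration tuples
and is kept stable across serialisation.

Iterated deletion of degree-1 vertices assigns each removed vertex the
round of its removal as its *height*; vertices that survive forever
(cycle cores, tree centers) get a `+∞` sentinel so that the threshold test
`ht(v) < ρ` is total.  For a branch-parameter `ρ ≥ 0` (default 2, the
value at which the vast majority of organic compounds have all their
"bushiness" in the exterior) the exterior is the set of vertices below the
threshold plus their incident edges; each connected component of exterior
edges is a fringe tree rooted at its unique interior vertex.  Every
interior vertex owns exactly one fringe tree, possibly the trivial
single-vertex one — this convention makes the fringe-frequency descriptors
sum to the interior size, an identity the tests assert.  An input whose
vertices all fall below the threshold raises `EmptyInteriorError` carrying
the graph, rather than silently returning an empty interior, because all
downstream descriptors assume at least one interior vertex.

## Descriptors

The feature vector has `K = 17 + |Λint| + |Λex| + |Γint| + |F|` slots.
The 17 fixed slots are: n, |Vint|, mean `mass*` (the single real-valued
slot), interior-vertex degree histogram over d∈[1,4] (degrees in the whole
graph), interior-degree histogram over d∈[1,4] (degrees within the
interior subgraph), hydro-degree histogram over d∈[0,3] (all vertices),
and interior double/triple bond counts.  The set-valued blocks count
interior elements, exterior elements, interior edge-configurations
`(cs(u), cs(v), β(uv))` with `cs(v) = (α(v), deg(v))` oriented by the
element-then-degree order, and fringe-tree r-isomorphism classes.  Slot
order is frozen; encodings sort each set by its canonical text so
serialised spaces are reproducible.  An element counts as "exterior" only
if it actually labels an exterior vertex somewhere in the data set.

Fringe trees are classified by a canonical code: recursively,
`(elem~bond children...)` with children sorted lexicographically as
strings and no bond token on the root.  Two chemical rooted trees receive
equal codes exactly when a root-preserving, label- and
multiplicity-preserving isomorphism exists.  The code doubles as a
parseable serialisation, so specification files may give fringe candidates
either as codes or as nested literals.  The acceptance suite certifies the
classification exhaustively: over all labelled rooted trees with ≤ 6
vertices (3 elements × 2 multiplicities, 298 584 classes) the number of
distinct codes equals an independent class count computed by a
multiset-of-branches recursion, and codes are invariant under random child
reshuffles — together: code equality ⇔ r-isomorphism.

Known edge case: a single-vertex interior has interior-degree 0, which
falls outside the printed histogram domain [1,4]; the interior-degree
conservation identity therefore holds only for interiors with ≥ 2
vertices.  Data curation (> 3 carbon atoms) makes the case irrelevant for
real data sets.

## Target specifications

A specification is `(seed graph, σint, σce)` with branch-parameter ρ.
Seed edges carry expansion classes: `ge2` → path of length ≥ 2, `ge1` →
path of length ≥ 1, `zero_one` → kept or dropped, `eq1` → kept as is;
parallel seed edges are supported (edges are keyed by id).  σint bounds
interior size, per-edge path lengths, leaf-path counts and lengths on path
interiors and seed vertices, and per-path double/triple-bond counts; σce
bounds total size, per-vertex fringe candidate sets F(v) and the shared
pool FE, allowed interior elements, and the frequencies of elements,
chemical symbols, adjacency-configurations and edge-configurations.
Generic linear side constraints over path lengths (e.g. `ℓ(a1) ≤ ℓ(a2)`)
are part of σint.  The σint vertex clause is read as a {0,1} leaf-path
count indicator per seed vertex plus separate length bounds — the two
roles the bound family plays on edges, disentangled.

All construction routes share one *plan* representation (path lengths,
leaf-path placements, fringe-code assignment, bond assignment) and one
`check_plan` bound checker, so the random sampler, the exhaustive
enumerator, the validator and the MILP decoder agree exactly on which
graphs are extensions.  Two structural rules close the loop between
construction and decomposition: every fringe tree has height ≤ ρ, and a
fringe tree at an interior vertex of interior-degree 1 has height exactly
ρ (otherwise the vertex would be re-classified exterior when the built
graph is decomposed).  With these rules, re-decomposing a built graph
always reproduces the planned interior.

Validation of an arbitrary graph recovers a plan by backtracking: anchor
seed vertices on interior vertices (filtered by element constraints,
per-vertex candidate sets and degree demands, with incremental adjacency
consistency on `eq1` edges), assign internally disjoint paths to seed
edges, and interpret the leftover interior as leaf paths.  The search is
exponential in the worst case but fast on molecule-sized inputs; the
47-atom reference reconstruction validates in well under a second.

## Training

`train` wraps scikit-learn's MLPRegressor (ReLU hidden layers, identity
output) and extracts the weights into a plain-array predictor whose
forward pass is self-contained and bit-reproducible.  No input scaling is
applied by default so the inversion MILP sees raw integer descriptors; the
optional min–max mode folds the affine transform into the first layer
before the model leaves the trainer, keeping everything linear.  The
coefficient of determination is computed from its definition
(1 − SS_res/SS_tot), not a library variant, and is undefined (an error)
for constant properties.  Five-fold cross-validation partitions by a
seeded permutation that depends only on the fold seed and the data-set
size, so fold membership is invariant under data-set reordering.  Model
files store weights in plain decimal text together with the descriptor
space, making the inversion step self-contained.

Before inversion, input nodes for edge-configurations and fringe codes
outside the specification are removed along with their first-layer weight
rows; on any specification-conforming graph those descriptors are zero, so
the reduced network computes identical outputs (asserted to 1e-9 in
tests).

## The inversion MILP

The encoding is slot-based.  Each `ge1/ge2` seed edge owns up to
`ℓUB − 1` prefix-activated internal vertex slots; its realised edges are a
direct edge (active iff length 1), chain edges (slot k active iff the
k-th vertex slot is), and closing edges (active iff slot k is the last
active one — a linear expression of two prefix binaries).  Leaf paths are
prefix-activated chains hanging off seed vertices and path slots.  Each
interior vertex slot selects one fringe code from its candidate set; the
code determines the element, the root degree and the root bond sum, so
valence is the linear constraint "interior bond sum ≤ valence − root bond
sum of the selected code".  Each edge slot selects a bond multiplicity.
Chemical-symbol indicators are AND-linearisations of element and
total-degree indicators; edge-configuration indicators combine endpoint
symbols and multiplicities, with explicit forbid constraints on any
endpoint-symbol/multiplicity combination whose configuration is outside
the allowed set.  All descriptor slots are linear sums of these binaries;
the mean-mass slot is linearised over the (bounded, integer) molecule size
with one indicator per admissible size.  The ReLU forward pass uses the
standard big-M constraints with per-neuron bounds from interval arithmetic
over the descriptor box; neurons whose pre-activation interval does not
straddle zero degenerate to fixed or affine form.  The target enters as
two inequalities `y*−ε ≤ out ≤ y*+ε`, with ε = 0 meaningful because the
output is continuous.  The default objective is pure feasibility;
minimising the size is available.

Connectivity can only break when optional `zero_one` edges are dropped;
rather than a flow encoding, `solve_inverse` decodes each incumbent,
checks connectivity, and excludes disconnected drop-sets with no-good
cuts before re-solving (at most 2^|E(0/1)| rounds, in practice zero or
one).  Every feasible decode is re-verified from scratch: specification
validation by the backtracking validator, descriptor equality slot by slot
(integer slots exact; the solver's continuous mean-mass copy to 1e-5,
since the exact value is already pinned by the integer element counts),
and the recomputed network output within `ε + 1e-6` of the target.  The
solver is HiGHS via `scipy.optimize.milp`.

Completeness rests on the shared construction semantics: every extension
corresponds to a witness assignment of the slot variables, and the
acceptance suite checks on an enumerable family that MILP feasibility at a
target coincides exactly with the existence of an enumerated graph
attaining it.

## Isomer counting and enumeration

The chemical isomers of an inferred graph are the other
specification-conforming graphs with the identical feature vector.  At the
fixed interior topology the fringe-frequency descriptors pin the multiset
of fringe codes and the edge-configuration descriptors pin the bond
multiset, so enumeration explores exactly the assignments of those fixed
multisets (codes over interior vertices subject to candidate sets, bond
multiplicities over interior edges subject to valence), filters on full
feature-vector equality and specification validity, deduplicates up to
isomorphism (invariant bucketing + exact VF2), and truncates at a cap
(default 100).  Interior *rewirings* — different interior topologies that
happen to share the feature vector — are out of scope of the enumeration,
matching the fixed-topology semantics of the exhaustive oracle it is
tested against.

The lower-bound count avoids materialising graphs: interior vertices are
grouped by (interior degree, root signature), where the root signature is
(element, root degree, root bond sum) of the assigned code; within a
signature, the count is the number of ways to split the code multiset
among the groups, each group restricted to codes admissible at every one
of its sites.  Any graph automorphism preserves interior degrees and root
signatures, so it permutes sites within groups, and distinct splits can
never be identified by an automorphism — the count is a certified lower
bound.  It is deliberately conservative (bond rearrangements contribute a
factor 1); when enumeration exhausts the class the exact count replaces
it.

## Synthetic data

The generator emits valence-valid connected graphs: a random interior tree
with degrees capped at 4, optional extra cycle edges, and fringe trees
drawn from a randomly generated pool of height ≤ ρ whose root elements can
carry the interior degree; a fraction of bonds is upgraded to double where
both endpoints have hydrogen slack.  Ground-truth property values are a
stated linear form over the 17 fixed descriptor slots (coefficients
documented in `synthetic.DEFAULT_COEFFICIENTS`) plus Gaussian noise of
configurable standard deviation, zero by default — so the end-to-end
train→invert round trip has a representable target function.  A second
entry point samples data sets from a specification's own extension set,
which guarantees witness graphs for inversion targets.

What the generator does not emulate: aromatic delocalisation, realistic
functional-group statistics, charged species, stereochemistry, and the
property noise structure of measured data.  Green tests therefore certify
algorithmic correctness (descriptor algebra, encoding exactness, inversion
soundness/completeness at toy scale), not predictive accuracy on real
chemistry.

## Problem sizes used in the test and acceptance suites

The enumerable family used throughout is a monocyclic specification whose
extension set has ~10^4 members with at most 8 atoms (n* = 8, interior ≤
5); the decomposition and conservation sweeps use 1000 random graphs of up
to ~30 atoms; the canonical-code certification sweeps all 504 381 labelled
rooted trees on ≤ 6 vertices; inversion round trips solve 10 MILPs against
a trained (K,6,1) network, and the ReLU-exactness check solves 200
fixed-input MILPs on (6,5,1) and (6,5,5,1) networks.  These sizes were
chosen so the whole suite certifies every contract in minutes on one CPU;
the MILP scales to a few tens of atoms per solve, with solve time growing
with `n*`, `|F|` and network width.

## Known limitations

- One solver backend (HiGHS via scipy); no CPLEX/Gurobi bindings.
- The MILP's candidate fringe sets must be finite and explicit; height-ρ
  trees are never synthesised on the fly.
- Validation and isomer enumeration are exponential in pathological
  specifications (many identical fringe codes on large symmetric
  interiors); they are meant for molecule-sized instances.
- SDF support is V2000 with bond orders 1–3; aromatic flags, charges and
  isotopes are rejected at the reader with per-record reasons.
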