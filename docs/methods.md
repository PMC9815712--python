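# Methods

## The BDT process and its sampler

The core stochastic object is a continuous-time birth/death/transformation
process over a set of *entities* (here B cells).  Each entity carries a
vector of nonnegative numeric properties ("slots") that stay constant
between events; every rate is a sum of polynomial terms

    rate_E(i) = Σ_terms  coeff · aggregate_factor(S) · slot_value_i

where S is the component-wise sum of slots over active entities.  Because of
this form the total event rate λ is available in O(#terms) from running
per-slot totals, and the next event is located in O(log n) by descending a
Fenwick (binary indexed) tree of per-slot partial sums.  Aggregate factors
(here only σ, the total affinity of activated cells) are re-evaluated in
O(1) after every event, which realises the rule that rates are constant
between events but may change at each event.

Two samplers implement one canonical decision order — one uniform for the
exponential waiting time `dt = −log1p(−u)/λ`, one uniform mapped through
(class birth→death→transform, terms in spec order, entities in ascending
slot-position order).  The fast path uses the Fenwick trees; the *naive
oracle* recomputes every entity's rates by direct summation at every event.
Fed the same stream they produce identical event sequences (the test suite
checks 10⁴ events on the reduced configuration); waiting times agree to
float round-off because the two λ evaluations differ only in summation
order.  A uniform landing in a float dead zone at a partition boundary is
clamped to the last active entity with a warning; this has never been
observed in testing and has probability at the level of double rounding.

Numerical hygiene: the per-slot running totals are rebuilt from the slot
matrix every 10⁶ events (and at every stage switch, where the state is
reconstructed anyway); a debug `verify()` asserts agreement between running
totals and direct sums at 10⁻⁹ relative tolerance.  Slot positions of dead
cells are recycled through a LIFO free list; entity ids are never reused.
Stop conditions are simulated-time limits (the state is advanced to the
boundary with no event, valid by memorylessness), an event-count cap
(reported as truncation), an aggregate predicate checked after every event,
and extinction — all returned as typed results, since dormant stages can
legitimately kill every cell.

Key kernels (Fenwick update/search, per-position mutation sampling) are
compiled with numba when available, with identical pure-Python fallbacks.

## The affinity-maturation instantiation

Cells are memory (g = 0) or activated (g = 1).  The numeric slots per cell
are (g, 1−g, (1−g)·t, g/a, g·a, g·1[a = 0]); the last slot routes activated
cells whose sequence acquired an in-frame stop codon (a = 0, so the
resource-competition death term g/a is undefined) to the fast death rate
λ_d instead — effectively immediate removal.  Transformations flip g and
keep the sequence; activation is g: 0→1.  The activated death rate is
λ_b(1−ρ_p−ρ_m)·σ/(C·a) + ρ_p·λ_b: apoptosis inversely proportional to the
cell's affinity share a/σ, plus plasma-cell differentiation treated as
death.  For a homogeneous activated population this balances birth at
n* = C(1−ρ_p)/(1−ρ_p−ρ_m), which the suite verifies within ±25% at reduced
scale.  Memory activation is λ_t·e^(ρ_a·A·(f−Δ₀)): a "typical" memory cell
(score Δ₀) activates at λ_t.

Default parameters (units: days, scores in BLOSUM units): λ_b = 6,
λ_d = 10⁴, λ_d′ = 1/402, λ_t = 0.01, ρ_p = 0.01, ρ_m = 0.25, ρ_a = 1/2,
A = 0.1, w_f = 1/3, κ = 2, μ = 5×10⁻⁴ per bp per generation, L = 125 aa,
CDR = 31–35, 50–65, 98–114, Δ₀ = −120, Δ₀′ = −75, C = 10⁵,
M = C·e^(A·Δ₀′).  δ defaults to BLOSUM62 (configurable).

A run starts from a single naive memory cell at t₁.  At every
infected-stage start all living cells' affinities are recomputed against the
round target in O(n·L) and the engine state is rebuilt.  Stage switches are
either fixed-duration (default 50 days) or affinity-threshold (σ ≥ M,
boundary inclusive); an infected stage that fails to reach M within a guard
window is reported as "infection not overcome" rather than silently
continuing.  When a target-sequence series is available the first rounds
act as dummy rounds (the round-1 target is the translated naive sequence)
and should be discarded in analyses.

Sequences are stored as diff chains (position, from, to) against the parent
and materialised on demand; only living cells keep a materialised copy.
Because affinity is a pure function of the sequence, the ~96% of children
born without any mutation inherit the parent's affinity unchanged.

## Somatic hypermutation

Mutations occur only at birth, independently for the two children and
independently across positions, with a probability and target-base
distribution given by the 5-mer context in the *parent* sequence.  The
shipped default table is a **synthetic** hotspot-motif stand-in constructed
deterministically in code — WRC/GYW contexts 8× baseline, SYC/GRS 0.25×,
transition:transversion 2:1 — it reproduces the qualitative structure of
empirical targeting models but is not an empirical table; users can supply
their own via TSV.  Calibration rescales all context probabilities by one
constant so that the *uniform mean over the 1024 contexts* equals μ; the
realised per-sequence rate then varies with composition, as intended for a
hotspot model.  Positions within two bases of an end use the edge rule: the
uniform average over all completions of the missing flanks (deterministic,
unbiased, no phantom flanking sequence).

## Target design and novelty

Round targets can be passed through from user FASTA or designed from an
antigen series: minimise Σ over ordered pairs (i, j) of
|κ·d_CDR(ζ_i, ζ_j) − d(η_i, η_j)|, where d is the BLOSUM self-minus-cross
distance.  Only CDR positions of ζ₂..ζ_r are free; all targets are
initialised to ζ₁ and improved by a deterministic first-improvement sweep
(rounds ascending, CDR positions ascending, amino acids alphabetical) until
a full sweep changes nothing.  With a single free position per sweep unit
the search is exhaustive; with interacting positions it terminates in
genuine single-move local optima on a substantial minority of random toy
instances (the suite asserts local optimality and reports the optimality
gap).  Novelty of a target ζ_i is −max_{j<i} Δ_{ζ_i}(ζ_j).

## Clonal trees and metrics

The true tree restricts the genealogy to sampled cells, the root and their
ancestors; unlabeled pass-through nodes are suppressed with mutation counts
summed; zero-mutation edges are merged so an unlabeled endpoint disappears
into its neighbour, while two labeled nodes joined by a zero-mutation edge
remain distinct (duplicate sampled sequences stay distinct labeled nodes,
matching how reconstruction tools emit one leaf per record).  Estimated
trees are contracted at a branch-length threshold of 10⁻⁴
substitutions/site: short internal edges collapse, and a short terminal
edge below an unlabeled parent relocates its label upward — the mechanism
that creates internal samples in estimated trees; two labels never merge.
The MST baseline runs Kruskal over pairwise nucleotide Hamming distances
with deterministic tie-breaking (weight, smaller record index, larger
record index) and orients edges away from the naive root.

A node's *cluster* is the set of labels at or below it (its own label
included; a labeled ancestor contributes no extra singleton).  Cluster
collections are de-duplicated sets; the all-label root cluster is kept by
default (flag available).  FDR, FNR and RF follow from set differences,
with starred variants dropping singletons.  Triplet metrics restrict both
trees to every 3-subset of labels: TD counts differing induced labeled
shapes, TED sums the per-triplet RF distance; the optimised implementation
encodes each induced 3-tree by its cluster sets via precomputed MRCAs and
is verified against literal per-triplet restriction.  MD sums, over ordered
label pairs, |branches(u → mrca)| differences; PD compares full path
lengths in branch counts.  RF, TD, TED, MD and PD can be divided by their
mean under uniform random relabeling of the reference (default 100 seeded
permutations); FDR/FNR are already normalised.  The Newick dialect writes
internal labels in the standard internal-name slot with lengths at 6
significant digits and round-trips bit-exactly (dendropy parses; a small
writer serialises).

## Reduced-scale study conditions

Tests and examples run a scaled-down configuration chosen once: C = 2000,
L = 25 aa with CDR 6–7, 10–12, 20–22 (the same ≈30% CDR fraction as the
full-scale default), Δ₀ = −24 and Δ₀′ = −15 (score scale reduced with L),
r = 2 with starts at days 0 and 200, affinity-threshold switching, all
other parameters at defaults.  Round 1 targets the translated naive
sequence; round 2 targets a deterministic 4-substitution CDR divergence of
it, so the re-activated memory pool starts at low affinity and the
population must evolve upward before σ reaches M — reproducing the
dip-then-rise of mean activated affinity within a stage.  The
4-substitution choice keeps the 20-replicate dynamics check at roughly
half a million events per replicate.

What the synthetic setup does *not* emulate: real V(D)J germline roots,
light chains, empirical hypermutation spectra (the 5-mer table is
synthetic), insertions/deletions, isotypes, sequencing error, or 3D
structural affinity.  Passing tests therefore demonstrate correctness of
the process and its bookkeeping, and qualitative immunological behaviour
(carrying capacity, selection, memory re-use, affinity dip) — not
quantitative agreement with any particular biological dataset.

## Known limitations

* A single entity species; no cross-species rate coupling, no antigen
  co-evolution within a run, one germinal center.
* The greedy target search is a local search; see above.
* An extinct run (the initial memory cell dies before first activation,
  ~7% of reduced-scale replicates) is a typed result, not an error; 
  analyses should filter on the stop reason.
* Metrics assume both trees carry exactly the same label set and that the
  trees are rooted; unrooted or branch-length-weighted variants are out of
  scope.
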