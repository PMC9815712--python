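# clonesim

Simulation of B-cell affinity maturation as a birth/death/transformation
(BDT) process, together with a metric suite for rooted *clonal trees* —
trees whose sampled sequences may label internal nodes and whose nodes may
have any number of children.

The package is aimed at people benchmarking antibody-lineage reconstruction
methods: it generates ground-truth clonal trees with realistic features
(sampled ancestors, multifurcations, zero-length branches, memory re-use
across repeated infections), provides a simple Hamming-distance
minimum-spanning-tree baseline reconstructor, and quantifies how well an
estimated tree recovers the truth.

## The model

A population of B cells evolves in continuous time.  Each cell *i* carries a
type flag *g<sub>i</sub>* (1 = activated, in a germinal center; 0 = memory), a
nucleotide sequence *s<sub>i</sub>* of length 3*L* coding the heavy-chain
variable region, and derived quantities: its affinity to the current target
and its activation propensity.  Infections arrive in *r* rounds; each round
has an **infected stage** (births, deaths, transformations) and a **dormant
stage** (deaths only: rate λ<sub>d</sub> for activated cells,
λ<sub>d</sub>′ for memory cells).

Affinity compares the translated sequence ξ against the round's target ζ —
the hypothetical best-binding antibody sequence — through a CDR-weighted
BLOSUM score

    Δ_ζ(ξ) = Σ_{p∈CDR} (δ(ξ_p, ζ_p) − δ(ζ_p, ζ_p)) + w_f · Σ_{p∉CDR} (…)
    a_i    = exp(A · Δ_ζ(ξ_i)),       a_i = 0 if s_i has an in-frame stop

with selective pressure *A* and framework down-weighting *w<sub>f</sub>*.
During the infected stage the per-cell, per-day rates are

| event      | activated cell (g = 1)                                    | memory cell (g = 0) |
|------------|-----------------------------------------------------------|---------------------|
| birth      | λ_b                                                       | 0                   |
| death      | λ_b(1−ρ_p−ρ_m)·σ/(C·a_i) + ρ_p·λ_b                        | λ_d′                |
| transform  | ρ_m·λ_b                                                   | λ_t·e^(−ρ_a·A·Δ₀)·a_i^ρ_a |

where σ = Σ g<sub>i</sub>a<sub>i</sub> is the total affinity of activated
cells and *C* the carrying capacity; death pressure scales with the inverse
of a cell's share of resources a<sub>i</sub>/σ, so higher-affinity clones
expand.  At each birth both child sequences mutate independently under a
context-dependent 5-mer somatic-hypermutation model calibrated to an overall
rate μ per base per generation.  A round ends either after a fixed duration
or when σ reaches a cure threshold *M* = C·e^(A·Δ₀′).

All rates are *polynomial terms* — coefficient × aggregate factor ×
per-cell weight — so the sampler maintains Fenwick-tree partial sums and
draws each (waiting time, event class, cell) in O(log n), simulating
genealogies with millions of cells.  A naive sampler that recomputes every
cell's rates at every event serves as an independent oracle: given the same
random stream it reproduces the fast sampler's trajectory exactly.

The metric half compares a reference tree *R* and estimate *E* (both induced
to their labeled nodes) through cluster precision/recall (FDR, FNR), the
Robinson–Foulds cluster distance (RF), triplet discordance and triplet edit
distance (TD, TED), MRCA and patristic discordance (MD, PD), singleton-free
starred variants, and normalization against a random-relabeling control.

## Worked example

Simulate one round at small scale, sample cells, extract the true tree,
reconstruct with the MST baseline, and compare:

```python
import numpy as np
from clonesim import (reduced_config, run_am, sample_cells, true_tree,
                      mst_tree, full_comparison)
from clonesim.am import materialize_sequence
from clonesim.shm import decode_dna

cfg = reduced_config()              # C=2000, L=25, two rounds
res = run_am(cfg, seed=1)
print(res.reason, res.n_events)     # completed 650806
final = res.rounds[-1]
print(round(final.duration, 1), final.n_activated_end)   # 27.7 2084

labels = sample_cells(res, 20, seed=1)
n_mut = [len(m) if m else 0 for m in res.muts]
R = true_tree(res.genealogy.parent, n_mut, labels)

ids = ["Psi_hat"] + sorted(labels, key=lambda s: int(s.split("_")[1]))
seqs = [cfg.root_sequence] + [decode_dna(materialize_sequence(res, labels[l]))
                              for l in ids[1:]]
E = mst_tree(ids, seqs, root_index=0)
rep = full_comparison(R, E, n_perm=100, seed=0)
print(round(rep["FDR"].raw, 3), round(rep["FNR"].raw, 3))   # 0.286 0.348
print(rep["RF"].raw, round(rep["RF"].normalized, 3))        # 14.0 0.481
```

The run completes both rounds after ~650k events; in round 2 the mean
affinity of activated cells first falls (mutation load during clonal
expansion) and then rises as selection takes over, and the stage ends when
the total activated affinity σ crosses M ≈ 446.  On this 20-sample
replicate the MST baseline misreports 28.6% of its clusters and misses
34.8% of the true ones; its RF distance of 14 is about half the random
relabeling control (0.48 after normalization).

A YAML-configured command line covers the same pipeline:

```
clonesim simulate --config cfg.yaml --seed 1 --out-prefix run
clonesim mst --fasta run.sampled.fasta --out mst.nwk
clonesim contract est.nwk est_contracted.nwk --threshold 1e-4
clonesim metrics --ref run.true.nwk --est mst.nwk --normalize 100 --seed 0
clonesim design-targets --zeta1 naive.fasta --antigens flu.fasta --out targets.fasta
```

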