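"""Per-round target design from an antigen series.

Round targets can either be supplied directly (e.g. known neutralising
antibodies, one per round) or *designed* so that the matrix of pairwise
BLOSUM distances between targets matches, up to a scale factor ``kappa``,
the pairwise distance matrix of a series of real antigen sequences sampled
through time.  Only CDR positions of rounds 2..r are free; all non-CDR
positions stay identical to the round-1 target (the translated naive
sequence), and no target may contain a stop symbol.

The combinatorial matching problem is attacked with a deterministic greedy
first-improvement search: sweep over (sequence, CDR position, amino acid) in
a fixed order, accept any strictly improving replacement, and repeat until a
full sweep changes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .am import aa_to_codes, blosum_delta, cdr_mask, codes_to_aa, _BLOSUM62

__all__ = ["AntigenSeries", "pair_distance", "objective", "greedy_targets", "novelty"]


@dataclass(frozen=True)
class AntigenSeries:
    """Antigen amino-acid sequences eta_1..eta_r with per-round dates."""

    sequences: tuple[str, ...]
    dates: Optional[tuple[float, ...]] = None

    def __post_init__(self):
        if len(self.sequences) < 1:
            raise ValueError("need at least one antigen sequence")
        lens = {len(s) for s in self.sequences}
        if len(lens) != 1:
            raise ValueError(f"antigen sequences must share one length, got {sorted(lens)}")
        if self.dates is not None and len(self.dates) != len(self.sequences):
            raise ValueError("need one date per antigen sequence")
        for s in self.sequences:
            aa_to_codes(s)  # alphabet check

    def __len__(self) -> int:
        return len(self.sequences)


def _codes(seqs: Sequence) -> list[np.ndarray]:
    return [aa_to_codes(s) if isinstance(s, str) else np.asarray(s, dtype=np.int64)
            for s in seqs]


def pair_distance(a: np.ndarray, b: np.ndarray, positions: np.ndarray,
                  delta: np.ndarray) -> float:
    """BLOSUM self-minus-cross distance of ``a`` to ``b`` over ``positions``.

    d(a, b) = sum_p delta(a_p, a_p) - delta(a_p, b_p);  d(a, a) = 0 and
    d is asymmetric in general.
    """
    ap, bp = a[positions], b[positions]
    return float((delta[ap, ap] - delta[ap, bp]).sum())


def _distance_matrix(seqs: list[np.ndarray], positions: np.ndarray,
                     delta: np.ndarray) -> np.ndarray:
    r = len(seqs)
    d = np.zeros((r, r), dtype=np.float64)
    for i in range(r):
        for j in range(r):
            if i != j:
                d[i, j] = pair_distance(seqs[i], seqs[j], positions, delta)
    return d


def objective(targets: Sequence, antigens: Sequence, kappa: float,
              cdr_ranges: Sequence[tuple[int, int]],
              delta: Optional[np.ndarray] = None) -> float:
    """Mismatch between scaled target distances and antigen distances.

    sum over all ordered pairs (i, j) of
    | kappa * d_CDR(zeta_i, zeta_j) - d_full(eta_i, eta_j) |  (i = j terms are 0).
    """
    d = _BLOSUM62 if delta is None else delta
    zs = _codes(targets)
    hs = _codes(antigens)
    if len(zs) != len(hs):
        raise ValueError("need one antigen per round target")
    cpos = np.flatnonzero(cdr_mask(len(zs[0]), cdr_ranges))
    allpos = np.arange(len(hs[0]))
    dz = _distance_matrix(zs, cpos, d)
    dh = _distance_matrix(hs, allpos, d)
    return float(np.abs(kappa * dz - dh).sum())


@dataclass
class GreedyResult:
    targets: tuple[str, ...]
    objective: float
    sweeps: int
    converged: bool
    trace: list[float]  # objective after each accepted move


def greedy_targets(zeta1: str, antigens: AntigenSeries, kappa: float,
                   cdr_ranges: Sequence[tuple[int, int]],
                   delta: Optional[np.ndarray] = None,
                   max_sweeps: int = 200) -> GreedyResult:
    """Greedy first-improvement design of zeta_2..zeta_r.

    All targets are initialised to ``zeta1``; the sweep order is rounds in
    ascending order, CDR positions ascending, amino acids alphabetical, and a
    replacement is accepted only if it strictly lowers the objective.  The
    search is fully deterministic and stops at the first sweep with no
    accepted move (or after ``max_sweeps``, returning the best-so-far with
    ``converged=False``).
    """
    d = _BLOSUM62 if delta is None else delta
    r = len(antigens)
    z1 = aa_to_codes(zeta1)
    zs = [z1.copy() for _ in range(r)]
    hs = _codes(antigens.sequences)
    cpos = np.flatnonzero(cdr_mask(len(z1), cdr_ranges))
    allpos = np.arange(len(hs[0]))
    dz = _distance_matrix(zs, cpos, d)
    dh = _distance_matrix(hs, allpos, d)

    def total(dzm: np.ndarray) -> float:
        return float(np.abs(kappa * dzm - dh).sum())

    cur = total(dz)
    trace = [cur]
    sweeps = 0
    converged = False
    while sweeps < max_sweeps:
        sweeps += 1
        improved = False
        for i in range(1, r):  # zeta_1 is fixed
            for p in cpos:
                old = zs[i][p]
                for cand in range(20):
                    if cand == old:
                        continue
                    # recompute row/column i of dz under the replacement
                    new_row = dz[i].copy()
                    new_col = dz[:, i].copy()
                    for j in range(r):
                        if j == i:
                            continue
                        zjp = zs[j][p]
                        new_row[j] += (d[cand, cand] - d[cand, zjp]) \
                            - (d[old, old] - d[old, zjp])
                        new_col[j] += d[zjp, old] - d[zjp, cand]
                    dz_try = dz.copy()
                    dz_try[i, :] = new_row
                    dz_try[:, i] = new_col
                    dz_try[i, i] = 0.0
                    val = total(dz_try)
                    if val < cur:
                        zs[i][p] = cand
                        dz = dz_try
                        cur = val
                        trace.append(cur)
                        improved = True
                        break  # first improvement: move to the next position
        if not improved:
            converged = True
            break
    return GreedyResult(tuple(codes_to_aa(z) for z in zs), cur, sweeps, converged, trace)


def novelty(targets: Sequence[str], cdr_ranges: Sequence[tuple[int, int]],
            w_f: float, delta: Optional[np.ndarray] = None) -> dict[int, float]:
    """Novelty of each round target (rounds 2..r, 1-based keys).

    novelty(i) = -max_{j < i} Delta_{zeta_i}(zeta_j): how far the new target
    sits from the closest previous one; 0 if some earlier target recurs.
    """
    if len(targets) < 2:
        return {}
    L = len(targets[0])
    mask = cdr_mask(L, cdr_ranges)
    out: dict[int, float] = {}
    for i in range(1, len(targets)):
        best = max(blosum_delta(targets[j], targets[i], mask, w_f, delta)
                   for j in range(i))
        out[i + 1] = -best
    return out
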