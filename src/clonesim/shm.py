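"""Context-dependent 5-mer somatic hypermutation (SHM) model.

Each position of a child sequence mutates independently of the others, with a
substitution probability and a target-base distribution that depend on the
5-mer context centred on that position in the *parent* sequence, following
the style of empirical targeting models (hot WRC/GYW motifs, cold SYC/GRS
motifs).  The per-context substitution probabilities are calibrated so that
the uniform mean over all 1024 contexts equals the configured per-base,
per-generation SHM rate ``mu``.

Positions within two bases of either end use the *edge rule*: rates and
target distributions are uniform averages over all completions of the
missing flank bases.

No empirical targeting table is bundled: the default produced by
:func:`default_fivemer_table` is a synthetic hotspot-motif stand-in generated
deterministically in code, and users may load their own empirical table from
TSV (columns ``fivemer  p_sub  p_to_A  p_to_C  p_to_G  p_to_T``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "BASES",
    "MutationEvent",
    "FivemerTable",
    "default_fivemer_table",
    "uniform_fivemer_table",
    "load_fivemer_table",
    "write_fivemer_table",
    "encode_dna",
    "decode_dna",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
N_CONTEXTS = 4 ** 5


def encode_dna(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A=0, C=1, G=2, T=3)."""
    try:
        return np.array([_BASE_INDEX[c] for c in seq.upper()], dtype=np.uint8)
    except KeyError as e:
        raise ValueError(f"non-ACGT character in sequence: {e.args[0]!r}") from None


def decode_dna(codes: np.ndarray) -> str:
    return "".join(BASES[int(c)] for c in codes)


def _py_site_rates_kernel(s, ps_to, ps_l0, ps_l1, ps_r1, ps_r0):
    L = s.shape[0]
    out = np.empty(L, dtype=np.float64)
    k0 = (s[0] * 4 + s[1]) * 4 + s[2]
    out[0] = ps_l0[k0]
    out[1] = ps_l1[k0 * 4 + s[3]]
    v = ((s[0] * 4 + s[1]) * 4 + s[2]) * 4 + s[3]
    for p in range(2, L - 2):
        v = (v * 4 + s[p + 2]) % 1024  # rolling 5-mer code around p
        out[p] = ps_to[v]
    out[L - 2] = ps_r1[((s[L - 4] * 4 + s[L - 3]) * 4 + s[L - 2]) * 4 + s[L - 1]]
    out[L - 1] = ps_r0[(s[L - 3] * 4 + s[L - 2]) * 4 + s[L - 1]]
    return out


def _py_mutate_kernel(s, rates, u, cum_to, cum_l0, cum_l1, cum_r1, cum_r0,
                      ev_pos, ev_to):
    """Positions with u < rate substitute; the target base is read off the
    cumulative substitute-to row (first index whose cumsum exceeds u)."""
    L = s.shape[0]
    n = 0
    for p in range(L):
        if u[p] < rates[p]:
            if 2 <= p < L - 2:
                v = (((s[p - 2] * 4 + s[p - 1]) * 4 + s[p]) * 4 + s[p + 1]) * 4 + s[p + 2]
                row = cum_to[v]
            elif p == 0:
                row = cum_l0[(s[0] * 4 + s[1]) * 4 + s[2]]
            elif p == 1:
                row = cum_l1[((s[0] * 4 + s[1]) * 4 + s[2]) * 4 + s[3]]
            elif p == L - 2:
                row = cum_r1[((s[L - 4] * 4 + s[L - 3]) * 4 + s[L - 2]) * 4 + s[L - 1]]
            else:
                row = cum_r0[(s[L - 3] * 4 + s[L - 2]) * 4 + s[L - 1]]
            b = 0
            while b < 3 and row[b] <= u[p]:
                b += 1
            if b != s[p]:  # self mass is 0; guard against float edges
                ev_pos[n] = p
                ev_to[n] = b
                n += 1
    return n


try:  # pragma: no cover
    from numba import njit as _njit

    _site_rates_kernel = _njit(cache=True)(_py_site_rates_kernel)
    _mutate_kernel = _njit(cache=True)(_py_mutate_kernel)
except Exception:  # pragma: no cover
    _site_rates_kernel = _py_site_rates_kernel
    _mutate_kernel = _py_mutate_kernel


class MutationEvent(NamedTuple):
    """A single substitution: 0-based position, parent base code, child base code."""

    pos: int
    from_base: int
    to_base: int

    def as_str(self) -> str:
        return f"{self.pos}:{BASES[self.from_base]}:{BASES[self.to_base]}"

    @classmethod
    def from_str(cls, s: str) -> "MutationEvent":
        pos, a, b = s.split(":")
        return cls(int(pos), _BASE_INDEX[a], _BASE_INDEX[b])


def _context_index(codes: np.ndarray) -> np.ndarray:
    """5-mer codes (n,5) -> flat context index (n,)."""
    c = codes.astype(np.int64)
    return (((c[:, 0] * 4 + c[:, 1]) * 4 + c[:, 2]) * 4 + c[:, 3]) * 4 + c[:, 4]


def fivemer_string(index: int) -> str:
    out = []
    for _ in range(5):
        out.append(BASES[index % 4])
        index //= 4
    return "".join(reversed(out))


@dataclass(frozen=True)
class FivemerTable:
    """Per-context substitution probability and conditional target distribution.

    ``p_sub[c]`` is the probability that the centre base of context ``c``
    substitutes in one generation; ``cond[c]`` is the distribution over the
    four bases of the substituted base (the self base has probability 0).
    """

    p_sub: np.ndarray  # (1024,)
    cond: np.ndarray   # (1024, 4)

    def __post_init__(self):
        p = np.asarray(self.p_sub, dtype=np.float64)
        c = np.asarray(self.cond, dtype=np.float64)
        if p.shape != (N_CONTEXTS,) or c.shape != (N_CONTEXTS, 4):
            raise ValueError("table arrays have wrong shape")
        if np.any(p < 0) or np.any(p >= 1):
            raise ValueError("substitution probabilities must lie in [0, 1)")
        if np.any(c < 0):
            raise ValueError("conditional probabilities must be nonnegative")
        if np.max(np.abs(c.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("conditional distributions must sum to 1")
        centre = np.arange(N_CONTEXTS) // 16 % 4
        if np.any(c[np.arange(N_CONTEXTS), centre] > 0):
            raise ValueError("self-substitution probability must be 0")
        object.__setattr__(self, "p_sub", p)
        object.__setattr__(self, "cond", c)
        # joint probability of substituting to each base, per context
        object.__setattr__(self, "_to", p[:, None] * c)
        # edge-rule tables: average the joint over the missing flank bases
        to6 = self._to.reshape(4, 4, 4, 4, 4, 4)
        object.__setattr__(self, "_to_l0", to6.mean(axis=(0, 1)).reshape(64, 4))
        object.__setattr__(self, "_to_l1", to6.mean(axis=0).reshape(256, 4))
        object.__setattr__(self, "_to_r1", to6.mean(axis=4).reshape(256, 4))
        object.__setattr__(self, "_to_r0", to6.mean(axis=(3, 4)).reshape(64, 4))
        # sampling caches: total substitution mass and cumulative joint rows
        for name in ("_to", "_to_l0", "_to_l1", "_to_r1", "_to_r0"):
            arr = getattr(self, name)
            object.__setattr__(self, "_ps" + name, arr.sum(axis=1))
            object.__setattr__(self, "_cum" + name, np.cumsum(arr, axis=1))

    # -- derived quantities -------------------------------------------
    @property
    def mean_rate(self) -> float:
        """Uniform mean substitution probability over all 1024 contexts."""
        return float(self.p_sub.mean())

    def calibrate(self, mu: float) -> "FivemerTable":
        """Rescale all p_sub by one constant so the uniform context mean is mu."""
        if not (0.0 < mu < 0.25):
            raise ValueError("mu must lie in (0, 0.25)")
        m = self.mean_rate
        if m <= 0.0:
            raise ValueError("cannot calibrate a table with zero mean rate")
        scale = mu / m
        scaled = self.p_sub * scale
        if np.any(scaled >= 1.0):
            raise ValueError(
                "calibration overflow: some context probabilities reach 1; use a lower mu")
        return FivemerTable(scaled, self.cond.copy())

    @staticmethod
    def _interior_contexts(s: np.ndarray) -> np.ndarray:
        return ((((s[:-4] * 4 + s[1:-3]) * 4 + s[2:-2]) * 4 + s[3:-1]) * 4 + s[4:])

    def _edge_keys(self, s: np.ndarray) -> tuple[int, int, int, int]:
        L = len(s)
        k0 = (int(s[0]) * 4 + int(s[1])) * 4 + int(s[2])
        k1 = k0 * 4 + int(s[3])
        kr1 = ((int(s[L - 4]) * 4 + int(s[L - 3])) * 4 + int(s[L - 2])) * 4 + int(s[L - 1])
        kr0 = (int(s[L - 3]) * 4 + int(s[L - 2])) * 4 + int(s[L - 1])
        return k0, k1, kr1, kr0

    def sub_to_probs(self, seq: np.ndarray) -> np.ndarray:
        """(L, 4) joint probability of each position substituting to each base.

        Interior positions use the full 5-mer context of the parent sequence;
        the first/last two positions use the edge rule.
        """
        s = np.asarray(seq, dtype=np.int64)
        L = len(s)
        if L < 5:
            raise ValueError("sequence must have length >= 5")
        out = np.empty((L, 4), dtype=np.float64)
        out[2:L - 2] = self._to[self._interior_contexts(s)]
        k0, k1, kr1, kr0 = self._edge_keys(s)
        out[0] = self._to_l0[k0]
        out[1] = self._to_l1[k1]
        out[L - 2] = self._to_r1[kr1]
        out[L - 1] = self._to_r0[kr0]
        return out

    def site_rates(self, seq: np.ndarray) -> np.ndarray:
        """(L,) total substitution probability per position (edge rule applied)."""
        s = np.asarray(seq, dtype=np.int64)
        if len(s) < 5:
            raise ValueError("sequence must have length >= 5")
        return _site_rates_kernel(s, self._ps_to, self._ps_to_l0, self._ps_to_l1,
                                  self._ps_to_r1, self._ps_to_r0)

    def _cum_row(self, s: np.ndarray, p: int) -> np.ndarray:
        """Cumulative joint substitute-to row for one position."""
        L = len(s)
        if 2 <= p < L - 2:
            c = s[p - 2:p + 3].astype(np.int64)
            idx = (((int(c[0]) * 4 + int(c[1])) * 4 + int(c[2])) * 4 + int(c[3])) * 4 + int(c[4])
            return self._cum_to[idx]
        k0, k1, kr1, kr0 = self._edge_keys(s.astype(np.int64))
        if p == 0:
            return self._cum_to_l0[k0]
        if p == 1:
            return self._cum_to_l1[k1]
        if p == L - 2:
            return self._cum_to_r1[kr1]
        return self._cum_to_r0[kr0]

    def site_substitution_probs(self, seq: np.ndarray, p: int) -> np.ndarray:
        """Distribution over {A,C,G,T} of position ``p`` of a child sequence."""
        s = np.asarray(seq, dtype=np.int64)
        if not 0 <= p < len(s):
            raise ValueError(f"position {p} out of range")
        to = self.sub_to_probs(s)[p]
        dist = to.copy()
        dist[s[p]] = 1.0 - to.sum()
        return dist

    def expected_mutations(self, seq: np.ndarray) -> float:
        """Analytic expectation of the number of substitutions in one child."""
        return float(self.sub_to_probs(seq).sum())

    def mutate_from(
        self, seq: np.ndarray, site_rates: np.ndarray, rng: np.random.Generator
    ) -> tuple[np.ndarray, list[MutationEvent]]:
        """One child of ``seq`` given its precomputed per-position rates.

        One uniform is consumed per position: the unit interval is split into
        the four substitute-to masses (A, C, G, T order) followed by the
        retain mass; the substitute-to rows are fetched lazily for the (rare)
        hit positions only, so siblings can share one ``site_rates`` vector.
        """
        L = len(seq)
        u = rng.random(L)
        s = seq.astype(np.int64)
        ev_pos = np.empty(L, dtype=np.int64)
        ev_to = np.empty(L, dtype=np.int64)
        n = _mutate_kernel(s, site_rates, u, self._cum_to, self._cum_to_l0,
                           self._cum_to_l1, self._cum_to_r1, self._cum_to_r0,
                           ev_pos, ev_to)
        child = seq.copy()
        events: list[MutationEvent] = []
        for k in range(n):
            p, b = int(ev_pos[k]), int(ev_to[k])
            child[p] = b
            events.append(MutationEvent(p, int(seq[p]), b))
        return child, events

    def mutate_child(
        self, seq: np.ndarray, rng: np.random.Generator
    ) -> tuple[np.ndarray, list[MutationEvent]]:
        """Sample one child sequence; every position is drawn independently."""
        s = np.asarray(seq, dtype=np.uint8)
        return self.mutate_from(s, self.site_rates(s), rng)


# ---------------------------------------------------------------------------
# Construction / IO
# ---------------------------------------------------------------------------

_W = {0, 3}          # A, T
_R = {0, 2}          # A, G
_S = {1, 2}          # C, G
_Y = {1, 3}          # C, T
_TRANSITION = {0: 2, 2: 0, 1: 3, 3: 1}

_HOT_FACTOR = 8.0
_COLD_FACTOR = 0.25
_TRANSITION_WEIGHT = 0.5  # remaining 0.5 split over the two transversions


def default_fivemer_table(mean_rate: float = 5e-4) -> FivemerTable:
    """Synthetic hotspot-motif 5-mer table (deterministic stand-in).

    Mutability is motif-based: WRC / GYW contexts (classic SHM hotspots) are
    8x the baseline, SYC / GRS coldspots 0.25x.  Substitutions favour
    transitions (probability 1/2) over each transversion (1/4).  The table is
    scaled so its uniform context mean equals ``mean_rate``.
    """
    rel = np.ones(N_CONTEXTS, dtype=np.float64)
    cond = np.zeros((N_CONTEXTS, 4), dtype=np.float64)
    for ctx in range(N_CONTEXTS):
        m2 = ctx // 256 % 4
        m1 = ctx // 64 % 4
        c = ctx // 16 % 4
        p1 = ctx // 4 % 4
        p2 = ctx % 4
        if c == 1 and m1 in _R and m2 in _W:       # WRC: hotspot C
            rel[ctx] = _HOT_FACTOR
        elif c == 2 and p1 in _Y and p2 in _W:     # GYW: hotspot G
            rel[ctx] = _HOT_FACTOR
        elif c == 1 and m1 in _Y and m2 in _S:     # SYC: coldspot C
            rel[ctx] = _COLD_FACTOR
        elif c == 2 and p1 in _R and p2 in _S:     # GRS: coldspot G
            rel[ctx] = _COLD_FACTOR
        for b in range(4):
            if b == c:
                continue
            cond[ctx, b] = _TRANSITION_WEIGHT if b == _TRANSITION[c] else (1 - _TRANSITION_WEIGHT) / 2
    p_sub = rel * (mean_rate / rel.mean())
    return FivemerTable(p_sub, cond)


def uniform_fivemer_table(rate: float = 5e-4) -> FivemerTable:
    """Context-independent fallback: every context mutates at ``rate`` with a
    uniform distribution over the three alternative bases."""
    p_sub = np.full(N_CONTEXTS, rate, dtype=np.float64)
    cond = np.full((N_CONTEXTS, 4), 1.0 / 3.0, dtype=np.float64)
    centre = np.arange(N_CONTEXTS) // 16 % 4
    cond[np.arange(N_CONTEXTS), centre] = 0.0
    return FivemerTable(p_sub, cond)


def load_fivemer_table(path) -> FivemerTable:
    """Read a TSV with columns fivemer, p_sub, p_to_A, p_to_C, p_to_G, p_to_T."""
    p_sub = np.full(N_CONTEXTS, np.nan, dtype=np.float64)
    cond = np.zeros((N_CONTEXTS, 4), dtype=np.float64)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["fivemer", "p_sub", "p_to_A", "p_to_C", "p_to_G", "p_to_T"]
        if header != expected:
            raise ValueError(f"expected TSV columns {expected}, got {header}")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise ValueError(f"line {ln}: expected 6 columns")
            mer = parts[0].upper()
            if len(mer) != 5 or any(ch not in _BASE_INDEX for ch in mer):
                raise ValueError(f"line {ln}: malformed 5-mer {parts[0]!r}")
            idx = _context_index(encode_dna(mer)[None, :])[0]
            p_sub[idx] = float(parts[1])
            cond[idx] = [float(x) for x in parts[2:6]]
    missing = np.flatnonzero(np.isnan(p_sub))
    if len(missing):
        names = ", ".join(fivemer_string(int(i)) for i in missing[:10])
        more = "" if len(missing) <= 10 else f" (+{len(missing) - 10} more)"
        raise ValueError(f"table is missing {len(missing)} contexts: {names}{more}")
    return FivemerTable(p_sub, cond)


def write_fivemer_table(table: FivemerTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("fivemer\tp_sub\tp_to_A\tp_to_C\tp_to_G\tp_to_T\n")
        for idx in range(N_CONTEXTS):
            row = "\t".join(format(x, ".10g") for x in table.cond[idx])
            fh.write(f"{fivemer_string(idx)}\t{table.p_sub[idx]:.10g}\t{row}\n")
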