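"""Affinity-maturation (AM) instantiation of the BDT engine.

Cells are either *memory* (g=0) or *activated* (g=1) B cells carrying a
nucleotide sequence of the antibody heavy-chain variable region (length 3L).
During an *infected* stage, activated cells divide (children mutate under the
5-mer SHM model), die at a rate shaped by resource competition, and mature
into memory cells; memory cells die slowly and are activated at a rate rising
with their affinity to the current round's target.  During a *dormant* stage
cells only die (fast for activated, slow for memory).

Affinity of a cell against the round target zeta is

    a = exp(A * Delta_zeta(xi))       (a = 0 if the DNA has an in-frame stop)

where Delta_zeta is a CDR-weighted BLOSUM similarity deficit (0 for the
target itself, negative otherwise) and A calibrates the selective pressure.
Memory activation follows  t = lambda_t * exp(-rho_a*A*Delta_0) * a**rho_a,
equal to lambda_t for a "typical" memory cell whose score is Delta_0.

Event rates in the infected stage (per cell, per day):

    birth      g * lambda_b
    death      g * [lambda_b(1-rho_p-rho_m) * sigma/(C*a) + rho_p*lambda_b]
               + (1-g) * lambda_d'
    transform  g * rho_m*lambda_b + (1-g) * t

with sigma the total affinity of activated cells and C the carrying
capacity.  An activated cell whose sequence contains a stop codon (a = 0)
instead receives the fast death rate lambda_d.  All rates are expressed as
polynomial terms so the engine samples events in O(log n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .bdt import (
    ALIVE,
    DEATH,
    EngineState,
    Genealogy,
    RateSpec,
    RateTerm,
    run_bdt,
)
from .shm import FivemerTable, MutationEvent, default_fivemer_table, encode_dna

__all__ = [
    "AA_ALPHABET",
    "STOP_CODE",
    "AMConfig",
    "AMRunResult",
    "RoundStats",
    "TargetScorer",
    "blosum62",
    "blosum_delta",
    "affinity",
    "memory_activation_rate",
    "cell_rates",
    "should_switch",
    "make_slots",
    "infected_spec",
    "dormant_spec",
    "translate_codes",
    "aa_to_codes",
    "codes_to_aa",
    "cdr_mask",
    "synthetic_root_sequence",
    "diverged_target",
    "reduced_config",
    "default_config",
    "run_am",
    "sample_cells",
    "materialize_sequence",
]

# ---------------------------------------------------------------------------
# Amino acids, translation, BLOSUM
# ---------------------------------------------------------------------------

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
STOP_CODE = 20
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

_BASES = "ACGT"


def _build_codon_table() -> np.ndarray:
    tbl = CodonTable.unambiguous_dna_by_id[1]
    out = np.full(64, STOP_CODE, dtype=np.uint8)
    for b0 in range(4):
        for b1 in range(4):
            for b2 in range(4):
                codon = _BASES[b0] + _BASES[b1] + _BASES[b2]
                if codon in tbl.stop_codons:
                    continue
                out[16 * b0 + 4 * b1 + b2] = _AA_INDEX[tbl.forward_table[codon]]
    return out


_CODON_AA = _build_codon_table()


def translate_codes(codes: np.ndarray) -> np.ndarray:
    """Nucleotide codes (3L,) -> amino-acid codes (L,), STOP_CODE for stops."""
    c = np.asarray(codes, dtype=np.int64)
    if len(c) % 3:
        raise ValueError("sequence length must be a multiple of 3")
    c = c.reshape(-1, 3)
    return _CODON_AA[16 * c[:, 0] + 4 * c[:, 1] + c[:, 2]]


def aa_to_codes(seq: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[a] for a in seq.upper()], dtype=np.uint8)
    except KeyError as e:
        raise ValueError(f"unknown amino-acid code {e.args[0]!r}") from None


def codes_to_aa(codes: np.ndarray) -> str:
    return "".join("*" if c == STOP_CODE else AA_ALPHABET[int(c)] for c in codes)


def blosum62() -> np.ndarray:
    """BLOSUM62 as a (20, 20) integer-valued array over AA_ALPHABET order."""
    m = substitution_matrices.load("BLOSUM62")
    out = np.zeros((20, 20), dtype=np.float64)
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            out[i, j] = m[a, b]
    return out


_BLOSUM62 = blosum62()


def cdr_mask(L: int, cdr_ranges: Sequence[tuple[int, int]]) -> np.ndarray:
    """1-based inclusive (start, end) ranges -> boolean mask of length L."""
    mask = np.zeros(L, dtype=bool)
    for lo, hi in cdr_ranges:
        if not (1 <= lo <= hi <= L):
            raise ValueError(f"CDR range ({lo}, {hi}) outside 1..{L}")
        mask[lo - 1:hi] = True
    return mask


# ---------------------------------------------------------------------------
# Scoring (Delta), affinity, activation
# ---------------------------------------------------------------------------

def blosum_delta(
    xi,
    zeta,
    cdr: np.ndarray,
    w_f: float,
    delta: Optional[np.ndarray] = None,
) -> float:
    """CDR-weighted BLOSUM score deficit of sequence ``xi`` against target ``zeta``.

    Delta_zeta(xi) = sum_{p in CDR} (d(xi_p, zeta_p) - d(zeta_p, zeta_p))
                   + w_f * sum_{p not in CDR} (same);   Delta_zeta(zeta) = 0.
    """
    d = _BLOSUM62 if delta is None else delta
    x = aa_to_codes(xi) if isinstance(xi, str) else np.asarray(xi, dtype=np.int64)
    z = aa_to_codes(zeta) if isinstance(zeta, str) else np.asarray(zeta, dtype=np.int64)
    if len(x) != len(z):
        raise ValueError(f"length mismatch: {len(x)} vs {len(z)}")
    if len(x) != len(cdr):
        raise ValueError("CDR mask length does not match sequences")
    w = np.where(cdr, 1.0, w_f)
    terms = d[x, z] - d[z, z]
    return float((w * terms).sum())


def affinity(score: float, A: float) -> float:
    """a = exp(A * score); the caller sets a = 0 for stop-codon sequences."""
    return math.exp(A * score)


def memory_activation_rate(a: float, lambda_t: float, rho_a: float,
                           A: float, Delta_0: float) -> float:
    """Activation rate of a memory cell with affinity ``a`` (per day).

    Equals lambda_t when the cell's score is the typical memory score Delta_0
    and increases monotonically with affinity as a**rho_a.
    """
    if a < 0:
        raise ValueError("affinity must be nonnegative")
    if a == 0.0:
        return 0.0
    return lambda_t * math.exp(-rho_a * A * Delta_0) * a ** rho_a


class TargetScorer:
    """Vectorised Delta/affinity evaluation against one round target."""

    def __init__(self, zeta: np.ndarray, cdr: np.ndarray, w_f: float,
                 delta: Optional[np.ndarray] = None):
        d = _BLOSUM62 if delta is None else delta
        z = np.asarray(zeta, dtype=np.int64)
        if np.any(z >= 20):
            raise ValueError("target sequence must not contain a stop symbol")
        w = np.where(cdr, 1.0, w_f)
        # M[p, aa] = w_p * (d(aa, zeta_p) - d(zeta_p, zeta_p))
        self.M = w[:, None] * (d[:, z].T - d[z, z][:, None])
        self.L = len(z)
        self.zeta = z

    def score(self, aa_codes: np.ndarray) -> Optional[float]:
        """Delta score, or None if the translation contains a stop."""
        if np.any(aa_codes == STOP_CODE):
            return None
        return float(self.M[np.arange(self.L), aa_codes].sum())


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class AMConfig:
    """All model parameters; defaults are the full-scale standard values."""

    lambda_b: float = 6.0          # activated-cell division rate (1/day)
    lambda_d: float = 1e4          # activated-cell death rate, dormant stage (1/day)
    lambda_dp: float = 1.0 / 402.0  # memory-cell death rate (1/day)
    lambda_t: float = 0.01         # activation rate of a typical memory cell (1/day)
    rho_p: float = 0.01            # plasma-differentiation fraction per division
    rho_m: float = 0.25            # memory-differentiation fraction per division
    rho_a: float = 0.5             # affinity sensitivity of activation
    A: float = 0.1                 # selective pressure
    w_f: float = 1.0 / 3.0         # framework-region score weight
    kappa: float = 2.0             # target-vs-antigen distance scaling
    mu: float = 5e-4               # SHM rate per bp per generation
    L: int = 125                   # amino-acid sequence length
    cdr: tuple[tuple[int, int], ...] = ((31, 35), (50, 65), (98, 114))
    Delta_0: float = -120.0        # typical memory-cell score
    Delta_0p: float = -75.0        # score granting cure (sets M)
    C: float = 1e5                 # carrying capacity (cells)
    M: Optional[float] = None      # affinity-sum switch threshold; default C*e^(A*Delta_0p)
    r: int = 1                     # rounds of infection
    t_start: tuple[float, ...] = (0.0,)  # infected-stage start times (days)
    root_sequence: str = ""        # naive-cell DNA, length 3L, in frame
    targets: Optional[tuple[str, ...]] = None  # per-round targets (AA, length L)
    switch_rule: str = "affinity_threshold"    # or "fixed_duration"
    infected_duration: float = 50.0            # D, for fixed_duration (days)
    sample_size: int = 200         # default number of sampled cells
    max_infected_days: float = 300.0
    max_events: int = 20_000_000
    ts_interval: float = 0.25      # time-series sampling interval (days)
    fivemer_table: Optional[FivemerTable] = None  # uncalibrated; default synthetic

    def __post_init__(self):
        if not self.root_sequence:
            self.root_sequence = synthetic_root_sequence(self.L)

    # -- derived -------------------------------------------------------
    @property
    def M_value(self) -> float:
        return self.C * math.exp(self.A * self.Delta_0p) if self.M is None else self.M

    @property
    def cdr_mask(self) -> np.ndarray:
        return cdr_mask(self.L, self.cdr)

    def table(self) -> FivemerTable:
        base = self.fivemer_table if self.fivemer_table is not None else default_fivemer_table()
        return base.calibrate(self.mu)

    def target_codes(self) -> list[np.ndarray]:
        if self.targets is None:
            raise ValueError("config has no targets; provide one AA sequence per round")
        return [aa_to_codes(t) for t in self.targets]

    def validate(self) -> None:
        for name in ("lambda_b", "lambda_d", "lambda_dp", "lambda_t"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.rho_p and 0 <= self.rho_m and self.rho_p + self.rho_m < 1):
            raise ValueError("need rho_p, rho_m >= 0 and rho_p + rho_m < 1")
        if not (0 < self.mu < 0.25):
            raise ValueError("mu must lie in (0, 0.25)")
        if len(self.t_start) != self.r:
            raise ValueError("t_start must list one start time per round")
        if any(b <= a for a, b in zip(self.t_start, self.t_start[1:])):
            raise ValueError("round start times must be strictly increasing")
        if self.switch_rule not in ("fixed_duration", "affinity_threshold"):
            raise ValueError(f"unknown switch rule {self.switch_rule!r}")
        if self.switch_rule == "fixed_duration":
            for a, b in zip(self.t_start, self.t_start[1:]):
                if b < a + self.infected_duration:
                    raise ValueError("rounds overlap: fixed infected duration passes next start")
        root = encode_dna(self.root_sequence)
        if len(root) != 3 * self.L:
            raise ValueError(f"root sequence must have length 3L = {3 * self.L}")
        if np.any(translate_codes(root) == STOP_CODE):
            raise ValueError("root sequence contains an in-frame stop codon")
        self.cdr_mask  # range check
        if self.targets is not None:
            if len(self.targets) != self.r:
                raise ValueError("need one target per round")
            for i, t in enumerate(self.targets):
                codes = aa_to_codes(t)
                if len(codes) != self.L:
                    raise ValueError(f"target {i + 1} has length {len(codes)}, expected {self.L}")


def synthetic_root_sequence(L: int, seed: int = 20240 + 7) -> str:
    """Deterministic synthetic in-frame naive sequence of length 3L (no stops)."""
    rng = np.random.default_rng(seed)
    sense = [i for i in range(64) if _CODON_AA[i] != STOP_CODE]
    codons = rng.choice(sense, size=L)
    out = []
    for c in codons:
        out.append(_BASES[c // 16] + _BASES[c // 4 % 4] + _BASES[c % 4])
    return "".join(out)


def diverged_target(zeta: str, n_sub: int, cdr_ranges: Sequence[tuple[int, int]],
                    delta: Optional[np.ndarray] = None) -> str:
    """Deterministically substitute ``n_sub`` evenly spaced CDR positions.

    Each chosen position is replaced by the alphabetically first amino acid
    with a non-positive BLOSUM score against the original, giving a moderate,
    reproducible divergence used by the bundled configurations.
    """
    d = _BLOSUM62 if delta is None else delta
    codes = aa_to_codes(zeta)
    mask = cdr_mask(len(codes), cdr_ranges)
    cdr_pos = np.flatnonzero(mask)
    if n_sub > len(cdr_pos):
        raise ValueError("more substitutions requested than CDR positions")
    picks = cdr_pos[np.linspace(0, len(cdr_pos) - 1, n_sub).round().astype(int)]
    for p in picks:
        orig = codes[p]
        for cand in range(20):
            if cand != orig and d[orig, cand] <= 0:
                codes[p] = cand
                break
    return codes_to_aa(codes)


def reduced_config(r: int = 2, sample_size: int = 50) -> AMConfig:
    """Scaled-down study conditions: C = 2000, L = 25, score scale / 5.

    Round 1 targets the naive sequence itself; later rounds use a target
    diverged at 4 CDR positions, so the activated population must evolve its
    affinity upward before the cure threshold sigma >= M can be reached.
    """
    L = 25
    cdr = ((6, 7), (10, 12), (20, 22))
    root = synthetic_root_sequence(L)
    zeta1 = codes_to_aa(translate_codes(encode_dna(root)))
    targets = [zeta1]
    for _ in range(1, r):
        targets.append(diverged_target(targets[-1], 4, cdr))
    t_start = tuple(200.0 * i for i in range(r))
    return AMConfig(
        L=L, cdr=cdr, C=2000.0, Delta_0=-24.0, Delta_0p=-15.0,
        r=r, t_start=t_start, root_sequence=root, targets=tuple(targets),
        switch_rule="affinity_threshold", max_infected_days=150.0,
        sample_size=sample_size, ts_interval=0.1,
    )


def default_config(r: int, targets: Sequence[str], t_start: Sequence[float],
                   root_sequence: Optional[str] = None, **overrides) -> AMConfig:
    """Full-scale configuration with user-supplied targets and schedule."""
    cfg = AMConfig(r=r, targets=tuple(targets), t_start=tuple(t_start), **overrides)
    if root_sequence is not None:
        cfg.root_sequence = root_sequence
    return cfg


# ---------------------------------------------------------------------------
# Slots and rate specs
# ---------------------------------------------------------------------------

# slot layout
SLOT_G = 0        # g
SLOT_MG = 1       # 1 - g
SLOT_T = 2        # (1 - g) * activation rate
SLOT_GOA = 3      # g / a   (0 when a = 0)
SLOT_GA = 4       # g * a
SLOT_ZSTOP = 5    # g * 1[a == 0]
N_SLOTS = 6


def make_slots(g: int, a: float, t_act: float) -> np.ndarray:
    return np.array([
        g,
        1 - g,
        (1 - g) * t_act,
        g / a if (g and a > 0) else 0.0,
        g * a,
        g * (1.0 if a == 0.0 else 0.0),
    ], dtype=np.float64)


def _sigma(state: EngineState) -> float:
    return state.totals[SLOT_GA]


def infected_spec(cfg: AMConfig) -> RateSpec:
    return RateSpec(
        birth=(RateTerm(cfg.lambda_b, SLOT_G),),
        death=(
            RateTerm(cfg.lambda_b * (1 - cfg.rho_p - cfg.rho_m) / cfg.C, SLOT_GOA, _sigma),
            RateTerm(cfg.rho_p * cfg.lambda_b, SLOT_G),
            RateTerm(cfg.lambda_dp, SLOT_MG),
            RateTerm(cfg.lambda_d, SLOT_ZSTOP),
        ),
        transform=(
            RateTerm(cfg.rho_m * cfg.lambda_b, SLOT_G),
            RateTerm(1.0, SLOT_T),
        ),
    )


def dormant_spec(cfg: AMConfig) -> RateSpec:
    return RateSpec(
        death=(
            RateTerm(cfg.lambda_d, SLOT_G),
            RateTerm(cfg.lambda_dp, SLOT_MG),
        ),
    )


def should_switch(cfg: AMConfig, stage_start: float, clock: float, sigma: float) -> bool:
    """Has the infected stage that began at ``stage_start`` ended by ``clock``?

    Under ``fixed_duration`` the stage ends at stage_start + D; under
    ``affinity_threshold`` it ends as soon as sigma >= M (boundary inclusive).
    """
    if cfg.switch_rule == "fixed_duration":
        return clock >= stage_start + cfg.infected_duration
    return sigma >= cfg.M_value


def cell_rates(g: int, a: float, stage: str, sigma: float, cfg: AMConfig
               ) -> tuple[float, float, float]:
    """Direct per-cell rate evaluation (independent of the slot machinery)."""
    if stage == "dormant":
        return 0.0, g * cfg.lambda_d + (1 - g) * cfg.lambda_dp, 0.0
    if stage != "infected":
        raise ValueError(f"unknown stage {stage!r}")
    b = g * cfg.lambda_b
    if g:
        if a > 0:
            d = cfg.lambda_b * (1 - cfg.rho_p - cfg.rho_m) * sigma / (cfg.C * a) \
                + cfg.rho_p * cfg.lambda_b
        else:
            d = cfg.lambda_d + cfg.rho_p * cfg.lambda_b
    else:
        d = cfg.lambda_dp
    t_act = memory_activation_rate(a, cfg.lambda_t, cfg.rho_a, cfg.A, cfg.Delta_0)
    t = g * cfg.rho_m * cfg.lambda_b + (1 - g) * t_act
    return b, d, t


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------

@dataclass
class RoundStats:
    round: int
    t_begin: float
    t_end: float           # end of the infected stage
    duration: float
    sigma_end: float
    n_activated_end: int
    n_memory_end: int


@dataclass
class AMRunResult:
    config: AMConfig
    genealogy: Genealogy
    g: list[int]                      # per-entity type flag
    muts: list[Optional[list[MutationEvent]]]
    sequences: dict[int, np.ndarray]  # alive cells only
    series: np.ndarray                # (t, round, stage, n_act, n_mem, sigma)
    rounds: list[RoundStats]
    reason: str                       # completed | extinct | not_overcome | truncated
    n_events: int

    @property
    def alive(self) -> list[int]:
        return [e for e in range(len(self.genealogy)) if self.genealogy.end_event[e] == ALIVE]

    def mean_activated_affinity(self) -> np.ndarray:
        """Per series row: sigma / n_act (NaN where no activated cells)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.series[:, 3] > 0,
                            self.series[:, 5] / self.series[:, 3], np.nan)


def run_am(cfg: AMConfig, seed: int, sampler: str = "fast",
           record_events: bool = False) -> AMRunResult:
    """Simulate all rounds starting from one naive memory cell at t_1.

    Randomness is split into independent named streams (engine, mutation)
    derived from ``seed`` so trajectories are reproducible and the engine
    stream stays comparable between the fast and naive samplers.
    """
    cfg.validate()
    ss = np.random.SeedSequence(seed)
    engine_ss, mutation_ss = ss.spawn(2)
    engine_rng = np.random.default_rng(engine_ss)
    mutation_rng = np.random.default_rng(mutation_ss)
    table = cfg.table()
    cmask = cfg.cdr_mask
    target_codes = cfg.target_codes()

    gen = Genealogy(record_events=record_events)
    cells: dict[int, tuple[np.ndarray, float]] = {}  # eid -> (sequence, affinity)
    g_flags: list[int] = []
    muts: list[Optional[list[MutationEvent]]] = []
    ctx: dict = {"scorer": None}
    act_scale = cfg.lambda_t * math.exp(-cfg.rho_a * cfg.A * cfg.Delta_0)

    def compute_affinity(codes: np.ndarray) -> float:
        sc = ctx["scorer"].score(translate_codes(codes))
        return 0.0 if sc is None else affinity(sc, cfg.A)

    def slots_for(g: int, a: float) -> np.ndarray:
        return make_slots(g, a, act_scale * a ** cfg.rho_a)

    def birth_factory(pid, parent_slots, child_ids, _rng):
        pseq, pa = cells.pop(pid)
        rates = table.site_rates(pseq)
        out = []
        for cid in child_ids:
            cseq, events = table.mutate_from(pseq, rates, mutation_rng)
            g_flags.append(1)
            muts.append(events or None)
            # the affinity is a pure function of the sequence: recompute only
            # when the child actually mutated
            a = compute_affinity(cseq) if events else pa
            cells[cid] = (cseq, a)
            out.append(slots_for(1, a))
        return out

    def transform_factory(pid, parent_slots, child_ids, _rng):
        (cid,) = child_ids
        cells[cid] = cells.pop(pid)  # sequence (and hence affinity) unchanged
        g_flags.append(1 - g_flags[pid])
        muts.append(None)
        return [slots_for(g_flags[cid], cells[cid][1])]

    # time series bookkeeping -------------------------------------------------
    series: list[tuple[float, float, float, float, float, float]] = []
    cursor = {"round": 0.0, "stage": 1.0, "next": 0.0}

    def snapshot(state: EngineState, t: float) -> None:
        series.append((t, cursor["round"], cursor["stage"],
                       state.totals[SLOT_G], state.totals[SLOT_MG], state.totals[SLOT_GA]))

    def on_event(state: EngineState, t: float, cls: int, eid: int) -> None:
        if cls == DEATH:
            cells.pop(eid, None)
        if t >= cursor["next"]:
            snapshot(state, t)
            cursor["next"] = t + cfg.ts_interval

    # initial state -----------------------------------------------------------
    root_codes = encode_dna(cfg.root_sequence)
    state = EngineState(N_SLOTS, capacity=1024)
    eid0 = gen.append(None, cfg.t_start[0])
    g_flags.append(0)
    muts.append(None)
    cells[eid0] = (root_codes, 1.0)
    state.add(eid0, make_slots(0, 1.0, 0.0))  # placeholder; retargeted below

    def retarget(state: EngineState) -> EngineState:
        """Recompute every living cell's affinity slots against the new target."""
        fresh = EngineState(N_SLOTS, capacity=state.capacity)
        for eid in sorted(state.entity_pos):
            seq, _ = cells[eid]
            a = compute_affinity(seq)
            cells[eid] = (seq, a)
            fresh.add(eid, slots_for(g_flags[eid], a))
        return fresh

    rounds: list[RoundStats] = []
    n_events = 0
    reason = "completed"
    t_now = cfg.t_start[0]
    M = cfg.M_value

    def finish(reason: str) -> AMRunResult:
        sequences = {eid: seq for eid, (seq, _a) in cells.items()}
        return AMRunResult(cfg, gen, g_flags, muts, sequences,
                           np.array(series, dtype=np.float64).reshape(-1, 6),
                           rounds, reason, n_events)

    for l in range(cfg.r):
        ctx["scorer"] = TargetScorer(target_codes[l], cmask, cfg.w_f)
        state = retarget(state)
        t_begin = max(t_now, cfg.t_start[l])
        cursor["round"], cursor["stage"] = float(l + 1), 1.0
        cursor["next"] = t_begin + cfg.ts_interval
        snapshot(state, t_begin)
        if cfg.switch_rule == "fixed_duration":
            stop_time, predicate = t_begin + cfg.infected_duration, None
        else:
            stop_time = t_begin + cfg.max_infected_days
            predicate = lambda s, t: should_switch(cfg, t_begin, t, s.totals[SLOT_GA])
        res = run_bdt(
            state, gen, infected_spec(cfg), engine_rng,
            t0=t_begin, stop_time=stop_time, predicate=predicate,
            max_events=cfg.max_events - n_events,
            birth_factory=birth_factory, transform_factory=transform_factory,
            on_event=on_event, sampler=sampler,
        )
        n_events += res.n_events
        t_now = res.t_end
        snapshot(state, t_now)
        rounds.append(RoundStats(l + 1, t_begin, t_now, t_now - t_begin,
                                 float(state.totals[SLOT_GA]),
                                 int(round(state.totals[SLOT_G])),
                                 int(round(state.totals[SLOT_MG]))))
        if res.reason == "extinct":
            return finish("extinct")
        if res.reason == "max_events":
            return finish("truncated")
        if cfg.switch_rule == "affinity_threshold" and res.reason == "time":
            # the infection was never overcome within the guard window
            return finish("not_overcome")
        if l + 1 < cfg.r:
            cursor["stage"] = 0.0
            cursor["next"] = t_now + cfg.ts_interval
            res = run_bdt(
                state, gen, dormant_spec(cfg), engine_rng,
                t0=t_now, stop_time=cfg.t_start[l + 1],
                max_events=cfg.max_events - n_events,
                birth_factory=birth_factory, transform_factory=transform_factory,
                on_event=on_event, sampler=sampler,
            )
            n_events += res.n_events
            t_now = res.t_end
            snapshot(state, t_now)
            if res.reason == "extinct":
                return finish("extinct")
            if res.reason == "max_events":
                return finish("truncated")
    return finish("completed")


# ---------------------------------------------------------------------------
# Sampling and sequence materialisation
# ---------------------------------------------------------------------------

def sample_cells(result: AMRunResult, size: int, policy: str = "memory_at_end",
                 rng: Optional[np.random.Generator] = None, seed: Optional[int] = None,
                 ) -> dict[str, int]:
    """Uniform sample without replacement; returns {'Psi_1': entity_id, ...}."""
    if rng is None:
        rng = np.random.default_rng(seed)
    alive = result.alive
    if policy == "memory_at_end":
        pool = [e for e in alive if result.g[e] == 0]
    elif policy == "all_alive_at_end":
        pool = list(alive)
    else:
        raise ValueError(f"unknown sampling policy {policy!r}")
    pool.sort()
    if size > len(pool):
        raise ValueError(f"requested {size} samples but only {len(pool)} eligible cells")
    if size == 0:
        return {}
    chosen = sorted(rng.choice(len(pool), size=size, replace=False).tolist())
    return {f"Psi_{k + 1}": pool[i] for k, i in enumerate(chosen)}


def materialize_sequence(result: AMRunResult, eid: int) -> np.ndarray:
    """Reconstruct any entity's sequence from the root and the diff chain."""
    if eid in result.sequences:
        return result.sequences[eid].copy()
    chain = []
    e = eid
    while e >= 0:
        chain.append(e)
        e = result.genealogy.parent[e]
    seq = encode_dna(result.config.root_sequence)
    for e in reversed(chain):
        for ev in result.muts[e] or ():
            seq[ev.pos] = ev.to_base
    return seq
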