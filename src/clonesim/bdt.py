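"""Generic continuous-time birth/death/transformation (BDT) process sampler.

Entities carry a vector of nonnegative numeric properties ("slots").  Each of
the three event classes (birth, death, transformation) has a per-entity rate
expressed as a sum of *polynomial terms*

    rate(entity i) = sum_terms  coeff * aggregate_factor(S) * slot_value_i

where ``S`` is the component-wise sum of slots over all active entities.  This
polynomial form lets the sampler find the total event rate in O(#terms) and
select the next (class, entity) pair in O(log n) using per-slot Fenwick
(binary indexed) trees of partial sums, so a genealogy on k nodes is sampled
in O(k log k) overall.

Two samplers share one canonical random-stream contract so that they produce
bit-identical trajectories when fed the same stream:

1. one uniform draw maps to the exponential waiting time ``dt = -log1p(-u)/lam``;
2. one uniform draw ``u in [0, lam)`` is mapped to (class, term, entity) by a
   fixed ordering: classes birth, death, transform; terms in spec order;
   entities in ascending slot-position order.

:func:`draw_event` is the fast Fenwick-based path; :func:`naive_draw_event`
recomputes every entity's rate by direct summation and is used as the test
oracle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, NamedTuple, Optional, Sequence

import numpy as np

__all__ = [
    "BIRTH",
    "DEATH",
    "TRANSFORM",
    "ALIVE",
    "EVENT_NAMES",
    "RateTerm",
    "RateSpec",
    "EngineState",
    "Genealogy",
    "BDTResult",
    "total_rates",
    "draw_event",
    "naive_draw_event",
    "apply_event",
    "run_bdt",
]

# event / end-event codes
ALIVE = 0
BIRTH = 1
DEATH = 2
TRANSFORM = 3
EVENT_NAMES = {ALIVE: "alive", BIRTH: "birth", DEATH: "death", TRANSFORM: "transform"}


# ---------------------------------------------------------------------------
# Fenwick tree primitives (operating on 1-indexed float64 arrays).
# numba acceleration is used when available; the pure-Python fallbacks are
# algorithmically identical.
# ---------------------------------------------------------------------------

def _py_fw_update_all(tree: np.ndarray, size: int, pos: int, deltas: np.ndarray) -> None:
    for s in range(tree.shape[0]):
        d = deltas[s]
        if d == 0.0:
            continue
        idx = pos + 1
        row = tree[s]
        while idx <= size:
            row[idx] += d
            idx += idx & (-idx)


def _py_fw_search(row: np.ndarray, size: int, u: float) -> int:
    """Smallest 0-based position p with prefix(p+1) > u (for u < total)."""
    idx = 0
    bit = 1
    while bit * 2 <= size:
        bit *= 2
    rem = u
    while bit:
        nxt = idx + bit
        if nxt <= size and row[nxt] <= rem:
            idx = nxt
            rem -= row[nxt]
        bit >>= 1
    return idx


def _py_state_add(tree, slots, totals, size, pos, vals):
    for s in range(vals.shape[0]):
        v = vals[s]
        slots[s, pos] = v
        totals[s] += v
        if v != 0.0:
            idx = pos + 1
            row = tree[s]
            while idx <= size:
                row[idx] += v
                idx += idx & (-idx)


def _py_state_remove(tree, slots, totals, size, pos):
    for s in range(slots.shape[0]):
        v = slots[s, pos]
        slots[s, pos] = 0.0
        totals[s] -= v
        if v != 0.0:
            idx = pos + 1
            row = tree[s]
            while idx <= size:
                row[idx] -= v
                idx += idx & (-idx)


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _fw_update_all = njit(cache=True)(_py_fw_update_all)
    _fw_search = njit(cache=True)(_py_fw_search)
    _state_add = njit(cache=True)(_py_state_add)
    _state_remove = njit(cache=True)(_py_state_remove)
except Exception:  # pragma: no cover
    _fw_update_all = _py_fw_update_all
    _fw_search = _py_fw_search
    _state_add = _py_state_add
    _state_remove = _py_state_remove


# ---------------------------------------------------------------------------
# Rate specification
# ---------------------------------------------------------------------------

class RateTerm(NamedTuple):
    """One polynomial rate term: ``coeff * agg(state) * slots[slot]``.

    ``agg`` is an O(1) function of the aggregate state (e.g. the total
    affinity sigma); ``None`` means the constant factor 1.
    """

    coeff: float
    slot: int
    agg: Optional[Callable[["EngineState"], float]] = None


@dataclass(frozen=True)
class RateSpec:
    """Per-class term lists; term order within a class is part of the
    canonical event-selection order."""

    birth: tuple[RateTerm, ...] = ()
    death: tuple[RateTerm, ...] = ()
    transform: tuple[RateTerm, ...] = ()

    @property
    def classes(self) -> tuple[tuple[int, tuple[RateTerm, ...]], ...]:
        return ((BIRTH, self.birth), (DEATH, self.death), (TRANSFORM, self.transform))

    def entity_rates(self, slots: np.ndarray, state: "EngineState") -> tuple[float, float, float]:
        """Direct per-entity rate evaluation (used in tests/oracles)."""
        out = []
        for _, terms in self.classes:
            r = 0.0
            for coeff, slot, agg in terms:
                a = 1.0 if agg is None else agg(state)
                r += coeff * a * float(slots[slot])
            out.append(r)
        return tuple(out)


# ---------------------------------------------------------------------------
# Aggregate state
# ---------------------------------------------------------------------------

class EngineState:
    """Active-entity slot matrix with per-slot Fenwick trees of partial sums.

    Positions of dead entities are recycled through a LIFO free list; entity
    ids are never reused.  Running per-slot totals are maintained with deltas
    and can be rebuilt from scratch to cancel floating-point drift.
    """

    def __init__(self, n_slots: int, capacity: int = 1024):
        self.n_slots = n_slots
        self.capacity = capacity
        self.slots = np.zeros((n_slots, capacity), dtype=np.float64)
        self.tree = np.zeros((n_slots, capacity + 1), dtype=np.float64)
        self.totals = np.zeros(n_slots, dtype=np.float64)
        self.pos_entity = np.full(capacity, -1, dtype=np.int64)
        self.entity_pos: dict[int, int] = {}
        self.free: list[int] = []
        self.next_pos = 0
        self.n_active = 0

    # -- bookkeeping ---------------------------------------------------
    def _grow(self) -> None:
        new_cap = self.capacity * 2
        slots = np.zeros((self.n_slots, new_cap), dtype=np.float64)
        slots[:, : self.capacity] = self.slots
        pe = np.full(new_cap, -1, dtype=np.int64)
        pe[: self.capacity] = self.pos_entity
        self.slots = slots
        self.pos_entity = pe
        self.capacity = new_cap
        self.tree = np.zeros((self.n_slots, new_cap + 1), dtype=np.float64)
        self._rebuild_trees()

    def _rebuild_trees(self) -> None:
        self.tree[:] = 0.0
        for s in range(self.n_slots):
            # O(n) Fenwick construction
            row = self.tree[s]
            row[1:] = self.slots[s]
            for idx in range(1, self.capacity + 1):
                par = idx + (idx & (-idx))
                if par <= self.capacity:
                    row[par] += row[idx]
        self.totals = self.slots.sum(axis=1)

    def rebuild(self) -> None:
        """Recompute trees and totals from the slot matrix (drift control)."""
        self._rebuild_trees()

    def add(self, entity_id: int, slot_values: Sequence[float]) -> int:
        if entity_id in self.entity_pos:
            raise ValueError(f"entity {entity_id} already active")
        vals = np.asarray(slot_values, dtype=np.float64)
        if vals.shape != (self.n_slots,):
            raise ValueError("slot vector has wrong length")
        if vals.min() < 0:
            raise ValueError("slot values must be nonnegative")
        if self.free:
            pos = self.free.pop()
        else:
            if self.next_pos >= self.capacity:
                self._grow()
            pos = self.next_pos
            self.next_pos += 1
        self.pos_entity[pos] = entity_id
        self.entity_pos[entity_id] = pos
        _state_add(self.tree, self.slots, self.totals, self.capacity, pos, vals)
        self.n_active += 1
        return pos

    def remove(self, entity_id: int) -> None:
        pos = self.entity_pos.pop(entity_id, None)
        if pos is None:
            raise ValueError(f"entity {entity_id} is not active")
        _state_remove(self.tree, self.slots, self.totals, self.capacity, pos)
        self.pos_entity[pos] = -1
        self.free.append(pos)
        self.n_active -= 1

    # -- queries -------------------------------------------------------
    def slot_total(self, slot: int) -> float:
        return float(self.totals[slot])

    def active_positions(self) -> np.ndarray:
        """Positions of active entities in ascending (canonical) order."""
        return np.flatnonzero(self.pos_entity[: self.next_pos] >= 0)

    def active_entities(self) -> list[int]:
        return [int(self.pos_entity[p]) for p in self.active_positions()]

    def entity_slots(self, entity_id: int) -> np.ndarray:
        return self.slots[:, self.entity_pos[entity_id]].copy()

    def max_drift(self) -> float:
        """Max relative discrepancy between running totals and direct sums."""
        direct = self.slots.sum(axis=1)
        denom = np.maximum(np.abs(direct), 1.0)
        return float(np.max(np.abs(direct - self.totals) / denom))

    def verify(self, rtol: float = 1e-9) -> None:
        if self.max_drift() > rtol:
            raise AssertionError("aggregate drift exceeds tolerance; rebuild required")


# ---------------------------------------------------------------------------
# Genealogy
# ---------------------------------------------------------------------------

@dataclass
class BDTResult:
    reason: str  # "time" | "extinct" | "max_events" | "predicate" | "stalled"
    t_end: float
    n_events: int
    truncated: bool = False


class Genealogy:
    """Append-only columnar record of every entity that ever existed."""

    def __init__(self, record_events: bool = False):
        self.parent: list[int] = []
        self.birth_time: list[float] = []
        self.end_time: list[Optional[float]] = []
        self.end_event: list[int] = []
        self.event_log: Optional[list[tuple[float, int, int]]] = [] if record_events else None
        self.root_id: Optional[int] = None

    def __len__(self) -> int:
        return len(self.parent)

    def append(self, parent_id: Optional[int], t: float) -> int:
        eid = len(self.parent)
        self.parent.append(-1 if parent_id is None else parent_id)
        self.birth_time.append(t)
        self.end_time.append(None)
        self.end_event.append(ALIVE)
        if parent_id is None and self.root_id is None:
            self.root_id = eid
        return eid

    def close(self, eid: int, t: float, code: int) -> None:
        if self.end_event[eid] != ALIVE:
            raise ValueError(f"entity {eid} already closed")
        if t < self.birth_time[eid]:
            raise ValueError("end time precedes birth time")
        self.end_time[eid] = t
        self.end_event[eid] = code

    def log(self, t: float, code: int, eid: int) -> None:
        if self.event_log is not None:
            self.event_log.append((t, code, eid))

    def children_map(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {}
        for eid, p in enumerate(self.parent):
            if p >= 0:
                ch.setdefault(p, []).append(eid)
        return ch

    def write_event_log(self, path) -> None:
        """Debug TSV of the recorded events: time, class, entity_id, parent_id."""
        if self.event_log is None:
            raise ValueError("genealogy was created without event recording")
        with open(path, "w") as fh:
            fh.write("time\tclass\tentity_id\tparent_id\n")
            for t, cls, eid in self.event_log:
                fh.write(f"{t:.10g}\t{EVENT_NAMES[cls]}\t{eid}\t{self.parent[eid]}\n")

    def validate(self) -> None:
        """Check rooted-tree structure and monotone times along lineages."""
        for eid, p in enumerate(self.parent):
            if p >= 0:
                if p >= eid:
                    raise AssertionError("parent id must precede child id")
                if self.birth_time[eid] < self.birth_time[p]:
                    raise AssertionError("times must be non-decreasing root-to-node")
            et, ee = self.end_time[eid], self.end_event[eid]
            if (et is None) != (ee == ALIVE):
                raise AssertionError("end_time set iff entity is closed")
        ch = self.children_map()
        for eid, ee in enumerate(self.end_event):
            n = len(ch.get(eid, ()))
            want = {BIRTH: 2, TRANSFORM: 1, DEATH: 0, ALIVE: 0}[ee]
            if n != want:
                raise AssertionError(
                    f"entity {eid}: end event {EVENT_NAMES[ee]} with {n} children")


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def total_rates(state: EngineState, spec: RateSpec) -> tuple[float, float, float, float]:
    """Per-class total rates and their sum; O(#terms), independent of n."""
    out = []
    for _, terms in spec.classes:
        tot = 0.0
        for coeff, slot, agg in terms:
            a = 1.0 if agg is None else agg(state)
            tot += coeff * a * state.totals[slot]
        out.append(tot)
    lam = out[0] + out[1] + out[2]
    return out[0], out[1], out[2], lam


class _Event(NamedTuple):
    dt: float
    cls: int
    entity_id: int


def _select_fast(state: EngineState, spec: RateSpec, u: float) -> tuple[int, int]:
    for cls, terms in spec.classes:
        for coeff, slot, agg in terms:
            a = 1.0 if agg is None else agg(state)
            per = coeff * a
            tt = per * state.totals[slot]
            if tt <= 0.0:
                continue
            if u < tt:
                pos = _fw_search(state.tree[slot], state.capacity, u / per)
                eid = int(state.pos_entity[pos]) if pos < state.capacity else -1
                if eid < 0:  # float-drift dead zone
                    warnings.warn("event selection hit a dead zone; clamping")
                    eid = int(state.pos_entity[state.active_positions()[-1]])
                return cls, eid
            u -= tt
    warnings.warn("event selection fell off the rate total; clamping to last entity")
    last_cls = BIRTH
    for cls, terms in spec.classes:
        for coeff, slot, agg in terms:
            a = 1.0 if agg is None else agg(state)
            if coeff * a * state.totals[slot] > 0.0:
                last_cls = cls
    return last_cls, int(state.pos_entity[state.active_positions()[-1]])


def draw_event(state: EngineState, spec: RateSpec, rng: np.random.Generator) -> Optional[_Event]:
    """Draw (dt, class, entity) for the next event; ``None`` signals lam <= 0.

    Consumes exactly two uniforms in the canonical order (see module docs).
    """
    if state.n_active == 0:
        return None
    _, _, _, lam = total_rates(state, spec)
    if lam <= 0.0:
        return None
    u1 = rng.random()
    dt = -math.log1p(-u1) / lam
    u2 = rng.random() * lam
    cls, eid = _select_fast(state, spec, u2)
    return _Event(dt, cls, eid)


def naive_draw_event(state: EngineState, spec: RateSpec, rng: np.random.Generator) -> Optional[_Event]:
    """Oracle sampler: recompute every active entity's rates directly.

    Same distributional contract and decision order as :func:`draw_event`
    (the canonical entity order is ascending slot position), but all sums are
    direct per-entity summations rather than Fenwick partial sums.
    """
    if state.n_active == 0:
        return None
    ap = state.active_positions()
    lam = 0.0
    per_term: list[tuple[int, np.ndarray]] = []
    for cls, terms in spec.classes:
        for coeff, slot, agg in terms:
            a = 1.0 if agg is None else agg(state)
            vec = coeff * a * state.slots[slot, ap]
            per_term.append((cls, vec))
            lam += float(vec.sum())
    if lam <= 0.0:
        return None
    u1 = rng.random()
    dt = -math.log1p(-u1) / lam
    u = rng.random() * lam
    for cls, vec in per_term:
        s = float(vec.sum())
        if s <= 0.0:
            continue
        if u < s:
            idx = int(np.searchsorted(np.cumsum(vec), u, side="right"))
            idx = min(idx, len(ap) - 1)
            return _Event(dt, cls, int(state.pos_entity[ap[idx]]))
        u -= s
    warnings.warn("naive selection fell off the rate total; clamping")
    cls = per_term[-1][0]
    return _Event(dt, cls, int(state.pos_entity[ap[-1]]))


# factory(parent_id, parent_slots, child_ids, rng) -> one slot vector per child
ChildFactory = Callable[[int, np.ndarray, list[int], np.random.Generator], list[np.ndarray]]


def identity_factory(parent_id: int, parent_slots: np.ndarray,
                     child_ids: list[int], rng: np.random.Generator) -> list[np.ndarray]:
    """Children inherit the parent's slot vector unchanged."""
    return [parent_slots.copy() for _ in child_ids]


def apply_event(
    genealogy: Genealogy,
    state: EngineState,
    t: float,
    cls: int,
    entity_id: int,
    birth_factory: ChildFactory,
    transform_factory: ChildFactory,
    rng: np.random.Generator,
) -> list[int]:
    """Apply one event at absolute time ``t``; returns the new child ids."""
    if entity_id not in state.entity_pos:
        raise ValueError(f"cannot apply event to inactive entity {entity_id}")
    genealogy.log(t, cls, entity_id)
    if cls == DEATH:
        genealogy.close(entity_id, t, DEATH)
        state.remove(entity_id)
        return []
    parent_slots = state.entity_slots(entity_id)
    if cls == BIRTH:
        genealogy.close(entity_id, t, BIRTH)
        state.remove(entity_id)
        child_ids = [genealogy.append(entity_id, t), genealogy.append(entity_id, t)]
        for cid, vals in zip(child_ids, birth_factory(entity_id, parent_slots, child_ids, rng)):
            state.add(cid, vals)
        return child_ids
    if cls == TRANSFORM:
        genealogy.close(entity_id, t, TRANSFORM)
        state.remove(entity_id)
        child_ids = [genealogy.append(entity_id, t)]
        for cid, vals in zip(child_ids, transform_factory(entity_id, parent_slots, child_ids, rng)):
            state.add(cid, vals)
        return child_ids
    raise ValueError(f"unknown event class {cls}")


def run_bdt(
    state: EngineState,
    genealogy: Genealogy,
    spec: RateSpec,
    rng: np.random.Generator,
    *,
    t0: float = 0.0,
    stop_time: Optional[float] = None,
    max_events: Optional[int] = None,
    predicate: Optional[Callable[[EngineState, float], bool]] = None,
    birth_factory: ChildFactory,
    transform_factory: ChildFactory,
    on_event: Optional[Callable[[EngineState, float, int, int], None]] = None,
    sampler: str = "fast",
    rebuild_every: int = 1_000_000,
    verify_every: Optional[int] = None,
) -> BDTResult:
    """Run the process until a stop condition fires.

    Stop conditions: simulated-time limit ``stop_time`` (state is advanced to
    that time with no event, valid by memorylessness), ``max_events`` cap
    (flagged as truncation), an aggregate ``predicate`` evaluated after every
    event, or extinction of the active set.
    """
    if sampler not in ("fast", "naive"):
        raise ValueError("sampler must be 'fast' or 'naive'")
    flat = tuple((cls, coeff, slot, agg)
                 for cls, terms in spec.classes for coeff, slot, agg in terms)
    fast = sampler == "fast"
    random = rng.random
    t = t0
    n_events = 0
    while True:
        if state.n_active == 0:
            return BDTResult("extinct", t, n_events)
        if max_events is not None and n_events >= max_events:
            return BDTResult("max_events", t, n_events, truncated=True)
        per_term: list = []
        lam = 0.0
        if fast:
            totals = state.totals
            for cls_, coeff, slot, agg in flat:
                per = coeff if agg is None else coeff * agg(state)
                tt = per * totals[slot]
                per_term.append((cls_, slot, per, tt))
                lam += tt
            ap = None
        else:
            # oracle path: recompute every active entity's rates directly
            ap = state.active_positions()
            for cls_, coeff, slot, agg in flat:
                per = coeff if agg is None else coeff * agg(state)
                vec = per * state.slots[slot, ap]
                per_term.append((cls_, vec))
                lam += float(vec.sum())
        if lam <= 0.0:
            if stop_time is not None:
                return BDTResult("time", stop_time, n_events)
            return BDTResult("stalled", t, n_events)
        u1 = random()
        dt = -math.log1p(-u1) / lam
        if stop_time is not None and t + dt > stop_time:
            # boundary lands between events: truncate the exponential clock
            return BDTResult("time", stop_time, n_events)
        t += dt
        u2 = random() * lam
        if fast:
            cls, eid = _select_from_totals(per_term, state, u2)
        else:
            cls, eid = _naive_select_from(per_term, state, ap, u2)
        apply_event(genealogy, state, t, cls, eid, birth_factory, transform_factory, rng)
        n_events += 1
        if on_event is not None:
            on_event(state, t, cls, eid)
        if rebuild_every and n_events % rebuild_every == 0:
            state.rebuild()
        if verify_every and n_events % verify_every == 0:
            state.verify()
        if predicate is not None and predicate(state, t):
            return BDTResult("predicate", t, n_events)


def _select_from_totals(per_term: list, state: EngineState, u: float) -> tuple[int, int]:
    """Fenwick selection given precomputed (class, slot, per, total) terms."""
    for cls, slot, per, tt in per_term:
        if tt <= 0.0:
            continue
        if u < tt:
            pos = _fw_search(state.tree[slot], state.capacity, u / per)
            eid = int(state.pos_entity[pos]) if pos < state.capacity else -1
            if eid < 0:  # float-drift dead zone
                warnings.warn("event selection hit a dead zone; clamping")
                eid = int(state.pos_entity[state.active_positions()[-1]])
            return cls, eid
        u -= tt
    warnings.warn("event selection fell off the rate total; clamping to last entity")
    cls = next((c for c, _s, _p, tt in reversed(per_term) if tt > 0.0), DEATH)
    return cls, int(state.pos_entity[state.active_positions()[-1]])


def _naive_select_from(
    per_term: list[tuple[int, np.ndarray]],
    state: EngineState,
    ap: np.ndarray,
    u: float,
) -> tuple[int, int]:
    for cls, vec in per_term:
        s = float(vec.sum())
        if s <= 0.0:
            continue
        if u < s:
            idx = int(np.searchsorted(np.cumsum(vec), u, side="right"))
            idx = min(idx, len(ap) - 1)
            return cls, int(state.pos_entity[ap[idx]])
        u -= s
    warnings.warn("naive selection fell off the rate total; clamping")
    cls = per_term[-1][0] if per_term else DEATH
    return cls, int(state.pos_entity[ap[-1]])
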