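"""Backlog queue engines.

Two engines turn capacity shocks into per-patient additional waits:

* an agent queue on a 2-week timestep, where each waiting patient is
  served in a step independently with probability ``min(1, capacity /
  waiting)`` (random service discipline; FIFO available for sensitivity);
* a deterministic aggregate calculator on a weekly timestep that tracks
  backlog size and assigns each arriving cohort the average expected wait
  ``backlog / capacity``.

Waits are *additional* waits beyond the status-quo waiting time; an
undisrupted, balanced queue yields waits of exactly zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .timeline import CapacitySeries

#: Sentinel expected wait when capacity is zero but patients are queued.
UNBOUNDED_WAIT = math.inf


@dataclass(frozen=True)
class QueueState:
    time_index: int = 0
    waiting: float = 0.0
    cumulative_served: float = 0.0

    def __post_init__(self) -> None:
        if self.waiting < 0:
            raise ValueError("waiting must be >= 0")
        if self.cumulative_served < 0:
            raise ValueError("cumulative_served must be >= 0")


@dataclass
class DelayDistribution:
    """Per-patient additional waits (weeks) produced by a queue engine."""

    procedure_type: str
    waits_weeks: np.ndarray
    arrival_step: np.ndarray
    service_step: np.ndarray
    drained: np.ndarray  # True for patients served in the post-horizon drain phase
    timestep_weeks: int = 2
    weights: np.ndarray | None = None  # patient counts per row (aggregate engine cohorts)

    def __post_init__(self) -> None:
        self.waits_weeks = np.asarray(self.waits_weeks, dtype=float)
        self.arrival_step = np.asarray(self.arrival_step, dtype=int)
        self.service_step = np.asarray(self.service_step, dtype=float)
        self.drained = np.asarray(self.drained, dtype=bool)
        if self.weights is None:
            self.weights = np.ones(len(self.waits_weeks))
        else:
            self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.waits_weeks)
        if not (
            len(self.arrival_step) == len(self.service_step) == len(self.drained)
            == len(self.weights) == n
        ):
            raise ValueError("all per-patient arrays must have equal length")
        if np.any(self.waits_weeks < 0):
            raise ValueError("additional waits must be >= 0")

    def __len__(self) -> int:
        return len(self.waits_weeks)

    @property
    def n_patients(self) -> float:
        return float(self.weights.sum())

    @property
    def mean_wait_weeks(self) -> float:
        if len(self) == 0 or self.weights.sum() == 0:
            return 0.0
        return float(np.average(self.waits_weeks, weights=self.weights))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": np.arange(len(self)),
                "arrival_step": self.arrival_step,
                "service_step": self.service_step,
                "additional_wait_weeks": self.waits_weeks,
                "drained_flag": self.drained.astype(int),
            }
        )


def step_queue_deterministic(
    state: QueueState, arrivals: float, capacity: float
) -> tuple[float, QueueState, float]:
    """One deterministic queue update.

    Serves ``min(waiting + arrivals, capacity)`` patients; the remaining
    backlog divided by capacity is the average expected wait (in steps)
    for patients still queued.
    """
    if arrivals < 0 or capacity < 0:
        raise ValueError("arrivals and capacity must be >= 0")
    present = state.waiting + arrivals
    served = min(present, capacity)
    waiting_next = present - served
    if capacity > 0:
        with np.errstate(over="ignore"):
            expected_wait = waiting_next / capacity
        if not np.isfinite(expected_wait):
            expected_wait = UNBOUNDED_WAIT
    else:
        expected_wait = UNBOUNDED_WAIT if waiting_next > 0 else 0.0
    next_state = QueueState(
        time_index=state.time_index + 1,
        waiting=waiting_next,
        cumulative_served=state.cumulative_served + served,
    )
    return served, next_state, expected_wait


def run_aggregate_queue(
    arrivals: Sequence[float],
    capacity: CapacitySeries | Sequence[float],
    timestep_weeks: int | None = None,
) -> tuple[DelayDistribution, pd.DataFrame]:
    """Deterministic aggregate backlog engine.

    Every patient arriving at step ``t`` is assigned the average expected
    wait computed from the backlog remaining after that step's service.
    Returns the per-cohort delay distribution and a step-level trace
    (arrivals, capacity, served, waiting, expected_wait_steps).
    """
    if isinstance(capacity, CapacitySeries):
        cap = capacity.capacity
        if timestep_weeks is None:
            timestep_weeks = capacity.timestep_weeks
        proc = capacity.procedure_type
    else:
        cap = np.asarray(capacity, dtype=float)
        proc = "aggregate"
    if timestep_weeks is None:
        timestep_weeks = 1
    arrivals = np.asarray(arrivals, dtype=float)
    if len(arrivals) != len(cap):
        raise ValueError(
            f"arrivals ({len(arrivals)}) and capacity ({len(cap)}) series lengths differ"
        )

    state = QueueState()
    rows = []
    cohort_waits = np.empty(len(arrivals))
    for t in range(len(arrivals)):
        served, state, wait = step_queue_deterministic(state, arrivals[t], cap[t])
        cohort_waits[t] = wait
        rows.append(
            {
                "step": t,
                "arrivals": arrivals[t],
                "capacity": cap[t],
                "served": served,
                "waiting": state.waiting,
                "expected_wait_steps": wait,
            }
        )
    trace = pd.DataFrame(rows)

    mask = arrivals > 0
    waits_weeks = cohort_waits[mask] * timestep_weeks
    steps = np.flatnonzero(mask)
    return (
        DelayDistribution(
            procedure_type=proc,
            waits_weeks=waits_weeks,
            arrival_step=steps,
            service_step=steps + cohort_waits[mask],
            drained=np.zeros(mask.sum(), dtype=bool),
            timestep_weeks=timestep_weeks,
            weights=arrivals[mask],
        ),
        trace,
    )


def deterministic_mean_wait_weeks(
    arrivals: Sequence[float],
    capacity: CapacitySeries | Sequence[float],
    timestep_weeks: int | None = None,
) -> float:
    """Mean additional wait implied by the deterministic backlog recursion.

    Total person-steps spent on the backlog equal the sum of post-service
    queue lengths regardless of service discipline, so the mean wait per
    arrival is ``sum(waiting_t) / sum(arrivals)`` — the deterministic
    oracle for the agent engine's mean wait.
    """
    dist, trace = run_aggregate_queue(arrivals, capacity, timestep_weeks)
    total = np.asarray(arrivals, dtype=float).sum()
    if total <= 0:
        raise ValueError("no arrivals")
    return float(trace["waiting"].sum() / total) * dist.timestep_weeks


def simulate_agent_queue(
    arrivals: Sequence[float],
    capacity: CapacitySeries | Sequence[float] | Callable[[int, int], float],
    seed: int | np.random.Generator,
    timestep_weeks: int = 2,
    initial_waiting: int = 0,
    discipline: str = "random",
) -> DelayDistribution:
    """Stochastic agent queue.

    Each waiting patient is served in a timestep independently with
    probability ``min(1, capacity_t / waiting_t)``; unserved patients
    carry over. Patients still queued at the horizon are served in a
    drain phase at the final capacity and flagged.

    ``capacity`` may be a :class:`CapacitySeries`, a plain per-step
    sequence, or a callable ``(step, n_waiting) -> capacity`` for adaptive
    capacity.
    """
    if discipline not in ("random", "fifo"):
        raise ValueError("discipline must be 'random' or 'fifo'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if isinstance(capacity, CapacitySeries):
        timestep_weeks = capacity.timestep_weeks
        proc = capacity.procedure_type
        cap_fn = lambda t, n: capacity.capacity[t]
        n_steps = len(capacity)
    elif callable(capacity):
        proc = "agent"
        cap_fn = capacity
        n_steps = len(arrivals) if hasattr(arrivals, "__len__") else 0
    else:
        cap_arr = np.asarray(capacity, dtype=float)
        proc = "agent"
        cap_fn = lambda t, n: cap_arr[t]
        n_steps = len(cap_arr)
    arrivals = np.asarray(arrivals, dtype=float)
    if not callable(capacity) and len(arrivals) != n_steps:
        raise ValueError(
            f"arrivals ({len(arrivals)}) and capacity ({n_steps}) series lengths differ"
        )

    arrival_steps: list[np.ndarray] = []
    service_steps: list[np.ndarray] = []
    drain_flags: list[np.ndarray] = []
    # waiting pool as an array of arrival steps (FIFO order preserved)
    pool = np.full(initial_waiting, 0, dtype=int) if initial_waiting else np.empty(0, dtype=int)

    def serve(pool: np.ndarray, cap: float, t: int, drained: bool) -> np.ndarray:
        n = len(pool)
        if n == 0:
            return pool
        p = min(1.0, cap / n)
        if discipline == "random":
            k = rng.binomial(n, p)
            if k:
                idx = rng.choice(n, size=k, replace=False)
                keep = np.ones(n, dtype=bool)
                keep[idx] = False
            else:
                keep = np.ones(n, dtype=bool)
        else:  # fifo: serve floor(cap) + stochastic remainder from the front
            k = min(n, int(cap) + (rng.random() < cap - int(cap)))
            keep = np.arange(n) >= k
        served = pool[~keep]
        if len(served):
            arrival_steps.append(served)
            service_steps.append(np.full(len(served), t))
            drain_flags.append(np.full(len(served), drained))
        return pool[keep]

    for t in range(len(arrivals)):
        new = np.full(int(arrivals[t]), t, dtype=int)
        pool = np.concatenate([pool, new]) if len(new) else pool
        pool = serve(pool, float(cap_fn(t, len(pool))), t, drained=False)

    # drain phase: serve leftovers at the mean recent capacity so censoring
    # at the horizon does not bias the delay distribution
    t = len(arrivals)
    if len(pool):
        if callable(capacity) and not isinstance(capacity, CapacitySeries):
            drain_cap = float(cap_fn(t - 1, len(pool)))
        else:
            cap_tail = (
                capacity.capacity if isinstance(capacity, CapacitySeries) else cap_arr
            )[-min(24, n_steps):]
            drain_cap = float(np.mean(cap_tail))
        if drain_cap <= 0:
            raise ValueError("cannot drain backlog: recent capacity is zero")
        while len(pool):
            pool = serve(pool, drain_cap, t, drained=True)
            t += 1

    if arrival_steps:
        arr = np.concatenate(arrival_steps)
        srv = np.concatenate(service_steps)
        drn = np.concatenate(drain_flags)
    else:
        arr = srv = np.empty(0, dtype=int)
        drn = np.empty(0, dtype=bool)
    order = np.argsort(arr, kind="stable")
    arr, srv, drn = arr[order], srv[order], drn[order]
    return DelayDistribution(
        procedure_type=proc,
        waits_weeks=(srv - arr) * timestep_weeks,
        arrival_step=arr,
        service_step=srv,
        drained=drn,
        timestep_weeks=timestep_weeks,
    )


def proportion_with_additional_wait(
    delays: DelayDistribution, threshold_weeks: float = 2.0
) -> float:
    """Fraction of served patients whose additional wait is >= threshold (inclusive)."""
    if len(delays) == 0 or delays.weights.sum() == 0:
        raise ValueError("delay distribution is empty")
    return float(
        np.average((delays.waits_weeks >= threshold_weeks).astype(float), weights=delays.weights)
    )
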