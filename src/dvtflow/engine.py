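"""Seeded discrete-event kernel: clock, future-event list, resource pools.

The kernel is generic: it knows nothing about DVT. Time is measured in
days from simulation start; resource service durations are expressed in
minutes and converted internally. Simultaneous events are totally ordered
by an explicit priority rank -- releases execute before seizes, seizes
before arrivals -- which prevents phantom waiting when a resource frees up
at the exact instant another entity requests it. Within equal (time,
priority), insertion order breaks ties.
"""

from __future__ import annotations

import heapq
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError, ConsistencyError

MINUTES_PER_DAY = 24 * 60.0

# simultaneous-event tiebreak ranks (lower executes first)
PRIORITY_RELEASE = 0
PRIORITY_SEIZE = 1
PRIORITY_ARRIVAL = 2
PRIORITY_OTHER = 3

Action = Callable[["Simulator"], None]


@dataclass(frozen=True)
class Event:
    time: float
    priority: int
    seq: int
    tag: str


class Simulator:
    """Future-event list with a monotone clock.

    ``log`` records every executed event as an :class:`Event`; model code
    appends its own structured rows to ``trace`` (the kernel does not
    interpret them).
    """

    def __init__(self) -> None:
        self.now: float = 0.0
        self._heap: list[tuple[float, int, int, Action, str]] = []
        self._seq = 0
        self.log: list[Event] = []
        self.trace: list[tuple] = []

    def schedule(self, time: float, priority: int, action: Action, tag: str = "") -> None:
        if time < self.now - 1e-9:
            raise ConsistencyError(
                f"event '{tag}' scheduled at t={time:.6f} before current clock {self.now:.6f}"
            )
        heapq.heappush(self._heap, (max(time, self.now), priority, self._seq, action, tag))
        self._seq += 1

    def run_until(self, horizon: float = math.inf) -> list[Event]:
        """Execute events in (time, priority, insertion) order up to horizon.

        Events timed strictly after ``horizon`` are left unexecuted.
        Returns the executed-event log.
        """
        heap = self._heap
        while heap and heap[0][0] <= horizon:
            time, priority, seq, action, tag = heapq.heappop(heap)
            self.now = time
            self.log.append(Event(time, priority, seq, tag))
            action(self)
        return self.log


@dataclass
class _Request:
    time: float
    minutes: float
    on_start: Callable[[float, float], None]  # (start_day, wait_days)


class ResourcePool:
    """A staffed pool with FIFO queueing.

    Effective capacity is ``max(1, round(headcount * allocation))``
    schedulable slots whenever any staff time is allocated; the allocation
    fraction otherwise only shapes capacity, while recorded service minutes
    are the raw hands-on DVT minutes (kept exact for the hour accounting).
    """

    def __init__(self, name: str, headcount: float, allocation: float = 1.0) -> None:
        effective = headcount * allocation
        self.name = name
        self.capacity = max(1, round(effective)) if effective > 0 else 0
        self.busy = 0
        self.queue: deque[_Request] = deque()
        self.busy_minutes = 0.0  # total service minutes delivered
        self.wait_minutes = 0.0  # total queueing time endured by requests
        self.n_served = 0

    @property
    def idle(self) -> int:
        return self.capacity - self.busy

    def request(self, sim: Simulator, minutes: float,
                on_start: Callable[[float, float], None] | None = None) -> None:
        """Seize one unit for ``minutes``; start now or queue FIFO.

        ``on_start(start_day, wait_days)`` fires when service begins.
        """
        if self.capacity <= 0:
            raise ConfigurationError(
                f"resource pool '{self.name}' has zero effective capacity but is "
                f"required by the pathway"
            )
        if minutes <= 0:
            raise ConfigurationError(f"non-positive service duration on pool '{self.name}'")
        req = _Request(sim.now, minutes, on_start or (lambda t, w: None))
        if self.busy < self.capacity:
            self._start(sim, req)
        else:
            self.queue.append(req)

    def _start(self, sim: Simulator, req: _Request) -> None:
        wait = sim.now - req.time
        self.busy += 1
        self.busy_minutes += req.minutes
        self.wait_minutes += wait * MINUTES_PER_DAY
        self.n_served += 1
        req.on_start(sim.now, wait)
        sim.schedule(sim.now + req.minutes / MINUTES_PER_DAY, PRIORITY_RELEASE,
                     self._release, tag=f"release:{self.name}")

    def _release(self, sim: Simulator) -> None:
        if self.busy <= 0:
            raise ConsistencyError(f"release on idle pool '{self.name}'")
        self.busy -= 1
        if self.queue:  # work-conserving: hand the freed unit straight on
            self._start(sim, self.queue.popleft())


# ---------------------------------------------------------------------------
# replications


@dataclass
class ReplicationSet:
    """Results of independent replications driven from one base seed."""

    n_reps: int
    base_seed: int
    seed_keys: list[int]
    results: list = field(default_factory=list)


def spawn_seeds(base_seed: int, n: int) -> list[np.random.SeedSequence]:
    """Distinct, reproducible child seed sequences for ``n`` replications."""
    return list(np.random.SeedSequence(base_seed).spawn(n))


def replicate(runner: Callable[[np.random.SeedSequence], object],
              n_reps: int, base_seed: int) -> ReplicationSet:
    """Run ``runner`` once per replication on mutually independent streams.

    Rerunning with the same base seed reproduces every result bit-for-bit;
    ``runner`` receives the replication's :class:`numpy.random.SeedSequence`.
    """
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    children = spawn_seeds(base_seed, n_reps)
    keys = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    rs = ReplicationSet(n_reps=n_reps, base_seed=base_seed, seed_keys=keys)
    for child in children:
        rs.results.append(runner(child))
    return rs


def assert_conservation(pools: Sequence[ResourcePool]) -> None:
    """busy + idle == capacity for every pool (debug/test helper)."""
    for p in pools:
        if p.busy + p.idle != p.capacity or p.busy < 0:
            raise ConsistencyError(f"conservation broken on pool '{p.name}'")
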