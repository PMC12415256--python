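"""Understanding-dependent symbolic emission over an inscription alphabet.

The observable layer is a nonstationary Markov chain over "inscriptions"
(the discrete symbols a problem-solver attends to).  Each session carries two
row-stochastic transition matrices: B0 for complete confusion and B1 for
enlightenment.  At latent understanding u the effective matrix is the convex
combination B_u = (1-u) B0 + u B1, so the statistics of the event stream
track the latent trajectory.  This module also houses the synthetic-corpus
generator, which doubles as the package's fixture factory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .dynamics import DriftParams, LatentTrajectory, SimConfig, insight_time, simulate_latent

__all__ = [
    "TransitionMatrix",
    "Event",
    "EventSeries",
    "SyntheticCorpus",
    "DEFAULT_CONCENTRATION",
    "random_transition_matrix",
    "interpolate",
    "emit_events",
    "generate_corpus",
]

#: Symmetric-Dirichlet concentration of the random transition-matrix rows.
#: Calibrated once so that baseline (far-from-insight) mean surprisal of the
#: standard synthetic corpus sits near 0.75 bits, then frozen.
DEFAULT_CONCENTRATION = 0.005

_ROW_SUM_TOL = 1e-12


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic transition matrix over an ordered inscription alphabet."""

    labels: tuple[str, ...]
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")
        if p.shape != (n, n):
            raise ValueError(f"probs must be {n}x{n}, got {p.shape}")
        if np.any(p < 0):
            raise ValueError("transition probabilities must be >= 0")
        if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("every row must sum to 1")
        object.__setattr__(self, "probs", p)

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class Event:
    time: float
    inscription: str
    is_new: bool


@dataclass(frozen=True)
class EventSeries:
    """Timestamped symbolic events of one session.

    Times are strictly increasing; ``is_new`` is true exactly at the first
    occurrence of each inscription label within the session.
    """

    session_id: str
    events: tuple[Event, ...]

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"session {self.session_id}: times must be strictly increasing")
        seen: set[str] = set()
        for i, e in enumerate(self.events):
            expected_new = e.inscription not in seen
            if e.is_new != expected_new:
                raise ValueError(
                    f"session {self.session_id}: is_new flag wrong at event {i} "
                    f"({e.inscription!r})"
                )
            seen.add(e.inscription)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.events])

    @property
    def labels(self) -> list[str]:
        return [e.inscription for e in self.events]

    @property
    def alphabet(self) -> list[str]:
        """Labels in order of first appearance."""
        return [e.inscription for e in self.events if e.is_new]


def with_recomputed_is_new(session_id: str, times: Sequence[float], labels: Sequence[str]) -> EventSeries:
    """Build an EventSeries, deriving is_new from first occurrences."""
    seen: set[str] = set()
    events = []
    for t, lab in zip(times, labels):
        events.append(Event(time=float(t), inscription=str(lab), is_new=lab not in seen))
        seen.add(lab)
    return EventSeries(session_id=session_id, events=tuple(events))


@dataclass(frozen=True)
class SessionRecord:
    series: EventSeries
    trajectory: LatentTrajectory
    insight_time: Optional[float]


@dataclass(frozen=True)
class SyntheticCorpus:
    """A set of simulated sessions with their latent trajectories and insights."""

    sessions: tuple[SessionRecord, ...]
    sim_config: SimConfig
    n_symbols: int
    concentration: float
    master_seed: int

    def event_series(self) -> list[EventSeries]:
        return [s.series for s in self.sessions]

    def insights(self) -> dict[str, list[float]]:
        """Insight timestamps keyed by session id (empty list when no insight)."""
        return {
            s.series.session_id: ([s.insight_time] if s.insight_time is not None else [])
            for s in self.sessions
        }


def _default_labels(n_symbols: int) -> tuple[str, ...]:
    width = len(str(n_symbols - 1))
    return tuple(f"i{k:0{width}d}" for k in range(n_symbols))


def random_transition_matrix(
    n_symbols: int,
    concentration: float = DEFAULT_CONCENTRATION,
    seed: int | np.random.Generator = 0,
    labels: Sequence[str] | None = None,
) -> TransitionMatrix:
    """Draw a transition matrix with i.i.d. symmetric-Dirichlet rows.

    Low concentration gives sparse, near-deterministic rows; in the limit of
    large concentration rows approach the uniform distribution.
    """
    if n_symbols < 2:
        raise ValueError("n_symbols must be >= 2")
    if not concentration > 0:
        raise ValueError("concentration must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = rng.dirichlet(np.full(n_symbols, concentration), size=n_symbols)
    lab = tuple(labels) if labels is not None else _default_labels(n_symbols)
    return TransitionMatrix(labels=lab, probs=probs)


def interpolate(b0: TransitionMatrix, b1: TransitionMatrix, u: float) -> TransitionMatrix:
    """Convex combination B_u = (1-u) B0 + u B1 (row-stochastic for u in [0,1])."""
    if b0.labels != b1.labels:
        raise ValueError("b0 and b1 must share the same label alphabet")
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"u must lie in [0, 1], got {u}")
    return TransitionMatrix(labels=b0.labels, probs=(1.0 - u) * b0.probs + u * b1.probs)


def emit_events(
    traj: LatentTrajectory,
    b0: TransitionMatrix,
    b1: TransitionMatrix,
    seed: int | np.random.Generator = 0,
    session_id: str = "s00",
) -> EventSeries:
    """Emit one symbolic event per latent time step.

    The first event is uniform over the alphabet (it has no predecessor and
    is excluded from transition statistics downstream).  The event at step
    t+1 is drawn from row ``current label`` of B_{u_t}, i.e. the transition
    out of step t uses the understanding at step t.
    """
    if b0.labels != b1.labels:
        raise ValueError("b0 and b1 must share the same label alphabet")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(traj.u)
    n_sym = b0.n
    idx = np.empty(n, dtype=int)
    idx[0] = rng.integers(n_sym)
    # one uniform variate per transition, inverted through the row CDF
    unif = rng.random(n - 1)
    p0, p1 = b0.probs, b1.probs
    for t in range(n - 1):
        u_t = traj.u[t]
        row = (1.0 - u_t) * p0[idx[t]] + u_t * p1[idx[t]]
        idx[t + 1] = np.searchsorted(np.cumsum(row), unif[t], side="right")
    idx = np.minimum(idx, n_sym - 1)  # guard against cumsum rounding at 1.0
    labels = [b0.labels[i] for i in idx]
    return with_recomputed_is_new(session_id, traj.times, labels)


def generate_corpus(
    n_sessions: int = 24,
    n_symbols: int = 25,
    sim: SimConfig | None = None,
    concentration: float = DEFAULT_CONCENTRATION,
    master_seed: int = 0,
    insight_threshold: float = 0.5,
) -> SyntheticCorpus:
    """Simulate a corpus of synthetic proof sessions.

    Per session: fresh B0 and B1 (rows ~ Dirichlet), a fresh latent
    trajectory under the standard gamma ramp, emitted events, and the model
    insight time (first upward crossing of U = ``insight_threshold``).
    Session seeds are derived deterministically from ``master_seed`` via
    numpy SeedSequence spawning, so corpora are byte-identical across runs.
    """
    if sim is None:
        sim = SimConfig()
    children = np.random.SeedSequence(master_seed).spawn(n_sessions)
    width = len(str(max(n_sessions - 1, 1)))
    sessions = []
    for k, child in enumerate(children):
        latent_seed, b0_seed, b1_seed, emit_seed = (
            int(s) for s in child.generate_state(4) % (2**31 - 1)
        )
        cfg = replace(sim, seed=latent_seed)
        traj = simulate_latent(cfg)
        b0 = random_transition_matrix(n_symbols, concentration, seed=b0_seed)
        b1 = random_transition_matrix(n_symbols, concentration, seed=b1_seed)
        sid = f"s{k:0{width}d}"
        series = emit_events(traj, b0, b1, seed=emit_seed, session_id=sid)
        t_ins = insight_time(traj, threshold=insight_threshold)
        sessions.append(SessionRecord(series=series, trajectory=traj, insight_time=t_ins))
    return SyntheticCorpus(
        sessions=tuple(sessions),
        sim_config=sim,
        n_symbols=n_symbols,
        concentration=concentration,
        master_seed=master_seed,
    )
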