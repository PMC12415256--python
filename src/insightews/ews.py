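"""Information-theoretic early-warning signal for symbolic event series.

The signal is the *conditional surprisal* of each event: h(E_t) = -log2
P(E_t | C_t), where the context C_t is the ordered sub-sequence of events in
a window of fixed width delta ending at t.  Probabilities are first-order
empirical transition probabilities estimated inside the window, with additive
smoothing so that never-seen transitions receive finite surprisal.  Rising
surprisal means the recent past has become a poor predictor of the present —
the symbolic fingerprint of a system losing resilience before a critical
transition.

Conventions (all configurable):

* window is the open interval (t - delta, t); the scored event itself is
  excluded, so an event never conditions on itself;
* the conditioning label is the actual predecessor event, even when that
  predecessor falls outside the window (only transition pairs fully inside
  the window contribute counts);
* the normalising alphabet is the set of labels seen in the session up to
  and including t, plus one virtual "novel" symbol, so that probability mass
  is always reserved for a label never seen before;
* when the conditioning label has no outgoing transitions in the window, the
  estimate backs off to the smoothed marginal label frequency of the window;
* the first event of a session and events with an empty context have
  *undefined* surprisal: they are flagged, never silently dropped.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .observation import Event, EventSeries

__all__ = [
    "ContextConfig",
    "SurprisalSeries",
    "MODEL_DELTA",
    "EMPIRICAL_DELTA",
    "context_window",
    "empirical_transition_probs",
    "surprisal_event",
    "surprisal_series",
    "sensitivity_grid",
]

#: Default context-window widths: 40 steps for model data, 60 s for
#: empirical data.
MODEL_DELTA = 40.0
EMPIRICAL_DELTA = 60.0


@dataclass(frozen=True)
class ContextConfig:
    """Configuration of the surprisal estimator.

    delta
        Context-window width: seconds for empirical data, steps for model
        data.
    smoothing_k
        Additive pseudocount applied to every transition cell.  The default
        0 uses raw empirical transition probabilities: events whose
        transition was never seen in the window get *undefined* surprisal
        (flagged and excluded downstream, with counts reported) rather than
        a smoothing-dependent finite value.  Positive k regularises all
        events to finite surprisal at the cost of an alphabet-size-dependent
        floor on the absolute level.
    backoff
        "marginal": fall back to the smoothed window label frequency when
        the conditioning label has no outgoing transitions in the window;
        "none": treat the row as all-pseudocount.
    """

    delta: float = MODEL_DELTA
    smoothing_k: float = 0.0
    backoff: Literal["none", "marginal"] = "marginal"

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError("delta must be > 0")
        if self.smoothing_k < 0:
            raise ValueError("smoothing_k must be >= 0")
        if self.backoff not in ("none", "marginal"):
            raise ValueError(f"unknown backoff {self.backoff!r}")


@dataclass(frozen=True)
class SurprisalSeries:
    """Per-event surprisal of one session.

    ``frame`` has one row per event with columns ``time``, ``inscription``,
    ``surprisal_bits`` (NaN where undefined), ``cond_prob``, ``context_n``
    and ``is_new``.  Undefined rows correspond to the session's first event
    or an empty context window.
    """

    session_id: str
    frame: pd.DataFrame
    config: ContextConfig

    @property
    def defined(self) -> pd.DataFrame:
        return self.frame[self.frame["surprisal_bits"].notna()]

    @property
    def n_undefined(self) -> int:
        return int(self.frame["surprisal_bits"].isna().sum())


def context_window(series: EventSeries, t: float, delta: float) -> tuple[Event, ...]:
    """Events of ``series`` with time strictly inside (t - delta, t).

    The event at exactly ``t`` is excluded (it is the one being scored).
    """
    times = [e.time for e in series.events]
    lo = bisect_right(times, t - delta)
    hi = bisect_left(times, t)
    return series.events[lo:hi]


def _transition_counts(context: Sequence[Event]) -> dict[str, dict[str, int]]:
    """First-order transition counts over consecutive pairs of the context."""
    counts: dict[str, dict[str, int]] = {}
    for prev, cur in zip(context, context[1:]):
        row = counts.setdefault(prev.inscription, {})
        row[cur.inscription] = row.get(cur.inscription, 0) + 1
    return counts


def empirical_transition_probs(
    context: Sequence[Event],
    alphabet: Sequence[str],
    cfg: ContextConfig,
) -> dict[str, dict[str, float]]:
    """Smoothed conditional next-label distributions estimated in a context.

    For each label i with outgoing transitions in the context,
    P(j|i) = (count(i->j) + k) / (count(i->.) + k*A) over the given alphabet
    of size A.  Labels present in the context but without outgoing
    transitions get the backoff row (smoothed marginal) when
    ``cfg.backoff == "marginal"``.  An empty context yields an empty table,
    signalling undefined surprisal.
    """
    if not context:
        return {}
    alphabet = list(alphabet)
    for e in context:
        if e.inscription not in alphabet:
            raise ValueError(f"context label {e.inscription!r} missing from alphabet")
    k = cfg.smoothing_k
    a = len(alphabet)
    counts = _transition_counts(context)
    table: dict[str, dict[str, float]] = {}
    for i, row in counts.items():
        n_i = sum(row.values())
        denom = n_i + k * a
        table[i] = {j: (row.get(j, 0) + k) / denom for j in alphabet}
    if cfg.backoff == "marginal":
        marg: dict[str, int] = {}
        for e in context:
            marg[e.inscription] = marg.get(e.inscription, 0) + 1
        m = len(context)
        backoff_row = {j: (marg.get(j, 0) + k) / (m + k * a) for j in alphabet}
        for e in context:
            table.setdefault(e.inscription, dict(backoff_row))
        table.setdefault("__backoff__", backoff_row)
    return table


def surprisal_event(
    event: Event,
    context: Sequence[Event],
    alphabet: Sequence[str],
    cfg: ContextConfig,
    prev_label: Optional[str] = None,
) -> tuple[Optional[float], Optional[float]]:
    """Surprisal (bits) and conditional probability of one event given its context.

    ``prev_label`` is the label of the event's actual predecessor; when None
    it defaults to the last context event.  Returns ``(None, None)`` when
    the context is empty or no predecessor exists.
    """
    if not context:
        return None, None
    if prev_label is None:
        prev_label = context[-1].inscription
    table = empirical_transition_probs(context, alphabet, cfg)
    row = table.get(prev_label)
    if row is None:
        if cfg.backoff == "marginal":
            row = table["__backoff__"]
        else:
            k = cfg.smoothing_k
            a = len(alphabet)
            if k == 0:
                return None, None
            row = {j: 1.0 / a for j in alphabet}
    p = row.get(event.inscription)
    if p is None:
        # event label absent from supplied alphabet: reserve the pseudocount
        # mass of one unseen cell
        k = cfg.smoothing_k
        if k == 0:
            return None, None
        n_i = sum(
            1 for a_, b_ in zip(context, context[1:]) if a_.inscription == prev_label
        )
        p = k / (n_i + k * len(alphabet))
    if p <= 0:
        return None, None
    return -math.log2(p), p


def surprisal_series(series: EventSeries, cfg: ContextConfig | None = None) -> SurprisalSeries:
    """Per-event conditional surprisal for a whole session.

    The normalising alphabet at each event is the set of labels seen in the
    session up to and including that event, plus one virtual novel symbol.
    The first event (no predecessor) and events with empty context are
    recorded with NaN surprisal.
    """
    if cfg is None:
        cfg = ContextConfig()
    events = series.events
    n = len(events)
    times = [e.time for e in events]
    labels = [e.inscription for e in events]
    k = cfg.smoothing_k

    surprisal = np.full(n, np.nan)
    cond_prob = np.full(n, np.nan)
    context_n = np.zeros(n, dtype=int)

    seen: set[str] = set()
    n_seen = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        seen.add(lab)
        n_seen[i] = len(seen)

    lo = 0
    for i in range(n):
        t = times[i]
        while times[lo] <= t - cfg.delta:
            lo += 1
        ctx_lo, ctx_hi = lo, i  # events with t-delta < time < t
        m = ctx_hi - ctx_lo
        context_n[i] = m
        if i == 0 or m == 0:
            continue
        a = n_seen[i] + 1  # seen-so-far alphabet plus one virtual novel symbol
        prev = labels[i - 1]
        cur = labels[i]
        # transition counts over pairs fully inside the window
        c_prev_cur = 0
        n_prev = 0
        any_trans = ctx_hi - ctx_lo >= 2
        for j in range(ctx_lo + 1, ctx_hi):
            if labels[j - 1] == prev:
                n_prev += 1
                if labels[j] == cur:
                    c_prev_cur += 1
        if n_prev > 0:
            p = (c_prev_cur + k) / (n_prev + k * a)
        elif cfg.backoff == "marginal":
            m_cur = sum(1 for j in range(ctx_lo, ctx_hi) if labels[j] == cur)
            p = (m_cur + k) / (m + k * a)
        else:
            p = k / (k * a) if k > 0 else np.nan
        if p > 0:
            surprisal[i] = -math.log2(p)
            cond_prob[i] = p

    frame = pd.DataFrame(
        {
            "time": times,
            "inscription": labels,
            "surprisal_bits": surprisal,
            "cond_prob": cond_prob,
            "context_n": context_n,
            "is_new": [e.is_new for e in events],
        }
    )
    return SurprisalSeries(session_id=series.session_id, frame=frame, config=cfg)


def sensitivity_grid(
    series_list: Iterable[EventSeries],
    insights: dict[str, list[float]],
    base_cfg: ContextConfig,
    w_pre: float,
    w_post: float,
    factors: Sequence[float] = (0.67, 1.0, 1.33),
) -> pd.DataFrame:
    """Epoch contrasts of the surprisal signal across context-width choices.

    Re-runs the surprisal estimator and the pre/post/other epoch contrast at
    delta scaled by each factor (defaults +/-33% around the base value) and
    tabulates the contrast estimates side by side.  Empty ``factors`` yields
    an empty table.
    """
    from .inference import epoch_contrast, label_epochs  # deferred: avoids cycle

    series_list = list(series_list)
    rows = []
    for f in factors:
        cfg = ContextConfig(delta=base_cfg.delta * f, smoothing_k=base_cfg.smoothing_k,
                            backoff=base_cfg.backoff)
        sups, labs = [], []
        for s in series_list:
            sups.append(surprisal_series(s, cfg))
            labs.append(label_epochs(s, insights.get(s.session_id, []), w_pre, w_post))
        contrast = epoch_contrast(sups, labs)
        rows.append(
            {
                "factor": f,
                "delta": cfg.delta,
                "mean_pre": contrast.loc["pre", "mean"],
                "mean_post": contrast.loc["post", "mean"],
                "mean_other": contrast.loc["other", "mean"],
                "contrast_pre": contrast.loc["pre", "mean"] - contrast.loc["other", "mean"],
                "contrast_post": contrast.loc["post", "mean"] - contrast.loc["other", "mean"],
            }
        )
    return pd.DataFrame(rows, columns=["factor", "delta", "mean_pre", "mean_post",
                                       "mean_other", "contrast_pre", "contrast_post"])
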