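"""Statistical layer: trend tests, epoch contrasts, mixed models, surrogates.

Everything here asks one question of the surprisal signal: does symbolic
behaviour become measurably less predictable as the system approaches a
critical transition?  Four complementary routes are provided:

* ``binned_trend`` — Kendall rank trend of a per-bin statistic (SD of the
  latent state, or mean surprisal) against the control parameter, averaged
  over simulated sessions and restricted to pre-transition samples;
* ``epoch_contrast`` / ``hierarchical_regression`` — mean surprisal in the
  windows immediately before/after each insight versus all other times, and
  the corresponding session-random-intercept linear model;
* ``surrogate_null`` — a time-permuted surrogate null that keeps every
  session's timestamps and label multiset but shuffles which label occurs
  when, destroying sequential structure while preserving timing and
  label-frequency nuisances;
* ``insight_locked_curve`` — the event-triggered average of surprisal with
  time re-referenced so each insight sits at zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import LatentTrajectory
from .ews import ContextConfig, SurprisalSeries, surprisal_series
from .observation import EventSeries, SyntheticCorpus, with_recomputed_is_new

logger = logging.getLogger(__name__)

__all__ = [
    "TrendResult",
    "EpochLabels",
    "SurrogateResult",
    "kendall_trend",
    "binned_trend",
    "label_epochs",
    "epoch_contrast",
    "hierarchical_regression",
    "permute_session",
    "surrogate_null",
    "insight_locked_curve",
]

DEFAULT_N_BINS = 15
#: Model epoch window width as a fraction of the session length.
MODEL_EPOCH_FRACTION = 0.10
#: Empirical epoch window width (seconds) around each insight.
EMPIRICAL_EPOCH_WIDTH = 120.0


@dataclass(frozen=True)
class TrendResult:
    """Kendall rank-trend summary: tau-b, concordant-pair count T, and p."""

    tau: float
    concordant_pairs: int
    discordant_pairs: int
    n: int
    p_value: float


@dataclass(frozen=True)
class EpochLabels:
    """Per-event pre-/post-insight flags for one session.

    An event is *pre* when it falls in (t_ins - w_pre, t_ins) for some
    insight and *post* when in [t_ins, t_ins + w_post); with several
    insights both flags can hold at once.
    """

    session_id: str
    pre: np.ndarray
    post: np.ndarray

    @property
    def other(self) -> np.ndarray:
        return ~(self.pre | self.post)


@dataclass(frozen=True)
class SurrogateResult:
    """Observed epoch contrasts against a label-permutation null."""

    n_permutations: int
    observed_contrast_pre: float
    observed_contrast_post: float
    null_pre: np.ndarray
    null_post: np.ndarray
    p_pre: float
    p_post: float


def kendall_trend(x: Sequence[float], y: Sequence[float]) -> TrendResult:
    """Kendall tau-b trend of y against x, with raw concordant-pair count.

    The p-value is scipy's (exact for small tie-free samples, otherwise the
    normal approximation).  Raises on length mismatch or n < 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points for a trend test")
    tau, p = stats.kendalltau(x, y)
    conc = disc = 0
    for i in range(n):
        for j in range(i + 1, n):
            s = (x[j] - x[i]) * (y[j] - y[i])
            if s > 0:
                conc += 1
            elif s < 0:
                disc += 1
    return TrendResult(tau=float(tau), concordant_pairs=conc, discordant_pairs=disc,
                       n=n, p_value=float(p))


def _pre_transition_mask(times: np.ndarray, t_ins: Optional[float]) -> np.ndarray:
    if t_ins is None:
        return np.ones(len(times), dtype=bool)
    return times < t_ins


def binned_trend(
    corpus: SyntheticCorpus,
    statistic: Literal["sd_u", "mean_surprisal", "sd_u_vs_surprisal"],
    n_bins: int = DEFAULT_N_BINS,
    restrict: bool = True,
    surprisals: Optional[Sequence[SurprisalSeries]] = None,
    cfg: Optional[ContextConfig] = None,
) -> TrendResult:
    """Kendall trend of a binned session statistic along the gamma ramp.

    gamma is split into ``n_bins`` equal-width bins spanning the ramp.  Per
    session the statistic is computed within each bin — the SD of latent
    understanding (``sd_u``), or the mean event surprisal
    (``mean_surprisal``) — using only samples before that session's insight
    when ``restrict`` is set.  Bin values are averaged across sessions
    (empty bins are dropped with a warning) and the Kendall trend of bin
    centre versus averaged statistic is returned.
    ``sd_u_vs_surprisal`` correlates the two binned statistics against each
    other instead of against gamma.

    Precomputed per-session ``surprisals`` may be passed to avoid repeating
    the estimation; otherwise they are computed with ``cfg`` (default model
    settings).
    """
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    # Bin edges span the gamma range actually contributing samples: under the
    # pre-transition restriction the ramp's top is never reached, so binning
    # the full ramp would leave empty top bins.
    gmins, gmaxs = [], []
    for rec in corpus.sessions:
        mask = _pre_transition_mask(rec.trajectory.times,
                                    rec.insight_time if restrict else None)
        if mask.any():
            g = rec.trajectory.gamma[mask]
            gmins.append(g.min())
            gmaxs.append(g.max())
    if not gmins:
        raise ValueError("no pre-transition samples in corpus")
    edges = np.linspace(min(gmins), max(gmaxs) + 1e-12, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    need_sup = statistic in ("mean_surprisal", "sd_u_vs_surprisal")
    need_sd = statistic in ("sd_u", "sd_u_vs_surprisal")
    if need_sup and surprisals is None:
        surprisals = [surprisal_series(s.series, cfg) for s in corpus.sessions]

    sd_mat = np.full((len(corpus.sessions), n_bins), np.nan)
    sup_mat = np.full((len(corpus.sessions), n_bins), np.nan)
    for s_idx, rec in enumerate(corpus.sessions):
        traj = rec.trajectory
        t_ins = rec.insight_time if restrict else None
        if need_sd:
            mask = _pre_transition_mask(traj.times, t_ins)
            g = traj.gamma[mask]
            u = traj.u[mask]
            bins = np.clip(np.digitize(g, edges) - 1, 0, n_bins - 1)
            for b in range(n_bins):
                sel = bins == b
                if sel.sum() >= 2:
                    sd_mat[s_idx, b] = np.std(u[sel], ddof=1)
        if need_sup:
            frame = surprisals[s_idx].defined
            ev_t = frame["time"].to_numpy()
            ev_h = frame["surprisal_bits"].to_numpy()
            mask = _pre_transition_mask(ev_t, t_ins)
            g = np.interp(ev_t[mask], traj.times, traj.gamma)
            bins = np.clip(np.digitize(g, edges) - 1, 0, n_bins - 1)
            h = ev_h[mask]
            for b in range(n_bins):
                sel = bins == b
                if sel.any():
                    sup_mat[s_idx, b] = np.mean(h[sel])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        sd_bin = np.nanmean(sd_mat, axis=0)
        sup_bin = np.nanmean(sup_mat, axis=0)

    if statistic == "sd_u":
        yv, xv = sd_bin, centers
    elif statistic == "mean_surprisal":
        yv, xv = sup_bin, centers
    else:
        xv, yv = sd_bin, sup_bin

    keep = ~(np.isnan(xv) | np.isnan(yv))
    if keep.sum() < n_bins:
        logger.warning("binned_trend: dropping %d empty gamma bins", n_bins - int(keep.sum()))
    return kendall_trend(xv[keep], yv[keep])


def label_epochs(
    series: EventSeries,
    insights: Sequence[float],
    w_pre: float,
    w_post: float,
) -> EpochLabels:
    """Flag events falling in the windows around each insight."""
    if w_pre < 0 or w_post < 0:
        raise ValueError("window widths must be >= 0")
    times = series.times
    pre = np.zeros(len(times), dtype=bool)
    post = np.zeros(len(times), dtype=bool)
    for t_ins in insights:
        pre |= (times > t_ins - w_pre) & (times < t_ins)
        post |= (times >= t_ins) & (times < t_ins + w_post)
    return EpochLabels(session_id=series.session_id, pre=pre, post=post)


def _stratum_stats(values: np.ndarray, sessions: np.ndarray) -> dict:
    n = len(values)
    if n == 0:
        return {"mean": np.nan, "se": np.nan, "se_session": np.nan, "n": 0}
    mean = float(np.mean(values))
    se = float(np.std(values, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    sess_means = pd.Series(values).groupby(pd.Series(sessions)).mean()
    k = len(sess_means)
    se_sess = float(sess_means.std(ddof=1) / np.sqrt(k)) if k > 1 else np.nan
    return {"mean": mean, "se": se, "se_session": se_sess, "n": n}


def epoch_contrast(
    surprisals: Sequence[SurprisalSeries],
    labels: Sequence[EpochLabels],
) -> pd.DataFrame:
    """Mean surprisal (with SEs) in pre-, post- and other-epoch strata.

    Returns a DataFrame indexed by stratum with columns ``mean``, ``se``
    (across events), ``se_session`` (across session means) and ``n``.
    Strata with no defined surprisals are reported with NaN mean and n = 0.
    """
    vals = {"pre": [], "post": [], "other": []}
    sess = {"pre": [], "post": [], "other": []}
    for sup, lab in zip(surprisals, labels):
        if sup.session_id != lab.session_id:
            raise ValueError("surprisal/label session mismatch")
        h = sup.frame["surprisal_bits"].to_numpy()
        defined = ~np.isnan(h)
        for name, mask in (("pre", lab.pre), ("post", lab.post), ("other", lab.other)):
            sel = mask & defined
            vals[name].append(h[sel])
            sess[name].append(np.full(int(sel.sum()), sup.session_id))
    rows = {}
    for name in ("pre", "post", "other"):
        v = np.concatenate(vals[name]) if vals[name] else np.array([])
        s = np.concatenate(sess[name]) if sess[name] else np.array([])
        rows[name] = _stratum_stats(v, s)
    return pd.DataFrame.from_dict(rows, orient="index")


def hierarchical_regression(
    surprisals: Sequence[SurprisalSeries],
    labels: Sequence[EpochLabels],
    time_scale: float = 60.0,
) -> pd.DataFrame:
    """Session-random-intercept linear model of per-event surprisal.

    Fixed effects: time (in units of ``time_scale``, e.g. minutes for
    second-stamped data), pre-insight flag, post-insight flag and the
    new-inscription flag; random intercept per session (statsmodels MixedLM,
    REML).  With a single session the model degrades to OLS with a warning.
    Returns a coefficient table with ``coef``, ``se`` and ``t`` per term.

    Raises
    ------
    ValueError
        If the design matrix is rank deficient (e.g. a constant covariate).
    """
    frames = []
    for sup, lab in zip(surprisals, labels):
        f = sup.frame.copy()
        f["pre"] = lab.pre.astype(float)
        f["post"] = lab.post.astype(float)
        f["session"] = sup.session_id
        frames.append(f)
    data = pd.concat(frames, ignore_index=True)
    data = data[data["surprisal_bits"].notna()].copy()
    data["time_scaled"] = data["time"] / time_scale
    data["is_new"] = data["is_new"].astype(float)

    exog_cols = ["time_scaled", "pre", "post", "is_new"]
    # constant covariates carry no information (e.g. is_new when unsmoothed
    # estimation leaves every novel-label event undefined): drop with warning
    degenerate = [c for c in exog_cols if data[c].nunique() <= 1]
    if degenerate:
        warnings.warn(f"dropping constant covariates from the model: {degenerate}")
        exog_cols = [c for c in exog_cols if c not in degenerate]
    import statsmodels.api as sm

    X = sm.add_constant(data[exog_cols], has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            "check for constant or collinear covariates"
        )
    y = data["surprisal_bits"]

    n_sessions = data["session"].nunique()
    if n_sessions < 2:
        warnings.warn("single session: fitting ordinary least squares, no random intercept")
        res = sm.OLS(y, X).fit()
        return pd.DataFrame({"coef": res.params, "se": res.bse, "t": res.tvalues})

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MixedLM convergence chatter
        model = sm.MixedLM(y, X, groups=data["session"])
        res = model.fit(reml=True)
    table = pd.DataFrame({"coef": res.params, "se": res.bse, "t": res.tvalues})
    return table.loc[["const"] + exog_cols]


def permute_session(series: EventSeries, seed: int | np.random.Generator = 0) -> EventSeries:
    """Time-permuted surrogate: shuffle which label occurs at which timestamp.

    Timestamps are untouched and the label multiset is conserved, so event
    timing and per-label interaction counts are preserved while sequential
    structure is destroyed.  ``is_new`` flags are recomputed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = series.labels
    perm = rng.permutation(len(labels))
    new_labels = [labels[i] for i in perm]
    return with_recomputed_is_new(series.session_id, [e.time for e in series.events], new_labels)


def surrogate_null(
    series_list: Sequence[EventSeries],
    insights: dict[str, list[float]],
    cfg: ContextConfig,
    w_pre: float,
    w_post: float,
    n_permutations: int = 500,
    seed: int = 0,
) -> SurrogateResult:
    """Permutation test of the pre/post surprisal elevation around insights.

    The observed statistic is the mean-surprisal contrast (pre - other and
    post - other) over all sessions.  Each surrogate shuffles labels across
    the fixed timestamps within every session, recomputes surprisal and the
    contrasts.  Upper-tail Monte-Carlo p-values use the (r+1)/(n+1)
    correction, so p is never exactly zero.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    series_list = list(series_list)
    labels = [
        label_epochs(s, insights.get(s.session_id, []), w_pre, w_post) for s in series_list
    ]

    def contrasts(slist: Sequence[EventSeries]) -> tuple[float, float]:
        sups = [surprisal_series(s, cfg) for s in slist]
        table = epoch_contrast(sups, labels)
        other = table.loc["other", "mean"]
        return (table.loc["pre", "mean"] - other, table.loc["post", "mean"] - other)

    obs_pre, obs_post = contrasts(series_list)
    rng = np.random.default_rng(seed)
    null_pre = np.empty(n_permutations)
    null_post = np.empty(n_permutations)
    for r in range(n_permutations):
        surr = [permute_session(s, rng) for s in series_list]
        null_pre[r], null_post[r] = contrasts(surr)

    p_pre = (np.sum(null_pre >= obs_pre) + 1) / (n_permutations + 1)
    p_post = (np.sum(null_post >= obs_post) + 1) / (n_permutations + 1)
    return SurrogateResult(
        n_permutations=n_permutations,
        observed_contrast_pre=float(obs_pre),
        observed_contrast_post=float(obs_post),
        null_pre=null_pre,
        null_post=null_post,
        p_pre=float(p_pre),
        p_post=float(p_post),
    )


def insight_locked_curve(
    surprisals: Sequence[SurprisalSeries],
    insights: dict[str, list[float]],
    window_width: float,
    step: float,
    span: Optional[float] = None,
) -> pd.DataFrame:
    """Insight-triggered average of surprisal.

    Events are re-timed relative to each insight in their session (an event
    contributes once per insight within ±``span``, default 5x the window
    width), pooled over sessions, and summarised by a sliding window of
    width ``window_width`` advanced by ``step``.  Returns a DataFrame with
    columns ``rel_time`` (window centre), ``mean``, ``se`` and ``n``; window
    parameters are carried in ``DataFrame.attrs``.
    """
    if span is None:
        span = 5.0 * window_width
    rel_times, values = [], []
    any_insight = False
    for sup in surprisals:
        ins = insights.get(sup.session_id, [])
        if ins:
            any_insight = True
        frame = sup.defined
        t = frame["time"].to_numpy()
        h = frame["surprisal_bits"].to_numpy()
        for t_ins in ins:
            rel = t - t_ins
            sel = np.abs(rel) <= span
            rel_times.append(rel[sel])
            values.append(h[sel])
    if not any_insight:
        raise ValueError("insight_locked_curve needs at least one insight")
    rel = np.concatenate(rel_times) if rel_times else np.array([])
    val = np.concatenate(values) if values else np.array([])

    centers = np.arange(-span, span + step / 2, step)
    rows = []
    for c in centers:
        sel = np.abs(rel - c) <= window_width / 2
        n = int(sel.sum())
        if n == 0:
            rows.append({"rel_time": c, "mean": np.nan, "se": np.nan, "n": 0})
        else:
            v = val[sel]
            se = float(np.std(v, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            rows.append({"rel_time": c, "mean": float(np.mean(v)), "se": se, "n": n})
    out = pd.DataFrame(rows)
    out.attrs["window_width"] = window_width
    out.attrs["step"] = step
    out.attrs["span"] = span
    return out
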