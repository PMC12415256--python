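# Methods

## The latent model

Understanding is a scalar `U ∈ [0, 1]` with drift

```
f(U) = γ (1−U)² / (h² + (1−U)²) − U (1−U)
```

The first term is *innovation*: a saturating drive toward the correct
understanding, strongest when far from it, weighted by the control
parameter γ. The second is *functional fixedness*: a restoring pull toward
the initial misconception at `U = 0`, vanishing at both ends of the
interval. `h²` is the squared half-saturation constant of the innovation
term; the default is `h² = 0.01` (i.e. h = 0.1). This value matters
structurally: with `h² = 0.01` the drift has two saddle-node folds, at
γ ≈ 0.1787 (the enlightened branch appears) and γ ≈ 0.2604 (the confused
branch vanishes), so a slow upward ramp of γ forces a critical transition
near 0.26. Values of `h²` above 1/27 ≈ 0.037 destroy the bistability
entirely (the interior extrema of γ(x) = (1−x)(h²+x²)/x, x = 1−U,
disappear), which is why `h²` is exposed but defaults to 0.01.

Stochastic sessions integrate `dU = f(U) dt + σ dW` with the
Euler–Maruyama scheme: `u_{t+1} = u_t + f(u_t) dt + σ √dt z_t`,
`z_t ~ N(0,1)`. Defaults: `dt = 1`, `n_steps = 2000`, γ ramped linearly
0.1 → 0.3, `u0 = 0.1` (the confused attractor at γ = 0.1 sits at
u\* ≈ 0.105), `σ = 0.02`. At σ = 0.02 escapes well before the fold are
rare (first crossings of U = 0.5 cluster in the last ~6% of the ramp
before γ\*) while γ-binned fluctuations remain measurable. `u` is clamped
to [0, 1] after each step; clamp events are counted and logged at DEBUG.
The model insight time is the first upward crossing of U = 0.5, the
midpoint separating the confused (`U < 0.5`) from the enlightened regime;
the threshold is configurable.

Fixed points are located by sign-change bracketing on a 4001-point grid
plus Brent refinement; stability is the sign of a central-difference
derivative (step 1e−6, ties within 1e−10 labelled unstable). `u = 1` is
always appended as a root (both drift terms vanish there; it is
unstable). Fold detection sweeps γ at 1e−3 resolution, counts interior
fixed points, and bisects the interval where the count changes; absence of
a fold is a regular result (`gamma_star = None`), not an error.

## The observation model

Each session draws two row-stochastic matrices over its inscription
alphabet: `B0` (confusion) and `B1` (enlightenment), rows i.i.d. symmetric
Dirichlet. The event at step `t+1` is drawn from row `current label` of
`B_u = (1−u_t) B0 + u_t B1`; the first event is uniform and carries no
transition information (it is excluded from downstream statistics). One
event per latent step is emitted by default. Session seeds derive from the
corpus master seed via `SeedSequence` spawning, making corpora
byte-reproducible.

The Dirichlet concentration is the one calibrated constant of the
generator. It was chosen **once** so that the baseline mean surprisal of
the standard synthetic corpus (events far from any insight, scored with
the default estimator below) sits near 0.75 bits, and then frozen at
`DEFAULT_CONCENTRATION = 0.005`. At this concentration rows are sparse and
near-deterministic, so behaviour within one regime is repetitive and its
unpredictability is dominated by the `B0`/`B1` mixing weight — i.e. by the
latent state, which is the regime the model is meant to emulate.

## The surprisal estimator

Per event: `h(E_t) = −log2 P(E_t | C_t)`, with `C_t` the events in the
open window `(t − δ, t)` (the scored event is excluded, so nothing
conditions on itself). `P` is the first-order empirical transition
probability in the window with additive pseudocount `k` over the alphabet
of labels seen so far in the session plus one virtual novel symbol:

```
P(j | i) = (c_ij + k) / (n_i + k·A)
```

The conditioning label is the event's *actual* predecessor even when that
predecessor lies outside the window; only transition pairs fully inside
the window contribute counts. When the conditioning label has no outgoing
transitions in the window the estimate backs off to the (equally
smoothed) marginal label frequency of the window.

The default is `k = 0`: raw empirical transition probabilities. Events
whose probability estimate is zero — the session's first event, events
with an empty context, never-before-seen transitions — have *undefined*
surprisal: they are flagged, counted, excluded from all downstream
statistics, and never silently dropped or assigned a value. The
alternative (`k > 0`) assigns every event a finite surprisal but
introduces a floor of order `−log2(k/(n_i + kA))` that scales with
alphabet size; with 25-symbol alphabets and 40-event windows that floor
is several bits and swamps the signal of interest. Raw estimation keeps
the absolute scale interpretable (0 bits = fully predicted) at the cost
of discarding the novel-transition events, whose count is reported.
Window defaults: δ = 40 steps for model data, 60 s for empirical data; a
sensitivity grid re-runs the epoch contrast at ±33% of δ.

## Inference

* **Binned trends.** γ is split into 15 equal-width bins spanning the γ
  range that actually contributes samples. Per session and bin, the
  statistic (SD of `U`, or mean surprisal of events mapped to γ via their
  timestamps) is computed on **pre-transition** samples only (before the
  session's insight); bin values are averaged across sessions and the
  Kendall τ-b of bin centre versus statistic is reported together with the
  raw concordant-pair count T and p-value. The pre-transition restriction
  is what makes the trend well-defined — after the escape, `U` pins near 1
  and both its SD and the event surprisal collapse — and it is also why
  bins span the restricted range: binning the full ramp would leave the
  top bins permanently empty. 15 bins of 24 sessions give 105 bin pairs.
* **Epochs.** Around each insight, `pre = (t_ins − w, t_ins)` and
  `post = [t_ins, t_ins + w)`; the default model width is 10% of the
  session (`w = 200` steps), the default empirical width 120 s. Events in
  neither window are "other"; flags are independent, so nearby insights
  can mark an event both pre and post. Contrasts report means, SEs across
  events, and session-weighted SEs.
* **Mixed model.** Per-event surprisal on fixed effects time, pre, post,
  is_new with a session random intercept (statsmodels `MixedLM`, REML).
  Constant covariates are dropped with a warning (with `k = 0`, every
  new-inscription event is undefined, so `is_new` is typically constant
  within the defined subset); genuine collinearity raises an explicit
  rank-deficiency error; a single-session corpus degrades to OLS with a
  warning.
* **Surrogate null.** Each surrogate shuffles labels across a session's
  fixed timestamps (conserving the timestamp vector and label multiset,
  asserted by construction), recomputes surprisal and the epoch
  contrasts; upper-tail Monte-Carlo p-values use the (r+1)/(n+1)
  correction.
* **Insight-locked curve.** Events re-timed relative to each insight
  (once per insight within ±span, default 5 windows), pooled, summarised
  by a sliding window mean ± SE.

## What the generator does and does not emulate

It emulates: per-session alphabets of ~25 symbols, hundreds to thousands
of events per session, nonstationary transition structure driven by a
latent state, annotated insight moments, and session-to-session
heterogeneity (fresh `B0`, `B1`, and noise realisation per session). It
does not emulate: inscription creation/erasure semantics, spatial layout,
irregular event timing (model events are equally spaced; empirical ones
are not), multiple insights per session, or insight annotations that are
noisy relative to the underlying transition. Passing tests on synthetic
corpora therefore validate the estimator and inference machinery under
the model's assumptions; they do not by themselves establish how large
the signal is in any real corpus.

## Numerical choices and edge cases

Degenerate inputs are contracts, not crashes: empty contexts and
single-event sessions yield flagged undefined surprisals; empty epoch
strata are reported with `n = 0`; empty γ-bins are dropped with a
warning; a fold search outside the bistable regime returns "no fold".
Determinism: every stochastic routine takes an explicit seed (or
Generator), and corpora, CLI runs and reports are byte-identical across
repeated runs with the same inputs. Event-table parsing is strict —
non-monotone timestamps are hard errors naming the row; `is_new` flags
are recomputed from first occurrences and mismatches against the file are
warned about and overridden.

## Known limitations

* The binned-trend taus of the standard synthetic study are high
  (typically 0.85–0.98 across the three statistics): with near-
  deterministic rows the signal is strongly monotone, and 15-bin Kendall
  statistics have a coarse, discrete sampling distribution.
* The mean surprisal in the pre-insight window is bounded below by the
  unpredictability inherent to the `B0`/`B1` mixture: along the confused
  branch `u*` climbs to ≈ 0.48 just before the fold, so pre-insight events
  carry at least the binary entropy of the mixing weight (~1 bit)
  regardless of the concentration. Absolute epoch levels are therefore
  strongly model- and estimator-dependent; the robust, assumption-light
  statements are the orderings and the surrogate-null p-values.
* Post-insight surprisal collapses quickly once behaviour settles on
  `B1`; whether the post epoch is elevated relative to "other" depends on
  how much of the transition turbulence the post window captures and can
  go either way at the default width.
* First-order transition probabilities only; higher-order context,
  entropy-rate or transfer-entropy estimators are out of scope.
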