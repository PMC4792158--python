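# Methods

## Transition sets and predictors (`sequence_stats`)

A location sequence over the alphabet {a, b, c, d} is reduced to the
multiset of its (n_prev+1)-grams.  Gram windows are **circular** by
default: an L-symbol nominal cycle contributes exactly L transitions, with
wrap-around, which is what makes an 8-symbol cycle yield 8 transitions and
keeps the gram distribution identical under tiling of the cycle.  Realized
trial streams (which are not cycles) are scored non-circularly.

All four predictors derive from the gram counts: JP is the relative
frequency, CP the within-prefix relative frequency, JE = −Σ JP log₂ JP and
CE = −Σ JP log₂ CP.  Entropies are in bits; the base is a convention and
only rescales values.  Zero-count grams are never stored, so 0·log 0 does
not arise.  Grams are emitted in lexicographic order; identical input
yields bit-identical output.  The chain rule CE = JE − H(prefix marginal)
holds to numerical precision and is enforced by property tests.

Per-trial predictor attachment looks each realized trial's gram up in the
**nominal** table of the training cycle; grams absent from that table
(random or probabilistic streams) fall back to the empirical table of the
realized stream itself, so every analysable trial has a predictor.  Both
nominal-only and empirical-only modes are available by passing or omitting
the nominal sequence.

Unless told otherwise, the analyses use transitions with **three previous
locations** (4-grams).  This history length makes the joint entropy of a
4-location no-repeat design span 1 to log₂108 ≈ 6.75 bits, wide enough to
pin both asymptotes of the sigmoid; with bigrams only (span ≤ log₂12 ≈
3.58 bits) the mid-point and asymptotes trade off and block-wise fits are
poorly identified.

## Sequence generators (`sequence_gen`)

*Random*: uniform over the three non-repeating successors, realized by a
cumulative-offset trick (vectorised, seeded).  *Repetitive*: cyclic
repetition of a pattern.  *Probabilistic*: first-order Markov realization
of a row-stochastic matrix with uniform initial state.  Longer-range
dependencies are an extension point, not implemented.

Six named presets emulate the canonical training groups; their identity is
a package choice (only the predictability ordering matters downstream) and
their nominal joint entropies are strictly ordered at every history
length:

| preset | construction | JE (bits, 1 prev) |
|---|---|---|
| random | uniform no-repeat | 3.585 |
| complex_probabilistic | cycle w. dominant successor p = 0.6 | 3.371 |
| simple_probabilistic | cycle w. dominant successor p = 0.8 | 2.922 |
| complex_repetitive | 12-cycle `abcabdabdcad` | 2.689 |
| simple_repetitive | 8-cycle `ababcdcd` | 2.5 |
| very_simple_repetitive | 4-cycle `abcd` | 2.0 |

The ordering is robust to history length because a deterministic L-cycle's
JE is capped at log₂ L while a Markov chain's JE grows by one conditional
entropy per added previous location.

The **entropy-graded family** emulates a multi-session design: targets are
evenly spaced across a JE range (default 1–3.58 bits at one previous
location), and each sequence is a Markov chain mixing a deterministic base
cycle (`abab` below 2 bits, `abcd` above) with the uniform no-repeat chain.
The substitution probability ε is solved by bisection against the chain's
*analytic* JE (stationary distribution × rows) — deterministic and free of
sampling noise in the solve — and the achieved JE is then measured on the
generated 882-trial sequence.  Near-periodic chains mix slowly, so an
882-trial realization can miss a low-entropy target by more than the
0.15-bit flag threshold; such sequences are flagged (`ok=False`), never
dropped, matching how a real session's empirical entropy deviates from its
design value.

## Synthetic sessions (`rt_synth`)

Design constants: 25 blocks × 49 trials = 1225; random blocks 1–4 and
23–25; training blocks 5–22; 3000 ms response deadline.

Mean RT on each trial is a logistic function of a predictor:

- `predictor="je"` (default): the block sequence's nominal 4-gram joint
  entropy — the session-level generative model behind median-RT analyses;
- `predictor="jp"`: the trial's joint probability under the nominal table
  — the trial-level dispersion model (decreasing orientation; defaults
  Xhalf = 0.10, slope = 0.04 in probability units, Ymax 480 / Ymin 280 ms).

Learning is an exponential drift of the sigmoid parameters across blocks
5–22, `param(b) = start + (end − start)(1 − e^{−rate(b−5)})`, clamped
outside training.  Defaults (entropy units are 4-gram JE): Xhalf 2.4 → 5.6
bits, Ymin 330 → 220 ms, Ymax 480 → 470 ms (near flat), slope 1, rate
0.1/block (≈ 82 % of the asymptotic change by block 22, so learning is
still visibly progressing in late blocks, as block-wise trajectory
analyses of this paradigm show).  Start/end values were chosen once to
bracket the attainable entropy range and produce realistic RTs
(~250–480 ms asymptotes).

Noise is **multiplicative lognormal** (σ = 0.25 of log RT): RT
distributions are right-skewed and medians are the summary statistic, and
the median of m·e^{N(0,σ²)} is m, so block medians are unbiased for the
generating sigmoid.  Errors are Bernoulli (3 %/trial) and flagged, not
re-presented; error dynamics are out of scope.  Per-subject random effects
are a lognormal baseline-speed multiplier (sd 0.08) and the noise scale.
RTs are truncated at the 3000 ms deadline.

What the generator does **not** emulate: sequential RT autocorrelation,
post-error slowing, fatigue/vigilance drifts within a session, reversal
(back-and-forth) and between-hand transition effects, and anticipatory
responses.  Passing recovery tests therefore shows the pipeline is correct
and well-identified under its own assumptions at the stated design scale —
not that real data satisfy those assumptions.

## Fitting (`model_fit`)

Linear fits are closed-form OLS.  Sigmoid fits are Levenberg–Marquardt
nonlinear least squares with deterministic multi-start: asymptotes seeded
from the 5th/95th RT percentiles, mid-point from the predictor median,
slope from range/6, plus five seed-jittered restarts (fixed restart seed
1234); lowest RSS wins, ties to first found.  Any parameter may be held
fixed; block-wise fits fix slope = 1, which the trajectory analysis
requires for stability.  Standard errors come from the Jacobian at the
optimum (σ² (JᵀJ)⁻¹).  R² is 1 − RSS/TSS, reported as-is (negative values
possible for nonlinear fits; constant-y data give R² = 0 by convention).
Non-convergence and degenerate optima (Ymax ≤ Ymin) are flagged, never
silently reported; grid cells and trajectory blocks carrying them are NaN.

Comparison grids evaluate {JP, CP} × {linear, sigmoid} × history length
1–4 on pooled single-trial RTs, and {JE, CE} × {linear, sigmoid} on
per-unit median RTs; every cell for a given history length uses the
identical point set.  The pooled-trial analysis window is trials 442–1078
(blocks 10–22), excluding the fast-changing early-training RTs; both
trial-index and block-range selectors are exposed.  Probability predictors
use the decreasing orientation and are not log-transformed by default
(configurable).

## Pipeline (`pipeline`, `cli`)

Plain CSV is the interchange format (columns `subject_id, group, session,
block, trial, location, correct, rt_ms`) — behavioural trial data has no
community binary standard.  Ingest validates columns and RT numeracy,
flags deadline violations as incorrect, and warns on unexpected block
sizes.  Every run writes a resolved-config YAML snapshot; all randomness
flows from the config seed, so outputs are byte-reproducible from the
snapshot alone.  The `srtlearn` console script exposes `generate-seq`,
`stats`, `simulate`, `fit`, `compare`, `blockfit` and `report`.

## Problem sizes and numerical choices

The recovery studies in the acceptance tests use the full multi-session
design scale (48 sessions × 1225 trials) with 100 replicates for the
grid-winner and parameter-recovery studies, sharing one fixed
entropy-graded family across replicates (the family is the experiment's
design; noise seeds vary per replicate).  Exhaustive oracle checks of
transition counting cover every 3-symbol sequence up to length 10.
Normalisation tolerances: 1e-12 for probability sums, 1e-9 for the
entropy chain rule.  Logistic arguments are clipped at ±500 before
exponentiation to avoid overflow; bisection for ε runs 60 iterations.

## Known limitations

- Sigmoid parameters are weakly identified when the predictor spans less
  than ~3 slope-widths; the package mitigates this by defaulting to 4-gram
  entropies and by fixing the slope in block-wise fits, but single-block
  estimates on narrow designs still carry large standard errors.
- The entropy-graded family's lowest targets are near-periodic chains
  whose finite-sample entropies deviate from the analytic solve (flagged
  per sequence).
- Only first-order Markov structure is generated; triad-like regularities
  beyond gram statistics are not modelled.
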