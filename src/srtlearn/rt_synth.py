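"""Synthetic reaction-time data for the serial reaction time task.

Sessions follow the canonical design: 1225 trials in 25 blocks of 49;
blocks 1-4 and 23-25 use random no-repeat sequences, blocks 5-22 the
group's (or session's) training sequence.  Reaction times are generated
from a sigmoid of a sequence predictor -- joint entropy of the block's
nominal sequence for session-level effects, or per-trial joint probability
for trial-level dispersion -- with learning dynamics across training blocks
(Xhalf drifts up as sequence structure is acquired, Ymin drifts down as
simple sequences become automatic, Ymax stays near flat) and multiplicative
lognormal noise.  Responses have a 3 s deadline; a small fraction of trials
is flagged incorrect and excluded from downstream RT modeling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequence_gen import SequenceSpec, gen_random_norepeat, preset_spec, PRESETS, \
    gen_entropy_graded_family
from .sequence_stats import per_trial_predictors

__all__ = [
    "SigmoidParams",
    "SessionDesign",
    "sigmoid_rt",
    "learning_trajectory",
    "simulate_session",
    "simulate_experiment1",
    "simulate_experiment2",
    "DEFAULT_START",
    "DEFAULT_END",
    "DEFAULT_JP_PARAMS",
    "DEFAULT_RATE",
    "DEFAULT_N_PREV",
    "RT_DEADLINE_MS",
]

RT_DEADLINE_MS = 3000.0


@dataclass(frozen=True)
class SigmoidParams:
    """Four-parameter logistic describing mean RT as a function of a
    predictor.

    xhalf : predictor value at mid-transition (bits for entropy predictors,
        probability units for probability predictors)
    ymax : high-asymptote RT, ms (unpredictable / untrained limit)
    ymin : low-asymptote RT, ms (fully automatic limit)
    slope : transition width in predictor units
    """

    xhalf: float
    ymax: float
    ymin: float
    slope: float = 1.0

    def __post_init__(self) -> None:
        if not (self.ymax > self.ymin > 0):
            raise ValueError(f"require ymax > ymin > 0, got {self}")
        if self.slope <= 0:
            raise ValueError(f"slope must be positive, got {self.slope}")


def sigmoid_rt(x, p: SigmoidParams, orientation: str = "increasing"):
    """Mean RT (ms) at predictor value(s) ``x`` under sigmoid ``p``.

    ``increasing`` (entropy predictors): RT rises from ymin to ymax as x
    grows, RT = ymin + (ymax-ymin) / (1 + exp(-(x - xhalf)/slope)).
    ``decreasing`` (probability predictors): the mirror image, with
    +(x - xhalf) inside the exponential.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("predictor values must be finite")
    if orientation == "increasing":
        z = -(x - p.xhalf) / p.slope
    elif orientation == "decreasing":
        z = (x - p.xhalf) / p.slope
    else:
        raise ValueError(f"orientation must be increasing|decreasing, got {orientation!r}")
    out = p.ymin + (p.ymax - p.ymin) / (1.0 + np.exp(z))
    return float(out) if out.ndim == 0 else out


# Default learning trajectory endpoints.  Entropy units are joint entropy
# of transitions with three previous locations (4-grams), which spans
# 1..log2(108) ~ 6.75 bits between the simplest no-repeat cycle and the
# uniform no-repeat chain; over training the mid-point shifts right
# (structure acquired) and the low asymptote falls (automation); the high
# asymptote barely moves.
DEFAULT_START = SigmoidParams(xhalf=2.4, ymax=480.0, ymin=330.0, slope=1.0)
DEFAULT_END = SigmoidParams(xhalf=5.6, ymax=470.0, ymin=220.0, slope=1.0)

# Trial-level dispersion model (probability predictor, decreasing
# orientation): mid-transition at JP = 0.1, width 0.04 probability units.
DEFAULT_JP_PARAMS = SigmoidParams(xhalf=0.10, ymax=480.0, ymin=280.0,
                                  slope=0.04)

DEFAULT_RATE = 0.1
DEFAULT_N_PREV = 3

TRAINED_BLOCKS = tuple(range(5, 23))
RANDOM_BLOCKS = tuple(range(1, 5)) + tuple(range(23, 26))


def learning_trajectory(block: int,
                        start_params: SigmoidParams = DEFAULT_START,
                        end_params: SigmoidParams = DEFAULT_END,
                        rate: float = DEFAULT_RATE) -> SigmoidParams:
    """Sigmoid parameters at a given training block (5-22).

    Exponential interpolation from ``start_params`` (block 5) toward
    ``end_params``: fraction covered is ``1 - exp(-rate * (block - 5))``.
    Blocks below 5 clamp to the start, above 22 to the block-22 value.
    """
    b = min(max(block, 5), 22)
    frac = 1.0 - math.exp(-rate * (b - 5))
    lerp = lambda a, z: a + (z - a) * frac
    return SigmoidParams(
        xhalf=lerp(start_params.xhalf, end_params.xhalf),
        ymax=lerp(start_params.ymax, end_params.ymax),
        ymin=lerp(start_params.ymin, end_params.ymin),
        slope=lerp(start_params.slope, end_params.slope),
    )


@dataclass(frozen=True)
class SessionDesign:
    """Block structure of one session plus the training-sequence spec."""

    sequence: SequenceSpec
    n_blocks: int = 25
    trials_per_block: int = 49
    random_blocks: tuple[int, ...] = RANDOM_BLOCKS
    trained_blocks: tuple[int, ...] = TRAINED_BLOCKS

    def __post_init__(self) -> None:
        blocks = sorted(self.random_blocks + self.trained_blocks)
        if blocks != list(range(1, self.n_blocks + 1)):
            raise ValueError("random and trained blocks must partition 1..n_blocks")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass(frozen=True)
class SubjectEffects:
    """Per-subject random effects: multiplicative baseline speed and the
    lognormal noise scale (sigma of log RT)."""

    baseline: float = 1.0
    noise_sigma: float = 0.25
    error_rate: float = 0.03


def _random_block_je(n_locations: int = 4, n_prev: int = 1) -> float:
    # uniform no-repeat chain: k * (k-1)^n_prev equiprobable grams
    return math.log2(n_locations * (n_locations - 1) ** n_prev)


def simulate_session(
    design: SessionDesign,
    subject_effects: SubjectEffects = SubjectEffects(),
    seed=None,
    *,
    start_params: SigmoidParams | None = None,
    end_params: SigmoidParams | None = None,
    rate: float = DEFAULT_RATE,
    predictor: str = "je",
    n_prev: int = DEFAULT_N_PREV,
    subject_id: str = "s01",
    group: str = "custom",
    session: int = 1,
) -> pd.DataFrame:
    """Simulate one full session of trial records.

    predictor
        ``"je"``: mean RT is the sigmoid (increasing) of the nominal joint
        entropy of the block's sequence -- the session-level generative
        model.  ``"jp"``: mean RT is the sigmoid (decreasing) of each
        trial's joint probability under the nominal table of the training
        sequence -- the trial-level dispersion model.

    Returns a DataFrame with one row per trial: subject_id, group, session,
    block, trial (1-based session-global), location, correct, rt_ms, and
    the generating predictor value in column ``x``.
    """
    rng = np.random.default_rng(seed)
    if start_params is None:
        start_params = DEFAULT_START if predictor == "je" else DEFAULT_JP_PARAMS
    if end_params is None:
        end_params = DEFAULT_END if predictor == "je" else DEFAULT_JP_PARAMS
    tpb = design.trials_per_block
    trained_seq = design.sequence.realize(
        length=len(design.trained_blocks) * tpb, rng=rng)
    nominal = design.sequence.nominal_sequence()

    locations: list[str] = []
    x_values = np.empty(design.n_trials)
    blocks = np.repeat(np.arange(1, design.n_blocks + 1), tpb)
    params_by_block = {b: learning_trajectory(b, start_params, end_params, rate)
                       for b in range(1, design.n_blocks + 1)}

    if predictor == "je":
        trained_je = design.sequence.nominal_je(n_prev)
        rand_je = _random_block_je(len(design.sequence.alphabet), n_prev)
    elif predictor == "jp":
        ptable = per_trial_predictors(trained_seq, n_prev, nominal=nominal)
        trained_jp = ptable["jp"].to_numpy()
        # leading trials lack a complete history: give them the random-limit JP
        k = len(design.sequence.alphabet)
        rand_jp = 1.0 / (k * (k - 1) ** n_prev)
        trained_jp = np.where(np.isnan(trained_jp), rand_jp, trained_jp)
    else:
        raise ValueError(f"predictor must be 'je' or 'jp', got {predictor!r}")

    t_idx = 0  # position in the trained stream
    mean_rt = np.empty(design.n_trials)
    pos = 0
    for b in range(1, design.n_blocks + 1):
        p = params_by_block[b]
        if b in design.trained_blocks:
            locs = trained_seq.symbols[t_idx:t_idx + tpb]
            if predictor == "je":
                xb = np.full(tpb, trained_je)
            else:
                xb = trained_jp[t_idx:t_idx + tpb]
            t_idx += tpb
        else:
            locs = gen_random_norepeat(tpb, len(design.sequence.alphabet),
                                       rng).symbols
            if predictor == "je":
                xb = np.full(tpb, rand_je)
            else:
                xb = np.full(tpb, rand_jp)
        locations.extend(locs)
        orient = "increasing" if predictor == "je" else "decreasing"
        mean_rt[pos:pos + tpb] = sigmoid_rt(xb, p, orient)
        x_values[pos:pos + tpb] = xb
        pos += tpb

    noise = (np.exp(rng.normal(0.0, subject_effects.noise_sigma,
                               design.n_trials))
             if subject_effects.noise_sigma > 0 else np.ones(design.n_trials))
    rt = np.minimum(mean_rt * subject_effects.baseline * noise, RT_DEADLINE_MS)
    correct = rng.random(design.n_trials) >= subject_effects.error_rate

    return pd.DataFrame({
        "subject_id": subject_id,
        "group": group,
        "session": session,
        "block": blocks,
        "trial": np.arange(1, design.n_trials + 1),
        "location": locations,
        "correct": correct,
        "rt_ms": rt,
        "x": x_values,
    })


def simulate_experiment1(
    n_per_group: int = 8,
    presets=PRESETS,
    seed=None,
    *,
    noise_sigma: float = 0.25,
    baseline_sd: float = 0.08,
    predictor: str = "je",
    n_prev: int = DEFAULT_N_PREV,
    **session_kwargs,
) -> pd.DataFrame:
    """Six training groups, ``n_per_group`` subjects each, one session per
    subject.  Subjects get lognormal baseline-speed random effects."""
    rng = np.random.default_rng(seed)
    frames = []
    sid = 0
    for g in presets:
        spec = preset_spec(g)
        design = SessionDesign(sequence=spec)
        for _ in range(n_per_group):
            sid += 1
            eff = SubjectEffects(
                baseline=float(np.exp(rng.normal(0.0, baseline_sd))) if baseline_sd > 0 else 1.0,
                noise_sigma=noise_sigma)
            frames.append(simulate_session(
                design, eff, rng, subject_id=f"s{sid:02d}", group=g,
                predictor=predictor, n_prev=n_prev, **session_kwargs))
    return pd.concat(frames, ignore_index=True)


def simulate_experiment2(
    n_sessions: int = 48,
    entropy_family: list[dict] | None = None,
    seed=None,
    *,
    noise_sigma: float = 0.25,
    predictor: str = "je",
    n_prev: int = DEFAULT_N_PREV,
    **session_kwargs,
) -> pd.DataFrame:
    """One over-trained subject, ``n_sessions`` sessions, each training a
    sequence of different joint entropy (entropy-graded family spanning the
    attainable range by default)."""
    rng = np.random.default_rng(seed)
    if entropy_family is None:
        entropy_family = gen_entropy_graded_family(
            n_sessions, seed=int(rng.integers(0, 2**31 - 1)))
    if len(entropy_family) < n_sessions:
        raise ValueError("entropy family smaller than n_sessions")
    frames = []
    for s in range(1, n_sessions + 1):
        spec = entropy_family[s - 1]["spec"]
        design = SessionDesign(sequence=spec)
        eff = SubjectEffects(baseline=1.0, noise_sigma=noise_sigma)
        frames.append(simulate_session(
            design, eff, rng, subject_id="s01", group="exp2", session=s,
            predictor=predictor, n_prev=n_prev, **session_kwargs))
    return pd.concat(frames, ignore_index=True)
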