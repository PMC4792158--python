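"""Transition-set statistics for stimulus location sequences.

A sequence of stimulus locations (over a small alphabet, canonically
``a``-``d`` for the four-location serial reaction time task) is summarised
by its set of *transitions*: (n_prev+1)-grams pairing each present location
with the ``n_prev`` locations that preceded it.  Four statistical predictors
are derived from a transition set:

- joint probability JP(g)        -- count(g) / total transitions
- conditional probability CP(g)  -- JP(g) / mass of grams sharing g's prefix
- joint entropy JE               -- -sum JP log2 JP   (bits)
- conditional entropy CE         -- -sum JP log2 CP   (bits)

JP/JE are *joint* predictors (open-loop control: global access to sequence
structure); CP/CE are *conditional* predictors (closed-loop control:
on-line prediction of the next location from the recent past).

Transition sets are built circularly by default, so a repeating nominal
cycle of length L contributes exactly L transitions.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_ALPHABET: tuple[str, ...] = ("a", "b", "c", "d")

__all__ = [
    "DEFAULT_ALPHABET",
    "LocationSequence",
    "TransitionSet",
    "PredictorTable",
    "build_transition_set",
    "joint_probability",
    "conditional_probability",
    "joint_entropy",
    "conditional_entropy",
    "predictor_table",
    "per_trial_predictors",
]


@dataclass(frozen=True)
class LocationSequence:
    """An ordered sequence of stimulus locations over a finite alphabet.

    Parameters
    ----------
    symbols
        The locations, one single-character label per trial.
    alphabet
        Allowed labels; defaults to the four-location alphabet a-d.
    circular
        Whether transition statistics treat the sequence as a repeating
        cycle (every position starts a transition, with wrap-around).
    """

    symbols: tuple[str, ...]
    alphabet: tuple[str, ...] = DEFAULT_ALPHABET
    circular: bool = True

    def __post_init__(self) -> None:
        bad = set(self.symbols) - set(self.alphabet)
        if bad:
            raise ValueError(f"symbols outside alphabet {self.alphabet}: {sorted(bad)}")

    @classmethod
    def from_string(cls, s: str, alphabet: Sequence[str] = DEFAULT_ALPHABET,
                    circular: bool = True) -> "LocationSequence":
        """Build from a plain string like ``"ababcdcd"`` (separators ``-`` and
        whitespace are ignored)."""
        cleaned = s.replace("-", "").replace(" ", "")
        return cls(tuple(cleaned), alphabet=tuple(alphabet), circular=circular)

    def __len__(self) -> int:
        return len(self.symbols)

    def __str__(self) -> str:
        return "".join(self.symbols)


@dataclass(frozen=True)
class TransitionSet:
    """Multiset of (n_prev+1)-grams with occurrence counts."""

    n_prev: int
    counts: Mapping[str, int]
    total: int
    alphabet: tuple[str, ...] = DEFAULT_ALPHABET

    def grams(self) -> list[str]:
        """Distinct grams in lexicographic order."""
        return sorted(self.counts)


def build_transition_set(seq: LocationSequence, n_prev: int) -> TransitionSet:
    """Slide an (n_prev+1)-wide window over the sequence and count grams.

    Circular sequences yield exactly ``len(seq)`` transitions (the window
    wraps); non-circular ones yield ``len(seq) - n_prev``.
    """
    if n_prev < 1:
        raise ValueError(f"n_prev must be >= 1, got {n_prev}")
    n = len(seq)
    if n < n_prev + 1:
        raise ValueError(
            f"sequence of length {n} too short for n_prev={n_prev} "
            f"(need at least {n_prev + 1} symbols)"
        )
    sym = seq.symbols
    counts: Counter[str] = Counter()
    if seq.circular:
        ext = sym + sym[:n_prev]
        for i in range(n):
            counts["".join(ext[i:i + n_prev + 1])] += 1
        total = n
    else:
        for i in range(n - n_prev):
            counts["".join(sym[i:i + n_prev + 1])] += 1
        total = n - n_prev
    return TransitionSet(n_prev=n_prev, counts=dict(counts), total=total,
                         alphabet=seq.alphabet)


def joint_probability(ts: TransitionSet) -> dict[str, float]:
    """JP(g) = count(g) / total transitions; keys in lexicographic order."""
    if ts.total < 1 or not ts.counts:
        raise ValueError("empty transition set")
    return {g: ts.counts[g] / ts.total for g in sorted(ts.counts)}


def conditional_probability(ts: TransitionSet) -> dict[str, float]:
    """CP(g) = count(g) / count of grams sharing g's previous-location prefix."""
    if ts.total < 1 or not ts.counts:
        raise ValueError("empty transition set")
    prefix_mass: Counter[str] = Counter()
    for g, c in ts.counts.items():
        prefix_mass[g[:-1]] += c
    return {g: ts.counts[g] / prefix_mass[g[:-1]] for g in sorted(ts.counts)}


def _check_normalized(jp: Mapping[str, float], tol: float = 1e-9) -> None:
    s = math.fsum(jp.values())
    if abs(s - 1.0) > tol:
        raise ValueError(f"joint probabilities sum to {s!r}, expected 1")


def joint_entropy(jp: Mapping[str, float]) -> float:
    """JE = -sum_g JP(g) log2 JP(g), in bits.

    Zero-probability grams never appear in tables, so 0*log(0) never arises.
    """
    if not jp:
        raise ValueError("empty probability mapping")
    _check_normalized(jp)
    return -math.fsum(p * math.log2(p) for p in jp.values() if p > 0)


def conditional_entropy(jp: Mapping[str, float], cp: Mapping[str, float]) -> float:
    """CE = -sum_g JP(g) log2 CP(g), in bits.

    By the chain rule this equals JE minus the entropy of the
    previous-location (prefix) marginal.
    """
    if set(jp) != set(cp):
        raise ValueError("jp and cp must be defined on the same gram set")
    _check_normalized(jp)
    return -math.fsum(jp[g] * math.log2(cp[g]) for g in jp if jp[g] > 0)


@dataclass(frozen=True)
class PredictorTable:
    """All four predictors of one sequence at one history length."""

    n_prev: int
    jp: Mapping[str, float]
    cp: Mapping[str, float]
    je: float
    ce: float
    n_transitions: int = 0
    counts: Mapping[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Per-gram table (gram, count, jp, cp), lexicographic gram order."""
        grams = sorted(self.jp)
        return pd.DataFrame({
            "gram": grams,
            "count": [self.counts.get(g, 0) for g in grams],
            "jp": [self.jp[g] for g in grams],
            "cp": [self.cp[g] for g in grams],
        })

    def sidecar(self) -> dict:
        """Sequence-level summary for JSON serialization."""
        return {"n_prev": self.n_prev, "je": self.je, "ce": self.ce,
                "n_transitions": self.n_transitions}


def predictor_table(seq: LocationSequence, n_prev: int) -> PredictorTable:
    """Build the transition set and compute JP, CP, JE and CE in one pass."""
    ts = build_transition_set(seq, n_prev)
    jp = joint_probability(ts)
    cp = conditional_probability(ts)
    return PredictorTable(n_prev=n_prev, jp=jp, cp=cp,
                          je=joint_entropy(jp), ce=conditional_entropy(jp, cp),
                          n_transitions=ts.total, counts=dict(ts.counts))


def per_trial_predictors(
    seq: LocationSequence,
    n_prev: int,
    nominal: LocationSequence | None = None,
) -> pd.DataFrame:
    """Attach JP and CP values to each trial of a realized stream.

    Trial ``i`` (0-based, ``i >= n_prev``) receives the probabilities of the
    gram ending at ``i``.  When ``nominal`` is given, grams are looked up in
    the table of the nominal generating cycle (computed circularly); grams
    absent from that table -- possible for random or probabilistic streams --
    fall back to the empirical table of the realized stream itself.  The
    first ``n_prev`` trials have no complete history and get NaN.

    Returns a DataFrame with columns trial, gram, jp, cp.
    """
    realized = predictor_table(seq, n_prev)
    if nominal is not None:
        table = predictor_table(nominal, n_prev)
        jp_lookup, cp_lookup = dict(table.jp), dict(table.cp)
        jp_fallback, cp_fallback = realized.jp, realized.cp
    else:
        jp_lookup, cp_lookup = dict(realized.jp), dict(realized.cp)
        jp_fallback, cp_fallback = {}, {}

    sym = seq.symbols
    rows = []
    for i in range(len(sym)):
        if i < n_prev:
            rows.append((i, None, np.nan, np.nan))
            continue
        g = "".join(sym[i - n_prev:i + 1])
        jp = jp_lookup.get(g, jp_fallback.get(g, np.nan))
        cp = cp_lookup.get(g, cp_fallback.get(g, np.nan))
        rows.append((i, g, jp, cp))
    return pd.DataFrame(rows, columns=["trial", "gram", "jp", "cp"])
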