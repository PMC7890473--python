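"""Ordinal-pattern encoding and the combinatorics of legitimate transitions.

A window of ``D`` consecutive values (spaced ``tau`` apart) is summarised by
the permutation of ranks of its elements: ``ranks[i]`` is the rank of the
i-th window element, with 0 for the smallest.  Ties are broken by temporal
order — the earlier element receives the lower rank (stable argsort), the
usual Bandt–Pompe convention.

For ``tau = 1`` consecutive windows share ``D - 1`` values, so a pattern can
only be followed by one of ``D`` of the ``D!`` patterns ("legitimate
transitions").  At ``D = 3`` each pattern has exactly 3 legal successors and
only the two monotone patterns may repeat (self-loops).

The six D=3 patterns carry canonical integer codes 1..6 in lexicographic
order::

    1 = (0,1,2)   2 = (0,2,1)   3 = (1,0,2)
    4 = (1,2,0)   5 = (2,0,1)   6 = (2,1,0)

Codes 1-3 are "upward waves" (last rank above first), codes 4-6 "downward".
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

__all__ = [
    "PATTERNS_D3",
    "UPWARD_CODES",
    "DOWNWARD_CODES",
    "PatternSequence",
    "SeriesLengthError",
    "encode_series",
    "pattern_code",
    "pattern_from_code",
    "legal_successors",
    "is_legal_transition",
    "reachable_fraction",
    "classify_wave",
    "next_step_direction",
    "self_loop_patterns",
]

#: The six D=3 rank patterns in canonical (lexicographic) order; index+1 = code.
PATTERNS_D3: tuple[tuple[int, ...], ...] = (
    (0, 1, 2),
    (0, 2, 1),
    (1, 0, 2),
    (1, 2, 0),
    (2, 0, 1),
    (2, 1, 0),
)

#: Elliot-style wave clusters: a D=3 pattern is upward iff its last rank
#: exceeds its first.
UPWARD_CODES: frozenset[int] = frozenset({1, 2, 3})
DOWNWARD_CODES: frozenset[int] = frozenset({4, 5, 6})

Wave = Literal["upward", "downward"]


class SeriesLengthError(ValueError):
    """Raised when a series is too short for the requested embedding."""


def _validate_pattern(p: tuple[int, ...]) -> tuple[int, ...]:
    p = tuple(int(x) for x in p)
    if sorted(p) != list(range(len(p))):
        raise ValueError(f"{p!r} is not a permutation of 0..{len(p) - 1}")
    return p


def pattern_code(p: Iterable[int]) -> int:
    """Canonical 1-based code of a D=3 pattern (lexicographic order)."""
    p = _validate_pattern(tuple(p))
    if len(p) != 3:
        raise ValueError(f"codes are defined for D=3 patterns, got D={len(p)}")
    return PATTERNS_D3.index(p) + 1


def pattern_from_code(code: int) -> tuple[int, int, int]:
    if not 1 <= code <= 6:
        raise ValueError(f"pattern code must be in 1..6, got {code}")
    return PATTERNS_D3[code - 1]


@dataclass(frozen=True)
class PatternSequence:
    """The symbolic series produced by ordinal encoding.

    Attributes
    ----------
    ranks
        Integer array of shape ``(m, D)``; row ``s`` is the rank pattern of
        the window starting at series position ``s`` (0-based), i.e. covering
        positions ``s, s + tau, ..., s + (D-1) tau``.
    D, tau
        Embedding dimension and time delay.
    source_length
        Length ``N`` of the raw series; ``m = N - (D-1) tau``.
    """

    ranks: np.ndarray
    D: int
    tau: int
    source_length: int

    def __len__(self) -> int:
        return self.ranks.shape[0]

    def __getitem__(self, s: int) -> tuple[int, ...]:
        return tuple(int(r) for r in self.ranks[s])

    @property
    def codes(self) -> np.ndarray:
        """1..6 codes of each pattern (D=3 only)."""
        if self.D != 3:
            raise ValueError("pattern codes are defined for D=3 only")
        r = self.ranks
        return r[:, 0] * 2 + (r[:, 1] > r[:, 2]) + 1


def encode_series(series, D: int = 3, tau: int = 1) -> PatternSequence:
    """Encode a real-valued series into overlapping rank patterns.

    Parameters
    ----------
    series
        1-D sequence of real numbers, length ``N >= (D-1) tau + 1``.
    D
        Window length (embedding dimension), ``>= 2``.
    tau
        Spacing between window elements, ``>= 1``.

    Returns
    -------
    PatternSequence with one pattern per window.  Ties within a window are
    broken by temporal order: the earlier element gets the lower rank.
    """
    if D < 2:
        raise ValueError(f"embedding dimension must be >= 2, got {D}")
    if tau < 1:
        raise ValueError(f"time delay must be >= 1, got {tau}")
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    min_len = (D - 1) * tau + 1
    if n < min_len:
        raise SeriesLengthError(
            f"series of length {n} is too short for D={D}, tau={tau} "
            f"(need at least {min_len} values)"
        )
    if not np.isfinite(x).all():
        bad = int(np.flatnonzero(~np.isfinite(x))[0])
        raise ValueError(f"series contains a non-finite value at position {bad}")
    m = n - (D - 1) * tau
    windows = x[np.arange(m)[:, None] + tau * np.arange(D)[None, :]]
    # double argsort = ranks; stable first pass gives earlier-element-lower-rank
    order = np.argsort(windows, axis=1, kind="stable")
    ranks = np.argsort(order, axis=1)
    return PatternSequence(ranks=ranks, D=D, tau=tau, source_length=n)


def _relative_ranks(values: tuple[int, ...]) -> tuple[int, ...]:
    """Ranks of a tuple of distinct integers, 0 = smallest."""
    order = sorted(range(len(values)), key=values.__getitem__)
    out = [0] * len(values)
    for rank, i in enumerate(order):
        out[i] = rank
    return tuple(out)


def legal_successors(p: Iterable[int], D: int | None = None) -> frozenset[tuple[int, ...]]:
    """The patterns that may legitimately follow ``p`` at ``tau = 1``.

    Successive windows overlap in ``D - 1`` elements, so the first ``D - 1``
    ranks of the successor must order-match the last ``D - 1`` ranks of
    ``p``; the only freedom is where the new value falls, giving exactly
    ``D`` legal successors.
    """
    p = _validate_pattern(tuple(p))
    if D is not None and D != len(p):
        raise ValueError(f"pattern {p!r} is not of dimension {D}")
    d = len(p)
    rel = _relative_ranks(p[1:])  # ranks 0..d-2 of the shared elements
    out = set()
    for new_rank in range(d):
        q = tuple(r + 1 if r >= new_rank else r for r in rel) + (new_rank,)
        out.add(q)
    return frozenset(out)


def is_legal_transition(p: Iterable[int], q: Iterable[int]) -> bool:
    """True iff pattern ``q`` may directly follow pattern ``p`` (tau = 1)."""
    p, q = _validate_pattern(tuple(p)), _validate_pattern(tuple(q))
    if len(p) != len(q):
        raise ValueError(f"dimension mismatch: {len(p)} vs {len(q)}")
    return q in legal_successors(p)


def reachable_fraction(D: int) -> float:
    """Fraction ``D / D!`` of patterns reachable in one step from any pattern."""
    if D < 2:
        raise ValueError(f"embedding dimension must be >= 2, got {D}")
    identity = tuple(range(D))
    return len(legal_successors(identity)) / math.factorial(D)


def classify_wave(p: Iterable[int]) -> Wave:
    """Elliot-wave cluster of a D=3 pattern: upward iff last rank > first."""
    p = _validate_pattern(tuple(p))
    if len(p) != 3:
        raise ValueError(f"wave classification is defined for D=3, got D={len(p)}")
    return "upward" if p[0] < p[2] else "downward"


def next_step_direction(q: Iterable[int]) -> Literal["increase", "decrease"]:
    """Direction of the step the successor pattern ``q`` implies.

    Reading ``q`` as the window (v2, v3, v4) that follows an observed
    (v1, v2, v3): the fourth value exceeds the third iff the last rank of
    ``q`` exceeds its middle rank.
    """
    q = _validate_pattern(tuple(q))
    if len(q) != 3:
        raise ValueError(f"step direction is defined for D=3, got D={len(q)}")
    return "increase" if q[2] > q[1] else "decrease"


def self_loop_patterns(D: int) -> frozenset[tuple[int, ...]]:
    """Patterns that may legally follow themselves (the monotone ones for D>2)."""
    if D < 2:
        raise ValueError(f"embedding dimension must be >= 2, got {D}")
    return frozenset(
        p for p in itertools.permutations(range(D)) if p in legal_successors(p)
    )
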