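"""Epoch statistics: transition probabilities and irreversibility scores.

An *epoch* is the stretch of raw values immediately preceding a target
window.  From it we estimate

* the 18 transition probability scores (TPS) over the legal D=3 transition
  graph — joint ``p_ij = n_ij / n_transitions`` by default, or row-normalised
  conditional probabilities;
* IRR — the Kullback–Leibler divergence between the ordinal-pattern
  distribution of the epoch read forward and read backward;
* IRR_SYM — for each pattern, the ratio of conditional transition mass
  leaving its up/down wave cluster to the mass staying inside it, plus the
  mean of the six per-pattern components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .patterns import (
    PATTERNS_D3,
    UPWARD_CODES,
    PatternSequence,
    SeriesLengthError,
    encode_series,
    legal_successors,
    pattern_code,
)

__all__ = [
    "LEGAL_PAIRS",
    "LEGAL_MASK",
    "REVERSAL_MAP",
    "TransitionMatrix",
    "IrreversibilityScores",
    "EpochFeatures",
    "InsufficientHistoryError",
    "pattern_distribution",
    "transition_matrix",
    "irr_kl",
    "irr_sym",
    "extract_epoch_features",
    "tps_columns",
]


def _legal_pairs() -> tuple[tuple[int, int], ...]:
    pairs = []
    for i, p in enumerate(PATTERNS_D3, start=1):
        for q in sorted(legal_successors(p)):
            pairs.append((i, pattern_code(q)))
    return tuple(pairs)


#: The 18 legal (from_code, to_code) transitions, row-major in pattern code.
LEGAL_PAIRS: tuple[tuple[int, int], ...] = _legal_pairs()

#: 6x6 boolean mask of legal cells (0-based indexing by code-1).
LEGAL_MASK: np.ndarray = np.zeros((6, 6), dtype=bool)
for _i, _j in LEGAL_PAIRS:
    LEGAL_MASK[_i - 1, _j - 1] = True

#: Codes of the windows that are the time-reversal images of codes 1..6:
#: reversing a tie-free series turns pattern (r0,r1,r2) into (r2,r1,r0).
REVERSAL_MAP: np.ndarray = np.array([6, 4, 5, 2, 3, 1])


def tps_columns() -> list[str]:
    """Stable feature-column names for the 18 legal transitions."""
    return [f"tps_{i}_{j}" for i, j in LEGAL_PAIRS]


class InsufficientHistoryError(ValueError):
    """Raised when a target lacks a full epoch or preceding window."""


@dataclass(frozen=True)
class TransitionMatrix:
    """Adjacent-pair transition counts of a D=3 pattern sequence.

    ``counts[i, j]`` is the number of times code ``i+1`` is immediately
    followed by code ``j+1``; the 18 structurally-illegal cells are always 0.
    """

    counts: np.ndarray
    n_transitions: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (6, 6):
            raise ValueError(f"counts must be 6x6, got {c.shape}")
        if (c < 0).any():
            raise ValueError("transition counts must be nonnegative")
        if c[~LEGAL_MASK].any():
            bad = np.argwhere((c > 0) & ~LEGAL_MASK)[0]
            raise ValueError(
                f"count on illegal transition {bad[0] + 1} -> {bad[1] + 1}"
            )

    @property
    def joint(self) -> np.ndarray:
        """``counts / n_transitions``; all 36 cells sum to 1."""
        if self.n_transitions == 0:
            return np.zeros((6, 6))
        return self.counts / self.n_transitions

    @property
    def conditional(self) -> np.ndarray:
        """Row-normalised counts; rows with no observations are all-zero."""
        rows = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            cond = np.where(rows > 0, self.counts / np.maximum(rows, 1), 0.0)
        return cond

    def tps_vector(self, mode: str = "joint") -> np.ndarray:
        """The 18 legal-cell probabilities in ``LEGAL_PAIRS`` order."""
        if mode == "joint":
            mat = self.joint
        elif mode == "conditional":
            mat = self.conditional
        else:
            raise ValueError(f"tps mode must be 'joint' or 'conditional', got {mode!r}")
        return np.array([mat[i - 1, j - 1] for i, j in LEGAL_PAIRS])


@dataclass(frozen=True)
class IrreversibilityScores:
    irr: float
    irr_sym: float
    irr_sym_components: np.ndarray


@dataclass(frozen=True)
class EpochFeatures:
    """Feature bundle for one target: PRE code + TPS + irreversibility."""

    pre: int
    tps: np.ndarray
    irr: float
    irr_sym: float
    irr_sym_components: np.ndarray
    target_start: int = field(default=-1)


def pattern_distribution(seq: PatternSequence) -> np.ndarray:
    """Relative frequency of each pattern code 1..6; sums to 1."""
    if len(seq) == 0:
        raise ValueError("cannot compute a pattern distribution of an empty sequence")
    counts = np.bincount(seq.codes - 1, minlength=6).astype(float)
    return counts / counts.sum()


def transition_matrix(seq: PatternSequence) -> TransitionMatrix:
    """Count adjacent pattern transitions of a tau=1 sequence."""
    if seq.tau != 1:
        raise ValueError("transition matrices are defined for tau=1 sequences")
    codes = seq.codes
    if codes.size < 2:
        raise ValueError("need at least 2 patterns to count a transition")
    pair = (codes[:-1] - 1) * 6 + (codes[1:] - 1)
    counts = np.bincount(pair, minlength=36).reshape(6, 6)
    return TransitionMatrix(counts=counts, n_transitions=int(codes.size - 1))


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    return float(np.sum(p * np.log(p / q)))


def irr_kl(series, D: int = 3, tau: int = 1, alpha: float = 1.0) -> float:
    """Irreversibility of a series as KL(forward ‖ backward), in nats.

    The forward distribution is the ordinal-pattern distribution of the
    series; the backward one is that of the series read in reverse.
    Additive (Laplace) smoothing ``alpha`` is applied to both count vectors
    before normalisation so the divergence is always finite.
    """
    if alpha <= 0:
        raise ValueError(f"smoothing constant must be > 0, got {alpha}")
    x = np.asarray(series, dtype=float).ravel()
    fwd = encode_series(x, D=D, tau=tau)
    bwd = encode_series(x[::-1], D=D, tau=tau)
    if D == 3:
        cf = np.bincount(fwd.codes - 1, minlength=6).astype(float)
        cb = np.bincount(bwd.codes - 1, minlength=6).astype(float)
    else:  # generic D: histogram over all D! patterns via lexicographic index
        import itertools

        index = {p: k for k, p in enumerate(itertools.permutations(range(D)))}
        nperm = len(index)
        cf = np.zeros(nperm)
        cb = np.zeros(nperm)
        for row in fwd.ranks:
            cf[index[tuple(int(r) for r in row)]] += 1
        for row in bwd.ranks:
            cb[index[tuple(int(r) for r in row)]] += 1
    pf = (cf + alpha) / (cf + alpha).sum()
    pb = (cb + alpha) / (cb + alpha).sum()
    return max(_kl(pf, pb), 0.0)


def _smoothed_conditional(counts: np.ndarray, alpha: float) -> np.ndarray:
    """Conditional matrix with ``alpha`` added to each of the 3 legal cells."""
    cond = np.zeros((6, 6))
    for i in range(6):
        legal = LEGAL_MASK[i]
        row = counts[i, legal].astype(float) + alpha
        total = row.sum()
        if total == 0:
            raise ValueError(
                f"pattern {i + 1} has no observed transitions and smoothing "
                "is disabled (alpha=0)"
            )
        cond[i, legal] = row / total
    return cond


def irr_sym(tm: TransitionMatrix, alpha: float = 1.0) -> tuple[float, np.ndarray]:
    """Symmetry-based irreversibility from up/down wave clusters.

    For each pattern, the component is the ratio of its conditional
    transition probability mass toward the opposite wave cluster to the mass
    staying inside its own cluster; the aggregate score is the mean of the
    six components.  ``alpha`` Laplace-smooths each row's three legal cells
    (``alpha=0`` uses raw conditionals and errors on unobserved rows).
    """
    cond = _smoothed_conditional(tm.counts, alpha)
    up = np.array([c - 1 for c in sorted(UPWARD_CODES)])
    components = np.empty(6)
    for i in range(6):
        in_cluster = up if (i + 1) in UPWARD_CODES else np.setdiff1d(np.arange(6), up)
        inside = cond[i, in_cluster].sum()
        outside = cond[i].sum() - inside
        if inside == 0:
            raise ValueError(
                f"pattern {i + 1} has zero in-cluster transition mass; "
                "use alpha > 0"
            )
        components[i] = outside / inside
    return float(components.mean()), components


def extract_epoch_features(
    series,
    target_start: int,
    epoch_len: int,
    *,
    alpha: float = 1.0,
    tps_mode: str = "joint",
) -> EpochFeatures:
    """Features of the epoch preceding the target window at ``target_start``.

    The epoch is ``series[target_start - epoch_len : target_start]`` — it
    ends at the value immediately before the target's first value, so epoch
    and target never overlap.  PRE is the pattern of the window starting one
    step before the target (it shares two values with the target).
    """
    x = np.asarray(series, dtype=float).ravel()
    t = int(target_start)
    if epoch_len < 4:
        raise ValueError(f"epoch_len must be >= 4 to observe a transition, got {epoch_len}")
    if t - epoch_len < 0 or t < 1:
        raise InsufficientHistoryError(
            f"target at {t} lacks a full epoch of {epoch_len} values"
        )
    if t + 2 >= x.size:
        raise InsufficientHistoryError(
            f"target window starting at {t} extends past the series end"
        )
    epoch = x[t - epoch_len : t]
    seq = encode_series(epoch, D=3, tau=1)
    tm = transition_matrix(seq)
    irr = irr_kl(epoch, alpha=alpha)
    sym, comps = irr_sym(tm, alpha=alpha)
    pre = int(encode_series(x[t - 1 : t + 2], D=3, tau=1).codes[0])
    return EpochFeatures(
        pre=pre,
        tps=tm.tps_vector(mode=tps_mode),
        irr=irr,
        irr_sym=sym,
        irr_sym_components=comps,
        target_start=t,
    )
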