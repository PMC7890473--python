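"""Seeded generators of price-like series with controllable ordinal structure.

Four processes cover the regimes the analysis pipeline must distinguish:

``iid_noise``
    Exchangeable draws — every D=3 pattern equally likely, time-reversible.
``random_walk``
    Cumulative sum of symmetric IID steps — monotone patterns twice as
    likely as mixed ones (1/4 vs 1/8), still ordinally reversible.
``asymmetric_wave``
    A jittered triangle wave whose rise/fall durations are skewed by an
    asymmetry parameter ``theta`` in [0, 1]; theta=0 is statistically
    time-symmetric, larger theta gives slower rises and steeper falls
    (and hence growing IRR and IRR_SYM).
``pattern_markov``
    A Markov chain over the six D=3 patterns (supported on the legal
    transition graph) rendered back into real values, so the emitted series
    re-encodes to exactly the sampled pattern chain.  Seeding the chain with
    a transition matrix measured on minute-resolution Bitcoin prices gives a
    stand-in series with that dataset's published transition structure.

All generators are deterministic given ``(seed, params)`` and emit tie-free
series with probability 1.
"""

from __future__ import annotations

import numpy as np

from .features import LEGAL_MASK
from .patterns import PATTERNS_D3, pattern_from_code

__all__ = [
    "BITCOIN_MINUTE_TPM",
    "gen_iid_noise",
    "gen_random_walk",
    "gen_asymmetric_wave",
    "gen_pattern_markov",
    "generate",
]

#: Conditional pattern-transition probabilities reported for a year of
#: minute-resolution Bitcoin closing prices (rows = from-code 1..6, columns =
#: to-code 1..6; 18 structurally-illegal cells are zero).  Rows are
#: renormalised before sampling (one printed row sums to 0.99 from rounding).
BITCOIN_MINUTE_TPM: np.ndarray = np.array(
    [
        [0.46, 0.27, 0.00, 0.27, 0.00, 0.00],
        [0.00, 0.00, 0.34, 0.00, 0.19, 0.47],
        [0.38, 0.42, 0.00, 0.19, 0.00, 0.00],
        [0.00, 0.00, 0.25, 0.00, 0.39, 0.36],
        [0.48, 0.27, 0.00, 0.25, 0.00, 0.00],
        [0.00, 0.00, 0.32, 0.00, 0.23, 0.45],
    ]
)


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_iid_noise(n: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """IID standard-normal draws (null model: uniform patterns, reversible)."""
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    return _rng(seed).standard_normal(n)


def gen_random_walk(
    n: int, seed: int | np.random.Generator = 0, step_scale: float = 1.0
) -> np.ndarray:
    """Gaussian random walk (price-like null; reversible, trending windows)."""
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    steps = _rng(seed).standard_normal(n) * step_scale
    return np.cumsum(steps)


def gen_asymmetric_wave(
    n: int,
    seed: int | np.random.Generator = 0,
    theta: float = 0.5,
    up_prob_gain: float = 0.35,
) -> np.ndarray:
    """Zero-drift walk with sawtooth-like slow rises and fast falls.

    Steps are exponential: upward with probability ``q = 1/2 +
    up_prob_gain * theta`` and mean 1, downward with probability ``1 - q``
    and mean ``q / (1 - q)`` (so the drift is zero).  ``theta = 0`` gives a
    symmetric — hence time-reversible — walk; increasing ``theta`` produces
    longer gentle up-runs punctured by fewer, larger drops, the classic
    irreversible up/down wave asymmetry.  Continuous steps make ties
    probability-zero events.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    if not 0.0 < up_prob_gain < 0.5:
        raise ValueError(f"up_prob_gain must be in (0, 0.5), got {up_prob_gain}")
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    rng = _rng(seed)
    q = 0.5 + up_prob_gain * theta
    down_mean = q / (1.0 - q)
    up = rng.random(n) < q
    steps = np.where(up, rng.exponential(1.0, n), -rng.exponential(down_mean, n))
    return np.cumsum(steps)


def gen_pattern_markov(
    n: int,
    seed: int | np.random.Generator = 0,
    matrix: np.ndarray | None = None,
) -> np.ndarray:
    """Render a pattern-level Markov chain into a real-valued series.

    ``matrix`` is a 6x6 row-stochastic conditional transition matrix
    supported only on the 18 legal cells (default: the Bitcoin minute-price
    matrix).  The chain of ``n - 2`` patterns is sampled first; values are
    then emitted so that every length-3 window realises its pattern exactly:
    each new value is placed at the midpoint of the admissible open interval
    between the previous two values, or one unit beyond the running range
    when the interval is half-infinite.

    Re-encoding the emitted series recovers the sampled chain exactly.
    """
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    rng = _rng(seed)
    M = BITCOIN_MINUTE_TPM if matrix is None else np.asarray(matrix, dtype=float)
    if M.shape != (6, 6):
        raise ValueError(f"transition matrix must be 6x6, got {M.shape}")
    if (M < 0).any():
        raise ValueError("transition matrix entries must be nonnegative")
    if (M[~LEGAL_MASK] > 0).any():
        i, j = np.argwhere((M > 0) & ~LEGAL_MASK)[0]
        raise ValueError(
            f"matrix places mass on the illegal transition {i + 1} -> {j + 1}"
        )
    rows = M.sum(axis=1)
    if (rows <= 0).any():
        raise ValueError("every row of the transition matrix needs positive mass")
    M = M / rows[:, None]

    n_pat = n - 2
    chain = np.empty(n_pat, dtype=np.int64)
    chain[0] = rng.integers(6)  # 0-based codes
    u = rng.random(n_pat - 1)
    cum = np.cumsum(M, axis=1)
    for s in range(1, n_pat):
        chain[s] = np.searchsorted(cum[chain[s - 1]], u[s - 1], side="right")

    vals = np.empty(n)
    first = pattern_from_code(int(chain[0]) + 1)
    for i, r in enumerate(first):  # any 3 values realising the first pattern
        vals[i] = float(r)
    for s in range(1, n_pat):
        q = PATTERNS_D3[chain[s]]
        a, b = vals[s], vals[s + 1]  # the two shared values of the new window
        lo, hi = min(a, b), max(a, b)
        if q[2] == 2:  # new value above both
            vals[s + 2] = hi + 1.0
        elif q[2] == 0:  # below both
            vals[s + 2] = lo - 1.0
        else:  # strictly between
            vals[s + 2] = 0.5 * (lo + hi)
    return vals


_KINDS = {
    "iid_noise": gen_iid_noise,
    "random_walk": gen_random_walk,
    "asymmetric_wave": gen_asymmetric_wave,
    "pattern_markov": gen_pattern_markov,
}


def generate(kind: str, n: int, seed: int = 0, **params) -> np.ndarray:
    """Dispatch to a generator by name; see module docstring for kinds."""
    try:
        fn = _KINDS[kind]
    except KeyError:
        raise ValueError(
            f"unknown generator kind {kind!r}; choose from {sorted(_KINDS)}"
        ) from None
    return fn(n, seed, **params)
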