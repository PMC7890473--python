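"""Ordinal encoding and the legal-transition combinatorics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ordpred import (
    PATTERNS_D3,
    SeriesLengthError,
    classify_wave,
    encode_series,
    is_legal_transition,
    legal_successors,
    next_step_direction,
    pattern_code,
    pattern_from_code,
    reachable_fraction,
    self_loop_patterns,
)
from .conftest import DEMO_PATTERNS, DEMO_SERIES, TABLE1


def brute_force_successors(p, D):
    """Oracle: observed pattern pairs over every ordering of D+1 distinct reals."""
    pairs = set()
    for values in itertools.permutations(range(D + 1)):
        seq = encode_series(list(map(float, values)), D=D)
        pairs.add((seq[0], seq[1]))
    return {q for (a, q) in pairs if a == tuple(p)}


class TestEncode:
    def test_demo_series(self):
        seq = encode_series(DEMO_SERIES)
        assert [seq[s] for s in range(len(seq))] == DEMO_PATTERNS
        assert len(seq) == len(DEMO_SERIES) - 2
        assert list(seq.codes) == [5, 1, 1, 2, 6, 6, 5, 1]

    @pytest.mark.parametrize(
        "series, expected",
        [
            ([1, 2, 3, 4], [(0, 1, 2), (0, 1, 2)]),
            ([5, 5, 5], [(0, 1, 2)]),  # earlier value gets the lower rank
            ([3, 1, 3], [(1, 0, 2)]),  # tie between first and last
        ],
    )
    def test_monotone_and_ties(self, series, expected):
        seq = encode_series(series)
        assert [seq[s] for s in range(len(seq))] == expected

    def test_window_count_general(self):
        seq = encode_series(np.arange(20.0), D=4, tau=3)
        assert len(seq) == 20 - 3 * 3

    def test_too_short_raises(self):
        with pytest.raises(SeriesLengthError):
            encode_series([9, 1])

    def test_non_finite_raises(self):
        with pytest.raises(ValueError, match="non-finite"):
            encode_series([1.0, np.nan, 2.0, 3.0])

    @given(st.lists(st.integers(0, 10), min_size=3, max_size=60))
    @settings(max_examples=60, derandomize=True)
    def test_adjacent_transitions_always_legal(self, values):
        """Any tau=1 encoding (ties included) walks the legal graph."""
        seq = encode_series([float(v) for v in values])
        for s in range(len(seq) - 1):
            assert is_legal_transition(seq[s], seq[s + 1])

    @given(st.integers(0, 2**31 - 1), st.integers(10, 50))
    @settings(max_examples=40, derandomize=True)
    def test_reversal_identity(self, seed, n):
        """Reversing a tie-free series reverses every pattern's rank string."""
        x = np.random.default_rng(seed).standard_normal(n)
        fwd = encode_series(x)
        bwd = encode_series(x[::-1])
        flipped = [tuple(reversed(bwd[s])) for s in range(len(bwd))][::-1]
        assert [fwd[s] for s in range(len(fwd))] == flipped


class TestLegalTransitions:
    def test_matches_published_table(self):
        for p, expected in TABLE1.items():
            assert legal_successors(p) == expected

    @pytest.mark.parametrize("D", [2, 3, 4])
    def test_matches_brute_force_oracle(self, D):
        for p in itertools.permutations(range(D)):
            assert legal_successors(p) == brute_force_successors(p, D)

    @pytest.mark.parametrize("D", [2, 3, 4, 5])
    def test_every_pattern_has_d_successors(self, D):
        for p in itertools.permutations(range(D)):
            assert len(legal_successors(p)) == D

    def test_d2_unconstrained(self):
        assert legal_successors((0, 1)) == {(0, 1), (1, 0)}
        assert legal_successors((1, 0)) == {(0, 1), (1, 0)}

    @pytest.mark.parametrize(
        "p, q, legal",
        [
            ((0, 1, 2), (2, 1, 0), False),
            ((0, 2, 1), (0, 2, 1), False),  # self-loop only for monotone patterns
            ((2, 1, 0), (2, 1, 0), True),
        ],
    )
    def test_is_legal_transition(self, p, q, legal):
        assert is_legal_transition(p, q) is legal

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            is_legal_transition((0, 1, 2), (0, 1))

    def test_invalid_pattern_raises(self):
        with pytest.raises(ValueError, match="permutation"):
            legal_successors((0, 0, 2))

    @pytest.mark.parametrize(
        "D, expected", [(2, 1.0), (3, 0.5), (4, 1 / 6), (5, 5 / 120)]
    )
    def test_reachable_fraction(self, D, expected):
        assert reachable_fraction(D) == pytest.approx(expected)
        assert reachable_fraction(D) == pytest.approx(D / math.factorial(D))

    @pytest.mark.parametrize(
        "D, expected",
        [
            (2, {(0, 1), (1, 0)}),
            (3, {(0, 1, 2), (2, 1, 0)}),
            (4, {(0, 1, 2, 3), (3, 2, 1, 0)}),
        ],
    )
    def test_self_loops_are_the_monotone_patterns(self, D, expected):
        assert self_loop_patterns(D) == expected


class TestWavesAndDirections:
    def test_cluster_assignment(self):
        up = {p for p in PATTERNS_D3 if classify_wave(p) == "upward"}
        assert up == {(0, 1, 2), (1, 0, 2), (0, 2, 1)}
        down = set(PATTERNS_D3) - up
        assert down == {(1, 2, 0), (2, 1, 0), (2, 0, 1)}

    def test_rank_reversal_flips_cluster(self):
        for p in PATTERNS_D3:
            flipped = tuple(reversed(p))
            assert classify_wave(p) != classify_wave(flipped)

    @pytest.mark.parametrize(
        "q, direction",
        [((0, 1, 2), "increase"), ((1, 2, 0), "decrease"), ((0, 2, 1), "decrease")],
    )
    def test_next_step_direction(self, q, direction):
        assert next_step_direction(q) == direction

    def test_two_thirds_of_012_successors_decrease(self):
        succ = legal_successors((0, 1, 2))
        down = [q for q in succ if next_step_direction(q) == "decrease"]
        assert len(down) / len(succ) == pytest.approx(2 / 3)

    def test_wave_requires_d3(self):
        with pytest.raises(ValueError, match="D=3"):
            classify_wave((0, 1, 2, 3))


def test_pattern_codes_round_trip():
    for code in range(1, 7):
        assert pattern_code(pattern_from_code(code)) == code
    assert [pattern_code(p) for p in PATTERNS_D3] == [1, 2, 3, 4, 5, 6]
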