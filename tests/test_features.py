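"""Epoch statistics: distributions, transition matrices, IRR and IRR_SYM."""

import math

import numpy as np
import pytest

from ordpred import (
    InsufficientHistoryError,
    LEGAL_PAIRS,
    TransitionMatrix,
    encode_series,
    extract_epoch_features,
    irr_kl,
    irr_sym,
    pattern_distribution,
    transition_matrix,
)
from ordpred.features import LEGAL_MASK, REVERSAL_MAP, tps_columns
from .conftest import DEMO_SERIES


def tm_from_conditional(cond, scale=100):
    """Build a count matrix realising the given conditional probabilities."""
    counts = np.rint(np.asarray(cond) * scale).astype(int)
    return TransitionMatrix(counts=counts, n_transitions=int(counts.sum()))


class TestDistributionsAndCounts:
    def test_demo_series_distribution(self):
        dist = pattern_distribution(encode_series(DEMO_SERIES))
        assert dist[0] == pytest.approx(3 / 8)  # {0,1,2} appears 3 of 8 times
        assert dist.sum() == pytest.approx(1.0)

    def test_single_pattern_is_indicator(self):
        dist = pattern_distribution(encode_series([1.0, 2.0, 3.0]))
        assert dist.tolist() == [1, 0, 0, 0, 0, 0]

    def test_demo_series_transition_matrix(self):
        tm = transition_matrix(encode_series(DEMO_SERIES))
        assert tm.n_transitions == 7
        assert tm.joint[0, 0] == pytest.approx(1 / 7)  # {0,1,2}->{0,1,2}
        # row {0,1,2} has two outgoing transitions, one to {0,2,1}
        assert tm.conditional[0, 1] == pytest.approx(1 / 2)
        assert tm.joint.sum() == pytest.approx(1.0)

    def test_illegal_cells_structurally_zero(self, rng):
        tm = transition_matrix(encode_series(rng.standard_normal(500)))
        assert not tm.counts[~LEGAL_MASK].any()

    def test_joint_conditional_relation(self, rng):
        tm = transition_matrix(encode_series(rng.standard_normal(400)))
        rows = tm.counts.sum(axis=1)
        recon = tm.conditional * (rows / tm.n_transitions)[:, None]
        np.testing.assert_allclose(recon, tm.joint, atol=1e-12)

    def test_count_on_illegal_cell_rejected(self):
        counts = np.zeros((6, 6), int)
        counts[0, 5] = 1  # {0,1,2} -> {2,1,0} is forbidden
        with pytest.raises(ValueError, match="illegal"):
            TransitionMatrix(counts=counts, n_transitions=1)

    def test_single_pattern_sequence_rejected(self):
        with pytest.raises(ValueError, match="transition"):
            transition_matrix(encode_series([1.0, 2.0, 3.0]))


class TestIrrKL:
    def test_palindrome_is_reversible(self):
        assert irr_kl([1, 4, 2, 9, 2, 4, 1]) == 0.0

    def test_strictly_increasing_closed_form(self):
        # 98 forward windows all {0,1,2}, 98 backward all {2,1,0}; with
        # alpha=1 both smoothed distributions are (99,1,1,1,1,1)/104 up to
        # a bin swap, giving KL = (98/104) ln 99.
        value = irr_kl(np.arange(100.0), alpha=1.0)
        assert value == pytest.approx((98 / 104) * math.log(99))

    def test_nonnegative_and_reversal_symmetric(self, rng):
        for _ in range(10):
            x = rng.standard_normal(200)
            forward = irr_kl(x)
            assert forward >= 0.0
            # the pattern histogram of the reversed series is the forward
            # histogram with ranks reversed, so IRR is reversal-invariant
            # only up to the KL asymmetry; check the distribution identity
            f = np.bincount(encode_series(x).codes - 1, minlength=6)
            b = np.bincount(encode_series(x[::-1]).codes - 1, minlength=6)
            np.testing.assert_array_equal(b, f[REVERSAL_MAP - 1])

    def test_generic_dimension_supported(self, rng):
        assert irr_kl(rng.standard_normal(300), D=4) >= 0.0

    def test_bad_smoothing_rejected(self):
        with pytest.raises(ValueError, match="smoothing"):
            irr_kl([1.0, 2.0, 3.0, 4.0], alpha=0.0)


class TestIrrSym:
    def test_reference_conditional_values(self):
        # conditional rows of the published minute-price table
        from ordpred.synth import BITCOIN_MINUTE_TPM

        tm = tm_from_conditional(BITCOIN_MINUTE_TPM)
        _, comps = irr_sym(tm, alpha=0.0)
        assert comps[0] == pytest.approx(0.27 / (0.46 + 0.27), abs=1e-9)
        assert comps[1] == pytest.approx((0.19 + 0.47) / 0.34, abs=1e-9)

    def test_uniform_conditional(self):
        uniform = np.where(LEGAL_MASK, 1 / 3, 0.0)
        tm = tm_from_conditional(uniform, scale=300)
        agg, comps = irr_sym(tm, alpha=0.0)
        np.testing.assert_allclose(comps, [0.5, 2.0, 0.5, 0.5, 2.0, 0.5])
        assert agg == pytest.approx(1.0)

    def test_cluster_symmetry_of_uniform_matrix(self):
        # flipping the series upside down maps each pattern to its rank
        # complement (r -> 2-r; codes 1<->6, 2<->5, 3<->4) and swaps the
        # clusters; the uniform matrix is invariant under that mirror, so
        # complementary patterns get equal components
        uniform = np.where(LEGAL_MASK, 1 / 3, 0.0)
        _, comps = irr_sym(tm_from_conditional(uniform, scale=300), alpha=0.0)
        for a, b in ((1, 6), (2, 5), (3, 4)):
            assert comps[a - 1] == pytest.approx(comps[b - 1])

    def test_zero_row_without_smoothing_rejected(self):
        counts = np.zeros((6, 6), int)
        counts[0, 0] = 5
        tm = TransitionMatrix(counts=counts, n_transitions=5)
        with pytest.raises(ValueError, match="smoothing|alpha"):
            irr_sym(tm, alpha=0.0)
        agg, comps = irr_sym(tm, alpha=1.0)  # smoothing rescues the zero rows
        assert np.isfinite(comps).all()


class TestEpochFeatures:
    def test_ten_value_epoch_has_seven_transitions(self, rng):
        x = rng.standard_normal(50)
        feats = extract_epoch_features(x, target_start=20, epoch_len=10)
        epoch_tm = transition_matrix(encode_series(x[10:20]))
        assert epoch_tm.n_transitions == 7
        np.testing.assert_allclose(feats.tps, epoch_tm.tps_vector("joint"))

    def test_pre_is_window_one_step_before_target(self, rng):
        x = rng.standard_normal(80)
        t = 40
        feats = extract_epoch_features(x, target_start=t, epoch_len=20)
        assert feats.pre == int(encode_series(x[t - 1 : t + 2]).codes[0])

    def test_planted_increasing_epoch(self):
        x = np.concatenate([np.arange(30.0), [5.0, 25.0, 7.0]])
        feats = extract_epoch_features(x, target_start=30, epoch_len=30)
        cols = tps_columns()
        assert feats.tps[cols.index("tps_1_1")] == pytest.approx(1.0)
        assert feats.tps.sum() == pytest.approx(1.0)

    def test_insufficient_history_signalled(self, rng):
        x = rng.standard_normal(30)
        with pytest.raises(InsufficientHistoryError):
            extract_epoch_features(x, target_start=5, epoch_len=10)
        with pytest.raises(InsufficientHistoryError):
            extract_epoch_features(x, target_start=29, epoch_len=10)


def test_legal_pairs_layout():
    assert len(LEGAL_PAIRS) == 18
    assert len(set(LEGAL_PAIRS)) == 18
    assert all(LEGAL_MASK[i - 1, j - 1] for i, j in LEGAL_PAIRS)
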