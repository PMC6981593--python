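import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from posim.classifier import (
    arcsine_average,
    classify,
    integrated_position_score,
    predict,
    prior_score,
)
from posim.scoring import FragmentConfig
from posim.seqio import InteractionTable, SequenceRecord

from .oracles import brute_force_scores, chain_prediction

# random binary membership with at least one member and one complement
memberships = st.integers(2, 12).flatmap(
    lambda n: st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
        lambda a: 0 < sum(a) < len(a)
    )
)


class TestIntegratedPositionScore:
    @pytest.mark.parametrize(
        "S_row, a, b, expected",
        [
            ([3, 1], [1, 0], [0, 1], 0.5),
            ([0, 0], [1, 0], [0, 1], 0.0),  # no evidence -> indefinite
            ([5, 5], [1, 0], [0, 1], 0.0),  # symmetric evidence cancels
        ],
    )
    def test_reference_examples(self, S_row, a, b, expected):
        assert integrated_position_score(S_row, a, b) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            integrated_position_score([1, 2, 3], [1, 0], [0, 1])

    def test_non_binary_weights_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            integrated_position_score([1, 2], [0.5, 0.5], [0.5, 0.5])


class TestArcsineAverage:
    @pytest.mark.parametrize(
        "vec, expected",
        [
            ([0.5, 0.5, 0.5], 0.5),
            ([1, -1], 0.0),
            ([0.3, 0.7], math.sin((math.asin(0.3) + math.asin(0.7)) / 2)),
        ],
    )
    def test_reference_examples(self, vec, expected):
        assert arcsine_average(vec) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            arcsine_average([0.2, 1.2])


class TestPriorScore:
    @pytest.mark.parametrize(
        "n_class, n_comp, expected", [(5, 5, 0.0), (4, 0, 1.0), (3, 1, 0.5)]
    )
    def test_class_complement_imbalance(self, n_class, n_comp, expected):
        a = [1] * n_class + [0] * n_comp
        b = [0] * n_class + [1] * n_comp
        assert prior_score(a, b) == expected


class TestClassify:
    @pytest.mark.parametrize(
        "t, t0, expected",
        [(0.9, 0.9, 0.0), (1, 0, 1.0), (-1, 0, -1.0), (0.8, 0.5, 0.5)],
    )
    def test_reference_examples(self, t, t0, expected):
        assert classify(t, t0) == pytest.approx(expected)

    @given(st.floats(-1, 1))
    def test_zero_prior_is_identity_and_self_is_zero(self, t):
        assert classify(t, 0.0) == pytest.approx(t)
        assert classify(t, t) == pytest.approx(0.0)

    @given(st.floats(-0.99, 0.99), st.floats(-1, 1), st.floats(-1, 1))
    def test_strictly_increasing_in_t(self, t0, t_a, t_b):
        lo, hi = sorted((t_a, t_b))
        if hi - lo > 1e-9:
            assert classify(lo, t0) < classify(hi, t0)

    @given(st.floats(-1, 1), st.floats(-1, 1))
    def test_range_bounded(self, t, t0):
        assert -1 <= classify(t, t0) <= 1


@st.composite
def random_stack_membership(draw):
    a = np.array(draw(memberships))
    n = len(a)
    m = draw(st.integers(1, 6))
    S = np.array(
        draw(
            st.lists(
                st.lists(
                    st.floats(0, 50, allow_nan=False, allow_infinity=False),
                    min_size=n,
                    max_size=n,
                ),
                min_size=m,
                max_size=m,
            )
        )
    )
    return S, a


def _full_chain(S: np.ndarray, a: np.ndarray):
    b = 1 - a
    t_p = np.array([integrated_position_score(row, a, b) for row in S])
    t = arcsine_average(t_p)
    t0 = prior_score(a, b)
    return t_p, t, t0, classify(t, t0)


class TestChainProperties:
    @given(random_stack_membership())
    def test_all_quantities_in_unit_interval(self, case):
        S, a = case
        t_p, t, t0, B = _full_chain(S, a)
        assert (np.abs(t_p) <= 1).all()
        assert -1 <= t <= 1 and -1 <= t0 <= 1 and -1 <= B <= 1

    @given(random_stack_membership(), st.floats(0.01, 100))
    def test_scale_invariance_of_scores(self, case, c):
        S, a = case
        _, t, _, B = _full_chain(S, a)
        _, t_scaled, _, B_scaled = _full_chain(S * c, a)
        assert t_scaled == pytest.approx(t, abs=1e-9)
        assert B_scaled == pytest.approx(B, abs=1e-9)

    @given(random_stack_membership())
    def test_swapping_class_and_complement_negates_everything(self, case):
        S, a = case
        t_p, t, t0, B = _full_chain(S, a)
        t_p2, t2, t02, B2 = _full_chain(S, 1 - a)
        assert np.allclose(t_p2, -t_p, atol=1e-12)
        assert t2 == pytest.approx(-t, abs=1e-9)
        assert t02 == pytest.approx(-t0, abs=1e-12)
        assert B2 == pytest.approx(-B, abs=1e-9)


class TestPredict:
    def _dataset(self):
        p1 = SequenceRecord("P1", "ACDEFGHIKLMNPQRSTVWY")
        p2 = SequenceRecord("P2", "YWVTSRQPNMLKIHGFEDCA")
        table = InteractionTable(["P1", "P2"], ["L1"], np.array([[1], [0]]))
        return p1, p2, table

    @pytest.mark.parametrize("like, sign", [("P1", 1), ("P2", -1)])
    def test_query_resembling_one_side_gets_signed_statistic(self, like, sign):
        p1, p2, table = self._dataset()
        query_seq = {"P1": p1, "P2": p2}[like].residues
        Q = SequenceRecord("Q", query_seq)
        cfg = FragmentConfig(5)
        results = predict(Q, [p1, p2], table, cfg)
        assert len(results) == 1
        res = results[0]
        # hand-chain through the defining formulas with the brute-force scores
        S = np.column_stack(
            [
                brute_force_scores(query_seq, p1.residues, 5),
                brute_force_scores(query_seq, p2.residues, 5),
            ]
        )
        t, t0, B = chain_prediction(S, [1, 0])
        assert res.B == pytest.approx(B, abs=1e-12)
        assert sign * res.B > 0

    def test_one_sided_class_is_skipped_with_warning(self, caplog):
        p1, p2, table_ = self._dataset()
        table = InteractionTable(["P1", "P2"], ["L1"], np.array([[1], [1]]))
        Q = SequenceRecord("Q", p1.residues)
        with caplog.at_level("WARNING", logger="posim"):
            results = predict(Q, [p1, p2], table, FragmentConfig(5))
        assert results == []
        assert "skipped" in caplog.text

    def test_query_in_training_rejected(self):
        p1, p2, table = self._dataset()
        with pytest.raises(ValueError, match="training"):
            predict(p1, [p1, p2], table, FragmentConfig(5))
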