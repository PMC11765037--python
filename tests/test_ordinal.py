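"""Ordinal pattern encoding, PDF estimation and information quantifiers."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecghc.ordinal import (
    HCPoint,
    OrdinalPDF,
    disequilibrium,
    disequilibrium_normalization,
    encode_patterns,
    estimate_pdf,
    jensen_shannon_divergence,
    normalized_entropy,
    shannon_entropy,
    statistical_complexity,
)

from conftest import naive_pattern_types, naive_pdf


class TestEncodePatterns:
    def test_worked_example_types(self):
        """The canonical D=3 example series maps to types 6, 5, 1, 4."""
        types = encode_patterns([1, 2, 5, 4, 3, 5], D=3, tau=1)
        assert types.tolist() == [6, 5, 1, 4]

    def test_monotone_series_is_all_ascending(self):
        types = encode_patterns(np.arange(100.0), D=4, tau=2)
        assert types.size == 100 - 3 * 2
        assert np.all(types == math.factorial(4))  # ascending = last type

    def test_descending_series_is_type_one(self):
        assert np.all(encode_patterns(np.arange(50.0)[::-1], D=4, tau=2) == 1)

    def test_amplitude_invariance(self, rng):
        x = rng.standard_normal(200)
        base = encode_patterns(x, 4, 2)
        assert np.array_equal(base, encode_patterns(3.7 * x + 42.0, 4, 2))

    def test_ties_broken_by_temporal_order(self):
        # constant series: earlier samples rank lower -> ascending pattern
        assert np.all(encode_patterns(np.zeros(10), 3, 1) == 6)

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError, match="too short"):
            encode_patterns([1.0, 2.0, 3.0], D=3, tau=2)

    def test_non_finite_values_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            encode_patterns([1.0, np.nan, 2.0, 3.0], D=3, tau=1)

    @given(
        data=st.lists(st.integers(0, 5), min_size=3, max_size=12),
        D=st.integers(2, 3),
        tau=st.integers(1, 2),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force_enumeration(self, data, D, tau):
        """Vectorized encoding equals exhaustive per-window enumeration."""
        if len(data) < (D - 1) * tau + 1:
            return
        assert encode_patterns(data, D, tau).tolist() == naive_pattern_types(
            data, D, tau
        )


class TestEstimatePdf:
    def test_worked_example_pdf(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pdf = estimate_pdf([1, 2, 5, 4, 3, 5], D=3, tau=1)
        assert pdf.n_windows == 4
        # types 6, 5, 1 and 4 each occur once
        expected = np.array([0.25, 0, 0, 0.25, 0.25, 0.25])
        np.testing.assert_allclose(pdf.probs, expected)

    def test_monotone_series_degenerate(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pdf = estimate_pdf(np.arange(20.0), D=3, tau=1)
        assert pdf.probs[-1] == 1.0 and pdf.probs[:-1].sum() == 0.0

    def test_iid_uniform_series_approaches_uniform_pdf(self, rng):
        x = rng.random(2**16)
        pdf = estimate_pdf(x, D=4, tau=2)
        np.testing.assert_allclose(pdf.probs, 1 / 24, atol=0.01)
        assert pdf.n_windows == 2**16 - 6

    def test_counts_normalize_for_any_tau(self, rng):
        for tau in (1, 2, 3):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pdf = estimate_pdf(rng.standard_normal(300), D=4, tau=tau)
            assert pdf.n_windows == 300 - 3 * tau
            assert abs(pdf.probs.sum() - 1) < 1e-12

    def test_short_series_warns(self):
        with pytest.warns(UserWarning, match="unreliable"):
            estimate_pdf(np.arange(10.0), D=3, tau=1)

    def test_time_reversal_swaps_ascending_and_descending(self, rng):
        x = np.sort(rng.standard_normal(30))
        fwd = estimate_pdf(x, 3, 1)
        rev = estimate_pdf(x[::-1], 3, 1)
        assert fwd.probs[-1] == 1.0 and rev.probs[0] == 1.0

    @given(seed=st.integers(0, 100))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_naive_pdf_on_random_series(self, seed):
        x = np.random.default_rng(seed).standard_normal(40)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pdf = estimate_pdf(x, 3, 1)
        np.testing.assert_allclose(pdf.probs, naive_pdf(x, 3, 1))


class TestEntropy:
    def test_uniform_entropy_is_log_alphabet(self):
        pdf = OrdinalPDF.uniform(4)
        assert shannon_entropy(pdf) == pytest.approx(math.log(24), abs=1e-12)
        assert normalized_entropy(pdf) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_entropy_is_zero(self):
        pdf = OrdinalPDF.degenerate(4, 7)
        assert shannon_entropy(pdf) == 0.0
        assert normalized_entropy(pdf) == 0.0

    def test_two_point_distribution(self):
        p = np.zeros(24)
        p[0] = p[1] = 0.5
        pdf = OrdinalPDF(p, D=4, tau=1)
        assert shannon_entropy(pdf) == pytest.approx(math.log(2), rel=1e-12)
        assert normalized_entropy(pdf) == pytest.approx(
            math.log(2) / math.log(24), rel=1e-12
        )


class TestJensenShannon:
    def test_self_divergence_is_zero(self, rng):
        for _ in range(10):
            p = rng.dirichlet(np.ones(24))
            assert jensen_shannon_divergence(p, p) == pytest.approx(0, abs=1e-12)

    def test_disjoint_degenerates_reach_log_two(self):
        p = OrdinalPDF.degenerate(3, 1)
        q = OrdinalPDF.degenerate(3, 2)
        assert jensen_shannon_divergence(p, q) == pytest.approx(math.log(2))

    def test_symmetry(self, rng):
        for _ in range(100):
            p, q = rng.dirichlet(np.ones(24), size=2)
            assert jensen_shannon_divergence(p, q) == pytest.approx(
                jensen_shannon_divergence(q, p), rel=1e-10
            )

    def test_sqrt_jsd_triangle_inequality(self, rng):
        for _ in range(100):
            p, q, r = rng.dirichlet(np.ones(24), size=3)
            d = lambda a, b: math.sqrt(jensen_shannon_divergence(a, b))
            assert d(p, r) <= d(p, q) + d(q, r) + 1e-12

    def test_alphabet_mismatch_raises(self):
        with pytest.raises(ValueError, match="alphabet"):
            jensen_shannon_divergence(np.ones(6) / 6, np.ones(24) / 24)


class TestDisequilibrium:
    def test_uniform_has_zero_disequilibrium(self):
        assert disequilibrium(OrdinalPDF.uniform(4)) == pytest.approx(0, abs=1e-12)

    def test_degenerate_has_unit_disequilibrium(self):
        assert disequilibrium(OrdinalPDF.degenerate(4, 3)) == pytest.approx(1.0)

    def test_degenerate_maximizes_jsd_to_uniform(self, rng):
        """Numerical maximization over the L=6 simplex confirms the Q0 choice."""
        from scipy.optimize import minimize

        L = 6
        pe = np.full(L, 1.0 / L)
        target = 1.0 / disequilibrium_normalization(L)

        def neg_jsd(z):
            p = np.exp(z - z.max())
            p /= p.sum()
            return -jensen_shannon_divergence(p, pe)

        best = -np.inf
        for _ in range(20):
            res = minimize(neg_jsd, rng.standard_normal(L) * 3, method="Nelder-Mead",
                           options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12})
            best = max(best, -res.fun)
        assert best <= target + 1e-9
        assert best == pytest.approx(target, rel=1e-3)

    def test_monotone_in_mixing_weight(self):
        L = 24
        delta = np.zeros(L)
        delta[0] = 1.0
        uniform = np.full(L, 1.0 / L)
        lams = np.linspace(0, 1, 21)
        q = [disequilibrium(l * delta + (1 - l) * uniform) for l in lams]
        assert np.all(np.diff(q) > 0)
        assert q[0] == pytest.approx(0, abs=1e-12)
        assert q[-1] == pytest.approx(1.0)


class TestStatisticalComplexity:
    def test_uniform_and_degenerate_extremes(self):
        top = statistical_complexity(OrdinalPDF.uniform(4))
        assert top.H == pytest.approx(1.0) and top.C == pytest.approx(0, abs=1e-12)
        bottom = statistical_complexity(OrdinalPDF.degenerate(4, 1))
        assert bottom.H == 0.0 and bottom.C == 0.0

    def test_product_structure_matches_direct_evaluation(self):
        L = 24
        p = 0.5 * np.eye(L)[0] + 0.5 / L
        hc = statistical_complexity(p)
        h_direct = -np.sum(p * np.log(p)) / math.log(L)
        pe = np.full(L, 1.0 / L)
        q_direct = disequilibrium_normalization(L) * jensen_shannon_divergence(p, pe)
        assert hc.H == pytest.approx(h_direct, rel=1e-12)
        assert hc.Q == pytest.approx(q_direct, rel=1e-12)
        assert hc.C == pytest.approx(h_direct * q_direct, rel=1e-12)

    def test_hcpoint_consistency_enforced(self):
        with pytest.raises(ValueError):
            HCPoint(H=0.5, C=0.4, Q=0.5)


class TestOrdinalPDFInvariants:
    def test_length_must_be_factorial(self):
        with pytest.raises(ValueError):
            OrdinalPDF(np.ones(5) / 5, D=3, tau=1)

    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError):
            OrdinalPDF(np.full(6, 0.2), D=3, tau=1)
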