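"""Closed-form quantities against enumeration, construction, and Monte Carlo."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bindgeom import theory as T
from bindgeom.theory import CodeParams, StimulusSpec


class TestStimulusSpec:
    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            StimulusSpec(K=0, n=2)
        with pytest.raises(ValueError):
            StimulusSpec(K=2, n=1)
        with pytest.raises(ValueError):
            StimulusSpec(K=2, n=2, S=0)

    def test_lattice_size(self):
        assert StimulusSpec(K=3, n=4).n_stimuli == 64


class TestLinearDistance:
    @pytest.mark.parametrize(
        "PL,K,n,expected",
        [(0.5, 2, 2, 1.0), (0.25, 1, 2, 1.0)],
    )
    def test_printed_examples(self, PL, K, n, expected):
        assert T.linear_distance_from_power(PL, StimulusSpec(K, n)) == pytest.approx(
            expected
        )

    @pytest.mark.parametrize("K,n", [(1, 2), (2, 3), (3, 4), (2, 5)])
    def test_power_equals_exact_lattice_variance(self, K, n):
        # independent oracle: total variance of the full lattice with spacing 1
        pts = np.array(list(itertools.product(range(n), repeat=K)), dtype=float)
        var = ((pts - pts.mean(axis=0)) ** 2).sum(axis=1).mean()
        assert T.linear_power_from_distance(1.0, StimulusSpec(K, n)) == pytest.approx(
            var
        )
        # round trip
        assert T.linear_distance_from_power(var, StimulusSpec(K, n)) == pytest.approx(
            1.0
        )


class TestNeighborCounts:
    @pytest.mark.parametrize(
        "K,n,nla,nld",
        [(2, 2, 2.0, 1.0), (1, 2, 1.0, 0.0)],
    )
    def test_small_lattices(self, K, n, nla, nld):
        nc = T.neighbor_counts(StimulusSpec(K, n))
        assert (nc.NLA, nc.NLD) == (nla, nld)
        assert nc.NNL == n**K - 1
        assert (nc.NC, nc.NCplus1) == (nc.NLA, nc.NLD)

    @pytest.mark.parametrize("K,n", [(2, 3), (3, 4), (4, 2), (2, 9)])
    def test_agrees_with_distance_based_enumeration(self, K, n):
        # independent oracle: count points at euclidean distance 1 and sqrt(2)
        pts = np.array(list(itertools.product(range(n), repeat=K)), dtype=float)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        nla = (np.abs(d - 1.0) < 1e-9).sum(axis=1).mean()
        nld = (np.abs(d - np.sqrt(2)) < 1e-9).sum(axis=1).mean()
        nc = T.neighbor_counts(StimulusSpec(K, n))
        assert nc.NLA == pytest.approx(nla)
        assert nc.NLD == pytest.approx(nld)


class TestCodeDistances:
    def test_pythagorean_combination(self):
        d = T.code_distances(CodeParams(dLV=3, dLA=3, dN=4, sigma=1))
        assert d.dC == pytest.approx(5.0)
        assert d.dCplus1 == pytest.approx(np.sqrt(2 * 9 + 16))

    def test_pure_nonlinear_code(self):
        d = T.code_distances(CodeParams(dLV=0, dLA=0, dN=2.0, sigma=1))
        assert d.dC == d.dCplus1 == pytest.approx(2.0)

    def test_chimera_distance_from_explicit_columns(self):
        # four orthogonal conjunctive columns of length m: the chimera offset
        # is M1+M2-M3-M4 with norm 2m, and the pairwise nonlinear distance
        # between stimuli is sqrt(2)*m = dN
        m = 0.7
        M = np.eye(8)[:, :4] * m
        dN = np.linalg.norm(M[:, 0] - M[:, 1])
        assert dN == pytest.approx(np.sqrt(2) * m)
        dS = np.linalg.norm(M[:, 0] + M[:, 1] - M[:, 2] - M[:, 3])
        assert dS == pytest.approx(2 * m)
        got = T.code_distances(CodeParams(dLV=1, dLA=1, dN=dN, sigma=1))
        assert got.dS == pytest.approx(dS)

    def test_nonorthogonal_cross_term_scale(self):
        d = T.code_distances(
            CodeParams(dLV=1, dLA=1, dN=2, sigma=1), orthogonal=False, n_neurons=100
        )
        assert d.cross_sd_c == pytest.approx(2 * 1 * 2 / 10)
        assert d.cross_sd_cplus1 == pytest.approx(np.sqrt(8) * 2 / 10)
        with pytest.raises(ValueError):
            T.code_distances(CodeParams(), orthogonal=False)


class TestChimericSetCount:
    def test_two_by_two_pair(self):
        # the one printed self-contained value: 1/4 for two binary features
        assert T.chimeric_set_count(StimulusSpec(2, 2, 2)) == pytest.approx(0.25)

    def test_single_feature_has_no_chimeras(self):
        assert T.chimeric_set_count(StimulusSpec(1, 2, 2)) == 0.0

    def test_requires_multiple_stimuli(self):
        with pytest.raises(ValueError):
            T.chimeric_set_count(StimulusSpec(2, 2, 1))

    def test_enumeration_cap(self):
        with pytest.raises(ValueError, match="cap"):
            T.chimeric_set_count(StimulusSpec(3, 3, 2))

    @pytest.mark.parametrize("K,n,S", [(2, 2, 2), (2, 3, 2), (1, 3, 2), (3, 2, 2)])
    def test_agrees_with_bruteforce_sum_matching(self, K, n, S):
        # independent oracle: explicit linear encodings summed per ordered draw
        pts = list(itertools.product(range(n), repeat=K))
        idx = range(len(pts))
        msets = list(itertools.combinations_with_replacement(idx, S))
        sums = {m: tuple(np.sum([pts[i] for i in m], axis=0)) for m in msets}
        total, count = 0, 0
        for draw in itertools.product(idx, repeat=S):
            me = tuple(sorted(draw))
            total += sum(
                1 for m in msets if m != me and sums[m] == sums[me]
            )
            count += 1
        assert T.chimeric_set_count(StimulusSpec(K, n, S)) == pytest.approx(
            total / count
        )


class TestErrorRates:
    def test_overall_vanishes_without_noise_limit(self):
        spec = StimulusSpec(2, 2, 1)
        p = CodeParams(dLV=1, dLA=1, dN=1, sigma=1e-6)
        assert T.overall_error_rate(p, spec) == pytest.approx(0.0, abs=1e-12)

    def test_overall_clipped_at_chance(self):
        spec = StimulusSpec(2, 2, 1)
        p = CodeParams(dLV=0, dLA=0, dN=0, sigma=1.0)
        # degenerate code: all neighbours coincide, bound (NC+NC+1)/2 clips
        assert T.overall_error_rate(p, spec) == pytest.approx(1 - 1 / 4)

    def test_binding_chance_at_zero_nonlinear_distance(self):
        spec = StimulusSpec(2, 2, 2)
        p = CodeParams(dLV=1, dLA=1, dN=0, sigma=0.4)
        assert T.binding_error_rate(p, spec) == pytest.approx(0.125)

    def test_binding_vanishes_for_large_nonlinear_distance(self):
        spec = StimulusSpec(2, 2, 2)
        p = CodeParams(dLV=1, dLA=1, dN=100, sigma=0.4)
        assert T.binding_error_rate(p, spec) == pytest.approx(0.0, abs=1e-12)

    def test_generalization_limits(self):
        assert T.generalization_error_rate(
            CodeParams(dLV=0, dLA=1, dN=1, sigma=0.3)
        ) == pytest.approx(0.5)
        # no nonlinear part, no SEM: reduces to Q(-dLV/(2 sigma))
        from scipy.stats import norm

        p = CodeParams(dLV=1.2, dLA=1, dN=0, sigma=0.3)
        assert T.generalization_error_rate(p) == pytest.approx(
            norm.cdf(-1.2 / (2 * 0.3))
        )
        assert T.generalization_error_rate(
            CodeParams(dLV=0, dLA=0, dN=0, sigma=0.5)
        ) == 0.5

    def test_sigma_must_be_positive(self):
        spec = StimulusSpec(2, 2, 2)
        with pytest.raises(ValueError):
            T.overall_error_rate(CodeParams(sigma=0), StimulusSpec(2, 2, 1))
        with pytest.raises(ValueError):
            T.binding_error_rate(CodeParams(sigma=0), spec)
        with pytest.raises(ValueError):
            T.generalization_error_rate(CodeParams(sigma=0))

    @given(
        dlv=st.floats(0.1, 3.0),
        dla=st.floats(0.0, 3.0),
        dn=st.floats(0.0, 3.0),
        sigma=st.floats(0.1, 2.0),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_binding_ignores_linear_distances(self, dlv, dla, dn, sigma):
        spec = StimulusSpec(2, 2, 2)
        base = T.binding_error_rate(CodeParams(1.0, 1.0, dn, sigma), spec)
        moved = T.binding_error_rate(CodeParams(dlv, dla, dn, sigma), spec)
        assert base == moved

    @given(
        dla=st.floats(0.0, 3.0),
        dn=st.floats(0.0, 3.0),
        sigma=st.floats(0.1, 2.0),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_generalization_ignores_bound_variable_distance(self, dla, dn, sigma):
        a = T.generalization_error_rate(CodeParams(1.0, 0.5, dn, sigma))
        b = T.generalization_error_rate(CodeParams(1.0, dla, dn, sigma))
        assert a == b

    @given(sigma=st.floats(0.15, 1.5), dlv=st.floats(0.2, 2.0))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_opposite_monotonicity_in_nonlinear_distance(self, sigma, dlv):
        spec1 = StimulusSpec(2, 2, 1)
        spec2 = StimulusSpec(2, 2, 2)
        dns = np.linspace(0, 2.5, 8)
        overall = [
            T.overall_error_rate(CodeParams(dlv, dlv, d, sigma), spec1) for d in dns
        ]
        binding = [
            T.binding_error_rate(CodeParams(dlv, dlv, d, sigma), spec2) for d in dns
        ]
        gen = [
            T.generalization_error_rate(CodeParams(dlv, dlv, d, sigma)) for d in dns
        ]
        assert all(a >= b - 1e-12 for a, b in zip(overall, overall[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(binding, binding[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(gen, gen[1:]))


class TestSubspaceCorrelation:
    @pytest.mark.parametrize(
        "dlv,dn,expected", [(1.0, 0.0, 1.0), (0.0, 1.0, 0.0), (1.0, 1.0, 0.5)]
    )
    def test_closed_form(self, dlv, dn, expected):
        assert T.subspace_correlation_from_distances(dlv, dn) == pytest.approx(expected)

    def test_matches_explicit_vector_construction(self):
        # v1 = L1 + M1 - M2, v2 = L1 + M3 - M4 with orthonormal columns
        dlv, m = 1.3, 0.9
        E = np.eye(10)
        L1 = E[:, 0] * dlv
        v1 = L1 + m * (E[:, 1] - E[:, 2])
        v2 = L1 + m * (E[:, 3] - E[:, 4])
        cos = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        dn = np.sqrt(2) * m
        assert T.subspace_correlation_from_distances(dlv, dn) == pytest.approx(cos)

    def test_undefined_for_degenerate_code(self):
        with pytest.raises(ValueError):
            T.subspace_correlation_from_distances(0.0, 0.0)


class TestContinuousEstimator:
    @pytest.mark.parametrize(
        "theta,sigma,expected",
        [(np.pi / 2, 1.0, 2.0), (np.pi / 6, 1.0, 8.0)],
    )
    def test_closed_form(self, theta, sigma, expected):
        assert T.continuous_estimator_variance(theta, sigma) == pytest.approx(expected)

    def test_singular_encodings_rejected(self):
        for theta in (0.0, np.pi):
            with pytest.raises(ValueError):
                T.continuous_estimator_variance(theta, 1.0)

    @pytest.mark.parametrize("theta,sigma", [(np.pi / 4, 0.5), (np.pi / 3, 1.0), (1.0, 0.25)])
    def test_matches_monte_carlo_decode_mse(self, theta, sigma, rng):
        # oracle: invert A = [[1, cos t], [0, sin t]] on noisy encodings
        A = np.array([[1.0, np.cos(theta)], [0.0, np.sin(theta)]])
        Ainv = np.linalg.inv(A)
        n = 200_000
        v = rng.standard_normal((n, 2))
        r = v @ A.T + rng.standard_normal((n, 2)) * sigma
        per_trial = ((r @ Ainv.T - v) ** 2).sum(axis=1)  # total sq err of the 2-vector
        mse = per_trial.mean()
        se = per_trial.std() / np.sqrt(n)
        expected = T.continuous_estimator_variance(theta, sigma)
        assert abs(mse - expected) < max(3 * se, 0.02 * expected)


class TestPowerBookkeeping:
    def test_nonlinear_power_round_trip(self):
        spec = StimulusSpec(2, 2)
        for dn in (0.0, 0.7, 2.0):
            p = T.nonlinear_power_from_distance(dn, spec)
            assert T.nonlinear_distance_from_power(p, spec) == pytest.approx(dn)

    def test_nonlinear_power_is_conjunctive_part_variance(self):
        # oracle: variance of one-hot columns of length m over the lattice
        spec = StimulusSpec(2, 2)
        m = 0.9
        M = np.eye(4) * m
        var = ((M - M.mean(axis=0)) ** 2).sum(axis=1).mean()
        assert T.nonlinear_power_from_distance(np.sqrt(2) * m, spec) == pytest.approx(
            var
        )
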