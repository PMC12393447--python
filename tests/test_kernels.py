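"""Kernel families: known values, reductions, PSD checks, serialization."""

import itertools
import math

import numpy as np
import pytest

import seqgp as sg
from seqgp.errors import ValidationError
from seqgp.kernels import krawtchouk_matrix, validate_psd

from conftest import random_kernel


class TestGeometricKernel:
    def test_self_covariance_is_sigma2(self):
        space = sg.SequenceSpace.uniform(4, "ACGT")
        k = sg.GeometricKernel(space, 2.5, 0.3)
        assert k.pair("AAAA", "AAAA") == pytest.approx(2.5)

    def test_zero_delta_constant_landscape(self):
        space = sg.SequenceSpace.uniform(3, 2)
        k = sg.GeometricKernel(space, 1.0, 0.0)
        K = k.matrix(space.enumerate_sequences())
        np.testing.assert_allclose(K, 1.0)

    def test_power_law_value(self):
        space = sg.SequenceSpace.uniform(3, "ACGT")
        k = sg.GeometricKernel(space, 2.0, 0.5)
        assert k.pair("AAA", "CGT") == pytest.approx(2.0 * 0.5**3)  # = 0.25

    def test_delta_above_one_needs_override(self):
        space = sg.SequenceSpace.uniform(2, 2)
        with pytest.raises(ValidationError):
            sg.GeometricKernel(space, 1.0, 1.5)
        sg.GeometricKernel(space, 1.0, 1.5, allow_extended=True)  # no raise


class TestConnectednessKernel:
    def test_gb1_site40_correlation(self, gb1_connectedness, gb1_space):
        x = "VDGV"
        x2 = gb1_space.mutate(x, "40", "A")
        assert gb1_connectedness.correlation(x, x2) == pytest.approx(0.92)

    def test_gb1_double_mutant_product(self, gb1_connectedness, gb1_space):
        x = "VDGV"
        x2 = gb1_space.mutate(gb1_space.mutate(x, "41", "A"), "54", "A")
        assert gb1_connectedness.pair(x, x2) == pytest.approx(0.46 * 0.62)

    def test_identical_sequences_give_sigma2(self, gb1_connectedness):
        assert gb1_connectedness.pair("VDGV", "VDGV") == pytest.approx(1.0)

    def test_wrong_delta_length_rejected(self):
        space = sg.SequenceSpace.uniform(3, 2)
        with pytest.raises(ValidationError):
            sg.ConnectednessKernel(space, 1.0, [0.5, 0.5])


class TestJengaKernel:
    def test_hoc_limit_is_scaled_identity(self):
        space = sg.SequenceSpace.uniform(2, 2)
        k = sg.hoc_kernel(space, sigma2=3.0)
        K = k.matrix(space.enumerate_sequences())
        np.testing.assert_allclose(K, 3.0 * np.eye(4), atol=1e-15)

    def test_single_site_geometric_mean(self):
        space = sg.SequenceSpace.uniform(1, 2)
        k = sg.JengaKernel(space, 1.0, [[0.19, 0.64]])
        assert k.pair("0", "1") == pytest.approx(math.sqrt(0.81 * 0.36))  # 0.54

    def test_delta_outside_unit_interval_rejected(self):
        space = sg.SequenceSpace.uniform(1, 2)
        with pytest.raises(ValidationError):
            sg.JengaKernel(space, 1.0, [[0.5, 1.2]])

    def test_wrong_allele_count_names_site(self):
        space = sg.SequenceSpace.uniform(2, "ACGT", site_labels=["-3", "+2"])
        with pytest.raises(ValidationError, match=r"\+2"):
            sg.JengaKernel(space, 1.0, [[0.1] * 4, [0.1] * 3])


class TestGeneralProductKernel:
    def test_double_mutant_product(self):
        space = sg.SequenceSpace.uniform(2, "AB")
        mats = [np.array([[0, 0.3], [0.3, 0]]), np.array([[0, 0.5], [0.5, 0]])]
        k = sg.GeneralProductKernel(space, 1.0, mats)
        assert k.pair("AA", "BB") == pytest.approx(0.7 * 0.5)

    def test_asymmetric_table_rejected(self):
        space = sg.SequenceSpace.uniform(1, "ABC")
        m = np.zeros((3, 3))
        m[0, 1] = 0.5
        with pytest.raises(ValidationError):
            sg.GeneralProductKernel(space, 1.0, [m])


class TestReductionChain:
    """geometric ⊂ connectedness ⊂ jenga ⊂ general_product, numerically exact."""

    @pytest.fixture
    def pairs(self, rng):
        space = sg.SequenceSpace.uniform(5, 4)
        seqs = space.enumerate_sequences()
        idx = rng.integers(0, len(seqs), size=(1000, 2))
        return space, [(seqs[i], seqs[j]) for i, j in idx]

    def test_geometric_equals_uniform_connectedness(self, pairs):
        space, pp = pairs
        g = sg.GeometricKernel(space, 1.7, 0.35)
        c = g.as_connectedness()
        for x, x2 in pp[:200]:
            assert g.pair(x, x2) == pytest.approx(c.pair(x, x2), abs=1e-12)

    def test_connectedness_equals_uniform_jenga(self, pairs, rng):
        space, pp = pairs
        c = sg.ConnectednessKernel(space, 1.3, rng.uniform(0, 0.9, 5))
        j = c.as_jenga()
        Kc = c.matrix([x for x, _ in pp], [x2 for _, x2 in pp])
        Kj = j.matrix([x for x, _ in pp], [x2 for _, x2 in pp])
        np.testing.assert_allclose(np.diag(Kc[: len(pp)]), np.diag(Kj[: len(pp)]), atol=1e-12)
        for (x, x2) in pp[:200]:
            assert c.pair(x, x2) == pytest.approx(j.pair(x, x2), abs=1e-12)

    def test_jenga_equals_consistent_general_product(self, pairs, rng):
        space, pp = pairs
        j = sg.JengaKernel(space, 0.9, [rng.uniform(0, 0.95, 4) for _ in range(5)])
        g = j.as_general_product()
        for (x, x2) in pp[:200]:
            assert j.pair(x, x2) == pytest.approx(g.pair(x, x2), abs=1e-12)


class TestKrawtchouk:
    @pytest.mark.parametrize("length,alpha", [(2, 2), (4, 4), (6, 20)])
    def test_normalization_at_zero(self, length, alpha):
        for k in range(length + 1):
            assert sg.krawtchouk(k, 0, length, alpha) == pytest.approx(1.0)

    def test_binary_first_order_is_linear(self):
        # l=2, alpha=2: W_1(d) = 1 - d
        assert [sg.krawtchouk(1, d, 2, 2) for d in range(3)] == [1.0, 0.0, -1.0]

    @pytest.mark.parametrize("length", [2, 4, 6])
    @pytest.mark.parametrize("alpha", [2, 4, 20])
    def test_orthogonality_under_distance_weights(self, length, alpha):
        W = krawtchouk_matrix(length, alpha)
        N = np.array(
            [math.comb(length, d) * (alpha - 1) ** d for d in range(length + 1)], float
        )
        G = (W * N[None, :]) @ W.T  # Gram matrix under the distance weights
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-6 * np.max(np.abs(np.diag(G)))


class TestVCKernel:
    def test_pure_additive_spectrum_is_linear_in_distance(self):
        space = sg.SequenceSpace.uniform(2, 2)
        k = sg.VCKernel(space, [0.0, 1.0, 0.0])
        np.testing.assert_allclose(
            k.covariance_at_distance(np.arange(3)), [1.0, 0.0, -1.0], atol=1e-12
        )

    def test_prior_variance_is_lambda_sum(self, rng):
        space = sg.SequenceSpace.uniform(4, "ACGT")
        lam = rng.uniform(0, 2, 5)
        k = sg.VCKernel(space, lam)
        assert k.pair("AAAA", "AAAA") == pytest.approx(lam.sum())

    @pytest.mark.parametrize("length", [2, 4, 8])
    def test_geometric_profile_representable(self, length):
        space = sg.SequenceSpace.uniform(length, 2)
        g = sg.GeometricKernel(space, 1.5, 0.4)
        kd = 1.5 * 0.6 ** np.arange(length + 1)
        vc = sg.VCKernel.from_distance_covariance(space, kd)
        np.testing.assert_allclose(
            vc.covariance_at_distance(np.arange(length + 1)), kd, atol=1e-10
        )

    def test_negative_lambda_rejected(self):
        space = sg.SequenceSpace.uniform(2, 2)
        with pytest.raises(ValidationError):
            sg.VCKernel(space, [0.0, -1.0, 0.0])


class TestKernelMatrix:
    def test_full_biallelic_matrix_by_distance(self):
        space = sg.SequenceSpace.uniform(2, 2)
        k = sg.ConnectednessKernel(space, 1.0, [0.5, 0.5])
        K = k.matrix(space.enumerate_sequences())
        seqs = space.enumerate_sequences()
        for i, j in itertools.product(range(4), repeat=2):
            d = sg.hamming_distance(seqs[i], seqs[j])
            assert K[i, j] == pytest.approx(0.5**d)

    def test_empty_query_gives_zero_columns(self, gb1_connectedness):
        K = gb1_connectedness.matrix(["VDGV"], [])
        assert K.shape == (1, 0)

    def test_diagonal_is_sigma2_and_symmetric(self, rng):
        space = sg.SequenceSpace.uniform(3, 3)
        for family in ("geometric", "connectedness", "jenga", "general_product", "vc"):
            k = random_kernel(space, family, rng)
            K = k.matrix(space.enumerate_sequences())
            np.testing.assert_allclose(np.diag(K), k.sigma2, atol=1e-12)
            np.testing.assert_allclose(K, K.T, atol=1e-12)


class TestSiteOrderEquivariance:
    def test_correlation_depends_only_on_factor_multiset(self, rng):
        """Permuting sites (with their parameters) leaves correlations invariant."""
        space = sg.SequenceSpace.uniform(4, 3)
        delta = rng.uniform(0, 0.9, 4)
        k = sg.ConnectednessKernel(space, 1.0, delta)
        perm = rng.permutation(4)
        k_perm = sg.ConnectednessKernel(space, 1.0, delta[perm])
        x, x2 = "0000", "1101"
        x_p = "".join(x[p] for p in perm)
        x2_p = "".join(x2[p] for p in perm)
        assert k.pair(x, x2) == pytest.approx(k_perm.pair(x_p, x2_p), abs=1e-12)


class TestMuDeltaConversion:
    @pytest.mark.parametrize("mu,alpha,expected", [(0.0, 4, 0.0), (1.0, 4, 1.0), (0.5, 4, 0.8)])
    def test_known_values(self, mu, alpha, expected):
        assert sg.mu_to_delta(mu, alpha) == pytest.approx(expected)

    def test_roundtrip(self, rng):
        mu = rng.uniform(0, 1, 20)
        for alpha in (2, 4, 20):
            np.testing.assert_allclose(
                sg.delta_to_mu(sg.mu_to_delta(mu, alpha), alpha), mu, atol=1e-12
            )

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValidationError):
            sg.mu_to_delta(0.5, 0.5)


class TestValidatePSD:
    def test_default_domain_passes_domain_check(self, rng):
        space = sg.SequenceSpace.uniform(3, 2)
        k = random_kernel(space, "connectedness", rng)
        assert validate_psd(k, "domain_check").passed

    def test_delta_above_one_can_still_be_psd(self):
        # l=1, alpha=2, delta=1.5: matrix [[1,-0.5],[-0.5,1]], eigenvalues {0.5, 1.5}
        space = sg.SequenceSpace.uniform(1, 2)
        k = sg.ConnectednessKernel(space, 1.0, [1.5], allow_extended=True)
        assert not validate_psd(k, "domain_check").passed
        report = validate_psd(k, "eigen_check")
        assert report.passed
        assert report.min_eig == pytest.approx(0.5)
        assert report.max_eig == pytest.approx(1.5)

    def test_delta_far_above_one_fails_eigen_check(self):
        space = sg.SequenceSpace.uniform(1, 2)
        k = sg.ConnectednessKernel(space, 1.0, [2.5], allow_extended=True)
        report = validate_psd(k, "eigen_check")
        assert not report.passed
        assert report.min_eig == pytest.approx(-0.5)

    def test_eigen_check_refuses_huge_spaces(self):
        space = sg.SequenceSpace.uniform(17, 2)
        k = sg.GeometricKernel(space, 1.0, 0.3)
        with pytest.raises(ValidationError):
            validate_psd(k, "eigen_check")

    @pytest.mark.parametrize("family", ["geometric", "connectedness", "jenga", "general_product", "vc"])
    def test_default_domain_kernels_pass_eigen_check(self, family, rng):
        """Randomized: every default-domain kernel is PSD on small full spaces."""
        for space in (sg.SequenceSpace.uniform(4, 2), sg.SequenceSpace.uniform(3, 4)):
            for _ in range(5):
                k = random_kernel(space, family, rng)
                assert validate_psd(k, "eigen_check").passed, (family, space.alphabet_sizes)


class TestSerialization:
    @pytest.mark.parametrize("family", ["geometric", "connectedness", "jenga", "general_product", "vc"])
    def test_json_roundtrip_bit_exact(self, family, rng):
        space = sg.SequenceSpace.uniform(3, "ACG", site_labels=["-1", "+1", "+2"])
        k = random_kernel(space, family, rng)
        k2 = sg.Kernel.from_json(k.to_json())
        seqs = space.enumerate_sequences()
        np.testing.assert_array_equal(k.matrix(seqs), k2.matrix(seqs))
        assert k2.space.site_labels == space.site_labels
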