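import numpy as np
import pytest

from cuelearn import (
    PCSpectrum,
    dof_count,
    generalized_variance,
    manipulative_complexity,
    pc_spectrum,
    session_vpe,
    trial_covariance,
    velocity_profile_error,
    vpe_block_variability,
)
from cuelearn.errors import InsufficientDataError, UndefinedMetricError
from conftest import bump_window


def cov_double_loop(window):
    """Textbook unbiased covariance, explicit double loop (oracle)."""
    w = np.asarray(window, float)
    n, c = w.shape
    means = w.mean(axis=0)
    out = np.zeros((c, c))
    for i in range(c):
        for j in range(c):
            out[i, j] = np.sum((w[:, i] - means[i]) * (w[:, j] - means[j])) / (n - 1)
    return out


class TestTrialCovariance:
    def test_identical_channels(self):
        col = np.arange(10.0)
        cov = trial_covariance(np.column_stack([col, col]))
        assert cov.shape == (2, 2)
        assert np.ptp(cov) == pytest.approx(0.0, abs=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        w = rng.normal(size=(40, 5))
        np.testing.assert_allclose(trial_covariance(w), cov_double_loop(w), atol=1e-12)

    def test_constant_offset_invariance(self, rng):
        w = rng.normal(size=(30, 4))
        w2 = w.copy()
        w2[:, 1] += 100.0
        np.testing.assert_allclose(trial_covariance(w), trial_covariance(w2), atol=1e-10)

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            trial_covariance(np.zeros((1, 3)))


class TestGeneralizedVariance:
    def test_identity(self):
        assert generalized_variance(np.eye(6)) == pytest.approx(1.0)

    def test_equals_eigenvalue_product(self, rng):
        # oracle: eigendecomposition product
        for d in (2, 4, 8, 12):
            a = rng.normal(size=(d, d))
            spd = a @ a.T + d * np.eye(d)
            gv = generalized_variance(spd)
            oracle = float(np.prod(np.linalg.eigvalsh(spd)))
            assert gv == pytest.approx(oracle, rel=1e-9)

    def test_scaling_law(self, rng):
        w = rng.normal(size=(50, 3))
        c = 2.5
        gv1 = generalized_variance(trial_covariance(w))
        gv2 = generalized_variance(trial_covariance(c * w))
        assert gv2 == pytest.approx(c ** (2 * 3) * gv1, rel=1e-9)

    def test_asymmetric_rejected(self):
        m = np.array([[1.0, 0.5], [0.0, 1.0]])
        with pytest.raises(UndefinedMetricError):
            generalized_variance(m)

    def test_tiny_negative_clipped(self):
        # singular covariance whose det may come out as a tiny negative number
        col = np.arange(8.0)
        w = np.column_stack([col, 2 * col, 3 * col])
        assert generalized_variance(trial_covariance(w)) >= 0.0


class TestPCSpectrum:
    def test_rank_one(self):
        col = np.arange(10.0)
        spec = pc_spectrum(np.column_stack([col, 2 * col, -col]))
        np.testing.assert_allclose(spec.variance_fractions[0], 1.0, atol=1e-12)
        np.testing.assert_allclose(spec.variance_fractions[1:], 0.0, atol=1e-12)

    def test_isotropic(self, rng):
        spec = pc_spectrum(rng.normal(size=(20000, 3)))
        assert np.all(spec.variance_fractions > 0.30)

    def test_constructed_eigenvalues(self):
        # orthogonal sign patterns give an exactly diagonal sample covariance;
        # variances scale as 4:1 -> fractions (0.8, 0.2) analytically
        c1 = 2.0 * np.array([1, -1, 1, -1, 1, -1, 1, -1], float)
        c2 = 1.0 * np.array([1, 1, -1, -1, 1, 1, -1, -1], float)
        spec = pc_spectrum(np.column_stack([c1, c2]))
        np.testing.assert_allclose(spec.variance_fractions, [0.8, 0.2], atol=1e-9)

    def test_sorted_and_normalized(self, rng):
        spec = pc_spectrum(rng.normal(size=(100, 6)))
        fr = spec.variance_fractions
        assert np.all(np.diff(fr) <= 1e-12)
        assert fr.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_flagged(self):
        with pytest.raises(UndefinedMetricError):
            pc_spectrum(np.ones((10, 3)))


class TestDofCount:
    def test_single_pc(self):
        assert dof_count(PCSpectrum(np.array([1.0, 0.0, 0.0]))) == 1

    def test_direct_count(self):
        spec = PCSpectrum(np.array([0.90, 0.05, 0.03, 0.011, 0.009]))
        assert dof_count(spec) == 4

    def test_threshold_monotonicity(self, rng):
        fr = rng.dirichlet(np.ones(8))
        spec = PCSpectrum(np.sort(fr)[::-1])
        counts = [dof_count(spec, th) for th in (0.001, 0.01, 0.05, 0.2)]
        assert counts == sorted(counts, reverse=True)


class TestManipulativeComplexity:
    @pytest.mark.parametrize("method", ["participation_ratio", "entropy"])
    def test_equal_spectrum_is_one(self, method):
        spec = PCSpectrum(np.full(6, 1 / 6))
        assert manipulative_complexity(spec, method) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("method", ["participation_ratio", "entropy"])
    def test_degenerate_spectrum_is_zero(self, method):
        spec = PCSpectrum(np.array([1.0, 0.0, 0.0, 0.0, 0.0, 0.0]))
        assert manipulative_complexity(spec, method) == pytest.approx(0.0, abs=1e-12)

    def test_half_half(self):
        # hand computation: PR = 1 / (0.25 + 0.25) = 2, C = (2-1)/(4-1) = 1/3
        spec = PCSpectrum(np.array([0.5, 0.5, 0.0, 0.0]))
        assert manipulative_complexity(spec) == pytest.approx(1 / 3, abs=1e-12)

    def test_amplitude_rescale_invariance(self, rng):
        w = bump_window(rng=rng, noise=0.05)
        s1 = pc_spectrum(w)
        s2 = pc_spectrum(10.0 * w)
        assert manipulative_complexity(s1) == pytest.approx(
            manipulative_complexity(s2), rel=1e-9
        )
        assert dof_count(s1) == dof_count(s2)

    def test_bounds(self, rng):
        for _ in range(20):
            fr = np.sort(rng.dirichlet(np.ones(6)))[::-1]
            c = manipulative_complexity(PCSpectrum(fr))
            assert 0.0 <= c <= 1.0 + 1e-12

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            manipulative_complexity(PCSpectrum(np.array([0.5, 0.5])), "bogus")

    def test_single_pc_undefined(self):
        with pytest.raises(UndefinedMetricError):
            manipulative_complexity(PCSpectrum(np.array([1.0])))


def vpe_brute_force(trial, library, exclude_index=None):
    """Naive double loop over channels and library trials (oracle)."""
    lib = [l for i, l in enumerate(library) if i != exclude_index]
    n_ch = trial.shape[1]
    out = np.full(n_ch, np.nan)
    for c in range(n_ch):
        p = trial[:, c]
        if np.std(p) == 0:
            continue
        dists = []
        for l in lib:
            q = l[:, c]
            if np.std(q) == 0:
                continue
            r = np.corrcoef(p, q)[0, 1]
            dists.append(1.0 - r)
        if dists:
            out[c] = min(dists)
    return out


class TestVelocityProfileError:
    def test_identical_profile_zero(self, rng):
        w = bump_window(rng=rng, noise=0.1)
        vpe = velocity_profile_error(w, [w.copy(), bump_window(rng=rng, noise=0.5)])
        np.testing.assert_allclose(vpe, 0.0, atol=1e-12)

    def test_negation_gives_two(self, rng):
        w = bump_window(rng=rng, noise=0.1)
        vpe = velocity_profile_error(w, [-w])
        np.testing.assert_allclose(vpe, 2.0, atol=1e-12)

    def test_matches_brute_force(self, rng):
        trial = rng.normal(size=(61, 7))
        library = [rng.normal(size=(61, 7)) for _ in range(5)]
        fast = velocity_profile_error(trial, library)
        slow = vpe_brute_force(trial, library)
        np.testing.assert_allclose(fast, slow, atol=1e-10)

    def test_exclusion(self, rng):
        trial = rng.normal(size=(20, 3))
        library = [trial, rng.normal(size=(20, 3))]
        with_self = velocity_profile_error(trial, library)
        without_self = velocity_profile_error(trial, library, exclude_index=0)
        np.testing.assert_allclose(with_self, 0.0, atol=1e-12)
        assert np.all(without_self > 0)

    def test_zero_variance_channel_nan(self, rng):
        trial = rng.normal(size=(20, 2))
        trial[:, 1] = 5.0
        vpe = velocity_profile_error(trial, [rng.normal(size=(20, 2))])
        assert np.isfinite(vpe[0])
        assert np.isnan(vpe[1])

    def test_empty_library(self, rng):
        with pytest.raises(UndefinedMetricError):
            velocity_profile_error(rng.normal(size=(20, 2)), [], exclude_index=None)

    def test_range(self, rng):
        for _ in range(10):
            vpe = velocity_profile_error(
                rng.normal(size=(30, 4)), [rng.normal(size=(30, 4)) for _ in range(3)]
            )
            assert np.all((vpe >= 0) & (vpe <= 2))


class TestSessionVPE:
    def test_successful_trial_excluded_from_self(self, rng):
        windows = [rng.normal(size=(30, 3)) for _ in range(6)]
        flags = [True, False, True, False, False, True]
        vpe = session_vpe(windows, flags, exclude_self=True)
        assert vpe.shape == (6, 3)
        assert np.all(vpe[0] > 0)  # not compared with itself
        vpe_lit = session_vpe(windows, flags, exclude_self=False)
        np.testing.assert_allclose(vpe_lit[0], 0.0, atol=1e-12)

    def test_no_successes(self, rng):
        with pytest.raises(UndefinedMetricError):
            session_vpe([rng.normal(size=(10, 2))], [False])


class TestVPEBlockVariability:
    def test_constant_zero_scale(self):
        vpes = np.full((10, 3), 0.4)
        np.testing.assert_allclose(vpe_block_variability(vpes), 0.0, atol=1e-12)

    def test_recovers_known_sd(self, rng):
        vpes = rng.normal(0.5, 0.1, size=(10_000, 2))
        scales = vpe_block_variability(vpes)
        np.testing.assert_allclose(scales, 0.1, atol=0.01)

    def test_permutation_invariance(self, rng):
        vpes = rng.uniform(0, 2, size=(25, 3))
        perm = rng.permutation(25)
        np.testing.assert_allclose(
            vpe_block_variability(vpes), vpe_block_variability(vpes[perm]), atol=1e-9
        )

    def test_small_block(self):
        with pytest.raises(InsufficientDataError):
            vpe_block_variability(np.zeros((3, 2)))
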