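"""PCA/Varimax loadings, SD profiling, wavelength picking and VIF screening."""

import numpy as np
import pytest
from statsmodels.stats.outliers_influence import variance_inflation_factor

from chlorospec.band_selection import (
    LoadingsMatrix,
    collinearity,
    pca_varimax,
    pick_wavelengths,
    sd_profile,
)
from chlorospec.errors import DecompositionError, GroupingError, InputError, SelectionError
from chlorospec.indices import FeatureTable
from chlorospec.synthetic import GeneratorConfig, SpectraSet, SpectrumRecord, simulate_spectrum


def two_block_data(n=300, p=40, seed=0):
    """Two independent latent factors, each driving one wavelength block."""
    rng = np.random.default_rng(seed)
    f1, f2 = rng.normal(size=(2, n))
    X = np.empty((n, p))
    X[:, : p // 2] = np.outer(f1, rng.uniform(0.7, 1.0, p // 2))
    X[:, p // 2 :] = np.outer(f2, rng.uniform(0.7, 1.0, p - p // 2))
    X += rng.normal(0, 0.05, X.shape)
    return X, np.arange(400.0, 400.0 + p)


class TestPcaVarimax:
    def test_two_block_structure_recovered(self):
        X, wl = two_block_data()
        lm = pca_varimax(X, wl, retain=2)
        half = X.shape[1] // 2
        for j in range(2):
            block_a = np.abs(lm.loadings[:half, j]).mean()
            block_b = np.abs(lm.loadings[half:, j]).mean()
            strong, weak = max(block_a, block_b), min(block_a, block_b)
            assert strong > 0.9 and weak < 0.2

    def test_rotation_preserves_communalities(self):
        X, wl = two_block_data(seed=3)
        unrotated = pca_varimax(X, wl, retain=1)
        rotated = pca_varimax(X, wl, retain=2)
        # per-row communalities equal the unrotated PCA's within 1e-8
        sd = X.std(axis=0, ddof=1)
        Z = (X - X.mean(axis=0)) / sd
        _, s, Vt = np.linalg.svd(Z, full_matrices=False)
        eig = s**2 / (X.shape[0] - 1)
        raw = Vt[:2].T * np.sqrt(eig[:2])
        np.testing.assert_allclose(
            rotated.communalities(), (raw**2).sum(axis=1), atol=1e-8
        )
        assert unrotated.components == 1

    def test_total_explained_variance_preserved(self):
        X, wl = two_block_data(seed=5)
        lm = pca_varimax(X, wl, retain=2)
        sd = X.std(axis=0, ddof=1)
        Z = (X - X.mean(axis=0)) / sd
        eig = np.linalg.svd(Z, compute_uv=False) ** 2 / (X.shape[0] - 1)
        assert lm.explained_variance.sum() == pytest.approx(eig[:2].sum(), rel=1e-8)

    def test_sample_order_invariance(self):
        X, wl = two_block_data(seed=9)
        perm = np.random.default_rng(1).permutation(X.shape[0])
        a = pca_varimax(X, wl, retain=2)
        b = pca_varimax(X[perm], wl, retain=2)
        np.testing.assert_allclose(a.loadings, b.loadings, atol=1e-8)

    def test_zero_variance_column_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 4))
        X[:, 2] = 1.0
        with pytest.raises(DecompositionError):
            pca_varimax(X, np.arange(4.0))

    def test_kaiser_retention_on_two_factor_data(self):
        X, wl = two_block_data()
        lm = pca_varimax(X, wl, retain="kaiser")
        assert lm.components == 2


class TestSdProfile:
    def test_identical_spectra_give_zero_profile(self):
        rec = simulate_spectrum(1500.0, 1.0, GeneratorConfig(noise_sd=0.0))
        clones = [
            SpectrumRecord(f"c{i}", rec.wavelengths, rec.reflectance, 1500.0) for i in range(4)
        ]
        prof = sd_profile(SpectraSet(clones), [(1000.0, 2000.0)])
        assert np.allclose(prof.relative_sd, 0.0)

    def test_profile_peak_near_red_absorption(self, default_dataset):
        prof = sd_profile(default_dataset, [(750.0, 1500.0), (750.0, 2500.0), (750.0, 3500.0)])
        assert abs(prof.peak_wavelength(-1) - 670.0) <= 15.0

    def test_wide_group_exceeds_narrow_group_at_670(self, default_dataset):
        prof = sd_profile(default_dataset, [(750.0, 1500.0), (750.0, 3500.0)])
        i670 = int(np.argmin(np.abs(prof.wavelengths - 670.0)))
        assert prof.relative_sd[i670, 1] > prof.relative_sd[i670, 0]

    def test_empty_group_rejected(self, default_dataset):
        with pytest.raises(GroupingError):
            sd_profile(default_dataset, [(10_000.0, 20_000.0)])


def gaussian_bump(wl, center, width):
    return np.exp(-(((wl - center) / width) ** 2))


class TestPickWavelengths:
    def make_loadings(self):
        wl = np.arange(400.0, 1001.0)
        curve = (
            0.5
            + 0.30 * gaussian_bump(wl, 516, 8)
            + 0.35 * gaussian_bump(wl, 551, 9)
            - 0.20 * gaussian_bump(wl, 763, 15)
        )
        return LoadingsMatrix(wl, curve[:, None], np.array([1.0]))

    def test_constructed_bumps_and_dip(self):
        picked = pick_wavelengths(self.make_loadings(), n_max=2, n_min=1)
        assert picked.maxima == [516.0, 551.0]
        assert picked.minima == [763.0]

    def test_single_interior_maximum(self):
        wl = np.arange(400.0, 1001.0)
        curve = 0.2 + 0.6 * gaussian_bump(wl, 700, 40)
        lm = LoadingsMatrix(wl, curve[:, None], np.array([1.0]))
        with pytest.raises(SelectionError):
            pick_wavelengths(lm, n_max=2, n_min=1)
        # requesting only what exists succeeds
        wl2 = np.arange(400.0, 1001.0)
        curve2 = curve - 0.3 * gaussian_bump(wl2, 900, 20)
        lm2 = LoadingsMatrix(wl2, curve2[:, None], np.array([1.0]))
        picked = pick_wavelengths(lm2, n_max=1, n_min=1)
        assert picked.maxima == [700.0]

    def test_too_many_requested_rejected(self):
        with pytest.raises(SelectionError):
            pick_wavelengths(self.make_loadings(), n_max=5, n_min=1)


class TestCollinearity:
    @staticmethod
    def exact_corr_pair(n=60, r=0.9, seed=0):
        rng = np.random.default_rng(seed)
        z = rng.normal(size=(n, 2))
        z -= z.mean(axis=0)
        # QR of centred columns: orthonormal and still zero-mean, so the
        # sample Pearson correlation of the constructed pair is exactly r
        q, _ = np.linalg.qr(z)
        x = q[:, 0]
        y = r * q[:, 0] + np.sqrt(1 - r * r) * q[:, 1]
        return x, y

    def test_two_feature_closed_form(self):
        x, y = self.exact_corr_pair()
        table = FeatureTable([f"s{i}" for i in range(60)], ["a", "b"], np.column_stack([x, y]))
        report = collinearity(table)
        expected = 1.0 / (1.0 - 0.81)
        np.testing.assert_allclose(report.vif, [expected, expected], atol=1e-6)
        assert report.flags.all()  # 5.263 exceeds the VIF threshold of 5

    def test_orthogonal_features_unit_vif(self):
        x, y = self.exact_corr_pair(r=0.0)
        table = FeatureTable([f"s{i}" for i in range(60)], ["a", "b"], np.column_stack([x, y]))
        report = collinearity(table)
        np.testing.assert_allclose(report.vif, [1.0, 1.0], atol=1e-9)
        assert not report.flags.any()

    def test_duplicate_feature_infinite_vif(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        z = rng.normal(size=50)
        table = FeatureTable(
            [f"s{i}" for i in range(50)], ["a", "dup", "c"], np.column_stack([x, x, z])
        )
        report = collinearity(table)
        assert np.isinf(report.vif[0]) and np.isinf(report.vif[1])
        assert report.flags[0] and report.flags[1]

    def test_tolerance_is_reciprocal_and_vif_at_least_one(self, default_table):
        report = collinearity(default_table)
        finite = np.isfinite(report.vif)
        np.testing.assert_allclose(
            report.vif[finite] * report.tolerance[finite], 1.0, atol=1e-9
        )
        assert (report.vif[finite] >= 1.0 - 1e-12).all()

    def test_matches_statsmodels_vif(self, default_table):
        report = collinearity(default_table)
        design = np.column_stack([np.ones(default_table.n_samples), default_table.values])
        for j in range(default_table.values.shape[1]):
            ref = variance_inflation_factor(design, j + 1)
            assert report.vif[j] == pytest.approx(ref, rel=1e-6)

    def test_too_few_samples_rejected(self):
        table = FeatureTable(["a", "b", "c"], ["f1", "f2"], np.random.default_rng(0).normal(size=(3, 2)))
        with pytest.raises(InputError):
            collinearity(table)
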