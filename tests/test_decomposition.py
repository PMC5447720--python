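"""PCA/ICA: subspace contracts, source recovery, and the frozen-model rule."""

import numpy as np
import pytest

from emgkin import EmgRecording, amari_index, fit_ica, fit_pca, project_pca, unmix
from emgkin.decomposition import (
    IcaModel,
    components_for_variance,
    load_model,
    model_checksum,
    save_model,
)
from util_sources import am_sources


def _emg(samples: np.ndarray) -> EmgRecording:
    return EmgRecording(samples, 1000.0)


class TestPca:
    def test_single_direction_gives_one_component(self, rng):
        direction = rng.standard_normal(8)
        data = np.outer(direction, rng.standard_normal(2000))
        model = fit_pca(_emg(data), 0.95)
        assert model.k == 1

    def test_equal_eigenvalues_require_all_components(self):
        assert components_for_variance(np.ones(8), 0.95) == 8

    def test_toy_spectrum_keeps_four_components(self):
        ev = np.array([5, 3, 1, 0.5, 0.25, 0.15, 0.07, 0.03])
        assert components_for_variance(ev, 0.95) == 4

    def test_projection_rows_orthonormal(self, rng):
        data = rng.standard_normal((8, 8)) @ rng.standard_normal((8, 5000))
        model = fit_pca(_emg(data), 1.0)
        np.testing.assert_allclose(
            model.projection @ model.projection.T, np.eye(model.k), atol=1e-8
        )

    def test_eigenvalue_sum_conserves_total_variance(self, rng):
        data = rng.standard_normal((8, 8)) @ rng.standard_normal((8, 5000))
        model = fit_pca(_emg(data), 0.95)
        total = np.var(data, axis=1, ddof=1).sum()
        assert model.eigenvalues.sum() == pytest.approx(total, rel=1e-6)

    def test_full_rank_reconstruction(self, rng):
        data = rng.standard_normal((8, 8)) @ rng.standard_normal((8, 3000))
        model = fit_pca(_emg(data), 1.0)
        centered = data - data.mean(axis=1, keepdims=True)
        recon = model.projection.T @ project_pca(model, _emg(data))
        assert np.linalg.norm(recon - centered) < 1e-6 * np.linalg.norm(centered)

    def test_projected_training_variances_equal_eigenvalues(self, rng):
        data = rng.standard_normal((8, 8)) @ rng.standard_normal((8, 5000))
        model = fit_pca(_emg(data), 0.95)
        comps = project_pca(model, _emg(data))
        np.testing.assert_allclose(
            np.var(comps, axis=1, ddof=1), model.eigenvalues[: model.k], rtol=1e-6
        )

    def test_zero_signal_projects_to_constant(self, rng):
        data = rng.standard_normal((8, 1000)) + 2.0
        model = fit_pca(_emg(data), 0.95)
        out = project_pca(model, _emg(np.zeros((8, 50))))
        expected = -model.projection @ model.channel_means
        np.testing.assert_allclose(out, np.tile(expected[:, None], (1, 50)), atol=1e-9)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="samples"):
            fit_pca(_emg(rng.standard_normal((8, 5))))

    def test_channel_mismatch_rejected(self, rng):
        model = fit_pca(_emg(rng.standard_normal((8, 100))))
        with pytest.raises(ValueError, match="channels"):
            project_pca(model, EmgRecording(np.zeros((4, 50))))

    def test_sklearn_pca_agrees(self, rng):
        sklearn = pytest.importorskip("sklearn.decomposition")
        data = rng.standard_normal((8, 8)) @ rng.standard_normal((8, 4000))
        model = fit_pca(_emg(data), 1.0)
        ref = sklearn.PCA().fit(data.T)
        np.testing.assert_allclose(
            model.eigenvalues, ref.explained_variance_, rtol=1e-8
        )
        np.testing.assert_allclose(
            np.abs(model.projection @ ref.components_.T), np.eye(8), atol=1e-6
        )


class TestIca:
    def test_known_2x2_mixing_recovered(self, rng):
        sources = rng.uniform(-1, 1, size=(2, 20000))
        mixing = np.array([[1.0, 0.6], [0.4, 1.0]])
        mixed = mixing @ sources
        pca = fit_pca(_emg(mixed), 1.0)
        model = fit_ica(pca, project_pca(pca, _emg(mixed)), seed=0)
        assert model.converged
        assert amari_index(model.channel_space_unmixing @ mixing) < 0.05

    def test_independent_white_sources_identity_mixing(self, rng):
        sources = rng.uniform(-1, 1, size=(2, 20000))
        pca = fit_pca(_emg(sources), 1.0)
        model = fit_ica(pca, project_pca(pca, _emg(sources)), seed=1)
        assert amari_index(model.channel_space_unmixing @ np.eye(2)) < 0.05

    def test_gaussian_sources_flagged_non_identifiable(self, rng):
        sources = rng.standard_normal((2, 20000))
        pca = fit_pca(_emg(sources), 1.0)
        with pytest.warns(RuntimeWarning):
            model = fit_ica(pca, project_pca(pca, _emg(sources)), seed=0)
        assert not model.identifiable

    def test_super_gaussian_sources_flagged_identifiable(self, rng):
        sources = am_sources(2, 20000, 1000.0, rng)
        mixed = np.array([[1.0, 0.4], [0.3, 1.0]]) @ sources
        pca = fit_pca(_emg(mixed), 1.0)
        model = fit_ica(pca, project_pca(pca, _emg(mixed)), seed=0)
        assert model.identifiable

    def test_recovered_components_nearly_uncorrelated(self, rng):
        sources = am_sources(3, 30000, 1000.0, rng)
        mixing = np.array(
            [[1.0, 0.3, 0.1], [0.2, 1.0, 0.3], [0.1, 0.2, 1.0], [0.4, 0.1, 0.9]]
        )
        mixed = mixing @ sources + 0.01 * rng.standard_normal((4, 30000))
        pca = fit_pca(_emg(mixed), 0.99)
        model = fit_ica(pca, project_pca(pca, _emg(mixed)), seed=2)
        ics = unmix(model, _emg(mixed))
        corr = np.corrcoef(ics)
        off = corr - np.diag(np.diag(corr))
        assert np.max(np.abs(off)) < 0.1

    def test_identity_unmixing_equals_whitened_components(self, rng):
        data = rng.standard_normal((4, 4)) @ rng.standard_normal((4, 3000))
        pca = fit_pca(_emg(data), 1.0)
        model = IcaModel(
            pca, np.eye(pca.k), np.arange(pca.k), np.ones(pca.k), True, 0, 0
        )
        whitened = project_pca(pca, _emg(data)) / np.sqrt(pca.eigenvalues[: pca.k])[:, None]
        np.testing.assert_allclose(unmix(model, _emg(data)), whitened, atol=1e-12)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_unmix_scales_linearly(self, rng):
        data = rng.standard_normal((4, 4)) @ rng.standard_normal((4, 3000))
        pca = fit_pca(_emg(data), 1.0)
        model = fit_ica(pca, project_pca(pca, _emg(data)), max_iter=50, seed=0)
        base = unmix(model, _emg(np.zeros((4, 10))))
        doubled = unmix(model, _emg(data[:, :10] * 2))
        single = unmix(model, _emg(data[:, :10]))
        np.testing.assert_allclose(doubled - base, 2 * (single - base), rtol=1e-9)

    def test_same_seed_reproducible(self, rng):
        sources = am_sources(2, 10000, 1000.0, rng)
        mixed = np.array([[1.0, 0.5], [0.3, 1.0]]) @ sources
        pca = fit_pca(_emg(mixed), 1.0)
        a = fit_ica(pca, project_pca(pca, _emg(mixed)), seed=7)
        b = fit_ica(pca, project_pca(pca, _emg(mixed)), seed=7)
        np.testing.assert_array_equal(a.unmixing, b.unmixing)

    def test_sklearn_fastica_agrees_on_recovery(self, rng):
        decomposition = pytest.importorskip("sklearn.decomposition")
        sources = am_sources(3, 30000, 1000.0, rng)
        mixing = np.array(
            [[1.0, 0.3, 0.1], [0.2, 1.0, 0.3], [0.1, 0.2, 1.0]]
        )
        mixed = mixing @ sources
        pca = fit_pca(_emg(mixed), 1.0)
        ours = fit_ica(pca, project_pca(pca, _emg(mixed)), seed=0)
        ref = decomposition.FastICA(
            n_components=3, fun="logcosh", whiten="unit-variance", random_state=0
        ).fit(mixed.T)
        ref_unmix = ref.components_
        assert amari_index(ours.channel_space_unmixing @ mixing) < 0.1
        assert amari_index(ref_unmix @ mixing) < 0.1


class TestAmariIndex:
    def test_identity_is_zero(self):
        assert amari_index(np.eye(4)) == 0.0

    def test_scaled_permutation_is_zero(self):
        p = np.array([[0, 3.0, 0], [0, 0, -0.5], [2.0, 0, 0]])
        assert amari_index(p) == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_worst_case(self):
        assert amari_index(np.ones((2, 2))) == pytest.approx(2.0)

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            amari_index(np.array([[1.0, 1.0], [0.0, 0.0]]))


class TestFrozenModels:
    def test_test_time_calls_leave_models_unchanged(self, rng):
        train = rng.standard_normal((8, 8)) @ rng.standard_normal((8, 5000))
        test = rng.standard_normal((8, 1000))
        pca = fit_pca(_emg(train), 0.95)
        ica = fit_ica(pca, project_pca(pca, _emg(train)), seed=0)
        before_pca, before_ica = model_checksum(pca), model_checksum(ica)
        project_pca(pca, _emg(test))
        unmix(ica, _emg(test))
        assert model_checksum(pca) == before_pca
        assert model_checksum(ica) == before_ica

    def test_model_serialization_round_trip(self, rng, tmp_path):
        train = rng.standard_normal((8, 8)) @ rng.standard_normal((8, 3000))
        pca = fit_pca(_emg(train), 0.95)
        ica = fit_ica(pca, project_pca(pca, _emg(train)), seed=0)
        save_model(ica, tmp_path / "ica.json")
        loaded = load_model(tmp_path / "ica.json")
        assert model_checksum(loaded) == model_checksum(ica)
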