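"""Integrated gradients axioms, consensus maps, latent features, PCA/UMAP."""

import numpy as np
import pandas as pd
import pytest

from aplsmear.interpret import (LatentFeatures, consensus_attribution, embed_latent,
                                extract_latent_features, integrated_gradients,
                                rank_most_predictive_cells)
from aplsmear.models import build_cell_classifier
from aplsmear.training import EvaluationReport


class _LinearSurrogate:
    """F(x) = w . x as a stand-in model: IG has the closed form w * (x - b)."""

    def __init__(self, w):
        self.w = w

    def delta_p(self, x):
        return np.tensordot(np.asarray(x, dtype=np.float64), self.w, axes=3)

    def delta_grad(self, x):
        return np.broadcast_to(self.w, np.asarray(x).shape).astype(np.float64)


def _report(scores):
    rows = [{"rep_id": 0, "patient_id": p, "path": f"{p}/c.png", "cell_type": "blast",
             "label": 1, "score": s} for p, s in scores.items()]
    df = pd.DataFrame(rows)
    return EvaluationReport(per_cell=df, per_sample=pd.DataFrame(), auc_cell=0.5,
                            auc_sample=0.5, baseline_auc_promyelocyte=0.5,
                            auc_by_cellcount_bin=pd.DataFrame())


class TestIntegratedGradients:
    def test_zero_displacement_gives_zero_map(self, tiny_arch, rng):
        net = build_cell_classifier(tiny_arch, seed=0)
        img = rng.random((48, 48, 3))
        m = integrated_gradients(net, img, steps=10, baseline=img.copy())
        np.testing.assert_allclose(m.values, 0.0, atol=1e-12)

    def test_linear_surrogate_closed_form(self, rng):
        w = rng.normal(size=(20, 20, 3))
        img = rng.random((20, 20, 3))
        base = rng.random((20, 20, 3))
        m = integrated_gradients(_LinearSurrogate(w), img, steps=50, baseline=base)
        np.testing.assert_allclose(m.values, (w * (img - base)).sum(axis=2), atol=1e-4)

    def test_completeness_error_shrinks_with_steps(self, tiny_arch, rng):
        """Attribution sum approaches dP(image) - dP(baseline); the left-Riemann
        error roughly halves as the step count doubles."""
        net = build_cell_classifier(tiny_arch, seed=1)
        img = rng.random((48, 48, 3))
        base = rng.random((48, 48, 3)) * 0.2
        target = (net.delta_p(img[None].astype(np.float32))[0]
                  - net.delta_p(base[None].astype(np.float32))[0])
        errs = []
        for steps in (25, 50, 100):
            m = integrated_gradients(net, img, steps=steps, baseline=base)
            errs.append(abs(m.values.sum() - target))
        assert errs[2] < errs[0]
        assert errs[2] < max(0.6 * errs[0], 1e-4)

    def test_steps_validation(self, tiny_arch, rng):
        net = build_cell_classifier(tiny_arch, seed=0)
        with pytest.raises(ValueError, match="steps"):
            integrated_gradients(net, rng.random((48, 48, 3)), steps=1)


class TestConsensus:
    def _tiny_ensemble(self, tiny_arch, n=4, identical=False):
        from aplsmear.training import EnsembleModel, MonteCarloConfig
        nets = [build_cell_classifier(tiny_arch, seed=0 if identical else i)
                for i in range(n)]
        return EnsembleModel(models=nets, splits=[], mode="cell", cell_scope="all_cells",
                             arch=tiny_arch, config=MonteCarloConfig(image_size=48))

    def test_single_model_consensus_equals_single_map(self, tiny_arch, rng):
        ens = self._tiny_ensemble(tiny_arch)
        img = rng.random((48, 48, 3))
        c = consensus_attribution(ens, img, n_models=1, seed=0, steps=10)
        singles = [integrated_gradients(m, img, steps=10).values for m in ens.models]
        assert any(np.allclose(c.values, s) for s in singles)

    def test_identical_models_consensus(self, tiny_arch, rng):
        ens = self._tiny_ensemble(tiny_arch, identical=True)
        img = rng.random((48, 48, 3))
        c = consensus_attribution(ens, img, n_models=3, seed=1, steps=10)
        np.testing.assert_allclose(
            c.values, integrated_gradients(ens.models[0], img, steps=10).values, atol=1e-10)

    def test_seeded_subset_reproducible(self, tiny_arch, rng):
        ens = self._tiny_ensemble(tiny_arch)
        img = rng.random((48, 48, 3))
        a = consensus_attribution(ens, img, n_models=2, seed=5, steps=10)
        b = consensus_attribution(ens, img, n_models=2, seed=5, steps=10)
        np.testing.assert_array_equal(a.values, b.values)

    def test_subset_larger_than_ensemble_rejected(self, tiny_arch, rng):
        ens = self._tiny_ensemble(tiny_arch)
        with pytest.raises(ValueError, match="exceeds"):
            consensus_attribution(ens, rng.random((48, 48, 3)), n_models=9)


class TestRankCells:
    def test_top_and_bottom(self):
        rep = _report({"a": 0.9, "b": 0.1, "c": 0.5})
        apl, non = rank_most_predictive_cells(rep, 1)
        assert apl["patient_id"].tolist() == ["a"]
        assert non["patient_id"].tolist() == ["b"]

    def test_k_zero(self):
        apl, non = rank_most_predictive_cells(_report({"a": 0.9}), 0)
        assert len(apl) == len(non) == 0

    def test_tie_break_lexicographic(self):
        rep = _report({"b": 0.5, "a": 0.5, "c": 0.5})
        apl, _ = rank_most_predictive_cells(rep, 3)
        assert apl["patient_id"].tolist() == ["a", "b", "c"]

    def test_k_truncated_with_warning(self):
        with pytest.warns(UserWarning, match="truncating"):
            apl, _ = rank_most_predictive_cells(_report({"a": 0.9}), 5)
        assert len(apl) == 1


class TestLatent:
    def _mil_ensemble(self, tiny_arch, n_models):
        from aplsmear.models import MILClassifier
        from aplsmear.training import EnsembleModel, MonteCarloConfig
        models = [MILClassifier(build_cell_classifier(tiny_arch, seed=i))
                  for i in range(n_models)]
        return EnsembleModel(models=models, splits=[], mode="mil", cell_scope="all_cells",
                             arch=tiny_arch, config=MonteCarloConfig(image_size=48))

    def test_single_model_dim_68(self, tiny_arch, rng):
        ens = self._mil_ensemble(tiny_arch, 1)
        f = extract_latent_features(ens, rng.random((3, 48, 48, 3)).astype(np.float32))
        assert f.matrix.shape == (3, 68)
        assert f.per_model_dim == 68

    def test_members_concatenate(self, tiny_arch, rng):
        ens = self._mil_ensemble(tiny_arch, 3)
        f = extract_latent_features(ens, rng.random((2, 48, 48, 3)).astype(np.float32))
        assert f.matrix.shape == (2, 204)

    def test_duplicate_models_duplicate_blocks(self, tiny_arch, rng):
        ens = self._mil_ensemble(tiny_arch, 2)
        ens.models[1] = ens.models[0]
        f = extract_latent_features(ens, rng.random((2, 48, 48, 3)).astype(np.float32))
        np.testing.assert_array_equal(f.matrix[:, :68], f.matrix[:, 68:])

    def test_cell_mode_ensemble_rejected(self, tiny_arch, rng):
        from aplsmear.training import EnsembleModel, MonteCarloConfig
        ens = EnsembleModel(models=[build_cell_classifier(tiny_arch, seed=0)], splits=[],
                            mode="cell", cell_scope="all_cells", arch=tiny_arch,
                            config=MonteCarloConfig())
        with pytest.raises(ValueError, match="MIL"):
            extract_latent_features(ens, rng.random((1, 48, 48, 3)).astype(np.float32))


class TestEmbedding:
    def test_rank2_features_keep_two_components(self, rng):
        """Eigen-spectrum oracle: data in a 2-D affine subspace plus tiny
        noise needs exactly 2 principal components for 99% variance."""
        n = 80
        basis = rng.normal(size=(2, 10))
        coords = rng.normal(size=(n, 2)) @ basis + 5.0
        noisy = coords + 1e-6 * rng.normal(size=coords.shape)
        feats = LatentFeatures(matrix=noisy, per_model_dim=10, n_models=1)
        emb = embed_latent(feats, seed=0)
        assert emb.pca_dims_kept == 2
        assert emb.explained_variance_kept >= 0.99

    def test_explained_variance_always_at_least_99(self, rng):
        feats = LatentFeatures(matrix=rng.normal(size=(40, 15)), per_model_dim=15,
                               n_models=1)
        emb = embed_latent(feats, seed=1)
        assert emb.explained_variance_kept >= 0.99

    def test_seeded_embedding_bit_reproducible(self, rng):
        x = rng.normal(size=(50, 12))
        feats = LatentFeatures(matrix=x, per_model_dim=12, n_models=1)
        labels = np.array([0, 1] * 25)
        a = embed_latent(feats, labels=labels, seed=3)
        b = embed_latent(feats, labels=labels, seed=3)
        np.testing.assert_array_equal(a.coords, b.coords)
        assert a.pca_dims_kept == b.pca_dims_kept

    def test_density_grids_per_class(self, rng):
        x = np.vstack([rng.normal(0, 1, size=(30, 6)), rng.normal(4, 1, size=(30, 6))])
        feats = LatentFeatures(matrix=x, per_model_dim=6, n_models=1)
        labels = np.array([0] * 30 + [1] * 30)
        emb = embed_latent(feats, labels=labels, seed=0)
        assert set(emb.density_by_class) == {0, 1}
        gx, gy, dens = emb.density_by_class[0]
        assert dens.shape == gx.shape

    def test_too_few_cells_rejected(self):
        feats = LatentFeatures(matrix=np.zeros((2, 5)), per_model_dim=5, n_models=1)
        with pytest.raises(ValueError, match="at least 3"):
            embed_latent(feats, seed=0)
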