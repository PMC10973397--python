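"""Generative core: distance expansion, invariant embedding, losses."""

import numpy as np
import pytest

from pocketforge.complex_io import featurize
from pocketforge.errors import AlignmentError, EncoderError
from pocketforge.fixtures import Motif, MotifSpec, make_probe_complex
from pocketforge.model import (
    DistanceGrid,
    GenerativeModel,
    ModelConfig,
    PosteriorParams,
    build_ligand_nodes,
    distance_kl,
    distance_loss,
    gaussian_expand,
    pocket_neighbors,
    regularization_loss,
    total_loss,
    type_loss,
)
from pocketforge.nn import Tensor
from tests.conftest import rigid_transform

GRID = DistanceGrid(0.0, 5.0, 25)


class TestGaussianExpand:
    def test_bin_center_is_argmax(self):
        center = GRID.centers[7]
        assert gaussian_expand(center, GRID).argmax() == 7

    @pytest.mark.parametrize("d", [0.0, 1.234, 3.7, 5.0])
    def test_normalized(self, d):
        assert gaussian_expand(d, GRID).sum() == pytest.approx(1.0)

    def test_small_sigma_approaches_one_hot(self):
        sharp = DistanceGrid(0.0, 5.0, 25, sigma=1e-4)
        w = gaussian_expand(GRID.centers[3], sharp)
        assert w[3] == pytest.approx(1.0)

    def test_beyond_grid_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamp"):
            w = gaussian_expand(7.5, GRID)
        assert w.argmax() == GRID.n_bins - 1

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            gaussian_expand(-0.1, GRID)


def _complex_inputs(seed=0, motif=Motif.HBOND):
    pocket, ligand, _ = make_probe_complex(MotifSpec(motif, seed=seed))
    config = ModelConfig.toy()
    prot_feats = featurize(pocket).matrix[:, :-7]
    com = ligand.coords.mean(axis=0)
    feats, coords = build_ligand_nodes(
        ligand.elements, ligand.coords, com, ligand.coords[0], config)
    from pocketforge.profiler import (
        condition_from_interactions,
        detect_interactions,
    )

    cond = condition_from_interactions(
        pocket, detect_interactions(pocket, ligand))
    return config, pocket, ligand, prot_feats, feats, coords, cond


class TestEmbedding:
    def test_rigid_motion_leaves_hidden_states_unchanged(self):
        config, pocket, ligand, prot, feats, coords, cond = _complex_inputs()
        model = GenerativeModel(config)
        base = model.embed_complex(feats, coords, prot, pocket.coords, cond)
        apply = rigid_transform(42)
        moved = model.embed_complex(
            feats, apply(coords), prot, apply(pocket.coords), cond)
        np.testing.assert_allclose(
            moved.h_ligand.data, base.h_ligand.data, atol=1e-5)
        np.testing.assert_allclose(
            moved.h_pocket.data, base.h_pocket.data, atol=1e-5)

    def test_condition_changes_pocket_embedding(self):
        config, pocket, ligand, prot, feats, coords, cond = _complex_inputs()
        model = GenerativeModel(config)
        ref = model.embed_complex(feats, coords, prot, pocket.coords, cond)
        masked = model.embed_complex(
            feats, coords, prot, pocket.coords, np.zeros_like(cond))
        assert not np.allclose(ref.h_pocket.data, masked.h_pocket.data)

    def test_misaligned_condition_rejected(self):
        config, pocket, ligand, prot, feats, coords, cond = _complex_inputs()
        model = GenerativeModel(config)
        with pytest.raises(AlignmentError):
            model.embed_complex(feats, coords, prot, pocket.coords, cond[:-1])

    def test_single_node_no_edges_is_finite(self):
        config = ModelConfig.toy()
        model = GenerativeModel(config)
        feats, coords = build_ligand_nodes(
            ["C"], np.zeros((1, 3)), np.zeros(3), np.zeros(3), config)
        prot = np.zeros((1, 12))
        prot[0, 0] = 1.0
        hidden = model.embed_complex(
            feats, coords, prot, np.array([[100.0, 0, 0]]),
            np.zeros((1, 7)))
        assert np.isfinite(hidden.h_ligand.data).all()
        assert np.isfinite(hidden.h_pocket.data).all()

    def test_pocket_permutation_consistency(self):
        config, pocket, ligand, prot, feats, coords, cond = _complex_inputs()
        model = GenerativeModel(config)
        base = model.embed_complex(feats, coords, prot, pocket.coords, cond)
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(pocket))
        permuted = model.embed_complex(
            feats, coords, prot[perm], pocket.coords[perm], cond[perm])
        np.testing.assert_allclose(
            permuted.h_pocket.data, base.h_pocket.data[perm], atol=1e-8)
        np.testing.assert_allclose(
            permuted.h_ligand.data, base.h_ligand.data, atol=1e-8)


class TestEncoder:
    def test_deterministic_and_rotation_invariant(self):
        config, pocket, ligand, prot, feats, coords, cond = _complex_inputs()
        model = GenerativeModel(config)
        args = (feats[:-2], coords[:-2], prot, pocket.coords, cond)
        a = model.encode_posterior(*args)
        b = model.encode_posterior(*args)
        np.testing.assert_array_equal(a.mean.data, b.mean.data)
        apply = rigid_transform(9)
        c = model.encode_posterior(
            feats[:-2], apply(coords[:-2]), prot, apply(pocket.coords), cond)
        np.testing.assert_allclose(c.mean.data, a.mean.data, atol=1e-5)
        np.testing.assert_allclose(c.log_var.data, a.log_var.data, atol=1e-5)

    def test_empty_ligand_rejected(self):
        config, pocket, ligand, prot, feats, coords, cond = _complex_inputs()
        model = GenerativeModel(config)
        with pytest.raises(EncoderError):
            model.encode_posterior(
                np.zeros((0, feats.shape[1])), np.zeros((0, 3)),
                prot, pocket.coords, cond)

    def test_reparameterized_sample_reproducible_under_seed(self):
        config, pocket, ligand, prot, feats, coords, cond = _complex_inputs()
        model = GenerativeModel(config)
        post = model.encode_posterior(
            feats[:-2], coords[:-2], prot, pocket.coords, cond)
        z1 = model.sample_latent(post, np.random.default_rng(3))
        z2 = model.sample_latent(post, np.random.default_rng(3))
        np.testing.assert_array_equal(z1.data, z2.data)


class TestPredictionHeads:
    def _setup(self):
        config, pocket, ligand, prot, feats, coords, cond = _complex_inputs()
        model = GenerativeModel(config)
        hidden = model.embed_complex(feats, coords, prot, pocket.coords, cond)
        nidx = pocket_neighbors(coords[-1], pocket.coords, config.k_neighbors)
        z = Tensor(np.zeros(config.latent_dim), requires_grad=False)
        return config, model, hidden, nidx, z

    def test_type_distributions_normalize(self):
        config, model, hidden, nidx, z = self._setup()
        lp_l, lp_p = model.predict_type(hidden, z, nidx)
        np.testing.assert_allclose(
            np.exp(lp_l.data).sum(axis=-1), 1.0, atol=1e-6)
        np.testing.assert_allclose(
            np.exp(lp_p.data).sum(axis=-1), 1.0, atol=1e-6)

    def test_small_pocket_uses_all_atoms(self):
        config, model, hidden, nidx, z = self._setup()
        assert len(nidx) == min(config.k_neighbors, hidden.h_pocket.shape[0])

    def test_distance_distributions_normalize_and_react_to_type(self):
        config, model, hidden, nidx, z = self._setup()
        carbon = config.type_onehot("C")
        oxygen = config.type_onehot("O")
        dp_c, _ = model.predict_distance(carbon, hidden, z, nidx)
        dp_o, _ = model.predict_distance(oxygen, hidden, z, nidx)
        np.testing.assert_allclose(
            np.exp(dp_c.data).sum(axis=-1), 1.0, atol=1e-6)
        assert not np.allclose(dp_c.data, dp_o.data)

    def test_stop_type_rejected_for_distances(self):
        config, model, hidden, nidx, z = self._setup()
        with pytest.raises(ValueError):
            model.predict_distance(config.stop_onehot(), hidden, z, nidx)


class TestLosses:
    def test_type_loss_zero_at_perfect_prediction(self):
        truth = np.zeros(10)
        truth[2] = 1.0
        logp = np.full((4, 10), -1e9)
        logp[:, 2] = 0.0
        loss = type_loss(Tensor(logp), Tensor(logp[:2]), truth)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-9)

    def test_type_loss_uniform_is_log_v(self):
        V = 10
        truth = np.zeros(V)
        truth[0] = 1.0
        logp = np.full((3, V), -np.log(V))
        loss = type_loss(Tensor(logp), Tensor(logp), truth)
        # one ligand-anchor mean + one pocket-anchor mean
        assert float(loss.data) == pytest.approx(2 * np.log(V))

    def test_type_loss_requires_one_hot(self):
        with pytest.raises(ValueError):
            type_loss(Tensor(np.zeros((1, 3))), Tensor(np.zeros((1, 3))),
                      np.array([0.5, 0.5, 0.0]))

    def test_distance_kl_zero_at_equality(self):
        q = gaussian_expand(2.0, GRID)
        loss = distance_kl(Tensor(np.log(q)[None, :]), q[None, :])
        assert float(loss.data) == pytest.approx(0.0, abs=1e-6)

    def test_distance_kl_two_bin_hand_value(self):
        p = np.array([[0.5, 0.5]])
        q = np.array([[0.9, 0.1]])
        loss = distance_kl(Tensor(np.log(p)), q)
        expected = 0.5 * np.log(0.5 / 0.9) + 0.5 * np.log(0.5 / 0.1)
        assert float(loss.data) == pytest.approx(expected, abs=1e-12)
        assert float(loss.data) == pytest.approx(0.5108, abs=1e-4)

    def test_distance_kl_nonnegative(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.dirichlet(np.ones(8))
            q = rng.dirichlet(np.ones(8))
            loss = distance_kl(Tensor(np.log(p)[None, :]), q[None, :])
            assert float(loss.data) >= -1e-12

    def test_distance_loss_sums_both_anchor_sets(self):
        q = gaussian_expand(1.5, GRID)[None, :]
        p_log = Tensor(np.log(np.maximum(q, 1e-300)))
        loss = distance_loss(p_log, q, p_log, q)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-6)

    def test_regularizer_closed_form(self):
        z = 6
        standard = PosteriorParams(Tensor(np.zeros(z)), Tensor(np.zeros(z)))
        assert float(regularization_loss(standard).data) == pytest.approx(0.0)
        mu = np.array([1.0, -2.0, 0.5, 0.0, 3.0, 1.5])
        shifted = PosteriorParams(Tensor(mu), Tensor(np.zeros(6)))
        assert float(regularization_loss(shifted).data) == pytest.approx(
            0.5 * np.sum(mu ** 2))

    def test_total_loss_beta_zero_is_reconstruction(self):
        recon = Tensor(np.array(3.7))
        posterior = PosteriorParams(Tensor(np.ones(4)), Tensor(np.zeros(4)))
        assert float(total_loss(recon, posterior, 0.0).data) == pytest.approx(3.7)
        assert float(total_loss(recon, posterior, 1.0).data) == pytest.approx(
            3.7 + 2.0)


class TestCheckpoint:
    def test_roundtrip_and_hash_guard(self, tmp_path):
        config = ModelConfig.toy(seed=3)
        model = GenerativeModel(config)
        path = tmp_path / "model.npz"
        model.save_checkpoint(str(path))
        loaded = GenerativeModel.load_checkpoint(str(path))
        for name, param in model.named_parameters().items():
            np.testing.assert_array_equal(
                loaded.named_parameters()[name].data, param.data)
        # corrupt the stored hash: loading must refuse
        data = dict(np.load(path))
        data["__config_hash__"] = np.frombuffer(b"0" * 64, dtype=np.uint8)
        np.savez(path, **data)
        with pytest.raises(ValueError, match="hash"):
            GenerativeModel.load_checkpoint(str(path))
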