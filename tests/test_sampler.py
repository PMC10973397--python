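"""Generation-time contracts: λ schedule, shells, clashes, termination."""

import numpy as np
import pytest

from pocketforge.complex_io import Atom3D, LigandMolecule
from pocketforge.fixtures import (
    Motif,
    MotifSpec,
    make_conditioning_pair,
    make_probe_complex,
)
from pocketforge.model import GenerativeModel, ModelConfig
from pocketforge.profiler import (
    assign_condition_reference_free,
    condition_from_interactions,
    detect_interactions,
)
from pocketforge.sampler import (
    SamplerConfig,
    generate,
    initialize_state,
    perceive_bonds,
    pocket_coefficient,
    sample_position,
    step,
)
from pocketforge.nn import Tensor
from tests.conftest import rigid_transform, transform_ligand, transform_pocket


@pytest.fixture(scope="module")
def hbond_setup():
    pocket, ligand, _ = make_probe_complex(MotifSpec(Motif.HBOND, seed=2))
    cond = condition_from_interactions(
        pocket, detect_interactions(pocket, ligand))
    config = ModelConfig.toy()
    model = GenerativeModel(config)  # untrained weights: contracts only
    return pocket, ligand, cond, config, model


class TestPocketCoefficient:
    @pytest.mark.parametrize(
        "distance, expected",
        [(2.0, 1.0), (4.0, 1.0), (6.0, 0.5), (8.0, 0.0), (11.0, 0.0)],
    )
    def test_linear_interpolation(self, hbond_setup, distance, expected):
        pocket, ligand, cond, config, model = hbond_setup
        sampler_cfg = SamplerConfig(noise_translation_sigma=0.0,
                                    noise_rotation_sigma_deg=0.0)
        # place the start so the nearest pocket atom sits at `distance`
        nearest = pocket.coords[
            np.argmin(np.linalg.norm(pocket.coords - pocket.coords.mean(0),
                                     axis=1))]
        direction = pocket.coords.mean(0) - nearest
        direction = direction / np.linalg.norm(direction)
        # move along the outward normal instead: robust choice of point
        probe = nearest - direction * distance
        state = initialize_state(pocket, cond, probe, None, sampler_cfg,
                                 np.random.default_rng(0))
        d_actual = np.linalg.norm(pocket.coords - state.anchor_pos,
                                  axis=1).min()
        lam = pocket_coefficient(state, sampler_cfg)
        # evaluate against the distance actually realized
        if d_actual <= 4.0:
            assert lam == 1.0
        elif d_actual >= 8.0:
            assert lam == 0.0
        else:
            assert lam == pytest.approx((8.0 - d_actual) / 4.0)


class TestInitializeState:
    def test_zero_noise_de_novo_keeps_start_point(self, hbond_setup):
        pocket, ligand, cond, config, model = hbond_setup
        sampler_cfg = SamplerConfig(noise_translation_sigma=0.0,
                                    noise_rotation_sigma_deg=0.0)
        start = pocket.coords.mean(axis=0)
        state = initialize_state(pocket, cond, start, None, sampler_cfg,
                                 np.random.default_rng(0))
        np.testing.assert_allclose(state.com_pos, start, atol=1e-12)

    def test_elaboration_noise_preserves_internal_coordinates(
            self, hbond_setup):
        pocket, ligand, cond, config, model = hbond_setup
        sampler_cfg = SamplerConfig(noise_translation_sigma=0.8,
                                    noise_rotation_sigma_deg=30.0)
        state = initialize_state(pocket, cond, ligand.coords.mean(0), ligand,
                                 sampler_cfg, np.random.default_rng(4))
        moved = np.array(state.coords)
        base = ligand.coords
        d_moved = np.linalg.norm(
            moved[:, None, :] - moved[None, :, :], axis=-1)
        d_base = np.linalg.norm(
            base[:, None, :] - base[None, :, :], axis=-1)
        np.testing.assert_allclose(d_moved, d_base, atol=1e-6)

    def test_fixed_seed_reproducible(self, hbond_setup):
        pocket, ligand, cond, config, model = hbond_setup
        sampler_cfg = SamplerConfig()
        a = initialize_state(pocket, cond, np.zeros(3), ligand, sampler_cfg,
                             np.random.default_rng(9))
        b = initialize_state(pocket, cond, np.zeros(3), ligand, sampler_cfg,
                             np.random.default_rng(9))
        np.testing.assert_array_equal(np.array(a.coords), np.array(b.coords))
        np.testing.assert_array_equal(a.com_pos, b.com_pos)
        assert a.anchor == b.anchor

    def test_core_clash_warning(self, hbond_setup):
        pocket, ligand, cond, config, model = hbond_setup
        clashing = transform_ligand(
            ligand, lambda c: c * 0 + pocket.coords[0])  # on top of pocket
        sampler_cfg = SamplerConfig(noise_translation_sigma=0.0,
                                    noise_rotation_sigma_deg=0.0)
        state = initialize_state(pocket, cond, pocket.coords[0], clashing,
                                 sampler_cfg, np.random.default_rng(0))
        assert any("pocket" in w for w in state.warnings)


class TestSamplePosition:
    def _state(self, hbond_setup, **cfg_kwargs):
        pocket, ligand, cond, config, model = hbond_setup
        sampler_cfg = SamplerConfig(noise_translation_sigma=0.0,
                                    noise_rotation_sigma_deg=0.0,
                                    **cfg_kwargs)
        state = initialize_state(pocket, cond, pocket.coords.mean(0) + 2.5,
                                 None, sampler_cfg, np.random.default_rng(0))
        z = Tensor(np.zeros(config.latent_dim), requires_grad=False)
        return state, model, z, sampler_cfg, config

    def test_lambda_zero_scores_spherically_symmetric(self, hbond_setup):
        """With only co-located dummy anchors and λ=0, every direction at a
        given radius scores identically, so sampling is direction-uniform."""
        from pocketforge.sampler import _embed_state, _local_frame, \
            _sphere_directions

        state, model, z, sampler_cfg, config = self._state(
            hbond_setup, n_directions=32)
        hidden, node_coords, nidx = _embed_state(state, model)
        x = config.type_onehot("C")
        dp_l, _ = model.predict_distance(x, hidden, z, nidx)
        frame = _local_frame(state.pocket.coords, state.anchor_pos)
        dirs = _sphere_directions(32) @ frame.T
        grid = config.distance_grid
        for radius in (1.2, 1.5, 1.8):
            cands = state.anchor_pos + radius * dirs
            d = np.linalg.norm(
                cands[:, None, :] - node_coords[None, :, :], axis=-1)
            scores = dp_l.data[
                np.arange(node_coords.shape[0])[None, :],
                grid.bin_of(d)].sum(axis=1)
            assert scores.max() - scores.min() < 1e-6

    def test_zero_temperature_is_deterministic_argmax(self, hbond_setup):
        state, model, z, sampler_cfg, config = self._state(
            hbond_setup, n_directions=32, temperature_position=0.0)
        x = config.type_onehot("C")
        positions = [
            sample_position(state, model, x, z, 1.0, sampler_cfg,
                            np.random.default_rng(seed))
            for seed in range(3)
        ]
        np.testing.assert_array_equal(positions[0], positions[1])
        np.testing.assert_array_equal(positions[1], positions[2])

    def test_all_candidates_clashing_is_a_dead_end(self, hbond_setup):
        pocket, ligand, cond, config, model = hbond_setup
        sampler_cfg = SamplerConfig(noise_translation_sigma=0.0,
                                    noise_rotation_sigma_deg=0.0,
                                    n_directions=16,
                                    clash_distance=50.0)  # nothing is far enough
        state = initialize_state(pocket, cond, pocket.coords.mean(0), None,
                                 sampler_cfg, np.random.default_rng(0))
        z = Tensor(np.zeros(config.latent_dim), requires_grad=False)
        x = config.type_onehot("C")
        assert sample_position(state, model, x, z, 1.0, sampler_cfg,
                               np.random.default_rng(1)) is None


class TestStepAndGenerate:
    def _generate(self, hbond_setup, seed, **cfg):
        pocket, ligand, cond, config, model = hbond_setup
        sampler_cfg = SamplerConfig(n_directions=48, max_atoms=5, **cfg)
        return generate(pocket, cond, sampler_cfg, model,
                        start=pocket.coords.mean(0) + 2.0,
                        rng=np.random.default_rng(seed)), pocket

    def test_generation_terminates_and_respects_budget(self, hbond_setup):
        for seed in range(5):
            mol, pocket = self._generate(hbond_setup, seed)
            assert len(mol.atoms) <= 5

    def test_placed_atoms_respect_clash_floor(self, hbond_setup):
        for seed in range(5):
            mol, pocket = self._generate(hbond_setup, seed)
            if len(mol.atoms) == 0:
                continue
            dmin = np.linalg.norm(
                mol.coords[:, None, :] - pocket.coords[None, :, :],
                axis=-1).min()
            assert dmin >= 1.2

    def test_bond_lengths_within_candidate_shell(self, hbond_setup):
        pocket, ligand, cond, config, model = hbond_setup
        sampler_cfg = SamplerConfig(n_directions=48, max_atoms=6)
        rng = np.random.default_rng(3)
        state = initialize_state(pocket, cond, pocket.coords.mean(0) + 2.0,
                                 None, sampler_cfg, rng)
        z = model.sample_latent(None, rng)
        while state.has_available_anchor() and not state.forced_termination:
            before = state.n_placed
            anchor_pos = state.anchor_pos.copy()
            state = step(state, model, z, sampler_cfg, rng)
            if state.n_placed > before:
                d = np.linalg.norm(state.coords[-1] - anchor_pos)
                assert 1.1 - 1e-9 <= d <= 1.9 + 1e-9

    def test_fixed_seed_reproducible(self, hbond_setup):
        a, _ = self._generate(hbond_setup, 11)
        b, _ = self._generate(hbond_setup, 11)
        assert a.elements == b.elements
        if len(a.atoms):
            np.testing.assert_array_equal(a.coords, b.coords)

    def test_distinct_seeds_give_distinct_molecules(self, hbond_setup):
        mols = [self._generate(hbond_setup, seed)[0] for seed in range(12)]
        signatures = {
            (tuple(m.elements), m.coords.round(3).tobytes())
            for m in mols if len(m.atoms)
        }
        assert len(signatures) >= 2

    def test_max_atoms_zero_with_core_returns_core(self, hbond_setup):
        pocket, ligand, cond, config, model = hbond_setup
        sampler_cfg = SamplerConfig(max_atoms=0, noise_translation_sigma=0.3,
                                    noise_rotation_sigma_deg=10.0)
        mol = generate(pocket, cond, sampler_cfg, model, core=ligand,
                       rng=np.random.default_rng(2))
        assert mol.elements == ligand.elements
        assert sorted(mol.bonds) == sorted(ligand.bonds)
        d_new = np.linalg.norm(
            mol.coords[:, None, :] - mol.coords[None, :, :], axis=-1)
        d_old = np.linalg.norm(
            ligand.coords[:, None, :] - ligand.coords[None, :, :], axis=-1)
        np.testing.assert_allclose(d_new, d_old, atol=1e-6)

    def test_equivariance_under_rigid_motion(self, hbond_setup):
        pocket, ligand, cond, config, model = hbond_setup
        sampler_cfg = SamplerConfig(n_directions=48, max_atoms=4)
        start = pocket.coords.mean(0) + 2.0
        base = generate(pocket, cond, sampler_cfg, model, start=start,
                        rng=np.random.default_rng(21))
        apply = rigid_transform(77)
        moved = generate(transform_pocket(pocket, apply), cond, sampler_cfg,
                         model, start=apply(start[None, :])[0],
                         rng=np.random.default_rng(21))
        assert moved.elements == base.elements
        if len(base.atoms):
            np.testing.assert_allclose(
                moved.coords, apply(base.coords), atol=1e-6)


class TestPerceiveBonds:
    def test_two_carbons_at_bonding_distance(self):
        mol = perceive_bonds([Atom3D("C", [0, 0, 0]),
                              Atom3D("C", [1.54, 0, 0])])
        assert [(i, j) for i, j, _ in mol.bonds] == [(0, 1)]

    def test_two_carbons_too_far(self):
        mol = perceive_bonds([Atom3D("C", [0, 0, 0]),
                              Atom3D("C", [3.0, 0, 0])])
        assert mol.bonds == []

    def test_single_atom(self):
        mol = perceive_bonds([Atom3D("C", [0, 0, 0])])
        assert mol.bonds == []
        assert mol.elements == ["C"]

    def test_overvalent_nitrogen_gets_charge(self):
        positions = [np.zeros(3)]
        for k in range(4):
            angle = 2 * np.pi * k / 4
            positions.append(np.array(
                [1.47 * np.cos(angle), 1.47 * np.sin(angle),
                 0.2 * (-1) ** k]))
        atoms = [Atom3D("N", positions[0])] + [
            Atom3D("C", p) for p in positions[1:]]
        mol = perceive_bonds(atoms)
        assert mol.atoms[0].formal_charge == 1
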