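"""Sequential atom placement inside a pocket (de novo and elaboration).

Generation iterates: embed the partial complex; combine per-anchor type
log-likelihoods from the ligand side and, weighted by the pocket
coefficient λ, from the k nearest pocket atoms of the atom-of-interest;
sample the type (STOP retires the anchor); then score a spherical grid of
candidate positions around the anchor by the same combination of distance
log-likelihoods and sample one.  The process terminates when every placed
atom is retired or the atom budget is exhausted.

λ interpolates linearly from 1 (anchor within ``lambda_d0`` of the pocket)
to 0 (beyond ``lambda_d1``), so the pocket's vote fades as generation
moves away from the protein surface.

The candidate grid and the initialization noise are expressed in a local
frame derived from the pocket geometry, so a rigid motion of pocket and
start point carries the whole generation along with it (the scores
themselves are invariant; the grid co-moves).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from pocketforge.complex_io import (
    Atom3D,
    COVALENT_RADII,
    LigandMolecule,
    ProteinPocket,
    featurize,
)
from pocketforge.errors import AnchorError
from pocketforge.model import (
    GenerativeModel,
    build_ligand_nodes,
    pocket_neighbors,
)
from pocketforge.nn import Tensor
from pocketforge.profiler import N_CLASSES, validate_condition

#: Anchor id of the center-of-mass start dummy.
COM_ANCHOR = -1


@dataclass
class SamplerConfig:
    """Generation-time knobs (all thresholds in Angstrom / degrees)."""

    shell_radii: tuple[float, float, float] = (1.1, 1.9, 0.1)  # min, max, step
    n_directions: int = 192
    temperature_type: float = 1.0
    temperature_position: float = 1.0
    max_atoms: int = 12
    noise_translation_sigma: float = 0.5
    noise_rotation_sigma_deg: float = 15.0
    clash_distance: float = 1.2
    core_clash_warning: float = 1.5
    lambda_d0: float = 4.0
    lambda_d1: float = 8.0
    bond_perception: str = "internal"  # or "openbabel"

    def __post_init__(self) -> None:
        if self.max_atoms < 0:
            raise ValueError("max_atoms must be >= 0")
        lo, hi, step = self.shell_radii
        if not (0 < lo <= hi and step > 0):
            raise ValueError("invalid candidate shell radii")

    @property
    def radii(self) -> np.ndarray:
        lo, hi, step = self.shell_radii
        return np.arange(lo, hi + 1e-9, step)


@dataclass
class PartialComplex:
    """Mutable generation state: pocket + placed atoms + dummies + flags."""

    pocket: ProteinPocket
    condition: np.ndarray
    com_pos: np.ndarray
    elements: list[str] = field(default_factory=list)
    coords: list[np.ndarray] = field(default_factory=list)
    available: list[bool] = field(default_factory=list)
    com_available: bool = True
    anchor: int = COM_ANCHOR
    step_count: int = 0
    n_core_atoms: int = 0
    core_bonds: list[tuple[int, int, float]] = field(default_factory=list)
    forced_termination: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def n_placed(self) -> int:
        return len(self.elements)

    @property
    def anchor_pos(self) -> np.ndarray:
        if self.anchor == COM_ANCHOR:
            return self.com_pos
        return self.coords[self.anchor]

    def available_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.available) if a]

    def has_available_anchor(self) -> bool:
        return bool(self.available_indices()) or (
            self.n_placed == 0 and self.com_available)


def _local_frame(pocket_coords: np.ndarray, origin: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame that co-moves with the pocket.

    Axis 1 points from the origin toward the pocket centroid; axis 2 is the
    orthogonalized direction of the pocket atom farthest from the origin
    (most orthogonal one on near-collinearity).  Falls back to the identity
    for degenerate geometries.
    """
    rel = pocket_coords - origin
    c = rel.mean(axis=0)
    if np.linalg.norm(c) < 1e-8:
        return np.eye(3)
    e1 = c / np.linalg.norm(c)
    ortho = rel - np.outer(rel @ e1, e1)
    norms = np.linalg.norm(ortho, axis=1)
    j = int(np.argmax(norms))
    if norms[j] < 1e-8:
        return np.eye(3)
    e2 = ortho[j] / norms[j]
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3])


def _sphere_directions(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit directions (Fibonacci sphere)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack([
        np.sin(phi) * np.cos(theta),
        np.sin(phi) * np.sin(theta),
        np.cos(phi),
    ])


def initialize_state(
    pocket: ProteinPocket,
    condition: np.ndarray,
    start_point: np.ndarray,
    core: LigandMolecule | None,
    config: SamplerConfig,
    rng: np.random.Generator,
) -> PartialComplex:
    """Initial generation state with roto-translational Gaussian noise.

    De novo: the center-of-mass dummy is placed at the noised start point.
    Elaboration: the core is placed, then rotated about its centroid and
    translated by the sampled noise — internal coordinates are exactly
    preserved.  Noise is expressed in the pocket's local frame so that the
    whole initialization co-moves under rigid motion of the inputs.
    """
    condition = validate_condition(condition, pocket)
    start_point = np.asarray(start_point, dtype=float)
    p_coords = pocket.coords
    lo = p_coords.min(axis=0) - 2.0
    hi = p_coords.max(axis=0) + 2.0
    state = PartialComplex(pocket=pocket, condition=condition,
                           com_pos=start_point.copy())
    if np.any(start_point < lo) or np.any(start_point > hi):
        state.warnings.append("start point outside the pocket bounding box")

    frame = _local_frame(p_coords, start_point)
    shift = frame @ (rng.normal(0.0, 1.0, 3) * config.noise_translation_sigma)
    axis_local = rng.normal(0.0, 1.0, 3)
    axis_local /= max(np.linalg.norm(axis_local), 1e-12)
    angle = abs(rng.normal(0.0, np.radians(config.noise_rotation_sigma_deg)))
    rotation = Rotation.from_rotvec(angle * (frame @ axis_local))

    if core is None:
        state.com_pos = start_point + shift
        return state
    core_coords = core.coords
    centroid = core_coords.mean(axis=0)
    moved = rotation.apply(core_coords - centroid) + centroid + shift
    state.com_pos = centroid + shift
    for element, pos in zip(core.elements, moved):
        state.elements.append(element)
        state.coords.append(pos)
        state.available.append(True)
    state.n_core_atoms = len(core.atoms)
    state.core_bonds = list(core.bonds)
    state.com_available = False
    heavy = [i for i, e in enumerate(state.elements) if e != "H"]
    if heavy:
        from scipy.spatial.distance import cdist

        dmin = cdist(np.array([state.coords[i] for i in heavy]),
                     p_coords).min()
        if dmin < config.core_clash_warning:
            state.warnings.append(
                f"core atom within {dmin:.2f} A of a pocket atom")
    avail = state.available_indices()
    state.anchor = avail[int(rng.integers(0, len(avail)))]
    return state


def pocket_coefficient(state: PartialComplex,
                       config: SamplerConfig) -> float:
    """λ: 1 when the anchor touches the pocket, fading linearly to 0."""
    d = float(np.linalg.norm(
        state.pocket.coords - state.anchor_pos, axis=1).min())
    if d <= config.lambda_d0:
        return 1.0
    if d >= config.lambda_d1:
        return 0.0
    return (config.lambda_d1 - d) / (config.lambda_d1 - config.lambda_d0)


def _embed_state(state: PartialComplex, model: GenerativeModel):
    feats, node_coords = build_ligand_nodes(
        state.elements,
        np.array(state.coords).reshape(-1, 3),
        state.com_pos, state.anchor_pos, model.config)
    prot_feats = featurize(state.pocket).matrix[:, : -N_CLASSES]
    hidden = model.embed_complex(
        feats, node_coords, prot_feats, state.pocket.coords, state.condition)
    neighbor_idx = pocket_neighbors(
        state.anchor_pos, state.pocket.coords, model.config.k_neighbors)
    return hidden, node_coords, neighbor_idx


def _temperature_softmax(logits: np.ndarray, temperature: float,
                         rng: np.random.Generator | None = None
                         ) -> np.ndarray:
    if temperature <= 0:
        probs = np.zeros_like(logits)
        probs[int(np.argmax(logits))] = 1.0
        return probs
    scaled = logits / temperature
    scaled -= scaled.max()
    probs = np.exp(scaled)
    return probs / probs.sum()


def combined_type_distribution(
    state: PartialComplex,
    model: GenerativeModel,
    z: Tensor,
    lam: float,
    config: SamplerConfig,
) -> np.ndarray:
    """Next-atom-type probabilities combining ligand and pocket anchors.

    Softmax of (Σ ligand-anchor log p + λ Σ pocket-anchor log p), with the
    type temperature applied.
    """
    hidden, _, neighbor_idx = _embed_state(state, model)
    lp_l, lp_p = model.predict_type(hidden, z, neighbor_idx)
    logits = lp_l.data.sum(axis=0) + lam * lp_p.data.sum(axis=0)
    return _temperature_softmax(logits, config.temperature_type)


def sample_position(
    state: PartialComplex,
    model: GenerativeModel,
    x_onehot: np.ndarray,
    z: Tensor,
    lam: float,
    config: SamplerConfig,
    rng: np.random.Generator,
) -> np.ndarray | None:
    """Sample the new atom's position from a shell grid around the anchor.

    Candidates on a spherical grid (radii from ``shell_radii``, quasi-uniform
    directions in the pocket's co-moving frame) are scored by the summed
    distance log-likelihoods toward every ligand node and, λ-weighted, the
    pocket neighbors, each evaluated at the candidate's distance by bin
    lookup.  Returns None (dead end) when every candidate clashes with an
    existing heavy atom.
    """
    hidden, node_coords, neighbor_idx = _embed_state(state, model)
    dp_l, dp_p = model.predict_distance(x_onehot, hidden, z, neighbor_idx)
    frame = _local_frame(state.pocket.coords, state.anchor_pos)
    dirs = _sphere_directions(config.n_directions) @ frame.T
    candidates = (state.anchor_pos
                  + (config.radii[:, None, None] * dirs[None, :, :])
                  ).reshape(-1, 3)
    grid = model.config.distance_grid

    def anchor_scores(anchor_coords: np.ndarray, logprobs: np.ndarray
                      ) -> np.ndarray:
        if len(anchor_coords) == 0:
            return np.zeros(len(candidates))
        d = np.linalg.norm(
            candidates[:, None, :] - anchor_coords[None, :, :], axis=-1)
        bins = grid.bin_of(d)
        return logprobs[np.arange(len(anchor_coords))[None, :], bins].sum(axis=1)

    scores = anchor_scores(node_coords, dp_l.data)
    scores = scores + lam * anchor_scores(
        state.pocket.coords[neighbor_idx], dp_p.data)

    # clash mask: pocket heavy atoms and placed atoms other than the anchor
    obstacles = [state.pocket.coords[state.pocket.heavy_indices()]]
    others = [i for i in range(state.n_placed) if i != state.anchor]
    if others:
        obstacles.append(np.array([state.coords[i] for i in others]))
    obstacle_coords = np.vstack(obstacles)
    dmin = np.linalg.norm(
        candidates[:, None, :] - obstacle_coords[None, :, :], axis=-1
    ).min(axis=1)
    ok = dmin >= config.clash_distance
    if not ok.any():
        return None
    scores = np.where(ok, scores, -np.inf)
    probs = _temperature_softmax(scores, config.temperature_position)
    choice = int(rng.choice(len(candidates), p=probs))
    return candidates[choice]


def step(
    state: PartialComplex,
    model: GenerativeModel,
    z: Tensor,
    config: SamplerConfig,
    rng: np.random.Generator,
) -> PartialComplex:
    """One generation event: place an atom, or retire the current anchor."""
    if not state.has_available_anchor():
        raise AnchorError("no available atom-of-interest")
    state = replace(
        state,
        elements=list(state.elements),
        coords=list(state.coords),
        available=list(state.available),
        warnings=list(state.warnings),
    )
    state.step_count += 1
    budget_used = state.n_placed - state.n_core_atoms
    if budget_used >= config.max_atoms:
        state.forced_termination = True
        return state
    lam = pocket_coefficient(state, config)
    probs = combined_type_distribution(state, model, z, lam, config)
    if config.temperature_type <= 0:
        type_idx = int(np.argmax(probs))
    else:
        type_idx = int(rng.choice(len(probs), p=probs))
    if type_idx == model.config.stop_index:
        _retire_anchor(state)
    else:
        x_onehot = np.zeros(model.config.n_types + 1)
        x_onehot[type_idx] = 1.0
        pos = sample_position(state, model, x_onehot, z, lam, config, rng)
        if pos is None:
            state.warnings.append(
                f"dead end at step {state.step_count}: all candidates clash")
            _retire_anchor(state)
        else:
            state.elements.append(model.config.type_vocabulary[type_idx])
            state.coords.append(pos)
            state.available.append(True)
    _resample_anchor(state, rng)
    return state


def _retire_anchor(state: PartialComplex) -> None:
    if state.anchor == COM_ANCHOR:
        state.com_available = False
    else:
        state.available[state.anchor] = False


def _resample_anchor(state: PartialComplex, rng: np.random.Generator) -> None:
    avail = state.available_indices()
    if avail:
        state.anchor = avail[int(rng.integers(0, len(avail)))]
    elif state.n_placed == 0 and state.com_available:
        state.anchor = COM_ANCHOR


def generate(
    pocket: ProteinPocket,
    condition: np.ndarray,
    config: SamplerConfig,
    model: GenerativeModel,
    core: LigandMolecule | None = None,
    start: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> LigandMolecule:
    """Design one ligand inside the pocket under the interaction condition.

    The latent z is drawn from the standard-normal prior; atoms are added
    by :func:`step` until every placed atom is retired (or the budget runs
    out); the dummies are dropped and bonds perceived on the result.  May
    return an empty molecule on an immediate STOP.
    """
    rng = rng or np.random.default_rng()
    if start is None:
        if core is not None:
            start = core.coords.mean(axis=0)
        else:
            start = pocket.coords.mean(axis=0)
    z = model.sample_latent(None, rng)
    state = initialize_state(pocket, condition, start, core, config, rng)
    while state.has_available_anchor() and not state.forced_termination:
        state = step(state, model, z, config, rng)
    if state.n_placed == 0:
        return LigandMolecule(atoms=[], bonds=[], validity_warning=(
            "; ".join(state.warnings) or None))
    if state.n_placed == state.n_core_atoms and core is not None:
        # nothing added: return the (noised) core with its bonds intact
        mol = LigandMolecule(
            atoms=[Atom3D(e, p, core.atoms[i].formal_charge,
                          core.atoms[i].is_aromatic, core.atoms[i].is_in_ring)
                   for i, (e, p) in enumerate(zip(state.elements, state.coords))],
            bonds=state.core_bonds)
    else:
        mol = perceive_bonds(
            [Atom3D(e, p) for e, p in zip(state.elements, state.coords)],
            method=config.bond_perception)
    if state.warnings:
        note = "; ".join(state.warnings)
        mol.validity_warning = (
            f"{mol.validity_warning}; {note}" if mol.validity_warning else note)
    return mol


# ---------------------------------------------------------------------------
# Bond perception
# ---------------------------------------------------------------------------

def perceive_bonds(atoms: list[Atom3D],
                   method: str = "internal") -> LigandMolecule:
    """Infer connectivity (and bond orders) for a set of typed positions.

    Connectivity: two atoms bond when their distance is below 1.25 x the
    sum of their covalent radii.  The internal method assigns single bonds
    and patches common formal charges (tetravalent N → N+); RDKit valence
    checking flags anything still impossible via ``validity_warning``.
    ``method="openbabel"`` delegates order assignment to the OpenBabel
    command-line tool through an SDF round-trip.
    """
    if not atoms:
        raise ValueError("perceive_bonds requires at least one atom")
    coords = np.array([a.position for a in atoms])
    n = len(atoms)
    bonds: list[tuple[int, int, float]] = []
    for i in range(n):
        for j in range(i + 1, n):
            cutoff = 1.25 * (COVALENT_RADII.get(atoms[i].element, 0.77)
                             + COVALENT_RADII.get(atoms[j].element, 0.77))
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                bonds.append((i, j, 1))
    if method == "openbabel":
        perceived = _openbabel_bonds(atoms)
        if perceived is not None:
            return perceived
    mol = LigandMolecule(
        atoms=[Atom3D(a.element, a.position) for a in atoms], bonds=bonds)
    _patch_charges(mol)
    try:
        from rdkit import Chem

        Chem.SanitizeMol(mol.to_rdkit(sanitize=False))
    except Exception as exc:
        mol.validity_warning = f"valence problem after perception: {exc}"
    return mol


_DEFAULT_VALENCE = {"C": 4, "N": 3, "O": 2, "F": 1, "P": 3, "S": 2,
                    "Cl": 1, "Br": 1, "I": 1}


def _patch_charges(mol: LigandMolecule) -> None:
    degree = {i: len(mol.neighbors(i)) for i in range(len(mol.atoms))}
    for i, atom in enumerate(mol.atoms):
        allowed = _DEFAULT_VALENCE.get(atom.element)
        if allowed is not None and degree[i] == allowed + 1:
            atom.formal_charge = 1 if atom.element in ("N", "O", "P", "S") else 0


def _openbabel_bonds(atoms: list[Atom3D]) -> LigandMolecule | None:
    """Shell out to ``obabel`` for bond-order perception (optional path)."""
    import shutil
    import subprocess
    import tempfile
    from pathlib import Path

    if shutil.which("obabel") is None:
        return None
    with tempfile.TemporaryDirectory() as tmp:
        xyz = Path(tmp) / "mol.xyz"
        sdf = Path(tmp) / "mol.sdf"
        lines = [str(len(atoms)), "generated"]
        for a in atoms:
            x, y, z = a.position
            lines.append(f"{a.element} {x:.4f} {y:.4f} {z:.4f}")
        xyz.write_text("\n".join(lines) + "\n")
        result = subprocess.run(
            ["obabel", str(xyz), "-O", str(sdf)],
            capture_output=True, text=True)
        if result.returncode != 0 or not sdf.exists():
            return None
        try:
            from pocketforge.complex_io import read_ligand

            return read_ligand(str(sdf))
        except Exception:
            return None
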