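"""Teacher-forced training over randomly traversed atom-placement orders.

Each epoch traverses every training complex along a fresh random
trajectory: the first atom is drawn uniformly, every later atom is drawn
uniformly from the unplaced covalent neighbors of the current
atom-of-interest, and an anchor whose neighborhood is exhausted receives
a STOP target and retires.  Type and distance losses are minimized
simultaneously, together with the VAE latent regularizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pocketforge.complex_io import LigandMolecule, ProteinPocket, featurize
from pocketforge.errors import ConnectivityError
from pocketforge.model import (
    GenerativeModel,
    ModelConfig,
    build_ligand_nodes,
    distance_loss,
    gaussian_expand,
    pocket_neighbors,
    regularization_loss,
    type_loss,
)
from pocketforge.nn import Adam

#: Anchor id of the center-of-mass start dummy.
COM_ANCHOR = -1


@dataclass
class TrajectoryStep:
    """One event: either place ``atom`` adjacent to ``anchor``, or STOP."""

    anchor: int  # ligand atom index, or COM_ANCHOR for the start dummy
    atom: int | None  # placed atom index; None encodes a STOP event

    @property
    def is_stop(self) -> bool:
        return self.atom is None


@dataclass
class Trajectory:
    """A random connected traversal of a reference ligand."""

    steps: list[TrajectoryStep]
    order: list[int]  # atom indices in placement order

    def __post_init__(self) -> None:
        placed: set[int] = set()
        for step in self.steps:
            if step.anchor != COM_ANCHOR and step.anchor not in placed:
                raise ValueError("anchor must be an already placed atom")
            if not step.is_stop:
                placed.add(step.atom)


def sample_trajectory(ligand: LigandMolecule,
                      rng: np.random.Generator) -> Trajectory:
    """Sample a random atom-placement trajectory of a connected ligand.

    The anchor is re-drawn uniformly from the available placed atoms after
    every event; STOP events are interleaved at the step an anchor's bonded
    neighborhood is exhausted.  Every prefix induces a connected subgraph.
    """
    n = len(ligand.atoms)
    if n == 0:
        raise ConnectivityError("ligand has no atoms")
    if not ligand.is_connected():
        raise ConnectivityError("ligand bond graph is disconnected")
    steps: list[TrajectoryStep] = []
    order: list[int] = []
    first = int(rng.integers(0, n))
    steps.append(TrajectoryStep(anchor=COM_ANCHOR, atom=first))
    order.append(first)
    placed = {first}
    available = [first]
    while available:
        anchor = available[int(rng.integers(0, len(available)))]
        open_neighbors = [v for v in ligand.neighbors(anchor)
                          if v not in placed]
        if open_neighbors:
            atom = open_neighbors[int(rng.integers(0, len(open_neighbors)))]
            steps.append(TrajectoryStep(anchor=anchor, atom=atom))
            order.append(atom)
            placed.add(atom)
            available.append(atom)
        else:
            steps.append(TrajectoryStep(anchor=anchor, atom=None))
            available.remove(anchor)
    return Trajectory(steps=steps, order=order)


@dataclass
class StepTargets:
    """Teacher-forcing inputs and targets for one trajectory step."""

    lig_node_feats: np.ndarray
    lig_node_coords: np.ndarray
    pocket_neighbor_idx: np.ndarray
    type_target: np.ndarray  # one-hot over vocabulary + STOP
    lig_dist_targets: np.ndarray | None  # (n_lig_nodes, n_bins); None on STOP
    pocket_dist_targets: np.ndarray | None


def build_step_targets(
    pocket: ProteinPocket,
    ligand: LigandMolecule,
    trajectory: Trajectory,
    t: int,
    config: ModelConfig,
) -> StepTargets:
    """Targets for step ``t`` (0-based) of a trajectory.

    The partial ligand holds the atoms placed before step ``t`` plus the
    center-of-mass and atom-of-interest dummies; distance targets are the
    Gaussian expansions of the true distances from the next atom to every
    ligand node and to the k nearest pocket atoms of the anchor.
    """
    step = trajectory.steps[t]
    coords = ligand.coords
    com = coords.mean(axis=0)
    placed = [s.atom for s in trajectory.steps[:t] if not s.is_stop]
    anchor_pos = com if step.anchor == COM_ANCHOR else coords[step.anchor]
    feats, node_coords = build_ligand_nodes(
        [ligand.atoms[i].element for i in placed],
        coords[placed] if placed else np.zeros((0, 3)),
        com, anchor_pos, config)
    p_coords = pocket.coords
    neighbor_idx = pocket_neighbors(anchor_pos, p_coords, config.k_neighbors)
    if step.is_stop:
        return StepTargets(feats, node_coords, neighbor_idx,
                           config.stop_onehot(), None, None)
    r_t = coords[step.atom]
    d_ll = np.linalg.norm(node_coords - r_t, axis=1)
    d_lp = np.linalg.norm(p_coords[neighbor_idx] - r_t, axis=1)
    grid = config.distance_grid
    eps = config.target_smoothing

    def smooth(q: np.ndarray) -> np.ndarray:
        return (1.0 - eps) * q + eps / grid.n_bins

    return StepTargets(
        feats, node_coords, neighbor_idx,
        config.type_onehot(ligand.atoms[step.atom].element),
        smooth(gaussian_expand(np.minimum(d_ll, grid.d_max), grid)),
        smooth(gaussian_expand(np.minimum(d_lp, grid.d_max), grid)),
    )


@dataclass
class TrainConfig:
    """Optimization settings (standard adaptive first-order defaults)."""

    epochs: int = 200
    learning_rate: float = 1e-3
    #: linear decay target; None keeps the learning rate constant
    final_learning_rate: float | None = None
    batch_size: int = 8
    seed: int = 0
    checkpoint_path: str | None = None
    checkpoint_every: int = 0  # epochs; 0 disables periodic checkpoints


@dataclass
class FitResult:
    model: GenerativeModel
    history: list[dict] = field(default_factory=list)


def _complex_losses(model: GenerativeModel, pocket: ProteinPocket,
                    ligand: LigandMolecule, condition: np.ndarray,
                    trajectory: Trajectory, rng: np.random.Generator):
    """Reconstruction + regularization losses for one complex/trajectory."""
    config = model.config
    prot_feats = featurize(pocket).matrix[:, : -7]
    p_coords = pocket.coords
    full_feats, full_coords = build_ligand_nodes(
        ligand.elements, ligand.coords,
        ligand.coords.mean(axis=0), ligand.coords.mean(axis=0), config)
    # encoder sees the real atoms only (dummy rows dropped)
    posterior = model.encode_posterior(
        full_feats[:-2], full_coords[:-2], prot_feats, p_coords, condition)
    z = model.sample_latent(posterior, rng)
    recon = None
    for t in range(len(trajectory.steps)):
        targets = build_step_targets(pocket, ligand, trajectory, t, config)
        hidden = model.embed_complex(
            targets.lig_node_feats, targets.lig_node_coords,
            prot_feats, p_coords, condition)
        lp_l, lp_p = model.predict_type(hidden, z, targets.pocket_neighbor_idx)
        step_loss = type_loss(lp_l, lp_p, targets.type_target)
        if targets.lig_dist_targets is not None:
            dp_l, dp_p = model.predict_distance(
                targets.type_target, hidden, z, targets.pocket_neighbor_idx)
            step_loss = step_loss + distance_loss(
                dp_l, targets.lig_dist_targets,
                dp_p, targets.pocket_dist_targets)
        recon = step_loss if recon is None else recon + step_loss
    return recon, regularization_loss(posterior)


def fit(
    dataset: list[tuple[ProteinPocket, LigandMolecule, np.ndarray]],
    config: ModelConfig,
    train: TrainConfig | None = None,
) -> FitResult:
    """Train the generative core on (pocket, ligand, condition) complexes.

    One fresh random trajectory per complex per epoch; gradient steps are
    taken per mini-batch of complexes.  The history records reconstruction
    and regularization losses per epoch (the regularizer is reported even
    when ``config.beta`` is zero, in which case it is excluded from the
    optimized objective).  Aborts on a non-finite loss, naming the complex.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    train = train or TrainConfig()
    model = GenerativeModel(config)
    params = model.parameters()
    opt = Adam(params, lr=train.learning_rate)
    rng = np.random.default_rng(train.seed)
    history: list[dict] = []
    for epoch in range(train.epochs):
        if train.final_learning_rate is not None and train.epochs > 1:
            frac = epoch / (train.epochs - 1)
            opt.lr = (train.learning_rate
                      + frac * (train.final_learning_rate - train.learning_rate))
        recon_sum = reg_sum = 0.0
        for start in range(0, len(dataset), train.batch_size):
            batch = dataset[start: start + train.batch_size]
            opt.zero_grad()
            batch_loss = None
            for ci, (pocket, ligand, condition) in enumerate(batch):
                trajectory = sample_trajectory(ligand, rng)
                recon, reg = _complex_losses(
                    model, pocket, ligand, condition, trajectory, rng)
                loss = recon + config.beta * reg if config.beta else recon
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, complex "
                        f"{start + ci} ({pocket.source_id or 'unnamed'})")
                recon_sum += float(recon.data)
                reg_sum += float(reg.data)
                batch_loss = loss if batch_loss is None else batch_loss + loss
            (batch_loss * (1.0 / len(batch))).backward()
            opt.step()
        history.append({
            "epoch": epoch,
            "recon": recon_sum / len(dataset),
            "reg": reg_sum / len(dataset),
            "total": (recon_sum + config.beta * reg_sum) / len(dataset),
        })
        if (train.checkpoint_path and train.checkpoint_every
                and (epoch + 1) % train.checkpoint_every == 0):
            model.save_checkpoint(train.checkpoint_path)
    if train.checkpoint_path:
        model.save_checkpoint(train.checkpoint_path)
    return FitResult(model=model, history=history)


def teacher_forced_type_accuracy(
    model: GenerativeModel,
    pocket: ProteinPocket,
    ligand: LigandMolecule,
    condition: np.ndarray,
    trajectory: Trajectory,
) -> float:
    """Fraction of placement steps whose greedy type prediction is correct.

    Decodes along the given ground-truth trajectory with the partial ligand
    teacher-forced and z at the prior mean; the combined per-anchor
    log-likelihood (pocket weight 1) picks the type.
    """
    from pocketforge.nn import Tensor

    config = model.config
    prot_feats = featurize(pocket).matrix[:, : -7]
    p_coords = pocket.coords
    z = Tensor(np.zeros(config.latent_dim), requires_grad=False)
    hits = total = 0
    for t, step in enumerate(trajectory.steps):
        if step.is_stop:
            continue
        targets = build_step_targets(pocket, ligand, trajectory, t, config)
        hidden = model.embed_complex(
            targets.lig_node_feats, targets.lig_node_coords,
            prot_feats, p_coords, condition)
        lp_l, lp_p = model.predict_type(hidden, z, targets.pocket_neighbor_idx)
        logp = lp_l.data.sum(axis=0) + lp_p.data.sum(axis=0)
        if int(np.argmax(logp)) == int(np.argmax(targets.type_target)):
            hits += 1
        total += 1
    return hits / max(total, 1)
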