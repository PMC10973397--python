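"""The conditional generative core: invariant embedding, VAE, losses.

The model factorizes the ligand distribution autoregressively: at each
step the next atom's type is predicted jointly from every already placed
ligand atom (plus two positional dummies: the ligand center-of-mass and
the current atom-of-interest) and from the k nearest pocket atoms of the
atom-of-interest; its position is then predicted as distance
distributions toward those same anchors, soft-binned on a fixed grid.

All learned functions consume interatomic distances only — raw
coordinates never enter the network — so every output is invariant under
rigid motion (E(3)) of the complex by construction.  The per-protein-atom
interaction condition is concatenated to the protein atom features before
message passing, which is how conditioning reaches every prediction.

The network runs on the package's numpy autodiff (:mod:`pocketforge.nn`).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from pocketforge.complex_io import LIGAND_ELEMENTS, PROTEIN_ELEMENTS
from pocketforge.errors import AlignmentError, EncoderError
from pocketforge.nn import MLP, Linear, Tensor, concat, scatter_add
from pocketforge.profiler import N_CLASSES

# protein feature width from complex_io.featurize, without the condition block
_PROT_FEAT_DIM = len(PROTEIN_ELEMENTS) + 3 + 2


@dataclass(frozen=True)
class DistanceGrid:
    """Fixed grid of Gaussian basis functions over distance (Angstrom)."""

    d_min: float = 0.0
    d_max: float = 5.0
    n_bins: int = 50
    sigma: float | None = None  # default: one bin width

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if not self.d_min < self.d_max:
            raise ValueError("grid min must be < max")
        if self.sigma is None:
            object.__setattr__(self, "sigma", self.bin_width)

    @property
    def bin_width(self) -> float:
        return (self.d_max - self.d_min) / (self.n_bins - 1)

    @property
    def centers(self) -> np.ndarray:
        return np.linspace(self.d_min, self.d_max, self.n_bins)

    def bin_of(self, d) -> np.ndarray:
        """Index of the nearest bin center (clipped to the grid)."""
        idx = np.rint((np.asarray(d) - self.d_min) / self.bin_width)
        return np.clip(idx, 0, self.n_bins - 1).astype(int)


def gaussian_expand(d: float | np.ndarray, grid: DistanceGrid) -> np.ndarray:
    """Soft-bin distances onto the grid: ``w_k ∝ exp(-(d-c_k)^2 / 2σ^2)``,
    renormalized to sum to one.  Distances beyond the grid are clamped
    with a warning.  Input may be a scalar or an array of distances; the
    output has one extra trailing axis of length ``n_bins``.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if np.any(d > grid.d_max):
        warnings.warn("distance beyond grid max; clamping", stacklevel=2)
        d = np.minimum(d, grid.d_max)
    diff = d[..., None] - grid.centers
    w = np.exp(-(diff ** 2) / (2.0 * grid.sigma ** 2))
    return w / w.sum(axis=-1, keepdims=True)


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the generative core (all config-exposed)."""

    hidden_dim: int = 128
    n_message_layers: int = 4
    latent_dim: int = 64
    k_neighbors: int = 16
    distance_grid: DistanceGrid = field(default_factory=DistanceGrid)
    edge_cutoff: float = 8.0
    n_edge_bins: int = 16
    type_vocabulary: tuple[str, ...] = LIGAND_ELEMENTS
    beta: float = 1.0
    #: uniform mixture weight on soft-binned distance targets; keeps the
    #: forward KL finite-scaled when one state admits several next atoms
    target_smoothing: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")

    @property
    def n_types(self) -> int:
        return len(self.type_vocabulary)

    @property
    def stop_index(self) -> int:
        """Index of the STOP class in the type-output vocabulary."""
        return self.n_types

    @property
    def edge_grid(self) -> DistanceGrid:
        return DistanceGrid(0.0, self.edge_cutoff, self.n_edge_bins)

    def type_onehot(self, element: str) -> np.ndarray:
        vec = np.zeros(self.n_types + 1)
        vec[self.type_vocabulary.index(element)] = 1.0
        return vec

    def stop_onehot(self) -> np.ndarray:
        vec = np.zeros(self.n_types + 1)
        vec[self.stop_index] = 1.0
        return vec

    @classmethod
    def toy(cls, seed: int = 0) -> "ModelConfig":
        """Desk-scale configuration for fixture-sized complexes.

        Sized so that training to convergence on a handful of 10-20-atom
        complexes takes tens of seconds on one CPU while keeping the edge
        features fine enough (~0.5 A bins) to resolve bonded shells.
        """
        return cls(hidden_dim=48, n_message_layers=3, latent_dim=8,
                   k_neighbors=8,
                   distance_grid=DistanceGrid(0.0, 5.0, 25),
                   n_edge_bins=16, seed=seed)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["type_vocabulary"] = list(payload["type_vocabulary"])
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()


class _MessageLayer:
    """One round of distance-gated message passing with residual update."""

    def __init__(self, hidden: int, n_edge_bins: int, rng: np.random.Generator):
        self.msg = MLP([2 * hidden + n_edge_bins, hidden, hidden], rng)
        # zero-init the residual update: layers start as the identity,
        # which keeps deep stacks stable under sum-style aggregation
        self.upd = MLP([2 * hidden, hidden, hidden], rng, zero_last=True)

    def __call__(self, h: Tensor, src: np.ndarray, dst: np.ndarray,
                 edge_feats: Tensor) -> Tensor:
        n = h.shape[0]
        if len(src) == 0:
            agg = Tensor(np.zeros(h.shape), requires_grad=False)
        else:
            m = self.msg(concat([h[src], h[dst], edge_feats], axis=-1))
            # sqrt-degree normalization: tames the scale of dense graphs
            # while keeping neighbor-count information (a plain mean is
            # count-blind, which hides shell occupancy from the decoder)
            deg = np.maximum(np.bincount(dst, minlength=n), 1).astype(float)
            agg = scatter_add(m, dst, n) * Tensor(
                1.0 / np.sqrt(deg)[:, None], requires_grad=False)
        return h + self.upd(concat([h, agg], axis=-1))

    def parameters(self):
        return self.msg.parameters() + self.upd.parameters()


@dataclass
class HiddenStates:
    """Invariant per-atom embeddings of a (partial) complex."""

    h_ligand: Tensor  # (n_ligand_nodes, hidden) incl. the two dummies
    h_pocket: Tensor  # (n_pocket_atoms, hidden)


@dataclass
class PosteriorParams:
    mean: Tensor
    log_var: Tensor


class GenerativeModel:
    """Conditional VAE placing ligand atoms one at a time inside a pocket."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        H, Z = config.hidden_dim, config.latent_dim
        V = config.n_types
        B = config.distance_grid.n_bins
        # ligand node input: element one-hot + (is_com_dummy, is_aoi_dummy)
        self.lig_proj = Linear(V + 2, H, rng)
        self.prot_proj = Linear(_PROT_FEAT_DIM + N_CLASSES, H, rng)
        self.layers = [
            _MessageLayer(H, config.n_edge_bins, rng)
            for _ in range(config.n_message_layers)
        ]
        # heads see (anchor hidden, atom-of-interest hidden, z [, type])
        self.type_head_l = MLP([2 * H + Z, H, V + 1], rng)
        self.type_head_p = MLP([2 * H + Z, H, V + 1], rng)
        self.dist_head_l = MLP([2 * H + Z + V, H, B], rng)
        self.dist_head_p = MLP([2 * H + Z + V, H, B], rng)
        self.encoder_head = MLP([2 * H, H, 2 * Z], rng)

    # -- parameter registry ------------------------------------------------

    def named_parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        modules = {
            "lig_proj": self.lig_proj, "prot_proj": self.prot_proj,
            "type_head_l": self.type_head_l, "type_head_p": self.type_head_p,
            "dist_head_l": self.dist_head_l, "dist_head_p": self.dist_head_p,
            "encoder_head": self.encoder_head,
        }
        for i, layer in enumerate(self.layers):
            modules[f"layer{i}.msg"] = layer.msg
            modules[f"layer{i}.upd"] = layer.upd
        for name, module in modules.items():
            for k, p in enumerate(module.parameters()):
                out[f"{name}.{k}"] = p
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    # -- embedding ---------------------------------------------------------

    def embed_complex(
        self,
        lig_node_feats: np.ndarray,
        lig_coords: np.ndarray,
        prot_feats: np.ndarray,
        prot_coords: np.ndarray,
        condition: np.ndarray,
    ) -> HiddenStates:
        """Embed a (partial) complex into per-atom hidden vectors.

        ``lig_node_feats`` rows cover placed atoms plus the two dummies;
        ``condition`` rows align with pocket atoms and are concatenated to
        the protein features before message passing.  Only interatomic
        distances enter the network.
        """
        condition = np.asarray(condition, dtype=float)
        if condition.shape != (prot_feats.shape[0], N_CLASSES):
            raise AlignmentError(
                f"condition shape {condition.shape} does not match "
                f"{prot_feats.shape[0]} pocket atoms"
            )
        n_l = lig_node_feats.shape[0]
        n_p = prot_feats.shape[0]
        h_l = self.lig_proj(Tensor(lig_node_feats, requires_grad=False))
        h_p = self.prot_proj(Tensor(
            np.concatenate([prot_feats, condition], axis=1),
            requires_grad=False))
        h = concat([h_l, h_p], axis=0)

        coords = np.concatenate([lig_coords, prot_coords], axis=0)
        diff = coords[:, None, :] - coords[None, :, :]
        dmat = np.sqrt((diff ** 2).sum(-1))
        src, dst = np.nonzero(
            (dmat <= self.config.edge_cutoff)
            & ~np.eye(n_l + n_p, dtype=bool))
        if len(src):
            edge_feats = Tensor(
                gaussian_expand(dmat[src, dst], self.config.edge_grid),
                requires_grad=False)
        else:
            edge_feats = Tensor(
                np.zeros((0, self.config.n_edge_bins)), requires_grad=False)
        for layer in self.layers:
            h = layer(h, src, dst, edge_feats)
        return HiddenStates(h_ligand=h[np.arange(n_l)],
                            h_pocket=h[np.arange(n_l, n_l + n_p)])

    # -- encoder -----------------------------------------------------------

    def encode_posterior(
        self,
        lig_node_feats: np.ndarray,
        lig_coords: np.ndarray,
        prot_feats: np.ndarray,
        prot_coords: np.ndarray,
        condition: np.ndarray,
    ) -> PosteriorParams:
        """Posterior q(z | L, P, I) from the complete complex (training only)."""
        if lig_node_feats.shape[0] == 0:
            raise EncoderError("cannot encode an empty ligand")
        hidden = self.embed_complex(
            lig_node_feats, lig_coords, prot_feats, prot_coords, condition)
        pooled = concat(
            [hidden.h_ligand.mean(axis=0, keepdims=True),
             hidden.h_pocket.mean(axis=0, keepdims=True)], axis=-1)
        stats = self.encoder_head(pooled).reshape(2, self.config.latent_dim)
        return PosteriorParams(mean=stats[np.arange(0, 1)].reshape(-1),
                               log_var=stats[np.arange(1, 2)].reshape(-1))

    def sample_latent(self, posterior: PosteriorParams | None,
                      rng: np.random.Generator) -> Tensor:
        """Reparameterized posterior sample, or a prior sample if None."""
        eps = rng.standard_normal(self.config.latent_dim)
        if posterior is None:
            return Tensor(eps, requires_grad=False)
        std = (posterior.log_var * 0.5).exp()
        return posterior.mean + std * Tensor(eps, requires_grad=False)

    # -- decoder heads -----------------------------------------------------

    def _head_input(self, h: Tensor, hidden: HiddenStates, z: Tensor,
                    extra: np.ndarray | None = None) -> Tensor:
        """Per-anchor head input: anchor hidden | AOI hidden | z [| extra].

        The atom-of-interest dummy is the last ligand node; broadcasting its
        embedding to every anchor lets each head condition on where the next
        atom is being attached.
        """
        n = h.shape[0]
        ones = Tensor(np.ones((n, 1)), requires_grad=False)
        n_lig = hidden.h_ligand.shape[0]
        aoi = hidden.h_ligand[np.arange(n_lig - 1, n_lig)]
        parts = [h, ones @ aoi, ones @ z.reshape(1, -1)]
        if extra is not None:
            parts.append(Tensor(
                np.broadcast_to(extra, (n, extra.size)).copy(),
                requires_grad=False))
        return concat(parts, axis=-1)

    def predict_type(self, hidden: HiddenStates, z: Tensor,
                     pocket_neighbor_idx: np.ndarray
                     ) -> tuple[Tensor, Tensor]:
        """Per-anchor next-atom-type log-distributions.

        Returns (ligand-anchor log-probs, pocket-neighbor log-probs), each
        row a normalized log-distribution over the vocabulary + STOP.
        """
        lp_l = self.type_head_l(
            self._head_input(hidden.h_ligand, hidden, z)).log_softmax(axis=-1)
        lp_p = self.type_head_p(
            self._head_input(hidden.h_pocket[pocket_neighbor_idx], hidden, z)
        ).log_softmax(axis=-1)
        return lp_l, lp_p

    def predict_distance(self, x_onehot: np.ndarray, hidden: HiddenStates,
                         z: Tensor, pocket_neighbor_idx: np.ndarray
                         ) -> tuple[Tensor, Tensor]:
        """Per-anchor distance log-distributions for a committed atom type.

        ``x_onehot`` is the (vocabulary+STOP)-length one-hot of the next
        atom's type; STOP is not a valid placement type.
        """
        x_onehot = np.asarray(x_onehot, dtype=float)
        if x_onehot[self.config.stop_index] != 0:
            raise ValueError("cannot predict a distance for the STOP type")
        x = x_onehot[: self.config.n_types]
        lp_l = self.dist_head_l(
            self._head_input(hidden.h_ligand, hidden, z, x)
        ).log_softmax(axis=-1)
        lp_p = self.dist_head_p(
            self._head_input(hidden.h_pocket[pocket_neighbor_idx], hidden, z, x)
        ).log_softmax(axis=-1)
        return lp_l, lp_p

    # -- checkpointing -----------------------------------------------------

    def save_checkpoint(self, path: str) -> None:
        """Write parameters + config (and its hash) to one ``.npz`` file."""
        arrays = {k: p.data for k, p in self.named_parameters().items()}
        payload = asdict(self.config)
        payload["type_vocabulary"] = list(payload["type_vocabulary"])
        np.savez(
            path,
            __config__=np.frombuffer(
                json.dumps(payload, sort_keys=True).encode(), dtype=np.uint8),
            __config_hash__=np.frombuffer(
                self.config.config_hash().encode(), dtype=np.uint8),
            **arrays,
        )

    @classmethod
    def load_checkpoint(cls, path: str) -> "GenerativeModel":
        with np.load(path) as data:
            payload = json.loads(bytes(data["__config__"]).decode())
            stored_hash = bytes(data["__config_hash__"]).decode()
            payload["type_vocabulary"] = tuple(payload["type_vocabulary"])
            payload["distance_grid"] = DistanceGrid(**payload["distance_grid"])
            config = ModelConfig(**payload)
            if config.config_hash() != stored_hash:
                raise ValueError(
                    "checkpoint config hash mismatch; refusing to load")
            model = cls(config)
            for name, param in model.named_parameters().items():
                param.data = np.array(data[name])
        return model


# ---------------------------------------------------------------------------
# Partial-complex node assembly
# ---------------------------------------------------------------------------

def build_ligand_nodes(
    elements: list[str],
    coords: np.ndarray,
    com_pos: np.ndarray,
    anchor_pos: np.ndarray,
    config: ModelConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Model-side ligand node matrix: placed atoms then the two dummies.

    Placed atoms carry their element one-hot; the center-of-mass and
    atom-of-interest dummies carry only their flag bit (they hold
    positional information, nothing chemical).  Returns (features, coords)
    with the dummies as the last two rows.
    """
    V = config.n_types
    n = len(elements)
    feats = np.zeros((n + 2, V + 2))
    for i, element in enumerate(elements):
        feats[i, config.type_vocabulary.index(element)] = 1.0
    feats[n, V] = 1.0      # center-of-mass dummy
    feats[n + 1, V + 1] = 1.0  # atom-of-interest dummy
    all_coords = np.vstack([
        np.asarray(coords, dtype=float).reshape(n, 3),
        np.asarray(com_pos, dtype=float).reshape(1, 3),
        np.asarray(anchor_pos, dtype=float).reshape(1, 3),
    ])
    return feats, all_coords


def pocket_neighbors(anchor_pos: np.ndarray, prot_coords: np.ndarray,
                     k: int) -> np.ndarray:
    """Indices of the k nearest pocket atoms to the anchor (all if fewer)."""
    d = np.linalg.norm(prot_coords - np.asarray(anchor_pos), axis=1)
    order = np.argsort(d, kind="stable")
    return order[: min(k, len(order))]


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

_Q_FLOOR = 1e-12  # numerical floor for Gaussian-expanded targets in KL


def type_loss(lig_logprobs: Tensor, pocket_logprobs: Tensor,
              truth_onehot: np.ndarray) -> Tensor:
    """Cross-entropy −log p[X_t], averaged per anchor set and summed.

    The one-hot target makes the literal forward KL infinite off-support;
    cross-entropy (≡ KL(q‖p) for one-hot q) is the finite reading.
    """
    truth = np.asarray(truth_onehot, dtype=float)
    if not (truth.min() >= 0 and np.isclose(truth.sum(), 1.0)
            and np.isclose(truth.max(), 1.0)):
        raise ValueError("type target must be one-hot")
    t = Tensor(truth, requires_grad=False)
    ce_l = -(lig_logprobs * t).sum(axis=-1).mean()
    ce_p = -(pocket_logprobs * t).sum(axis=-1).mean()
    return ce_l + ce_p


def distance_kl(p_logprobs: Tensor, q: np.ndarray) -> Tensor:
    """Mean over anchors of KL(p ‖ q) in nats, q a soft-binned target."""
    q = np.maximum(np.asarray(q, dtype=float), _Q_FLOOR)
    q = q / q.sum(axis=-1, keepdims=True)
    p = p_logprobs.exp()
    log_q = Tensor(np.log(q), requires_grad=False)
    return (p * (p_logprobs - log_q)).sum(axis=-1).mean()


def distance_loss(lig_logprobs: Tensor, lig_targets: np.ndarray,
                  pocket_logprobs: Tensor, pocket_targets: np.ndarray
                  ) -> Tensor:
    """Ligand-anchor KL + pocket-anchor KL, each averaged within its set."""
    return (distance_kl(lig_logprobs, lig_targets)
            + distance_kl(pocket_logprobs, pocket_targets))


def regularization_loss(posterior: PosteriorParams) -> Tensor:
    """Closed-form KL(q(z|·) ‖ N(0, I)) for a diagonal Gaussian posterior."""
    mu, lv = posterior.mean, posterior.log_var
    return ((mu * mu + lv.exp() - lv - 1.0).sum()) * 0.5


def total_loss(recon: Tensor, posterior: PosteriorParams,
               beta: float) -> Tensor:
    """ELBO objective: reconstruction + β · regularization."""
    return recon + beta * regularization_loss(posterior)
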