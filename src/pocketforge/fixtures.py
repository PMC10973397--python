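"""Synthetic pocket+ligand complexes with designed interaction motifs.

Every fixture is a small free-floating cluster of amino-acid functional
groups (with PDB-legal residue/atom names) plus a 1-8 heavy-atom ligand,
constructed so that *exactly* the requested non-covalent motif is present
at the requested geometry.  The expected interaction list is returned
alongside and acts as ground truth for the profiler: margins between the
motif geometry and all detection cutoffs are built in, so no unintended
interaction can appear.

Fixtures are deterministic functions of their seed.  Each complex is
placed in a random rigid frame (rotation + translation drawn from the
seed), which exercises the frame-independence of everything downstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from pocketforge.complex_io import (
    Atom3D,
    COVALENT_RADII,
    LigandMolecule,
    ProteinPocket,
)
from pocketforge.errors import SpecError
from pocketforge.profiler import (
    DetectedInteraction,
    InteractionType,
    condition_from_interactions,
    detect_interactions,
)


class Motif(enum.Enum):
    HBOND = "HBOND"
    SALT_BRIDGE = "SALT_BRIDGE"
    HYDROPHOBIC = "HYDROPHOBIC"
    PI_STACK = "PI_STACK"
    NONE = "NONE"


#: Geometry ranges (Angstrom) inside which each motif is detectable with a
#: safety margin against every other cutoff.
DETECTABLE_RANGE: dict[Motif, tuple[float, float]] = {
    Motif.HBOND: (2.5, 3.9),
    Motif.SALT_BRIDGE: (3.2, 5.3),
    Motif.HYDROPHOBIC: (3.2, 3.95),
    Motif.PI_STACK: (4.05, 5.3),
    Motif.NONE: (6.0, 12.0),
}

DEFAULT_DISTANCE: dict[Motif, float] = {
    Motif.HBOND: 2.9,
    Motif.SALT_BRIDGE: 4.0,
    Motif.HYDROPHOBIC: 3.8,
    Motif.PI_STACK: 4.2,
    Motif.NONE: 7.0,
}


@dataclass
class MotifSpec:
    """Specification of a synthetic interaction-motif complex."""

    motif: Motif
    distance: float | None = None
    angle: float | None = None  # HBOND: D-H...A angle for the explicit H
    jitter: float = 0.0  # Gaussian sigma (A) applied to spectator atoms
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.motif, str):
            self.motif = Motif(self.motif)
        if self.distance is None:
            self.distance = DEFAULT_DISTANCE[self.motif]
        lo, hi = DETECTABLE_RANGE[self.motif]
        if not (lo <= self.distance <= hi):
            raise SpecError(
                f"{self.motif.value} distance {self.distance} outside "
                f"detectable range [{lo}, {hi}]"
            )
        if self.jitter < 0:
            raise SpecError("jitter must be non-negative")


@dataclass
class _Builder:
    """Accumulates pocket/ligand atoms before assembly."""

    p_atoms: list[Atom3D] = field(default_factory=list)
    p_meta: list[tuple[str, int, str, str]] = field(default_factory=list)  # res, num, chain, name
    l_atoms: list[Atom3D] = field(default_factory=list)
    l_bonds: list[tuple[int, int, float]] = field(default_factory=list)
    key_pocket: set[int] = field(default_factory=set)
    key_ligand: set[int] = field(default_factory=set)

    def pocket_atom(self, element, pos, res, num, name, charge=0,
                    aromatic=False, ring=False, key=False) -> int:
        self.p_atoms.append(Atom3D(element, np.asarray(pos, float), charge,
                                   aromatic, ring))
        self.p_meta.append((res, num, "A", name))
        idx = len(self.p_atoms) - 1
        if key:
            self.key_pocket.add(idx)
        return idx

    def ligand_atom(self, element, pos, charge=0, aromatic=False, ring=False,
                    key=False) -> int:
        self.l_atoms.append(Atom3D(element, np.asarray(pos, float), charge,
                                   aromatic, ring))
        idx = len(self.l_atoms) - 1
        if key:
            self.key_ligand.add(idx)
        return idx

    def bond(self, i, j, order=1) -> None:
        self.l_bonds.append((i, j, order))


def _hexagon(center: np.ndarray, radius: float, z: float,
             phase: float = 0.0) -> list[np.ndarray]:
    pts = []
    for k in range(6):
        ang = phase + k * np.pi / 3
        pts.append(center + np.array([radius * np.cos(ang),
                                      radius * np.sin(ang), z]))
    return pts


def _build_hbond(b: _Builder, d: float, angle: float | None) -> None:
    # pocket: ALA backbone fragment, carbonyl O is the acceptor
    o = b.pocket_atom("O", (d, 0.0, 0.0), "ALA", 1, "O", key=True)
    c = b.pocket_atom("C", (d + 1.23, 0.0, 0.0), "ALA", 1, "C")
    b.pocket_atom("C", (d + 2.75, 0.0, 0.0), "ALA", 1, "CA")
    b.pocket_atom("N", (d + 4.22, 0.0, 0.0), "ALA", 1, "N")
    del o, c
    # ligand: ethanol-like donor; hydroxyl O at the origin points at the O
    lo = b.ligand_atom("O", (0.0, 0.0, 0.0), key=True)
    c2 = b.ligand_atom("C", (0.0, 1.43, 0.0))
    c1 = b.ligand_atom("C", (1.10, 2.40, 0.0))
    b.bond(lo, c2)
    b.bond(c2, c1)
    if angle is not None:
        # explicit donor hydrogen at the requested D-H...A angle
        theta = np.radians(180.0 - angle)
        h_pos = np.array([0.97 * np.cos(theta), -0.97 * np.sin(theta), 0.0])
        h = b.ligand_atom("H", h_pos)
        b.bond(lo, h)


def _build_salt_bridge(b: _Builder, d: float) -> None:
    # pocket: ASP carboxylate; group centroid sits d from the ligand N+
    half = np.radians(30.0)
    cg = np.array([d + 1.25 * np.cos(half), 0.0, 0.0])
    od1 = cg + 1.25 * np.array([-np.cos(half), np.sin(half), 0.0])
    od2 = cg + 1.25 * np.array([-np.cos(half), -np.sin(half), 0.0])
    b.pocket_atom("O", od1, "ASP", 1, "OD1", charge=-1, key=True)
    b.pocket_atom("O", od2, "ASP", 1, "OD2", key=True)
    b.pocket_atom("C", cg, "ASP", 1, "CG")
    b.pocket_atom("C", cg + np.array([1.52, 0.0, 0.0]), "ASP", 1, "CB")
    # ligand: methylammonium
    n = b.ligand_atom("N", (0.0, 0.0, 0.0), charge=1, key=True)
    c = b.ligand_atom("C", (-1.47, 0.0, 0.0))
    b.bond(n, c)


def _build_hydrophobic(b: _Builder, d: float) -> None:
    # pocket: LEU side chain; only CD1 is within reach of the ligand
    cd1 = b.pocket_atom("C", (d, 0.0, 0.0), "LEU", 1, "CD1", key=True)
    b.pocket_atom("C", (d + 1.52, 0.0, 0.0), "LEU", 1, "CG")
    b.pocket_atom("C", (d + 2.28, 1.32, 0.0), "LEU", 1, "CD2")
    b.pocket_atom("C", (d + 2.28, -1.32, 0.0), "LEU", 1, "CB")
    del cd1
    # ligand: propane, C1 at the contact
    c1 = b.ligand_atom("C", (0.0, 0.0, 0.0), key=True)
    c2 = b.ligand_atom("C", (-1.26, 0.89, 0.0))
    c3 = b.ligand_atom("C", (-2.52, 0.0, 0.0))
    b.bond(c1, c2)
    b.bond(c2, c3)


def _build_pi_stack(b: _Builder, d: float, angle: float | None) -> None:
    tilt = 0.0 if angle is None else float(angle)
    # pocket: PHE ring stacked above the ligand benzene, twisted 30 degrees
    ring_names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    pts = _hexagon(np.zeros(3), 1.39, 0.0, phase=np.pi / 6)
    rot = Rotation.from_euler("y", tilt, degrees=True)
    for name, pt in zip(ring_names, pts):
        pos = rot.apply(pt) + np.array([0.0, 0.0, d])
        b.pocket_atom("C", pos, "PHE", 1, name, aromatic=True, ring=True,
                      key=True)
    # ligand: benzene in the z=0 plane
    idx = [
        b.ligand_atom("C", pt, aromatic=True, ring=True, key=True)
        for pt in _hexagon(np.zeros(3), 1.39, 0.0)
    ]
    for k in range(6):
        b.bond(idx[k], idx[(k + 1) % 6], 1.5)


def _build_none(b: _Builder, d: float) -> None:
    # pocket: GLY backbone; ligand: a lone methane carbon far away
    b.pocket_atom("N", (d, 0.0, 0.0), "GLY", 1, "N")
    b.pocket_atom("C", (d + 1.47, 0.0, 0.0), "GLY", 1, "CA")
    b.pocket_atom("C", (d + 2.99, 0.0, 0.0), "GLY", 1, "C")
    b.pocket_atom("O", (d + 2.99, 1.23, 0.0), "GLY", 1, "O")
    b.ligand_atom("C", (0.0, 0.0, 0.0))


def make_probe_complex(
    spec: MotifSpec,
) -> tuple[ProteinPocket, LigandMolecule, list[DetectedInteraction]]:
    """Build a pocket+ligand pair exhibiting exactly the requested motif.

    Returns the complex in a random rigid frame drawn from ``spec.seed``,
    together with the ground-truth interaction list (empty for
    ``Motif.NONE``).  Spectator atoms are jittered by ``spec.jitter``;
    the atoms realizing the motif keep their exact geometry.
    """
    rng = np.random.default_rng(spec.seed)
    b = _Builder()
    d = float(spec.distance)
    if spec.motif == Motif.HBOND:
        _build_hbond(b, d, spec.angle)
    elif spec.motif == Motif.SALT_BRIDGE:
        _build_salt_bridge(b, d)
    elif spec.motif == Motif.HYDROPHOBIC:
        _build_hydrophobic(b, d)
    elif spec.motif == Motif.PI_STACK:
        _build_pi_stack(b, d, spec.angle)
    else:
        _build_none(b, d)

    if spec.jitter > 0:
        for i, atom in enumerate(b.p_atoms):
            if i not in b.key_pocket:
                atom.position = atom.position + rng.normal(0, spec.jitter, 3)
        for i, atom in enumerate(b.l_atoms):
            if i not in b.key_ligand:
                atom.position = atom.position + rng.normal(0, spec.jitter, 3)

    # random rigid frame
    rotation = Rotation.from_quat(_random_unit_quaternion(rng))
    translation = rng.uniform(-10.0, 10.0, 3)
    for atom in b.p_atoms + b.l_atoms:
        atom.position = rotation.apply(atom.position) + translation

    pocket = ProteinPocket(
        atoms=b.p_atoms,
        residue_name=[m[0] for m in b.p_meta],
        residue_number=[m[1] for m in b.p_meta],
        chain_id=[m[2] for m in b.p_meta],
        atom_name=[m[3] for m in b.p_meta],
        source_id=f"probe-{spec.motif.value.lower()}-{spec.seed}",
    )
    ligand = LigandMolecule(atoms=b.l_atoms, bonds=b.l_bonds)
    expected = _expected_interactions(spec, pocket, ligand, b)
    return pocket, ligand, expected


def _random_unit_quaternion(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


def _expected_interactions(
    spec: MotifSpec, pocket: ProteinPocket, ligand: LigandMolecule, b: _Builder
) -> list[DetectedInteraction]:
    if spec.motif == Motif.NONE:
        return []
    p_idx = sorted(b.key_pocket)
    l_idx = sorted(b.key_ligand)
    if spec.motif == Motif.HBOND:
        d = float(np.linalg.norm(pocket.coords[p_idx[0]] - ligand.coords[l_idx[0]]))
        angle = None
        if spec.angle is not None:
            # realized D-H...A angle, measured from the built coordinates
            donor, acceptor = ligand.coords[l_idx[0]], pocket.coords[p_idx[0]]
            h = next(ligand.coords[j] for j in ligand.neighbors(l_idx[0])
                     if ligand.atoms[j].element == "H")
            v1, v2 = donor - h, acceptor - h
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        return [DetectedInteraction(
            InteractionType.HBOND, p_idx, l_idx, d,
            angle=angle, protein_role="acceptor",
        )]
    if spec.motif == Motif.SALT_BRIDGE:
        d = float(np.linalg.norm(
            pocket.coords[p_idx].mean(axis=0) - ligand.coords[l_idx].mean(axis=0)
        ))
        return [DetectedInteraction(
            InteractionType.SALT_BRIDGE, p_idx, l_idx, d, protein_role="anion",
        )]
    if spec.motif == Motif.HYDROPHOBIC:
        d = float(np.linalg.norm(pocket.coords[p_idx[0]] - ligand.coords[l_idx[0]]))
        return [DetectedInteraction(
            InteractionType.HYDROPHOBIC, p_idx, l_idx, d,
        )]
    # PI_STACK
    d = float(np.linalg.norm(
        pocket.coords[p_idx].mean(axis=0) - ligand.coords[l_idx].mean(axis=0)
    ))
    return [DetectedInteraction(
        InteractionType.PI_STACK, p_idx, l_idx, d,
        angle=0.0 if spec.angle is None else float(spec.angle),
    )]


# bond-length factor per bond order, relative to the covalent-radius sum
_ORDER_LENGTH_FACTOR = {1: 1.0, 1.5: 0.91, 2: 0.875, 3: 0.79}


def _check_bond_sanity(ligand: LigandMolecule, tol: float = 0.05) -> None:
    coords = ligand.coords
    for i, j, order in ligand.bonds:
        expected = _ORDER_LENGTH_FACTOR[order] * (
            COVALENT_RADII[ligand.atoms[i].element]
            + COVALENT_RADII[ligand.atoms[j].element]
        )
        actual = float(np.linalg.norm(coords[i] - coords[j]))
        if abs(actual - expected) > tol * expected:
            raise SpecError(
                f"bond {i}-{j} length {actual:.3f} deviates more than "
                f"{tol:.0%} from {expected:.3f}"
            )


def make_training_set(
    n: int,
    motif_mix: dict[Motif, float] | None = None,
    seed: int = 0,
    jitter: float = 0.0,
) -> list[tuple[ProteinPocket, LigandMolecule, np.ndarray]]:
    """Build ``n`` probe complexes with reference-based conditions attached.

    ``motif_mix`` gives relative weights per motif (default: the four
    interaction motifs equally).  Counts follow a largest-remainder split
    of the weights, so they are exact and deterministic; motif distances
    are randomized within each motif's detectable range using sub-seeds
    derived from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if motif_mix is None:
        motif_mix = {
            Motif.HBOND: 1, Motif.SALT_BRIDGE: 1,
            Motif.HYDROPHOBIC: 1, Motif.PI_STACK: 1,
        }
    motifs = sorted(motif_mix, key=lambda m: m.value)
    weights = np.array([motif_mix[m] for m in motifs], dtype=float)
    weights = weights / weights.sum()
    counts = np.floor(weights * n).astype(int)
    remainders = weights * n - counts
    for k in np.argsort(-remainders)[: n - counts.sum()]:
        counts[k] += 1

    rng = np.random.default_rng(seed)
    out = []
    for motif, count in zip(motifs, counts):
        for _ in range(count):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            lo, hi = DETECTABLE_RANGE[motif]
            margin = 0.05 * (hi - lo)
            dist = float(np.random.default_rng(sub_seed).uniform(
                lo + margin, hi - margin))
            spec = MotifSpec(motif, distance=dist, jitter=jitter, seed=sub_seed)
            pocket, ligand, _ = make_probe_complex(spec)
            _check_bond_sanity(ligand)
            cond = condition_from_interactions(
                pocket, detect_interactions(pocket, ligand))
            out.append((pocket, ligand, cond))
    return out


def make_overfit_complex(
    seed: int = 0,
) -> tuple[ProteinPocket, LigandMolecule, np.ndarray]:
    """One H-bonded complex suited to single-complex memorization studies.

    The ligand is a hexanol-like chain (hydroxyl O at 2.9 A from an ALA
    backbone carbonyl, five aliphatic carbons zig-zagging away from the
    pocket).  With a single heteroatom at a chain end, the next atom's
    element is determined by the teacher-forced partial state at almost
    every step, so type-recovery measures memorization rather than
    irreducible trajectory ambiguity.  Returned with its reference-based
    condition; placed in a random rigid frame drawn from ``seed``.
    """
    rng = np.random.default_rng(seed)
    b = _Builder()
    _build_hbond(b, 2.9, None)
    # extend the ethanol-like ligand to a 6-heavy-atom chain
    zig = np.array([-1.26, 0.89, 0.0])  # chain extends away from the pocket
    zag = np.array([-1.26, -0.89, 0.0])
    last = b.l_atoms[-1].position
    prev = len(b.l_atoms) - 1
    for k in range(3):
        last = last + (zig if k % 2 == 0 else zag)
        idx = b.ligand_atom("C", last)
        b.bond(prev, idx)
        prev = idx
    rotation = Rotation.from_quat(_random_unit_quaternion(rng))
    translation = rng.uniform(-10.0, 10.0, 3)
    for atom in b.p_atoms + b.l_atoms:
        atom.position = rotation.apply(atom.position) + translation
    pocket = ProteinPocket(
        atoms=b.p_atoms,
        residue_name=[m[0] for m in b.p_meta],
        residue_number=[m[1] for m in b.p_meta],
        chain_id=[m[2] for m in b.p_meta],
        atom_name=[m[3] for m in b.p_meta],
        source_id=f"overfit-hbond-{seed}",
    )
    ligand = LigandMolecule(atoms=b.l_atoms, bonds=b.l_bonds)
    cond = condition_from_interactions(
        pocket, detect_interactions(pocket, ligand))
    return pocket, ligand, cond


def make_conditioning_pair(
    seed: int = 0, jitter: float = 0.0
) -> list[tuple[ProteinPocket, LigandMolecule, np.ndarray,
                list[DetectedInteraction]]]:
    """A two-complex set sharing one twin-site pocket, for conditioning tests.

    The pocket carries two *chemically identical* H-bond acceptor sites
    (mirrored ALA backbone-carbonyl fragments on opposite sides of the
    origin).  Variant one binds a methanol-like donor at the +x site,
    variant two the mirrored donor at the -x site; each forms exactly one
    hydrogen bond.  Because the two sites are indistinguishable by atom
    features alone, the interaction condition (which marks only the bonded
    carbonyl oxygen) is the sole signal telling a generator which site to
    serve — masking it removes exactly that information.
    """
    rng = np.random.default_rng(seed)
    p_atoms: list[Atom3D] = []
    p_meta: list[tuple[str, int, str, str]] = []

    def pocket_atom(element, pos, res, num, name):
        p_atoms.append(Atom3D(element, np.asarray(pos, float)))
        p_meta.append((res, num, "A", name))
        return len(p_atoms) - 1

    key = []
    for sign, resnum in ((+1, 1), (-1, 2)):
        key.append(pocket_atom("O", (sign * 4.5, 0.0, 0.0), "ALA", resnum, "O"))
        pocket_atom("C", (sign * 5.73, 0.0, 0.0), "ALA", resnum, "C")
        pocket_atom("C", (sign * 7.25, 0.0, 0.0), "ALA", resnum, "CA")
        pocket_atom("N", (sign * 8.72, 0.0, 0.0), "ALA", resnum, "N")

    if jitter > 0:
        for i, atom in enumerate(p_atoms):
            if i not in key:
                atom.position = atom.position + rng.normal(0, jitter, 3)

    pocket = ProteinPocket(
        atoms=p_atoms,
        residue_name=[m[0] for m in p_meta],
        residue_number=[m[1] for m in p_meta],
        chain_id=[m[2] for m in p_meta],
        atom_name=[m[3] for m in p_meta],
        source_id=f"twin-site-{seed}",
    )

    # methanol-like donors (one O + one C keeps the next-atom type
    # determined by the partial state, which a product-of-anchors type
    # model represents faithfully), mirrored across the two sites
    ligands = [
        LigandMolecule(
            atoms=[
                Atom3D("O", np.array([sign * 1.6, 0.0, 0.0])),
                Atom3D("C", np.array([sign * 1.6, 1.43, 0.0])),
            ],
            bonds=[(0, 1, 1)],
        )
        for sign in (+1, -1)
    ]

    out = []
    for lig in ligands:
        inters = detect_interactions(pocket, lig)
        cond = condition_from_interactions(pocket, inters)
        out.append((pocket, lig, cond, inters))
    return out
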