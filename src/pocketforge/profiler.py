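"""Protein-ligand interaction profiling and per-atom interaction conditions.

Stage 1 of the design workflow.  Three ways to obtain a condition matrix
(one row per pocket atom, 7 one-hot columns):

* **reference-free** — rule-based classification of the bare pocket
  (no bound ligand needed), used at generation time;
* **reference-based** — geometric detection of the four non-covalent
  interaction types (hydrogen bond, hydrophobic contact, salt bridge,
  pi-pi stacking) in a bound complex, then
  :func:`condition_from_interactions`;
* **manual** — any valid one-hot matrix supplied by the user.

The rule set for protein atoms (donor/acceptor/charge/aromatic/apolar
membership) is a reconstruction from standard amino-acid chemistry, driven
by residue and atom names, with element-level fallbacks for non-standard
residues.  Geometric thresholds follow widely used profiler defaults and
are exposed on :class:`ProfilerThresholds`.

Condition class order (fixed for serialization):
ANION, CATION, HB_DONOR, HB_ACCEPTOR, AROMATIC, HYDROPHOBIC,
NON_INTERACTING.  Fingerprint type order within each 4-bit atom block:
HBOND, HYDROPHOBIC, SALT_BRIDGE, PI_STACK.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from scipy.spatial.distance import cdist

from pocketforge.complex_io import LigandMolecule, ProteinPocket
from pocketforge.errors import AlignmentError, TargetMismatchError


class InteractionClass(enum.IntEnum):
    """The 7 per-protein-atom interaction condition classes."""

    ANION = 0
    CATION = 1
    HB_DONOR = 2
    HB_ACCEPTOR = 3
    AROMATIC = 4
    HYDROPHOBIC = 5
    NON_INTERACTING = 6


class InteractionType(enum.IntEnum):
    """The 4 detected non-covalent interaction types (fingerprint order)."""

    HBOND = 0
    HYDROPHOBIC = 1
    SALT_BRIDGE = 2
    PI_STACK = 3


N_CLASSES = len(InteractionClass)
N_TYPES = len(InteractionType)

#: Priority when one atom matches several condition classes: charged first,
#: then directional H-bond roles, then aromatic, then hydrophobic.
CLASS_PRIORITY: tuple[InteractionClass, ...] = (
    InteractionClass.ANION,
    InteractionClass.CATION,
    InteractionClass.HB_DONOR,
    InteractionClass.HB_ACCEPTOR,
    InteractionClass.AROMATIC,
    InteractionClass.HYDROPHOBIC,
)


@dataclass(frozen=True)
class ProfilerThresholds:
    """Geometric cutoffs for interaction detection (Angstrom / degrees)."""

    hbond_dist_max: float = 4.1
    hbond_angle_min: float = 100.0
    hydrophobic_dist_max: float = 4.0
    saltbridge_dist_max: float = 5.5
    pistack_dist_max: float = 5.5
    pistack_parallel_angle_max: float = 30.0
    pistack_tshape_angle_min: float = 60.0
    pistack_tshape_angle_max: float = 90.0


DEFAULT_THRESHOLDS = ProfilerThresholds()


@dataclass
class DetectedInteraction:
    """One detected non-covalent contact between pocket and ligand."""

    itype: InteractionType
    protein_atom_indices: list[int]
    ligand_atom_indices: list[int]
    distance: float
    angle: float | None = None
    #: for HBOND: "donor"/"acceptor"; for SALT_BRIDGE: "anion"/"cation";
    #: describes the protein side's role.
    protein_role: str | None = None

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("interaction distance must be positive")


# ---------------------------------------------------------------------------
# Protein-side chemistry templates (reconstruction; residue/atom-name driven)
# ---------------------------------------------------------------------------

_BACKBONE_DONOR_N = "N"
_BACKBONE_ACCEPTOR_O = ("O", "OXT")

# side-chain H-bond donors per residue
_SC_DONORS: dict[str, set[str]] = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "TRP": {"NE1"},
    "HIS": {"ND1", "NE2"}, "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"},
}
# side-chain H-bond acceptors per residue
_SC_ACCEPTORS: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"}, "GLN": {"OE1"},
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"}, "MET": {"SD"},
}
# formally charged side-chain groups: residue -> (atom names, sign)
_CHARGED_GROUPS: dict[str, tuple[set[str], int]] = {
    "ASP": ({"OD1", "OD2"}, -1),
    "GLU": ({"OE1", "OE2"}, -1),
    "LYS": ({"NZ"}, +1),
    "ARG": ({"NE", "NH1", "NH2"}, +1),
}
# aromatic ring systems: residue -> list of ring atom-name tuples
_AROMATIC_RINGS: dict[str, list[tuple[str, ...]]] = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TRP": [
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
    ],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
}
# apolar carbons (carbon bonded only to C/H in the standard residue)
_APOLAR_CARBONS: dict[str, set[str]] = {
    "ALA": {"CB"},
    "VAL": {"CB", "CG1", "CG2"},
    "LEU": {"CB", "CG", "CD1", "CD2"},
    "ILE": {"CB", "CG1", "CG2", "CD1"},
    "MET": {"CB"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2"},
    "TRP": {"CB", "CE3", "CZ2", "CZ3", "CH2"},
    "PRO": {"CB", "CG"},
    "LYS": {"CB", "CG", "CD"},
    "ARG": {"CB", "CG"},
    "GLU": {"CB", "CG"},
    "GLN": {"CB", "CG"},
    "ASP": {"CB"},
    "ASN": {"CB"},
    "THR": {"CG2"},
}


def _protein_atom_classes(pocket: ProteinPocket, i: int) -> set[InteractionClass]:
    """All condition classes atom ``i`` matches under the rule set."""
    res = pocket.residue_name[i]
    name = pocket.atom_name[i]
    element = pocket.atoms[i].element
    classes: set[InteractionClass] = set()

    group = _CHARGED_GROUPS.get(res)
    if group and name in group[0]:
        classes.add(InteractionClass.ANION if group[1] < 0 else InteractionClass.CATION)
    if name == _BACKBONE_DONOR_N and res != "PRO" and element == "N":
        classes.add(InteractionClass.HB_DONOR)
    if name in _SC_DONORS.get(res, ()):  # noqa: SIM118 - set-or-tuple lookup
        classes.add(InteractionClass.HB_DONOR)
    if name in _BACKBONE_ACCEPTOR_O and element == "O":
        classes.add(InteractionClass.HB_ACCEPTOR)
    if name in _SC_ACCEPTORS.get(res, ()):
        classes.add(InteractionClass.HB_ACCEPTOR)
    for ring in _AROMATIC_RINGS.get(res, []):
        if name in ring:
            classes.add(InteractionClass.AROMATIC)
    if name in _APOLAR_CARBONS.get(res, ()):
        classes.add(InteractionClass.HYDROPHOBIC)

    if not classes and res not in _KNOWN_RESIDUES:
        # element-level fallback for non-standard residues
        if element == "O":
            classes.add(InteractionClass.HB_ACCEPTOR)
        elif element == "N":
            classes.add(InteractionClass.HB_DONOR)
    return classes


_KNOWN_RESIDUES = (
    set(_SC_DONORS) | set(_SC_ACCEPTORS) | set(_CHARGED_GROUPS)
    | set(_AROMATIC_RINGS) | set(_APOLAR_CARBONS) | {"GLY"}
)


def _resolve_priority(classes: set[InteractionClass]) -> InteractionClass:
    for cls in CLASS_PRIORITY:
        if cls in classes:
            return cls
    return InteractionClass.NON_INTERACTING


def assign_condition_reference_free(pocket: ProteinPocket) -> np.ndarray:
    """Assign a 7-class one-hot condition to every pocket atom by rules alone.

    Deterministic and total: atoms matching several criteria are resolved by
    :data:`CLASS_PRIORITY`; atoms matching none become NON_INTERACTING.
    """
    if len(pocket) == 0:
        raise ValueError("pocket is empty")
    cond = np.zeros((len(pocket), N_CLASSES), dtype=float)
    for i in range(len(pocket)):
        cls = _resolve_priority(_protein_atom_classes(pocket, i))
        cond[i, cls] = 1.0
    return cond


def mask_condition(cond: np.ndarray) -> np.ndarray:
    """The ablation control: a zero matrix of the same shape."""
    cond = np.asarray(cond, dtype=float)
    if cond.ndim != 2 or cond.shape[1] != N_CLASSES:
        raise ValueError(f"condition must be (n_atoms, {N_CLASSES})")
    return np.zeros_like(cond)


def validate_condition(cond: np.ndarray, pocket: ProteinPocket) -> np.ndarray:
    """Check shape/one-hot invariants of a condition matrix against a pocket."""
    cond = np.asarray(cond, dtype=float)
    if cond.shape != (len(pocket), N_CLASSES):
        raise AlignmentError(
            f"condition shape {cond.shape} does not align with pocket of {len(pocket)} atoms"
        )
    row_sums = cond.sum(axis=1)
    if not (np.allclose(row_sums, 1.0) or np.allclose(cond, 0.0)):
        raise AlignmentError("condition rows must be one-hot, or the matrix all-zero")
    return cond


# ---------------------------------------------------------------------------
# Ligand-side chemistry (RDKit / SMARTS)
# ---------------------------------------------------------------------------

_HBD_SMARTS = Chem.MolFromSmarts("[$([N;!H0;+0]),$([O;!H0;+0]),$([N;!H0;+1])]")
_HBA_SMARTS = Chem.MolFromSmarts("[$([O;+0]),$([O;-1]),$([N;+0;!X4;!$([N;!H0])])]")


def _ligand_rdkit(ligand: LigandMolecule) -> Chem.Mol | None:
    try:
        return ligand.to_rdkit(sanitize=True)
    except Exception:
        try:
            mol = ligand.to_rdkit(sanitize=False)
            mol.UpdatePropertyCache(strict=False)
            return mol
        except Exception:
            return None


def _ligand_donors_acceptors(ligand: LigandMolecule) -> tuple[set[int], set[int]]:
    mol = _ligand_rdkit(ligand)
    if mol is None:
        donors = {i for i, a in enumerate(ligand.atoms)
                  if a.element == "N" and a.formal_charge >= 0}
        acceptors = {i for i, a in enumerate(ligand.atoms)
                     if a.element == "O" and a.formal_charge <= 0}
        return donors, acceptors
    donors = {m[0] for m in mol.GetSubstructMatches(_HBD_SMARTS)}
    acceptors = {m[0] for m in mol.GetSubstructMatches(_HBA_SMARTS)}
    return donors, acceptors


def _ligand_apolar_carbons(ligand: LigandMolecule) -> set[int]:
    """Carbons bonded only to carbon (hydrogens are implicit/stripped)."""
    out = set()
    for i, atom in enumerate(ligand.atoms):
        if atom.element != "C" or atom.formal_charge != 0:
            continue
        if all(ligand.atoms[j].element in ("C", "H") for j in ligand.neighbors(i)):
            out.add(i)
    return out


def _ligand_charged_groups(ligand: LigandMolecule) -> list[tuple[list[int], int]]:
    """Charged groups: each charged atom plus resonance-equivalent oxygens."""
    groups: list[tuple[list[int], int]] = []
    seen: set[int] = set()
    for i, atom in enumerate(ligand.atoms):
        if atom.formal_charge == 0 or i in seen:
            continue
        members = {i}
        if atom.element == "O":
            # carboxylate-like: include sibling oxygens on the same carbon
            for c in ligand.neighbors(i):
                if ligand.atoms[c].element == "C":
                    for o in ligand.neighbors(c):
                        if ligand.atoms[o].element == "O":
                            members.add(o)
        seen |= members
        groups.append((sorted(members), 1 if atom.formal_charge > 0 else -1))
    return groups


def _ligand_aromatic_rings(ligand: LigandMolecule) -> list[list[int]]:
    mol = _ligand_rdkit(ligand)
    rings: list[list[int]] = []
    if mol is not None:
        for ring in mol.GetRingInfo().AtomRings():
            if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
                rings.append(sorted(ring))
    else:
        # fallback on stored aromatic flags: connected aromatic components
        import networkx as nx

        g = nx.Graph()
        arom = [i for i, a in enumerate(ligand.atoms) if a.is_aromatic]
        g.add_nodes_from(arom)
        g.add_edges_from(
            (i, j) for i, j, _ in ligand.bonds
            if i in set(arom) and j in set(arom)
        )
        rings = [sorted(c) for c in nx.connected_components(g) if len(c) >= 5]
    return rings


def _ring_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of a ring (least-squares plane)."""
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[2]


def _protein_charged_groups(pocket: ProteinPocket) -> list[tuple[list[int], int]]:
    groups: dict[tuple[str, int, int], list[int]] = {}
    for i in range(len(pocket)):
        res = pocket.residue_name[i]
        spec = _CHARGED_GROUPS.get(res)
        if spec and pocket.atom_name[i] in spec[0]:
            key = (pocket.chain_id[i], pocket.residue_number[i], spec[1])
            groups.setdefault(key, []).append(i)
    return [(sorted(v), k[2]) for k, v in sorted(groups.items())]


def _protein_aromatic_rings(pocket: ProteinPocket) -> list[list[int]]:
    rings: list[list[int]] = []
    by_res: dict[tuple[str, int, str], dict[str, int]] = {}
    for i in range(len(pocket)):
        key = (pocket.chain_id[i], pocket.residue_number[i], pocket.residue_name[i])
        by_res.setdefault(key, {})[pocket.atom_name[i]] = i
    for (chain, num, res), atom_map in sorted(by_res.items()):
        for ring_names in _AROMATIC_RINGS.get(res, []):
            if all(n in atom_map for n in ring_names):
                rings.append([atom_map[n] for n in ring_names])
    return rings


# ---------------------------------------------------------------------------
# Geometric detection
# ---------------------------------------------------------------------------

def detect_interactions(
    pocket: ProteinPocket,
    ligand: LigandMolecule,
    thresholds: ProfilerThresholds = DEFAULT_THRESHOLDS,
) -> list[DetectedInteraction]:
    """Detect hydrogen bonds, hydrophobic contacts, salt bridges and
    pi-stackings between a pocket and a bound ligand.

    Purely geometric and deterministic; output sorted by (type, distance).
    H-bond donor angles are checked only when explicit donor hydrogens are
    present (crystal structures usually lack them); heavy-atom distance is
    the criterion otherwise.  Atom pairs belonging to opposite formally
    charged groups are counted as salt bridges, not hydrogen bonds.
    """
    p_coords = pocket.coords
    l_coords = ligand.coords
    th = thresholds
    out: list[DetectedInteraction] = []

    p_charged = _protein_charged_groups(pocket)
    l_charged = _ligand_charged_groups(ligand)
    p_charged_atoms = {i for grp, _ in p_charged for i in grp}
    l_charged_atoms = {i for grp, _ in l_charged for i in grp}

    # --- hydrogen bonds ---------------------------------------------------
    p_donors, p_acceptors = set(), set()
    for i in range(len(pocket)):
        classes = _protein_atom_classes(pocket, i)
        if InteractionClass.HB_DONOR in classes:
            p_donors.add(i)
        if InteractionClass.HB_ACCEPTOR in classes:
            p_acceptors.add(i)
    l_donors, l_acceptors = _ligand_donors_acceptors(ligand)

    hb_hits: set[tuple[int, int, str]] = set()
    for p_set, l_set, role in ((p_donors, l_acceptors, "donor"),
                               (p_acceptors, l_donors, "acceptor")):
        for pi in sorted(p_set):
            if pi in p_charged_atoms:
                # skip protein charged-group atoms paired with ligand
                # opposite charges: handled as salt bridges below
                pass
            for li in sorted(l_set):
                if pi in p_charged_atoms and li in l_charged_atoms:
                    continue
                d = float(np.linalg.norm(p_coords[pi] - l_coords[li]))
                if d <= th.hbond_dist_max and (pi, li, role) not in hb_hits:
                    angle = _donor_angle(pocket, ligand, pi, li, role)
                    if angle is not None and angle < th.hbond_angle_min:
                        continue
                    hb_hits.add((pi, li, role))
                    out.append(DetectedInteraction(
                        itype=InteractionType.HBOND,
                        protein_atom_indices=[pi],
                        ligand_atom_indices=[li],
                        distance=d,
                        angle=angle,
                        protein_role=role,
                    ))

    # --- hydrophobic contacts ----------------------------------------------
    p_apolar = sorted(
        i for i in range(len(pocket))
        if pocket.atom_name[i] in _APOLAR_CARBONS.get(pocket.residue_name[i], ())
    )
    l_apolar = sorted(_ligand_apolar_carbons(ligand))
    if p_apolar and l_apolar:
        dm = cdist(p_coords[p_apolar], l_coords[l_apolar])
        for a, pi in enumerate(p_apolar):
            for b, li in enumerate(l_apolar):
                if dm[a, b] <= th.hydrophobic_dist_max:
                    out.append(DetectedInteraction(
                        itype=InteractionType.HYDROPHOBIC,
                        protein_atom_indices=[pi],
                        ligand_atom_indices=[li],
                        distance=float(dm[a, b]),
                    ))

    # --- salt bridges -------------------------------------------------------
    for p_grp, p_sign in p_charged:
        for l_grp, l_sign in l_charged:
            if p_sign * l_sign >= 0:
                continue
            pc = p_coords[p_grp].mean(axis=0)
            lc = l_coords[l_grp].mean(axis=0)
            d = float(np.linalg.norm(pc - lc))
            if d <= th.saltbridge_dist_max:
                out.append(DetectedInteraction(
                    itype=InteractionType.SALT_BRIDGE,
                    protein_atom_indices=list(p_grp),
                    ligand_atom_indices=list(l_grp),
                    distance=d,
                    protein_role="anion" if p_sign < 0 else "cation",
                ))

    # --- pi-pi stacking -----------------------------------------------------
    for p_ring in _protein_aromatic_rings(pocket):
        p_cent, p_norm = _ring_plane(p_coords[p_ring])
        for l_ring in _ligand_aromatic_rings(ligand):
            l_cent, l_norm = _ring_plane(l_coords[l_ring])
            d = float(np.linalg.norm(p_cent - l_cent))
            if d > th.pistack_dist_max:
                continue
            cosang = abs(float(np.dot(p_norm, l_norm)))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            parallel = angle <= th.pistack_parallel_angle_max
            tshaped = th.pistack_tshape_angle_min <= angle <= th.pistack_tshape_angle_max
            if parallel or tshaped:
                out.append(DetectedInteraction(
                    itype=InteractionType.PI_STACK,
                    protein_atom_indices=sorted(p_ring),
                    ligand_atom_indices=sorted(l_ring),
                    distance=d,
                    angle=angle,
                ))

    out.sort(key=lambda x: (int(x.itype), x.distance, x.protein_atom_indices))
    return out


def _donor_angle(
    pocket: ProteinPocket, ligand: LigandMolecule, pi: int, li: int, role: str
) -> float | None:
    """Donor-H...acceptor angle in degrees, or None when no explicit H."""
    if role == "acceptor":
        # ligand donates: look for an explicit H bonded to the ligand donor
        donor_pos, acceptor_pos = ligand.coords[li], pocket.coords[pi]
        h_positions = [
            ligand.coords[j] for j in ligand.neighbors(li)
            if ligand.atoms[j].element == "H"
        ]
    else:
        # protein donates: explicit protein hydrogens are rare; none tracked
        return None
    best = None
    for h in h_positions:
        v1 = donor_pos - h
        v2 = acceptor_pos - h
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        best = ang if best is None else max(best, ang)
    return best


# ---------------------------------------------------------------------------
# Conditions and fingerprints from detected interactions
# ---------------------------------------------------------------------------

_TYPE_TO_CLASS = {
    InteractionType.HYDROPHOBIC: InteractionClass.HYDROPHOBIC,
    InteractionType.PI_STACK: InteractionClass.AROMATIC,
}


def condition_from_interactions(
    pocket: ProteinPocket, interactions: list[DetectedInteraction]
) -> np.ndarray:
    """Reference-based condition: protein atoms get the class matching the
    role they play in a detected interaction; the rest are NON_INTERACTING.

    Multi-matched atoms resolve by :data:`CLASS_PRIORITY`.
    """
    per_atom: dict[int, set[InteractionClass]] = {}
    for inter in interactions:
        if inter.itype == InteractionType.HBOND:
            cls = (InteractionClass.HB_DONOR if inter.protein_role == "donor"
                   else InteractionClass.HB_ACCEPTOR)
        elif inter.itype == InteractionType.SALT_BRIDGE:
            cls = (InteractionClass.ANION if inter.protein_role == "anion"
                   else InteractionClass.CATION)
        else:
            cls = _TYPE_TO_CLASS[inter.itype]
        for i in inter.protein_atom_indices:
            if not (0 <= i < len(pocket)):
                raise IndexError(
                    f"interaction references protein atom {i} of {len(pocket)}"
                )
            per_atom.setdefault(i, set()).add(cls)
    cond = np.zeros((len(pocket), N_CLASSES), dtype=float)
    for i in range(len(pocket)):
        cond[i, _resolve_priority(per_atom.get(i, set()))] = 1.0
    return cond


def interaction_fingerprint(
    pocket: ProteinPocket, interactions: list[DetectedInteraction]
) -> np.ndarray:
    """Binary fingerprint, 4 bits per pocket atom in pocket-atom order.

    Bit (4*j + k) is set iff atom j participates in interaction type k
    (HBOND, HYDROPHOBIC, SALT_BRIDGE, PI_STACK).  An atom involved in
    several types sets several bits; non-interacting atoms contribute
    all-zero blocks.
    """
    fp = np.zeros(N_TYPES * len(pocket), dtype=int)
    for inter in interactions:
        for i in inter.protein_atom_indices:
            if not (0 <= i < len(pocket)):
                raise IndexError(
                    f"interaction references protein atom {i} of {len(pocket)}"
                )
            fp[N_TYPES * i + int(inter.itype)] = 1
    return fp


def interaction_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity between two interaction fingerprints of one target.

    Returns 0.0 when either fingerprint is all-zero (convention), so the
    value always lies in [0, 1] for binary fingerprints.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise TargetMismatchError(
            f"fingerprint lengths differ ({a.size} vs {b.size}); "
            "similarity is defined only for one target's atom order"
        )
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


# ---------------------------------------------------------------------------
# Text serialization (TSV)
# ---------------------------------------------------------------------------

def condition_to_tsv(pocket: ProteinPocket, cond: np.ndarray) -> str:
    cond = validate_condition(cond, pocket)
    header = ["chain", "residue_number", "residue_name", "atom_name", "element"]
    header += [cls.name for cls in InteractionClass]
    lines = ["\t".join(header)]
    for i in range(len(pocket)):
        row = [
            pocket.chain_id[i], str(pocket.residue_number[i]),
            pocket.residue_name[i], pocket.atom_name[i], pocket.atoms[i].element,
        ] + [str(int(v)) for v in cond[i]]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def condition_from_tsv(text: str, pocket: ProteinPocket) -> np.ndarray:
    """Parse a condition matrix written by :func:`condition_to_tsv`."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    class_cols = [header.index(cls.name) for cls in InteractionClass]
    rows = []
    for line in lines[1:]:
        fields = line.split("\t")
        rows.append([float(fields[c]) for c in class_cols])
    return validate_condition(np.array(rows, dtype=float), pocket)


def interactions_to_tsv(
    pocket: ProteinPocket, interactions: list[DetectedInteraction]
) -> str:
    header = ["type", "residue", "protein_atoms", "ligand_atoms",
              "distance_A", "angle_deg", "protein_role"]
    lines = ["\t".join(header)]
    for inter in interactions:
        i0 = inter.protein_atom_indices[0]
        residue = (f"{pocket.chain_id[i0]}:{pocket.residue_name[i0]}"
                   f"{pocket.residue_number[i0]}")
        lines.append("\t".join([
            inter.itype.name,
            residue,
            ",".join(pocket.atom_name[i] for i in inter.protein_atom_indices),
            ",".join(str(i) for i in inter.ligand_atom_indices),
            f"{inter.distance:.3f}",
            "" if inter.angle is None else f"{inter.angle:.1f}",
            inter.protein_role or "",
        ]))
    return "\n".join(lines) + "\n"
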