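"""Structure I/O, pocket extraction, and atom featurization.

Proteins travel as :class:`ProteinPocket` (PDB-backed, ordered atoms with
residue metadata); ligands as :class:`LigandMolecule` (SDF-backed, atoms +
bonds).  Atom order is load-bearing everywhere downstream: interaction
conditions and fingerprints are per-atom vectors indexed in pocket order.

Element vocabularies:

* ligand: C, N, O, F, P, S, Cl, Br, I (common drug elements);
* protein: C, N, O, S, P, Se plus a catch-all ``other`` bucket for metals
  and anything else (mapped with a warning).

Feature rows are concatenated one-hot/binary blocks, in order:
element one-hot | charge-sign one-hot (neg/zero/pos) | aromatic bit |
ring bit.  Protein rows additionally reserve a zeroed 7-wide interaction
condition block that the profiler fills in later.  The block layout is
versioned via :data:`FEATURE_LAYOUT_VERSION`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
from rdkit import Chem
from scipy.spatial.distance import cdist

from pocketforge.errors import (
    DimensionalityError,
    ElementError,
    EmptyPocketError,
    ParseError,
)

FEATURE_LAYOUT_VERSION = "1"

LIGAND_ELEMENTS: tuple[str, ...] = ("C", "N", "O", "F", "P", "S", "Cl", "Br", "I")
PROTEIN_ELEMENTS: tuple[str, ...] = ("C", "N", "O", "S", "P", "Se", "other")

N_CONDITION_CLASSES = 7

_WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}

#: Covalent radii in Angstrom (Cordero et al. consensus values), used for
#: distance-based connectivity perception.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39, "Se": 1.20,
}


@dataclass
class Atom3D:
    """A single atom: chemical identity plus a Cartesian position in Angstrom."""

    element: str
    position: np.ndarray
    formal_charge: int = 0
    is_aromatic: bool = False
    is_in_ring: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"invalid atom position {self.position!r}")


@dataclass
class ProteinPocket:
    """An ordered set of protein atoms lining a binding site.

    Atom order is stable and shared by every per-atom vector derived from
    the pocket (interaction conditions, fingerprints).
    """

    atoms: list[Atom3D]
    residue_name: list[str]
    residue_number: list[int]
    chain_id: list[str]
    atom_name: list[str]
    source_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for name in ("residue_name", "residue_number", "chain_id", "atom_name"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match atom count")
        keys = list(zip(self.chain_id, self.residue_number, self.atom_name))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, residue_number, atom_name) triple")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def residue_keys(self) -> list[tuple[str, int]]:
        """Per-atom (chain, residue number) keys."""
        return list(zip(self.chain_id, self.residue_number))

    def heavy_indices(self) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.element != "H"], dtype=int
        )

    def subset(self, indices: list[int] | np.ndarray, source_id: str | None = None
               ) -> "ProteinPocket":
        idx = list(indices)
        return ProteinPocket(
            atoms=[self.atoms[i] for i in idx],
            residue_name=[self.residue_name[i] for i in idx],
            residue_number=[self.residue_number[i] for i in idx],
            chain_id=[self.chain_id[i] for i in idx],
            atom_name=[self.atom_name[i] for i in idx],
            source_id=self.source_id if source_id is None else source_id,
        )


@dataclass
class LigandMolecule:
    """A small molecule: ordered atoms plus a covalent bond list.

    Bond orders are 1, 2, 3 or 1.5 (aromatic).  ``validity_warning`` carries
    a human-readable note when the source record violated valence rules but
    was read anyway.
    """

    atoms: list[Atom3D]
    bonds: list[tuple[int, int, float]] = field(default_factory=list)
    is_fragment_set: bool = False
    validity_warning: str | None = None

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) index out of range for {n} atoms")
            if i == j:
                raise ValueError(f"self-loop bond on atom {i}")
            if order not in (1, 2, 3, 1.5):
                raise ValueError(f"unsupported bond order {order!r}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def is_connected(self) -> bool:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(len(self.atoms)))
        g.add_edges_from((i, j) for i, j, _ in self.bonds)
        return len(self.atoms) == 0 or nx.is_connected(g)

    # -- RDKit bridge -----------------------------------------------------

    _RD_ORDERS = {
        1: Chem.BondType.SINGLE,
        2: Chem.BondType.DOUBLE,
        3: Chem.BondType.TRIPLE,
        1.5: Chem.BondType.AROMATIC,
    }

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, strip_hs: bool = True) -> "LigandMolecule":
        warning = None
        if strip_hs:
            mol = Chem.RemoveHs(mol, sanitize=False)
        try:
            Chem.SanitizeMol(Chem.Mol(mol))
        except Exception as exc:  # carried, not raised: record stays usable
            warning = f"sanitization issue: {exc}"
        conf = mol.GetConformer()
        atoms = []
        for atom in mol.GetAtoms():
            pos = conf.GetAtomPosition(atom.GetIdx())
            atoms.append(
                Atom3D(
                    element=atom.GetSymbol(),
                    position=np.array([pos.x, pos.y, pos.z]),
                    formal_charge=atom.GetFormalCharge(),
                    is_aromatic=atom.GetIsAromatic(),
                    is_in_ring=atom.IsInRing(),
                )
            )
        rev = {v: k for k, v in cls._RD_ORDERS.items()}
        bonds = []
        for bond in mol.GetBonds():
            order = rev.get(bond.GetBondType())
            if order is None:
                order = 1
            if bond.GetIsAromatic():
                order = 1.5
            bonds.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order))
        return cls(atoms=atoms, bonds=bonds, validity_warning=warning)

    def to_rdkit(self, sanitize: bool = True) -> Chem.Mol:
        rw = Chem.RWMol()
        for atom in self.atoms:
            a = Chem.Atom(atom.element)
            a.SetFormalCharge(int(atom.formal_charge))
            rw.AddAtom(a)
        for i, j, order in self.bonds:
            rw.AddBond(int(i), int(j), self._RD_ORDERS[order])
            if order == 1.5:
                rw.GetBondBetweenAtoms(int(i), int(j)).SetIsAromatic(True)
                rw.GetAtomWithIdx(int(i)).SetIsAromatic(True)
                rw.GetAtomWithIdx(int(j)).SetIsAromatic(True)
        conf = Chem.Conformer(len(self.atoms))
        for idx, atom in enumerate(self.atoms):
            conf.SetAtomPosition(idx, [float(x) for x in atom.position])
        mol = rw.GetMol()
        mol.AddConformer(conf)
        if sanitize:
            Chem.SanitizeMol(mol)
        return mol


@dataclass
class FeatureMatrix:
    """Per-atom feature rows: concatenated one-hot / binary blocks."""

    matrix: np.ndarray
    columns: list[str]
    kind: str  # "ligand" | "protein"
    layout_version: str = FEATURE_LAYOUT_VERSION

    @property
    def width(self) -> int:
        return self.matrix.shape[1]


# ---------------------------------------------------------------------------
# PDB side
# ---------------------------------------------------------------------------

def _validate_pdb_lines(path: str) -> None:
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith(("ATOM", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise ParseError(f"{path}:{lineno}: truncated record: {line.rstrip()!r}")
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: unparsable coordinates: {line.rstrip()!r}"
                    ) from exc


def read_pocket(path: str, include_hetero: bool = True) -> ProteinPocket:
    """Read a protein pocket from a PDB file.

    Atoms come back in file order; water records are excluded.  Raises
    :class:`ParseError` (naming the offending line where possible) on
    malformed input and :class:`ElementError` on an unknown element symbol.
    """
    _validate_pdb_lines(path)
    try:
        structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc
    atoms: list[Atom3D] = []
    res_names: list[str] = []
    res_numbers: list[int] = []
    chains: list[str] = []
    atom_names: list[str] = []
    for model in structure:
        for chain in model:
            for residue in chain:
                if residue.name in _WATER_RESNAMES:
                    continue
                if not include_hetero and residue.het_flag == "H":
                    continue
                for atom in residue:
                    symbol = atom.element.name
                    if symbol in ("", "X"):
                        raise ElementError(
                            f"unknown element for atom {atom.name!r} in {residue.name}"
                        )
                    atoms.append(
                        Atom3D(
                            element=symbol,
                            position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        )
                    )
                    res_names.append(residue.name)
                    res_numbers.append(residue.seqid.num)
                    chains.append(chain.name)
                    atom_names.append(atom.name)
        break  # first model only
    if not atoms:
        raise ParseError(f"no ATOM/HETATM records found in {path}")
    return ProteinPocket(
        atoms=atoms,
        residue_name=res_names,
        residue_number=res_numbers,
        chain_id=chains,
        atom_name=atom_names,
        source_id=str(path),
    )


def write_pocket(pocket: ProteinPocket, path: str) -> None:
    """Write a pocket as a PDB file (coordinates at PDB's 1e-3 A precision)."""
    # gemmi's add_* methods copy their argument, so assemble bottom-up:
    # group atoms into residues first, then build the hierarchy once.
    groups: dict[tuple[str, int, str], list[int]] = {}
    chain_order: list[str] = []
    for i in range(len(pocket.atoms)):
        key = (pocket.chain_id[i], pocket.residue_number[i],
               pocket.residue_name[i])
        if key not in groups and key[0] not in chain_order:
            chain_order.append(key[0])
        groups.setdefault(key, []).append(i)

    st = gemmi.Structure()
    st.name = pocket.source_id or "pocket"
    model = gemmi.Model("1")
    for cid in chain_order:
        chain = gemmi.Chain(cid)
        for (gcid, num, name), indices in groups.items():
            if gcid != cid:
                continue
            res = gemmi.Residue()
            res.name = name
            res.seqid = gemmi.SeqId(num, " ")
            for i in indices:
                g_atom = gemmi.Atom()
                g_atom.name = pocket.atom_name[i]
                g_atom.element = gemmi.Element(pocket.atoms[i].element)
                g_atom.pos = gemmi.Position(
                    *[float(x) for x in pocket.atoms[i].position])
                res.add_atom(g_atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# SDF side
# ---------------------------------------------------------------------------

def read_ligand(path: str, strip_hs: bool = True) -> LigandMolecule:
    """Read the first record of an SDF file as a :class:`LigandMolecule`.

    Aromaticity is perceived by RDKit.  2D-only records raise
    :class:`DimensionalityError`; valence problems are carried as a
    ``validity_warning`` on the returned molecule.
    """
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    try:
        mol = next(iter(supplier))
    except StopIteration:
        mol = None
    if mol is None:
        raise ParseError(f"cannot parse SDF file {path}")
    warning = None
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        warning = f"valence/sanitization issue: {exc}"
        Chem.SanitizeMol(
            mol,
            Chem.SanitizeFlags.SANITIZE_ALL
            ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES
            ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE,
            catchErrors=True,
        )
    if mol.GetNumConformers() == 0:
        raise ParseError(f"no coordinates in {path}")
    conf = mol.GetConformer()
    zs = [conf.GetAtomPosition(i).z for i in range(mol.GetNumAtoms())]
    if not conf.Is3D() and all(abs(z) < 1e-9 for z in zs):
        raise DimensionalityError(f"{path} carries 2D-only coordinates")
    lig = LigandMolecule.from_rdkit(mol, strip_hs=strip_hs)
    if warning and not lig.validity_warning:
        lig.validity_warning = warning
    return lig


def write_ligand(ligand: LigandMolecule, path: str, name: str = "ligand") -> None:
    """Write a ligand as a single-record V2000 SDF file."""
    mol = ligand.to_rdkit(sanitize=False)
    mol.SetProp("_Name", name)
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    writer.write(mol)
    writer.close()


# ---------------------------------------------------------------------------
# Pocket extraction
# ---------------------------------------------------------------------------

def extract_pocket(
    full_protein: ProteinPocket, ligand: LigandMolecule, radius: float = 8.0
) -> ProteinPocket:
    """Cut a binding pocket out of a full protein by a whole-residue rule.

    Every atom of any residue that has at least one atom within ``radius``
    Angstrom of any ligand heavy atom is kept, in original order.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    lig_heavy = np.array(
        [a.position for a in ligand.atoms if a.element != "H"], dtype=float
    ).reshape(-1, 3)
    if lig_heavy.shape[0] == 0:
        raise ValueError("ligand has no heavy atoms")
    dmin = cdist(full_protein.coords, lig_heavy).min(axis=1)
    keys = full_protein.residue_keys()
    hit_residues = {keys[i] for i in np.nonzero(dmin <= radius)[0]}
    keep = [i for i, key in enumerate(keys) if key in hit_residues]
    if not keep:
        raise EmptyPocketError(
            f"no residue within {radius} A of the ligand"
        )
    return full_protein.subset(keep)


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------

def _charge_sign_block(charge: int) -> list[float]:
    return [1.0 if charge < 0 else 0.0,
            1.0 if charge == 0 else 0.0,
            1.0 if charge > 0 else 0.0]


def featurize(mol: ProteinPocket | LigandMolecule) -> FeatureMatrix:
    """Encode atoms as rows of one-hot/binary blocks.

    The layout (element one-hot | charge sign | aromatic | ring) encodes no
    absolute position, so the output is invariant under rigid motion of the
    coordinates.  Protein matrices end with a zeroed 7-wide interaction
    condition block that the profiler fills.
    """
    if isinstance(mol, ProteinPocket):
        vocab, kind = PROTEIN_ELEMENTS, "protein"
    elif isinstance(mol, LigandMolecule):
        vocab, kind = LIGAND_ELEMENTS, "ligand"
    else:
        raise TypeError(f"cannot featurize {type(mol).__name__}")

    rows = []
    for atom in mol.atoms:
        element = atom.element
        if element not in vocab:
            if kind == "protein":
                warnings.warn(
                    f"element {element!r} outside protein vocabulary; using 'other'",
                    stacklevel=2,
                )
                element = "other"
            else:
                raise ElementError(f"ligand element {element!r} not in vocabulary")
        one_hot = [1.0 if element == v else 0.0 for v in vocab]
        row = one_hot + _charge_sign_block(atom.formal_charge)
        row += [1.0 if atom.is_aromatic else 0.0, 1.0 if atom.is_in_ring else 0.0]
        if kind == "protein":
            row += [0.0] * N_CONDITION_CLASSES
        rows.append(row)

    columns = [f"element_{v}" for v in vocab]
    columns += ["charge_neg", "charge_zero", "charge_pos", "aromatic", "in_ring"]
    if kind == "protein":
        columns += [f"condition_{k}" for k in range(N_CONDITION_CLASSES)]
    return FeatureMatrix(
        matrix=np.array(rows, dtype=float).reshape(len(mol.atoms), len(columns)),
        columns=columns,
        kind=kind,
    )
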