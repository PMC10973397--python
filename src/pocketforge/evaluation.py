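"""Evaluation metrics: scaffold diversity/novelty, interaction geometry,
and the mutant-selectivity screen.

Scaffold accounting works on Bemis-Murcko scaffolds (ring systems plus
linkers, side chains pruned), canonicalized as stereochemistry-stripped
SMILES.  Acyclic molecules share a single empty-scaffold bucket.
Diversity is unique scaffolds over valid molecules; novelty is the
fraction of unique scaffolds absent from a reference scaffold set.

The selectivity screen applies the thermodynamic rule of thumb that each
1.36 kcal/mol of binding free energy corresponds to a 10-fold change in
inhibitory concentration; the default threshold of 2 x 1.36 = 2.72
kcal/mol therefore marks a 100-fold selectivity window.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from pocketforge.complex_io import LigandMolecule, ProteinPocket
from pocketforge.errors import UndefinedMetricError
from pocketforge.profiler import (
    DetectedInteraction,
    InteractionType,
    ProfilerThresholds,
    DEFAULT_THRESHOLDS,
    detect_interactions,
)

#: kcal/mol of binding free energy per decade of inhibitory concentration
#: (RT·ln10 at room temperature).
KCAL_PER_LOG10_UNIT = 1.36

#: Default selectivity criterion: a 100-fold concentration window.
SELECTIVITY_THRESHOLD = 2 * KCAL_PER_LOG10_UNIT

#: Canonical sentinel for molecules with no ring system.
EMPTY_SCAFFOLD = ""


@dataclass
class ScaffoldReport:
    """Scaffold-level diversity/novelty accounting for a molecule set."""

    n_valid: int
    n_unique_scaffolds: int
    n_novel: int | None = None
    scaffold_counts: Counter = field(default_factory=Counter)

    @property
    def diversity(self) -> float:
        return self.n_unique_scaffolds / self.n_valid

    @property
    def novelty(self) -> float | None:
        if self.n_novel is None:
            return None
        return self.n_novel / self.n_unique_scaffolds


def _as_rdkit(mol) -> Chem.Mol | None:
    if isinstance(mol, Chem.Mol):
        out = Chem.Mol(mol)
    elif isinstance(mol, LigandMolecule):
        try:
            out = mol.to_rdkit(sanitize=False)
        except Exception:
            return None
    elif isinstance(mol, str):
        out = Chem.MolFromSmiles(mol)
        if out is None:
            return None
    else:
        return None
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def is_valid_molecule(mol) -> bool:
    """Validity rule: parses, sanitizes, and is one connected fragment."""
    rd = _as_rdkit(mol)
    if rd is None or rd.GetNumAtoms() == 0:
        return False
    return len(Chem.GetMolFrags(rd)) == 1


def bemis_murcko_scaffold(mol) -> str:
    """Canonical Bemis-Murcko scaffold SMILES (stereo stripped).

    Accepts a :class:`LigandMolecule`, an RDKit mol, or a SMILES string.
    Acyclic molecules map to :data:`EMPTY_SCAFFOLD`.
    """
    rd = _as_rdkit(mol)
    if rd is None:
        raise ValueError("invalid molecule; cannot extract a scaffold")
    Chem.RemoveStereochemistry(rd)
    scaffold = MurckoScaffold.GetScaffoldForMol(rd)
    if scaffold.GetNumAtoms() == 0:
        return EMPTY_SCAFFOLD
    return Chem.MolToSmiles(scaffold)


def scaffold_diversity(mols: list) -> ScaffoldReport:
    """Unique-scaffold fraction among the valid molecules of a set."""
    if not mols:
        raise UndefinedMetricError("diversity undefined for an empty set")
    counts: Counter = Counter()
    n_valid = 0
    for mol in mols:
        if not is_valid_molecule(mol):
            continue
        n_valid += 1
        counts[bemis_murcko_scaffold(mol)] += 1
    if n_valid == 0:
        raise UndefinedMetricError("diversity undefined: no valid molecules")
    return ScaffoldReport(n_valid=n_valid, n_unique_scaffolds=len(counts),
                          scaffold_counts=counts)


def scaffold_novelty(scaffolds: list[str],
                     reference_scaffolds: set[str] | list[str]
                     ) -> ScaffoldReport:
    """Fraction of unique scaffolds absent from the reference set."""
    unique = set(scaffolds)
    reference = set(reference_scaffolds)
    novel = unique - reference
    return ScaffoldReport(
        n_valid=len(scaffolds),
        n_unique_scaffolds=len(unique),
        n_novel=len(novel),
        scaffold_counts=Counter(scaffolds),
    )


def interactions_per_molecule(
    complexes: list[tuple[ProteinPocket, LigandMolecule]],
    thresholds: ProfilerThresholds = DEFAULT_THRESHOLDS,
) -> dict[InteractionType, float]:
    """Mean detected-interaction count per molecule, by type."""
    if not complexes:
        raise UndefinedMetricError("no complexes given")
    totals = {t: 0 for t in InteractionType}
    for pocket, ligand in complexes:
        for inter in detect_interactions(pocket, ligand, thresholds):
            totals[inter.itype] += 1
    return {t: totals[t] / len(complexes) for t in InteractionType}


def interaction_distance_distribution(
    complexes: list[tuple[ProteinPocket, LigandMolecule]],
    itype: InteractionType,
    thresholds: ProfilerThresholds = DEFAULT_THRESHOLDS,
) -> list[float]:
    """Pooled detected-interaction distances (Angstrom) of one type."""
    itype = InteractionType(itype)
    out: list[float] = []
    for pocket, ligand in complexes:
        for inter in detect_interactions(pocket, ligand, thresholds):
            if inter.itype == itype:
                out.append(inter.distance)
    return out


@dataclass
class SelectivityRecord:
    """One molecule's scores toward a target and an off-target (kcal/mol)."""

    molecule_id: str
    score_target: float
    score_offtarget: float
    threshold: float = SELECTIVITY_THRESHOLD

    @property
    def delta(self) -> float:
        return self.score_offtarget - self.score_target

    @property
    def selective(self) -> bool:
        # inclusive boundary: a molecule exactly at the 100-fold window counts
        return self.delta >= self.threshold


def selectivity_screen(
    records: list[tuple[str, float, float]],
    threshold: float = SELECTIVITY_THRESHOLD,
) -> list[SelectivityRecord]:
    """Classify (id, score_target, score_offtarget) triples by selectivity.

    Scores are binding affinities in kcal/mol with lower = stronger;
    a molecule is selective when it binds the target at least ``threshold``
    kcal/mol more strongly than the off-target.
    """
    return [
        SelectivityRecord(molecule_id=str(mid), score_target=float(st),
                          score_offtarget=float(so), threshold=threshold)
        for mid, st, so in records
    ]
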