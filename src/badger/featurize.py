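"""Chemistry and cell-line featurization.

Molecules are decomposed into BRICS fragments; each fragment is hashed to a
folded Morgan (circular) fingerprint.  Cell lines are embedded by their
Spearman rank correlation against a panel of anchor cell lines' basal
expression profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from rdkit import Chem
from rdkit.Chem import BRICS
from rdkit.Chem import rdFingerprintGenerator
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "InvalidMoleculeError", "FragmentSet", "CellSimilarityVector",
    "brics_decompose", "fragment_fingerprints", "featurize_molecule",
    "spearman_correlation", "cell_similarity_vector", "tanimoto",
]

DEFAULT_N_BITS = 1024
DEFAULT_RADIUS = 2


class InvalidMoleculeError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


@dataclass
class FragmentSet:
    """BRICS fragments of one molecule and their fingerprint matrix F (k×bits)."""

    parent_smiles: str
    fragment_smiles: list[str]
    fingerprints: np.ndarray

    def __post_init__(self):
        if len(self.fragment_smiles) < 1:
            raise ValueError("a molecule must yield at least one fragment")
        self.fingerprints = np.asarray(self.fingerprints, dtype=float)
        if self.fingerprints.shape[0] != len(self.fragment_smiles):
            raise ValueError("fingerprint rows must match fragment count")

    @property
    def k(self) -> int:
        return len(self.fragment_smiles)


@dataclass
class CellSimilarityVector:
    """Spearman similarities of one cell line to every anchor cell line."""

    cell_id: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


def _parse(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidMoleculeError(f"cannot parse SMILES {smiles!r}")
    return mol


def brics_decompose(smiles: str) -> list[str]:
    """BRICS fragments of a molecule, in canonical-SMILES lexicographic order.

    A molecule with no BRICS-cleavable bond yields a single fragment: its own
    canonical SMILES.  Attachment points appear as numbered dummy atoms
    (e.g. ``[14*]``) in the fragment SMILES.
    """
    mol = _parse(smiles)
    frags = sorted(BRICS.BRICSDecompose(mol))
    if not frags:
        frags = [Chem.MolToSmiles(mol)]
    return list(frags)


def _strip_dummies(mol: Chem.Mol) -> Chem.Mol:
    """Replace BRICS attachment dummies with hydrogens before hashing, so a
    fragment's fingerprint reflects its chemistry, not its cleavage labels."""
    em = Chem.RWMol(mol)
    for atom in em.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomicNum(1)
            atom.SetIsotope(0)
    out = em.GetMol()
    Chem.SanitizeMol(out)
    return Chem.RemoveHs(out)


def fragment_fingerprints(fragment_smiles: list[str],
                          n_bits: int = DEFAULT_N_BITS,
                          radius: int = DEFAULT_RADIUS) -> np.ndarray:
    """Folded Morgan fingerprints, one 0/1 row per fragment."""
    if n_bits < 64:
        raise ValueError("n_bits must be at least 64")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius,
                                                    fpSize=n_bits)
    rows = np.zeros((len(fragment_smiles), n_bits))
    for i, smi in enumerate(fragment_smiles):
        try:
            mol = _strip_dummies(_parse(smi))
        except InvalidMoleculeError:
            raise InvalidMoleculeError(
                f"cannot parse fragment {i} ({smi!r})") from None
        fp = gen.GetFingerprint(mol)
        rows[i, list(fp.GetOnBits())] = 1.0
    return rows


def featurize_molecule(smiles: str, n_bits: int = DEFAULT_N_BITS,
                       radius: int = DEFAULT_RADIUS) -> FragmentSet:
    """BRICS decomposition + per-fragment Morgan fingerprints."""
    frags = brics_decompose(smiles)
    return FragmentSet(parent_smiles=smiles, fragment_smiles=frags,
                       fingerprints=fragment_fingerprints(frags, n_bits,
                                                          radius))


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient of two binary fingerprint vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def spearman_correlation(x, y) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("inputs must be equal-length 1-D vectors, length ≥ 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def cell_similarity_vector(cell_id: str, basal_profile,
                           anchor_profiles: pd.DataFrame
                           ) -> CellSimilarityVector:
    """Similarity embedding of one cell line against the anchor panel.

    ``anchor_profiles`` is a genes × anchor-cells frame; ``basal_profile``
    must be indexed by the same genes (a Series) or be a plain vector in the
    same gene order.
    """
    if isinstance(basal_profile, pd.Series):
        if not basal_profile.index.equals(anchor_profiles.index):
            if set(basal_profile.index) != set(anchor_profiles.index):
                raise ValueError("basal profile gene set differs from anchors")
            basal_profile = basal_profile.reindex(anchor_profiles.index)
        vec = basal_profile.to_numpy(dtype=float)
    else:
        vec = np.asarray(basal_profile, dtype=float)
        if vec.shape[0] != anchor_profiles.shape[0]:
            raise ValueError("basal profile length differs from anchor genes")
    values = np.array([
        spearman_correlation(vec, anchor_profiles[c].to_numpy(dtype=float))
        for c in anchor_profiles.columns])
    return CellSimilarityVector(cell_id=cell_id, values=values)
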