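"""Thin RDKit layer shared by the replay buffer, shaping, and metrics.

Everything chemistry-aware in the package funnels through these helpers so
the rest of the code deals only in canonical SMILES strings and numpy
fingerprint vectors. RDKit logging is silenced: the RL loop routinely emits
syntactically broken strings and per-molecule parse warnings would swamp
the training log.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors
from rdkit.Chem.Scaffolds import MurckoScaffold
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

_MORGAN_CACHE: dict[tuple[int, int], object] = {}


def mol_from_smiles(smiles: str):
    """Parse a SMILES string; returns None for invalid input."""
    if not smiles:
        return None
    return Chem.MolFromSmiles(smiles)


def is_valid(smiles: str) -> bool:
    return mol_from_smiles(smiles) is not None


def canonical_smiles(smiles: str) -> str | None:
    """Canonical form of a SMILES string, or None if unparseable."""
    mol = mol_from_smiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def murcko_scaffold(smiles: str) -> str | None:
    """Bemis-Murcko framework as canonical SMILES ('' for acyclic molecules)."""
    mol = mol_from_smiles(smiles)
    if mol is None:
        return None
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaffold)


def _generator(radius: int, n_bits: int):
    key = (radius, n_bits)
    if key not in _MORGAN_CACHE:
        _MORGAN_CACHE[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits
        )
    return _MORGAN_CACHE[key]


def morgan_fingerprint(smiles: str, radius: int = 2, n_bits: int = 2048) -> np.ndarray | None:
    """Binary hashed circular fingerprint as a float64 vector, or None."""
    mol = mol_from_smiles(smiles)
    if mol is None:
        return None
    fp = _generator(radius, n_bits).GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.float64)
    for bit in fp.GetOnBits():
        arr[bit] = 1.0
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity between two binary fingerprint vectors."""
    inter = float(np.dot(a, b))
    union = float(a.sum() + b.sum() - inter)
    if union == 0.0:
        return 1.0
    return inter / union


def ring_count(smiles: str) -> int | None:
    mol = mol_from_smiles(smiles)
    if mol is None:
        return None
    return int(mol.GetRingInfo().NumRings())


def basic_properties(smiles: str) -> dict[str, float] | None:
    """Molecular weight, Crippen LogP, rotatable-bond count."""
    mol = mol_from_smiles(smiles)
    if mol is None:
        return None
    return {
        "mol_weight": float(Descriptors.MolWt(mol)),
        "logp": float(Crippen.MolLogP(mol)),
        "rotatable_bonds": float(Descriptors.NumRotatableBonds(mol)),
    }


def matches_smarts(smiles: str, smarts_patterns: list[str]) -> bool:
    """True if the molecule matches any of the SMARTS alerts."""
    mol = mol_from_smiles(smiles)
    if mol is None:
        return False
    for pattern in smarts_patterns:
        query = Chem.MolFromSmarts(pattern)
        if query is None:
            raise ValueError(f"invalid SMARTS pattern: {pattern!r}")
        if mol.HasSubstructMatch(query):
            return True
    return False
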