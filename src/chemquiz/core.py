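"""Molecular substrate for the benchmark.

Molecules are plain RDKit ``Mol`` objects, sanitized and stereo-stripped on
ingestion so that every downstream ground truth is a function of the 2D
molecular graph alone.  This module provides SMILES parsing, the three
string-variant writers (canonical / randomized / semicanonical) with their
atom-order bookkeeping, small graph utilities, and the two bundled fixture
molecule libraries that stand in for external compound collections.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

Molecule = Chem.Mol

SmilesMode = Literal["canonical", "randomized", "semicanonical"]


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed and sanitized."""


class NoPathError(ValueError):
    """Raised when two atoms lie in different fragments of a molecule."""


@dataclass(frozen=True)
class SmilesVariant:
    """A SMILES string together with its atom-appearance order.

    ``order_map[i]`` is the atom id (in the reference molecule) of the i-th
    heavy atom written in ``text``.  Position indices are 0-based here; prompt
    text uses 1-based positions and converts exactly once at the boundary.
    """

    text: str
    order_map: tuple[int, ...]
    mode: SmilesMode

    def position_of_atom(self, atom_id: int) -> int:
        return self.order_map.index(atom_id)


@dataclass(frozen=True)
class MoleculeLibrary:
    name: str
    molecules: tuple[Molecule, ...]
    provenance: str

    def __len__(self) -> int:
        return len(self.molecules)

    def __iter__(self):
        return iter(self.molecules)

    def __getitem__(self, i: int) -> Molecule:
        return self.molecules[i]


def parse_smiles(text: str) -> Molecule:
    """Parse and sanitize a SMILES string, stripping stereochemistry.

    Raises :class:`InvalidSmilesError` on any syntax or valence problem; the
    scorer catches this and treats the answer as wrong rather than crashing.
    """
    if not isinstance(text, str) or not text.strip():
        raise InvalidSmilesError(f"empty or non-string SMILES: {text!r}")
    mol = Chem.MolFromSmiles(text.strip())
    if mol is None:
        raise InvalidSmilesError(f"unparseable SMILES: {text!r}")
    Chem.RemoveStereochemistry(mol)
    return mol


def try_parse_smiles(text: str) -> Molecule | None:
    try:
        return parse_smiles(text)
    except InvalidSmilesError:
        return None


def canonical_smiles(mol: Molecule) -> str:
    return Chem.MolToSmiles(mol)


def _output_order(mol: Molecule) -> list[int]:
    # set by RDKit's SMILES writer on the molecule it was called with
    return list(mol.GetPropsAsDict(True, True)["_smilesAtomOutputOrder"])


def canonical_variant(mol: Molecule) -> SmilesVariant:
    text = Chem.MolToSmiles(mol)
    return SmilesVariant(text, tuple(_output_order(mol)), "canonical")


def randomized_smiles(mol: Molecule, seed: int) -> SmilesVariant:
    """Write the molecule with a seeded random atom traversal order."""
    rng = np.random.default_rng(seed)
    perm = [int(x) for x in rng.permutation(mol.GetNumAtoms())]
    shuffled = Chem.RenumberAtoms(mol, perm)
    text = Chem.MolToSmiles(shuffled, canonical=False)
    # shuffled atom j is reference atom perm[j]
    order_map = tuple(perm[j] for j in _output_order(shuffled))
    return SmilesVariant(text, order_map, "randomized")


def semicanonical_smiles(mol: Molecule, seed: int) -> SmilesVariant:
    """Root the canonical traversal at a seeded random atom.

    The string starts on a random atom but follows the canonical atom
    ranking thereafter, so large substructures keep their canonical spelling.
    """
    rng = np.random.default_rng(seed)
    root = int(rng.integers(mol.GetNumAtoms()))
    text = Chem.MolToSmiles(mol, rootedAtAtom=root)
    return SmilesVariant(text, tuple(_output_order(mol)), "semicanonical")


def smiles_variant(mol: Molecule, mode: SmilesMode, seed: int = 0) -> SmilesVariant:
    if mode == "canonical":
        return canonical_variant(mol)
    if mode == "randomized":
        return randomized_smiles(mol, seed)
    if mode == "semicanonical":
        return semicanonical_smiles(mol, seed)
    raise ValueError(f"unknown SMILES mode: {mode}")


def graph_distance(mol: Molecule, a: int, b: int) -> int:
    """Number of bonds on the shortest path between atoms ``a`` and ``b``."""
    if a == b:
        raise ValueError("atoms must be distinct")
    path = Chem.GetShortestPath(mol, a, b)
    if not path:
        raise NoPathError(f"atoms {a} and {b} are in different fragments")
    return len(path) - 1


def cycle_rank(mol: Molecule) -> int:
    """Number of independent rings: bonds - atoms + fragments."""
    n_frags = len(Chem.GetMolFrags(mol))
    return mol.GetNumBonds() - mol.GetNumAtoms() + n_frags


def heavy_atom_count(mol: Molecule) -> int:
    return mol.GetNumHeavyAtoms()


def element_count(mol: Molecule, element: str) -> int:
    if element == "H":
        return sum(a.GetTotalNumHs() for a in mol.GetAtoms()) + sum(
            1 for a in mol.GetAtoms() if a.GetSymbol() == "H"
        )
    return sum(1 for a in mol.GetAtoms() if a.GetSymbol() == element)


def molecular_formula(mol: Molecule) -> str:
    """Hill-notation molecular formula (C, H, then alphabetical)."""
    return rdMolDescriptors.CalcMolFormula(mol)


def _load_library(filename: str, name: str, provenance: str) -> MoleculeLibrary:
    ref = resources.files("chemquiz.data").joinpath(filename)
    if not ref.is_file():
        raise FileNotFoundError(f"fixture library missing: {filename}")
    mols = []
    for line in ref.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        mols.append(parse_smiles(line))
    return MoleculeLibrary(name, tuple(mols), provenance)


@functools.lru_cache(maxsize=None)
def druglike_library() -> MoleculeLibrary:
    """Bundled drug-like molecules, 10-30 heavy atoms, organic-subset elements."""
    return _load_library(
        "druglike.smi",
        "druglike",
        "synthetic drug-like set assembled combinatorially from common "
        "pharmacophore scaffolds and substituents (stands in for a ZINC sample)",
    )


@functools.lru_cache(maxsize=None)
def small_molecule_library() -> MoleculeLibrary:
    """Bundled C/H/N/O molecules of at most 10 heavy atoms."""
    return _load_library(
        "small_chno.smi",
        "small_chno",
        "enumerated simple C/H/N/O organic molecules of <= 10 heavy atoms",
    )


def library_subset(
    lib: MoleculeLibrary, predicate, name: str | None = None
) -> MoleculeLibrary:
    kept = tuple(m for m in lib if predicate(m))
    return MoleculeLibrary(name or lib.name, kept, lib.provenance)
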