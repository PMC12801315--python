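"""SMILES-to-IUPAC-name question construction.

Three sub-benchmarks: (1) drug-like molecules sampled from the bundled
library, (2) a functional-group diagnostic -- six distinct groups from a
40-entry library attached to one benzene ring, and (3) a locant diagnostic --
three halogens placed on benzene, pyridine, naphthalene or quinoline.

Ground truth is always the structure (canonical SMILES), never a preferred
name string: the scorer judges an answer by parsing the submitted name to a
structure and comparing graphs.  Constructed diagnostics are validated at
build time by round-tripping a systematic name of the construction recipe
through the name parser; draws that fail are resampled.
"""

from __future__ import annotations

from collections import Counter
from typing import Literal

import numpy as np
from rdkit import Chem

from . import core
from .nameparse import (
    _PARENTS,
    SUBSTITUENT_SMILES,
    BuiltinParser,
    attach_fragment,
)
from .records import ANSWER_INSTRUCTION, QuestionRecord

# The 40-entry functional group library: (prefix name, fragment SMILES with
# attachment at atom 0).  Every entry attaches to an aromatic carbon and
# yields a sanitizable molecule.
FUNCTIONAL_GROUPS: tuple[tuple[str, str], ...] = (
    ("fluoro", "F"),
    ("chloro", "Cl"),
    ("bromo", "Br"),
    ("iodo", "I"),
    ("methyl", "C"),
    ("ethyl", "CC"),
    ("propyl", "CCC"),
    ("isopropyl", "C(C)C"),
    ("butyl", "CCCC"),
    ("tert-butyl", "C(C)(C)C"),
    ("ethenyl", "C=C"),
    ("prop-2-en-1-yl", "CC=C"),
    ("ethynyl", "C#C"),
    ("phenyl", "c1ccccc1"),
    ("benzyl", "Cc1ccccc1"),
    ("hydroxy", "O"),
    ("methoxy", "OC"),
    ("ethoxy", "OCC"),
    ("phenoxy", "Oc1ccccc1"),
    ("trifluoromethoxy", "OC(F)(F)F"),
    ("amino", "N"),
    ("methylamino", "NC"),
    ("dimethylamino", "N(C)C"),
    ("acetamido", "NC(C)=O"),
    ("nitro", "[N+](=O)[O-]"),
    ("cyano", "C#N"),
    ("trifluoromethyl", "C(F)(F)F"),
    ("formyl", "C=O"),
    ("acetyl", "C(C)=O"),
    ("carboxy", "C(=O)O"),
    ("methoxycarbonyl", "C(=O)OC"),
    ("ethoxycarbonyl", "C(=O)OCC"),
    ("carbamoyl", "C(=O)N"),
    ("methylcarbamoyl", "C(=O)NC"),
    ("dimethylcarbamoyl", "C(=O)N(C)C"),
    ("methylsulfonyl", "S(C)(=O)=O"),
    ("sulfamoyl", "S(N)(=O)=O"),
    ("methylsulfanyl", "SC"),
    ("hydroxymethyl", "CO"),
    ("aminomethyl", "CN"),
)

HALOGENS = ("fluoro", "chloro", "bromo", "iodo")

LocantScaffold = Literal["benzene", "pyridine", "naphthalene", "quinoline"]

_NAME_PROMPT = (
    "Write an IUPAC name for the molecule with SMILES string {smiles}\n"
    "Any valid systematic name for this structure is accepted.\n" + ANSWER_INSTRUCTION
)


def _recipe_name(placements: list[tuple[str, str]], parent: str) -> str:
    """Systematic name of a prefix-substituted parent from (locant, group) pairs.

    Groups are ordered alphabetically; repeated groups get a multiplying
    prefix with combined locants, e.g. 1,3-dichloro-5-bromo... -> but ordered
    alphabetically (bromo before chloro).
    """
    by_group: dict[str, list[str]] = {}
    for loc, group in placements:
        by_group.setdefault(group, []).append(loc)
    mult = {2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}
    parts = []
    for group in sorted(by_group):
        locs = sorted(by_group[group], key=lambda s: (len(s), s))
        prefix = mult.get(len(locs), "")
        parts.append(f"{','.join(locs)}-{prefix}{group}")
    return "-".join(parts) + parent


def _scaffold_positions(parent: str) -> tuple[Chem.Mol, list[tuple[str, int]]]:
    smiles, labels = _PARENTS[parent]
    mol = Chem.MolFromSmiles(smiles)
    positions = [
        (labels[a.GetIdx()], a.GetIdx())
        for a in mol.GetAtoms()
        if a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1
    ]
    return mol, positions


def build_hexasubstituted_benzene(
    seed: int, max_retries: int = 50
) -> tuple[core.Molecule, str]:
    """Attach six distinct library groups to the six benzene positions.

    Returns the molecule and a systematic reference name of the recipe.
    Draws whose product fails sanitization or whose reference name does not
    round-trip to the product are redrawn (bounded retries).
    """
    rng = np.random.default_rng(seed)
    parser = BuiltinParser()
    for _ in range(max_retries):
        picks = rng.choice(len(FUNCTIONAL_GROUPS), size=6, replace=False)
        scaffold, positions = _scaffold_positions("benzene")
        mol = scaffold
        placements = []
        ok = True
        for (label, idx), k in zip(positions, picks):
            name, frag = FUNCTIONAL_GROUPS[int(k)]
            nxt = attach_fragment(mol, idx, frag)
            if nxt is None:
                ok = False
                break
            mol = nxt
            placements.append((label, name))
        if not ok:
            continue
        Chem.RemoveStereochemistry(mol)
        ref_name = _recipe_name(placements, "benzene")
        named = parser.parse(ref_name)
        if named is None or Chem.MolToSmiles(Chem.MolFromSmiles(named)) != (
            core.canonical_smiles(mol)
        ):
            continue
        return mol, ref_name
    raise RuntimeError("could not build a hexasubstituted benzene")


def build_halogen_locant_molecule(
    scaffold: LocantScaffold, seed: int
) -> tuple[core.Molecule, str]:
    """Place three halogens (drawn with replacement) on distinct CH positions."""
    rng = np.random.default_rng(seed)
    parser = BuiltinParser()
    for _ in range(50):
        base, positions = _scaffold_positions(scaffold)
        sites = [positions[int(i)] for i in rng.choice(len(positions), 3, replace=False)]
        halos = [HALOGENS[int(i)] for i in rng.integers(len(HALOGENS), size=3)]
        mol = base
        placements = []
        ok = True
        for (label, idx), halo in zip(sites, halos):
            nxt = attach_fragment(mol, idx, SUBSTITUENT_SMILES[halo])
            if nxt is None:
                ok = False
                break
            mol = nxt
            placements.append((label, halo))
        if not ok:
            continue
        Chem.RemoveStereochemistry(mol)
        ref_name = _recipe_name(placements, scaffold)
        named = parser.parse(ref_name)
        if named is None or Chem.MolToSmiles(Chem.MolFromSmiles(named)) != (
            core.canonical_smiles(mol)
        ):
            continue
        return mol, ref_name
    raise RuntimeError(f"could not build a halogenated {scaffold}")


def gen_iupac_sample_question(
    mol: core.Molecule,
    smiles_mode: Literal["canonical", "randomized"],
    seed: int,
    qid: str,
) -> QuestionRecord:
    variant = core.smiles_variant(mol, smiles_mode, seed=seed)
    return QuestionRecord(
        id=qid,
        category="iupac_zinc",
        prompt=_NAME_PROMPT.format(smiles=variant.text),
        truth=core.canonical_smiles(mol),
        meta={
            "seed": seed,
            "source_smiles": core.canonical_smiles(mol),
            "smiles_mode": smiles_mode,
        },
    )


def gen_iupac_fg_question(seed: int, qid: str) -> QuestionRecord:
    mol, ref_name = build_hexasubstituted_benzene(seed)
    return QuestionRecord(
        id=qid,
        category="iupac_fg",
        prompt=_NAME_PROMPT.format(smiles=core.canonical_smiles(mol)),
        truth=core.canonical_smiles(mol),
        meta={
            "seed": seed,
            "source_smiles": core.canonical_smiles(mol),
            "smiles_mode": "canonical",
            "reference_name": ref_name,
        },
    )


def gen_iupac_locant_question(
    scaffold: LocantScaffold, seed: int, qid: str
) -> QuestionRecord:
    mol, ref_name = build_halogen_locant_molecule(scaffold, seed)
    return QuestionRecord(
        id=qid,
        category="iupac_locant",
        prompt=_NAME_PROMPT.format(smiles=core.canonical_smiles(mol)),
        truth=core.canonical_smiles(mol),
        meta={
            "seed": seed,
            "source_smiles": core.canonical_smiles(mol),
            "smiles_mode": "canonical",
            "scaffold": scaffold,
            "reference_name": ref_name,
        },
    )


def substituent_count_on_ring(mol: core.Molecule) -> int:
    """Number of non-H substituents attached to the (first) benzene ring."""
    ring = next(
        (
            r
            for r in mol.GetRingInfo().AtomRings()
            if len(r) == 6
            and all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in r)
        ),
        None,
    )
    if ring is None:
        return 0
    count = 0
    for idx in ring:
        for nb in mol.GetAtomWithIdx(idx).GetNeighbors():
            if nb.GetIdx() not in ring:
                count += 1
    return count
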