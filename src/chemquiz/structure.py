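"""Generators for the molecular-interpretation question categories.

Four categories: carbon counting, ring counting, shortest path between two
marked positions, and atom mapping between two SMILES representations of the
same molecule.  Every ground truth is computed from the molecular graph, so
the scorer can verify answers without re-running generation.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from rdkit import Chem
from rdkit.Chem import RWMol

from . import core
from .records import ANSWER_INSTRUCTION, QuestionRecord


def gen_count_question(
    mol: core.Molecule, kind: Literal["carbon", "ring"], seed: int, qid: str
) -> QuestionRecord:
    """Ask for the number of carbon atoms or of rings in one molecule."""
    smiles = core.canonical_smiles(mol)
    if kind == "carbon":
        truth = core.element_count(mol, "C")
        what = "carbon atoms"
        category = "carbon_count"
    elif kind == "ring":
        truth = core.cycle_rank(mol)
        what = "rings"
        category = "ring_count"
    else:
        raise ValueError(f"unknown count kind: {kind}")
    prompt = (
        f"Consider the molecule with SMILES string {smiles}\n"
        f"How many {what} does this molecule contain?\n"
        f"{ANSWER_INSTRUCTION}"
    )
    return QuestionRecord(
        id=qid,
        category=category,
        prompt=prompt,
        truth=truth,
        meta={"seed": seed, "source_smiles": smiles, "smiles_mode": "canonical"},
    )


def _attach_dummies(mol: core.Molecule, a: int, b: int) -> core.Molecule | None:
    """Attach a wildcard atom to each of two heavy atoms; None if invalid."""
    rw = RWMol(mol)
    for site in (a, b):
        dummy = rw.AddAtom(Chem.Atom(0))
        rw.AddBond(site, dummy, Chem.BondType.SINGLE)
    try:
        out = rw.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def gen_shortest_path_question(
    mol: core.Molecule,
    smiles_mode: Literal["canonical", "randomized"],
    seed: int,
    qid: str,
) -> QuestionRecord:
    """Mark two random positions with wildcard atoms; ask the bond distance.

    The two dummy atoms each add one attachment bond, so the reported
    distance is the heavy-atom path length plus two.
    """
    rng = np.random.default_rng(seed)
    sites = [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() >= 1]
    if len(sites) < 2:
        raise ValueError("molecule lacks two substitutable positions")
    for attempt in range(50):
        a, b = (
            sites[int(x)] for x in rng.choice(len(sites), size=2, replace=False)
        )
        marked = _attach_dummies(mol, a, b)
        if marked is None:
            continue
        truth = core.graph_distance(mol, a, b) + 2
        variant = core.smiles_variant(
            marked, smiles_mode, seed=int(rng.integers(2**31))
        )
        prompt = (
            f"The molecule with SMILES string {variant.text} contains two "
            "dummy atoms written as *.\n"
            "What is the number of bonds on the shortest path between the two "
            "dummy atoms? Count every bond on the path, including the two "
            "bonds attaching the dummy atoms.\n"
            f"{ANSWER_INSTRUCTION}"
        )
        return QuestionRecord(
            id=qid,
            category="shortest_path",
            prompt=prompt,
            truth=truth,
            meta={
                "seed": seed,
                "source_smiles": core.canonical_smiles(mol),
                "marked_smiles": variant.text,
                "smiles_mode": smiles_mode,
                "endpoints": [a, b],
            },
        )
    raise RuntimeError("could not place dummy atoms after 50 attempts")


def gen_atom_mapping_question(
    mol: core.Molecule,
    variant_mode: Literal["randomized", "semicanonical"],
    seed: int,
    qid: str,
) -> QuestionRecord:
    """Two SMILES spellings of one molecule; ask the position-to-position map.

    Positions are 1-based indices of heavy atoms in order of appearance in
    each string.  The stored truth is the mapping induced by the two writers'
    atom output orders; the scorer additionally accepts any automorphism-
    composed variant of it.
    """
    n = mol.GetNumHeavyAtoms()
    rng = np.random.default_rng(seed)
    for attempt in range(50):
        sa, sb = (int(x) for x in rng.integers(2**31, size=2))
        if variant_mode == "randomized":
            va = core.randomized_smiles(mol, sa)
            vb = core.randomized_smiles(mol, sb)
        else:
            va = core.semicanonical_smiles(mol, sa)
            vb = core.semicanonical_smiles(mol, sb)
        if va.text != vb.text:
            break
    else:
        raise RuntimeError("could not generate two distinct SMILES variants")
    atom_to_pos_b = {atom: i for i, atom in enumerate(vb.order_map)}
    mapping = {
        str(i + 1): atom_to_pos_b[atom] + 1 for i, atom in enumerate(va.order_map)
    }
    prompt = (
        "The following two SMILES strings represent the same molecule:\n"
        f"String A: {va.text}\n"
        f"String B: {vb.text}\n"
        "Number the heavy atoms of each string 1, 2, 3, ... in their order of "
        "appearance in that string (hydrogens are not counted).\n"
        "Map every atom of string A to the corresponding atom of string B.\n"
        'Give your final answer on the last line in the form '
        '"Answer: 1->3, 2->1, ..." listing every atom of string A.'
    )
    return QuestionRecord(
        id=qid,
        category="atom_map",
        prompt=prompt,
        truth={
            "mapping": mapping,
            "smiles_a": va.text,
            "smiles_b": vb.text,
            "order_map_a": list(va.order_map),
            "order_map_b": list(vb.order_map),
            "source_smiles": core.canonical_smiles(mol),
        },
        meta={
            "seed": seed,
            "source_smiles": core.canonical_smiles(mol),
            "smiles_mode": variant_mode,
            "n_heavy": n,
        },
    )
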