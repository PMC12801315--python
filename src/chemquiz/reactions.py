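"""Reaction-prediction question generation.

Nine undergraduate-level reaction classes, each encoded as an RDKit
reaction-SMARTS rewrite plus a seeded reactant sampler.  Every generated
question has exactly one sanitizable product: substituent draws that give
zero or several distinct products (competing reactive sites) are redrawn,
keeping the single-product discipline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from . import core
from .records import ANSWER_INSTRUCTION, QuestionRecord

# substituent pools used by the reactant samplers
_ALKYL = ["CC", "CCC", "CCCC", "CC(C)C", "CCCCC"]
_ARYL = ["c1ccccc1", "Cc1ccccc1", "COc1ccccc1", "Clc1ccccc1", "Fc1ccccc1"]


@dataclass(frozen=True)
class ReactionTemplate:
    name: str
    smarts: str
    conditions: str
    # returns reactant SMILES tuple drawn from the rng
    sampler: Callable[[np.random.Generator], tuple[str, ...]]

    def run(self, reactant_smiles: tuple[str, ...]) -> str | None:
        """Apply the rewrite; canonical product SMILES, or None if not unique."""
        rxn = AllChem.ReactionFromSmarts(self.smarts)
        mols = tuple(Chem.MolFromSmiles(s) for s in reactant_smiles)
        if any(m is None for m in mols):
            return None
        products = set()
        for prods in rxn.RunReactants(mols):
            for p in prods:
                try:
                    Chem.SanitizeMol(p)
                except Exception:
                    continue
                Chem.RemoveStereochemistry(p)
                products.add(Chem.MolToSmiles(p))
        if len(products) != 1:
            return None
        return products.pop()


def _sn2(rng):  # primary alkyl bromide
    r = _ALKYL[int(rng.integers(len(_ALKYL)))]
    return (f"BrC{r}",)


def _click(rng):  # organic azide + terminal alkyne
    r1 = ["Cc1ccccc1", "CCC", "c1ccccc1", "CCCC", "COC(=O)C"][
        int(rng.integers(5))
    ]
    r2 = _ARYL[int(rng.integers(len(_ARYL)))]
    return (f"N(=[N+]=[N-])C{r1}", f"C#C{r2}")


def _simmons_smith(rng):  # simple terminal/internal alkene
    r = ["c1ccccc1", "CCC", "CCCC", "Cc1ccccc1", "CCc1ccccc1"][
        int(rng.integers(5))
    ]
    return (f"C=C{r}",)


def _suzuki(rng):  # aryl bromide + arylboronic acid
    a = ["Cc1ccc(Br)cc1", "COc1ccc(Br)cc1", "Fc1ccc(Br)cc1", "Brc1ccccc1",
         "CCc1ccc(Br)cc1"][int(rng.integers(5))]
    b = ["OB(O)c1ccccc1", "OB(O)c1ccc(C)cc1", "OB(O)c1ccc(OC)cc1",
         "OB(O)c1ccc(F)cc1", "OB(O)c1cccc(C)c1"][int(rng.integers(5))]
    return (a, b)


def _amide(rng):  # acid chloride + primary/secondary amine
    acid = ["CC(=O)Cl", "CCC(=O)Cl", "O=C(Cl)c1ccccc1", "CC(C)C(=O)Cl",
            "O=C(Cl)c1ccc(C)cc1"][int(rng.integers(5))]
    amine = ["NCC", "NCCC", "NC1CCCCC1", "N(C)CC", "NCc1ccccc1"][
        int(rng.integers(5))
    ]
    return (acid, amine)


def _reductive_amination(rng):  # aldehyde/ketone + primary amine
    carbonyl = ["CC=O", "CCC=O", "O=Cc1ccccc1", "CC(C)=O", "O=C1CCCCC1"][
        int(rng.integers(5))
    ]
    amine = ["NCC", "NCCC", "NCc1ccccc1", "NC(C)C", "NCCCC"][
        int(rng.integers(5))
    ]
    return (carbonyl, amine)


def _fischer(rng):  # carboxylic acid + primary alcohol
    acid = ["CC(=O)O", "CCC(=O)O", "OC(=O)c1ccccc1", "CC(C)C(=O)O",
            "OC(=O)c1ccc(C)cc1"][int(rng.integers(5))]
    alcohol = ["OC", "OCC", "OCCC", "OCC(C)C", "OCCCC"][int(rng.integers(5))]
    return (acid, alcohol)


def _grignard(rng):  # ketone + alkyl/aryl magnesium bromide
    ketone = ["CC(C)=O", "CCC(C)=O", "CC(=O)c1ccccc1", "O=C1CCCCC1",
              "CCC(=O)CC"][int(rng.integers(5))]
    rmgx = ["C[Mg]Br", "CC[Mg]Br", "Br[Mg]c1ccccc1", "CCC[Mg]Br",
            "CC(C)[Mg]Br"][int(rng.integers(5))]
    return (ketone, rmgx)


def _wittig(rng):  # aldehyde + (alkylidene)triphenylphosphorane
    aldehyde = ["CC=O", "CCC=O", "O=Cc1ccccc1", "CCCC=O", "O=Cc1ccc(C)cc1"][
        int(rng.integers(5))
    ]
    ylide = ["C(=P(c1ccccc1)(c1ccccc1)c1ccccc1)C",
             "C(=P(c1ccccc1)(c1ccccc1)c1ccccc1)CC",
             "C=P(c1ccccc1)(c1ccccc1)c1ccccc1",
             "C(=P(c1ccccc1)(c1ccccc1)c1ccccc1)CCC",
             "C(=P(c1ccccc1)(c1ccccc1)c1ccccc1)c1ccccc1"][
        int(rng.integers(5))
    ]
    return (aldehyde, ylide)


TEMPLATES: tuple[ReactionTemplate, ...] = (
    ReactionTemplate(
        "sn2_hydroxide",
        "[CX4;H2:1][Br]>>[C:1]O",
        "aqueous NaOH, SN2 substitution",
        _sn2,
    ),
    ReactionTemplate(
        "cuaac_click",
        "[#6:4][N:1]=[N+:2]=[N-:3].[C:6]#[CH1:7]>>"
        "[#6:4][N:1]1[CH1:7]=[C:6][N+0:3]=[N+0:2]1",
        "copper(I) catalyst (CuAAC click reaction)",
        _click,
    ),
    ReactionTemplate(
        "simmons_smith",
        "[CX3;H2:1]=[CX3;H1:2]>>[C:1]1[C:2]C1",
        "CH2I2, Zn(Cu) (Simmons-Smith cyclopropanation)",
        _simmons_smith,
    ),
    ReactionTemplate(
        "suzuki_coupling",
        "[c:1][Br].[c:2][B]([OX2H1])[OX2H1]>>[c:1][c:2]",
        "Pd(PPh3)4 catalyst, K2CO3 base (Suzuki-Miyaura coupling)",
        _suzuki,
    ),
    ReactionTemplate(
        "amide_formation",
        "[C:1](=[O:2])Cl.[NX3;H2,H1;!$(NC=O):3]>>[C:1](=[O:2])[N:3]",
        "triethylamine base, acylation of the amine",
        _amide,
    ),
    ReactionTemplate(
        "reductive_amination",
        "[C:1]=[OX1].[NX3;H2:2]>>[C:1][N:2]",
        "NaBH3CN, mild acid (reductive amination)",
        _reductive_amination,
    ),
    ReactionTemplate(
        "fischer_esterification",
        "[C:1](=[O:2])[OX2H1].[OX2H1:3][CX4:4]>>[C:1](=[O:2])[O:3][C:4]",
        "catalytic H2SO4, reflux (Fischer esterification)",
        _fischer,
    ),
    ReactionTemplate(
        "grignard_ketone",
        "[C:1](=[OX1:2])([#6:3])[#6:4].[#6:5][Mg]>>"
        "[C:1]([OX2:2])([#6:3])([#6:4])[#6:5]",
        "Grignard reagent in dry ether, then aqueous workup",
        _grignard,
    ),
    ReactionTemplate(
        "wittig_olefination",
        "[CX3;H1:1]=[OX1].[C:2]=[PX4]>>[C:1]=[C:2]",
        "Wittig olefination with the phosphonium ylide",
        _wittig,
    ),
)


def reaction_template_set() -> tuple[ReactionTemplate, ...]:
    """The nine reaction-class templates."""
    return TEMPLATES


def gen_reaction_question(
    template: ReactionTemplate,
    smiles_mode: Literal["canonical", "randomized"],
    seed: int,
    qid: str,
) -> QuestionRecord:
    rng = np.random.default_rng(seed)
    for _ in range(50):
        reactants = template.sampler(rng)
        product = template.run(reactants)
        if product is None:
            continue
        shown = []
        for s in reactants:
            mol = core.parse_smiles(s)
            shown.append(core.smiles_variant(mol, smiles_mode,
                                             seed=int(rng.integers(2**31))).text)
        prompt = (
            "Predict the product of the following reaction.\n"
            f"Reactant(s): {' + '.join(shown)}\n"
            f"Conditions: {template.conditions}\n"
            "Write the major organic product as a SMILES string.\n"
            f"{ANSWER_INSTRUCTION}"
        )
        return QuestionRecord(
            id=qid,
            category="reaction",
            prompt=prompt,
            truth=product,
            meta={
                "seed": seed,
                "reaction_class": template.name,
                "reactants": [core.canonical_smiles(core.parse_smiles(s))
                              for s in reactants],
                "smiles_mode": smiles_mode,
            },
        )
    raise RuntimeError(f"no unambiguous reactants for {template.name}")
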