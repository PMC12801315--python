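"""Free-Wilson (additive substituent contribution) questions.

Each instance places one of three halogens (F, Cl, Br) at each of three
positions of a benzofuran scaffold.  Every (position, substituent) pair
carries a hidden integer contribution and a molecule's score is the plain
sum of its three contributions.  Seven scored training molecules are shown
and the score of an eighth must be predicted; the training set is drawn so
that the query is uniquely determined by the additive model (rank check on
the reparameterized design matrix, not luck).

The analytic solver doubles as the internal oracle: it fits the additive
model exactly from the seven equations and predicts the query.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from rdkit import Chem

from . import core
from .nameparse import attach_fragment
from .records import ANSWER_INSTRUCTION, QuestionRecord

SCAFFOLD_SMILES = "c1ccc2occc2c1"  # benzofuran
# three substitutable CH positions: furan C2, benzo C4 and C6 (atom indices)
SITES: tuple[int, int, int] = (5, 0, 2)
SUBSTITUENTS: tuple[str, ...] = ("F", "Cl", "Br")

Combination = tuple[str, str, str]

# Noise scale for the noisy variant, in score units.  The seven training
# equations determine the seven model parameters exactly, so training noise
# propagates to the query prediction undamped; 0.3 (an occasional +/-1 flip
# after rounding) keeps an exact solver inside the +/-2 scoring band for
# >= 95% of seeds, which is the generator health target.
NOISE_SD = 0.3


class UnderdeterminedError(ValueError):
    """The query score is not pinned down by the training equations."""


@dataclass(frozen=True)
class FreeWilsonInstance:
    values: dict[tuple[int, str], int]  # (position, substituent) -> value
    training: tuple[tuple[Combination, int], ...]  # 7 noise-free pairs
    query: Combination
    noise: bool
    displayed_scores: tuple[int, ...]  # training scores as shown (maybe noisy)

    def score(self, combo: Combination) -> int:
        return sum(self.values[(p, s)] for p, s in enumerate(combo))


def _design_row(combo: Combination) -> np.ndarray:
    """Intercept + indicator for each position's non-reference substituents."""
    row = [1.0]
    for s in combo:
        for other in SUBSTITUENTS[1:]:
            row.append(1.0 if s == other else 0.0)
    return np.array(row)


def solve_free_wilson(
    training: list[tuple[Combination, float]], query: Combination
) -> float:
    """Exact additive-model prediction of the query score.

    Raises :class:`UnderdeterminedError` when the query indicator vector is
    outside the span of the training design matrix.
    """
    a = np.array([_design_row(c) for c, _ in training])
    y = np.array([s for _, s in training], dtype=float)
    q = _design_row(query)
    rank_a = np.linalg.matrix_rank(a)
    if np.linalg.matrix_rank(np.vstack([a, q])) > rank_a:
        raise UnderdeterminedError("query not in the training design span")
    coef, *_ = np.linalg.lstsq(a, y, rcond=None)
    return float(q @ coef)


def draw_instance(seed: int, noise: bool = False) -> FreeWilsonInstance:
    """Draw values and an identifiable 7+1 combination split."""
    rng = np.random.default_rng(seed)
    values = {
        (p, s): int(rng.integers(1, 21))
        for p in range(3)
        for s in SUBSTITUENTS
    }
    all_combos = list(product(SUBSTITUENTS, repeat=3))
    for _ in range(200):
        picks = rng.choice(len(all_combos), size=8, replace=False)
        combos = [all_combos[int(i)] for i in picks]
        train, query = combos[:7], combos[7]
        a = np.array([_design_row(c) for c in train])
        if np.linalg.matrix_rank(a) < 7:
            continue
        scores = tuple(
            sum(values[(p, s)] for p, s in enumerate(c)) for c in train
        )
        displayed = scores
        if noise:
            displayed = tuple(
                int(s + round(rng.normal(0.0, NOISE_SD))) for s in scores
            )
        return FreeWilsonInstance(
            values=values,
            training=tuple(zip(train, scores)),
            query=query,
            noise=noise,
            displayed_scores=displayed,
        )
    raise RuntimeError("could not draw an identifiable instance")


def combo_to_molecule(combo: Combination) -> core.Molecule:
    mol = Chem.MolFromSmiles(SCAFFOLD_SMILES)
    # attach highest index first so earlier sites keep their atom ids
    for site, sub in sorted(zip(SITES, combo), reverse=True):
        mol = attach_fragment(mol, site, sub)
        if mol is None:
            raise RuntimeError("substituent attachment failed")
    return mol


def gen_free_wilson_question(seed: int, noise: bool, qid: str) -> QuestionRecord:
    inst = draw_instance(seed, noise=noise)
    truth = inst.score(inst.query)
    # guard: the noise-free system must pin the query to the stored truth
    pred = solve_free_wilson([(c, float(s)) for c, s in inst.training], inst.query)
    assert round(pred) == truth
    lines = []
    for (combo, _), shown in zip(inst.training, inst.displayed_scores):
        smi = core.canonical_smiles(combo_to_molecule(combo))
        lines.append(f"{smi} score: {shown}")
    query_smi = core.canonical_smiles(combo_to_molecule(inst.query))
    tolerance = 2 if noise else 0
    noise_note = (
        "The scores contain a small amount of measurement noise.\n" if noise else ""
    )
    prompt = (
        "The following molecules share a common scaffold with substituents at "
        "three positions. Each molecule has a measured score:\n"
        + "\n".join(lines)
        + f"\n{noise_note}"
        + f"Predict the score of the molecule {query_smi}\n"
        + ANSWER_INSTRUCTION
    )
    return QuestionRecord(
        id=qid,
        category="free_wilson",
        prompt=prompt,
        truth={"value": truth, "tolerance": tolerance},
        meta={
            "seed": seed,
            "noise": noise,
            "query_smiles": query_smi,
            "training": [
                {"combo": list(c), "score": s, "shown": shown}
                for (c, s), shown in zip(inst.training, inst.displayed_scores)
            ],
            "query_combo": list(inst.query),
        },
    )
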