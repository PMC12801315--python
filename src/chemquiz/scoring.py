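"""Answer extraction, equivalence checking, and evaluation statistics.

Free-text responses are reduced to an answer by a regular-expression parser
(strict: a final ``Answer: <...>`` line; lenient: strict first, then a
category-aware fallback).  Equivalence is then judged per category:
numeric questions compare values, structural questions compare sanitized
molecular graphs (stereo stripped, canonical SMILES plus an InChI
cross-check), naming questions parse the submitted name to a structure,
and atom-mapping answers are accepted whenever the induced atom
correspondence is a graph automorphism-compatible isomorphism, so no valid
symmetry-equivalent mapping is penalized.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

from rdkit import Chem
from scipy import stats

from . import core
from .nameparse import NameParser, default_parser
from .records import QuestionRecord

Mode = Literal["strict", "lenient"]

_ANSWER_RE = re.compile(r"^[ \t>*]*answer\s*[:\-]\s*(.+?)\s*$", re.I | re.M)
_NUMBER_RE = re.compile(r"[-+]?\d+(?:\.\d+)?")
_SMILES_TOKEN_RE = re.compile(r"[A-Za-z0-9@+\-\[\]\(\)=#$%/\\.*:]{2,}")
_PAIR_RE = re.compile(r"(\d+)\s*(?:->|→|=>|:|—>|-)\s*(\d+)")


@dataclass
class Judgment:
    question_id: str
    verdict: Literal["correct", "incorrect", "unparseable"]
    extracted: str | None
    detail: str = ""

    @property
    def correct(self) -> bool:
        return self.verdict == "correct"


@dataclass
class CategoryScore:
    n: int
    k: int
    accuracy: float
    ci_low: float
    ci_high: float


@dataclass
class ScoreReport:
    per_category: dict[str, CategoryScore]
    overall: CategoryScore
    mode: Mode
    judgments: list[Judgment] = field(default_factory=list)


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def extract_answer(
    response: str, mode: Mode = "strict", category: str | None = None
) -> str | None:
    """Pull the answer text out of a free-form response.

    Strict mode takes the last ``Answer: <...>`` line only.  Lenient mode
    falls back to the last plausible token for the category: the last number
    for numeric questions, the last SMILES-like token for structural ones,
    the last position-pair list for mapping, the last non-empty line for
    names.
    """
    if not response:
        return None
    matches = _ANSWER_RE.findall(response)
    if matches:
        return matches[-1].strip()
    if mode == "strict":
        return None
    numeric = {"carbon_count", "ring_count", "shortest_path", "free_wilson"}
    if category in numeric:
        nums = _NUMBER_RE.findall(response)
        return nums[-1] if nums else None
    if category == "atom_map":
        pairs = _PAIR_RE.findall(response)
        if not pairs:
            return None
        return ", ".join(f"{a}->{b}" for a, b in pairs)
    if category in {"reaction", "nmr_1d", "nmr_2d"}:
        tokens = [
            t
            for t in _SMILES_TOKEN_RE.findall(response)
            if core.try_parse_smiles(t) is not None
        ]
        return tokens[-1] if tokens else None
    # naming and unknown categories: last non-empty line
    lines = [ln.strip() for ln in response.splitlines() if ln.strip()]
    return lines[-1] if lines else None


# ---------------------------------------------------------------------------
# equivalence checks
# ---------------------------------------------------------------------------


def numbers_equal(answer: str, truth: float, tolerance: float = 0.0) -> bool:
    """Whitespace/format tolerant numeric comparison ("7", " 7 ", "7.0")."""
    try:
        value = float(answer.strip().rstrip("."))
    except (ValueError, AttributeError):
        return False
    return abs(value - float(truth)) <= tolerance + 1e-9


def smiles_equivalent(a: str, b: str) -> bool:
    """Structural equality of two SMILES strings, stereo stripped.

    Canonical-SMILES equality with a standard-InChI cross-check; both must
    agree for a positive verdict.
    """
    mol_a = core.try_parse_smiles(a)
    mol_b = core.try_parse_smiles(b)
    if mol_a is None or mol_b is None:
        return False
    by_smiles = core.canonical_smiles(mol_a) == core.canonical_smiles(mol_b)
    if not by_smiles:
        return False
    by_inchi = Chem.MolToInchi(mol_a) == Chem.MolToInchi(mol_b)
    return by_smiles and by_inchi


def check_iupac(
    name: str, truth_smiles: str, parser: NameParser | None = None
) -> bool:
    """A name is correct when it parses to the intended structure.

    The answer may also be the structure itself written as SMILES.  Name
    parsing goes through the configured backend (OPSIN when installed, the
    built-in restricted parser otherwise); a name the backend cannot parse
    is simply wrong, whereas a missing backend raises a configuration error
    at construction time in :func:`chemquiz.nameparse.OpsinParser`.
    """
    if not name:
        return False
    name = name.strip().strip(".")
    if smiles_equivalent(name, truth_smiles):
        return True
    parser = parser or default_parser()
    parsed = parser.parse(name)
    if parsed is None:
        return False
    return smiles_equivalent(parsed, truth_smiles)


def parse_mapping(answer: str) -> dict[int, int] | None:
    pairs = _PAIR_RE.findall(answer or "")
    if not pairs:
        return None
    mapping: dict[int, int] = {}
    for a, b in pairs:
        ka = int(a)
        if ka in mapping:
            return None
        mapping[ka] = int(b)
    return mapping


def check_mapping(answer: str | Mapping[int, int], truth: Mapping) -> bool:
    """Accept any position mapping whose induced atom map is an isomorphism.

    The stored reference mapping is only one of possibly many correct
    answers: composing the truth with any graph automorphism of the molecule
    is equally valid.  The check is therefore structural -- the induced
    atom-to-atom correspondence must be a bijection preserving element,
    charge, aromaticity and every bond with its order.
    """
    if isinstance(answer, Mapping):
        mapping = {int(k): int(v) for k, v in answer.items()}
    else:
        mapping = parse_mapping(answer)
    if mapping is None:
        return False
    order_a = list(truth["order_map_a"])
    order_b = list(truth["order_map_b"])
    n = len(order_a)
    if sorted(mapping) != list(range(1, n + 1)):
        return False
    if sorted(mapping.values()) != list(range(1, n + 1)):
        return False
    mol = core.parse_smiles(truth["source_smiles"])
    # induced atom correspondence on the molecule
    atom_map = {
        order_a[pos_a - 1]: order_b[pos_b - 1] for pos_a, pos_b in mapping.items()
    }
    for i, j in atom_map.items():
        ai, aj = mol.GetAtomWithIdx(i), mol.GetAtomWithIdx(j)
        if (
            ai.GetSymbol() != aj.GetSymbol()
            or ai.GetFormalCharge() != aj.GetFormalCharge()
            or ai.GetIsAromatic() != aj.GetIsAromatic()
            or ai.GetTotalNumHs() != aj.GetTotalNumHs()
        ):
            return False
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        image = mol.GetBondBetweenAtoms(atom_map[u], atom_map[v])
        if image is None or image.GetBondType() != bond.GetBondType():
            return False
    return True


# ---------------------------------------------------------------------------
# per-question judging
# ---------------------------------------------------------------------------


def judge_question(
    question: QuestionRecord,
    response: str | None,
    mode: Mode = "strict",
    parser: NameParser | None = None,
) -> Judgment:
    qid = question.id
    if response is None:
        return Judgment(qid, "incorrect", None, "no response")
    answer = extract_answer(response, mode, question.category)
    if answer is None:
        return Judgment(qid, "unparseable", None, "no answer found in response")
    cat = question.category
    if cat in {"carbon_count", "ring_count", "shortest_path"}:
        ok = numbers_equal(answer, float(question.truth))
    elif cat == "free_wilson":
        ok = numbers_equal(
            answer, float(question.truth["value"]), float(question.truth["tolerance"])
        )
    elif cat == "atom_map":
        ok = check_mapping(answer, question.truth)
    elif cat in {"iupac_zinc", "iupac_fg", "iupac_locant"}:
        ok = check_iupac(answer, question.truth, parser)
    elif cat in {"reaction", "nmr_1d", "nmr_2d"}:
        ok = smiles_equivalent(answer, question.truth)
    else:  # pragma: no cover - schema guards categories
        raise ValueError(f"unknown category: {cat}")
    return Judgment(qid, "correct" if ok else "incorrect", answer)


def truth_as_response(question: QuestionRecord) -> str:
    """Render the stored ground truth as a well-formed response line."""
    if question.category == "atom_map":
        mapping = question.truth["mapping"]
        body = ", ".join(
            f"{k}->{mapping[k]}" for k in sorted(mapping, key=int)
        )
    elif question.category == "free_wilson":
        body = str(question.truth["value"])
    else:
        body = str(question.truth)
    return f"Answer: {body}"


# ---------------------------------------------------------------------------
# statistics and aggregation
# ---------------------------------------------------------------------------


def binomial_ci(k: int, n: int) -> tuple[float, float]:
    """Wald 95% interval p +/- 1.96 * SE of the binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    p = k / n
    half = 1.96 * math.sqrt(p * (1.0 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))


def mcnemar_one_tailed(b: int, c: int) -> float:
    """Exact one-sided McNemar p value from the discordant counts.

    ``b`` counts items only the first condition got right, ``c`` items only
    the second got right; the p value is P(X >= max(b, c)) for
    X ~ Binomial(b + c, 1/2).
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    return float(stats.binom.sf(max(b, c) - 1, n, 0.5))


def _cat_score(k: int, n: int) -> CategoryScore:
    low, high = binomial_ci(k, n)
    return CategoryScore(n=n, k=k, accuracy=k / n, ci_low=low, ci_high=high)


def score_benchmark(
    questions: Iterable[QuestionRecord],
    responses: Mapping[str, str],
    mode: Mode = "strict",
    parser: NameParser | None = None,
) -> ScoreReport:
    """Judge every question and aggregate accuracies with 95% CIs.

    Missing responses count as incorrect.  Duplicate question ids are a
    hard error.
    """
    questions = list(questions)
    ids = [q.id for q in questions]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate question ids")
    unknown = set(responses) - set(ids)
    if unknown:
        raise ValueError(f"responses for unknown question ids: {sorted(unknown)[:5]}")
    if parser is None:
        parser = default_parser()
    judgments = [
        judge_question(q, responses.get(q.id), mode, parser) for q in questions
    ]
    per_cat: dict[str, list[bool]] = {}
    for q, j in zip(questions, judgments):
        per_cat.setdefault(q.category, []).append(j.correct)
    per_category = {
        cat: _cat_score(sum(oks), len(oks)) for cat, oks in sorted(per_cat.items())
    }
    overall = _cat_score(sum(j.correct for j in judgments), len(judgments))
    return ScoreReport(
        per_category=per_category, overall=overall, mode=mode, judgments=judgments
    )


@dataclass
class McNemarRow:
    b: int  # correct only in report A
    c: int  # correct only in report B
    p_value: float


def compare_reports(
    questions: Iterable[QuestionRecord], a: ScoreReport, b: ScoreReport
) -> dict[str, McNemarRow]:
    """Pairwise one-tailed McNemar comparison of two reports, per category."""
    questions = list(questions)
    ja = {j.question_id: j.correct for j in a.judgments}
    jb = {j.question_id: j.correct for j in b.judgments}
    if set(ja) != set(jb) or set(ja) != {q.id for q in questions}:
        raise ValueError("reports do not cover the same benchmark")
    rows: dict[str, tuple[int, int]] = {}
    for q in questions:
        only_a = ja[q.id] and not jb[q.id]
        only_b = jb[q.id] and not ja[q.id]
        for key in (q.category, "overall"):
            x, y = rows.get(key, (0, 0))
            rows[key] = (x + only_a, y + only_b)
    return {
        key: McNemarRow(b=x, c=y, p_value=mcnemar_one_tailed(x, y))
        for key, (x, y) in sorted(rows.items())
    }


def render_report(report: ScoreReport) -> str:
    lines = [f"mode: {report.mode}", ""]
    header = f"{'category':<16}{'n':>6}{'k':>6}{'acc':>8}{'95% CI':>18}"
    lines.append(header)
    for cat, s in report.per_category.items():
        lines.append(
            f"{cat:<16}{s.n:>6}{s.k:>6}{s.accuracy:>8.3f}"
            f"   [{s.ci_low:.3f}, {s.ci_high:.3f}]"
        )
    s = report.overall
    lines.append(
        f"{'overall':<16}{s.n:>6}{s.k:>6}{s.accuracy:>8.3f}"
        f"   [{s.ci_low:.3f}, {s.ci_high:.3f}]"
    )
    return "\n".join(lines)
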