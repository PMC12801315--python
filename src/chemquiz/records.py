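"""Benchmark question records.

A :class:`QuestionRecord` is one benchmark item: prompt text, a
machine-checkable ground truth, and enough generation metadata (seed,
source structure, SMILES mode) to reproduce it.  Records serialize to
one JSON object per line in the benchmark JSONL file.
"""

from __future__ import annotations

import json
from typing import Any, Literal

from pydantic import BaseModel, Field, field_validator

Category = Literal[
    "carbon_count",
    "ring_count",
    "shortest_path",
    "atom_map",
    "iupac_zinc",
    "iupac_fg",
    "iupac_locant",
    "free_wilson",
    "reaction",
    "nmr_1d",
    "nmr_2d",
]

CATEGORIES: tuple[str, ...] = (
    "carbon_count",
    "ring_count",
    "shortest_path",
    "atom_map",
    "iupac_zinc",
    "iupac_fg",
    "iupac_locant",
    "free_wilson",
    "reaction",
    "nmr_1d",
    "nmr_2d",
)

ANSWER_INSTRUCTION = (
    'Give your final answer on the last line in the form "Answer: <answer>".'
)


class QuestionRecord(BaseModel):
    """One benchmark question with its verifiable ground truth."""

    id: str
    category: Category
    prompt: str
    truth: Any
    meta: dict[str, Any] = Field(default_factory=dict)

    @field_validator("id")
    @classmethod
    def _nonempty_id(cls, v: str) -> str:
        if not v:
            raise ValueError("question id must be non-empty")
        return v

    def to_json(self) -> str:
        return json.dumps(self.model_dump(), sort_keys=True, ensure_ascii=False)

    @classmethod
    def from_json(cls, line: str) -> "QuestionRecord":
        return cls.model_validate(json.loads(line))


def read_jsonl(path) -> list[QuestionRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(QuestionRecord.from_json(line))
    ids = [r.id for r in records]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate question ids in benchmark file")
    return records


def write_jsonl(path, records) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(rec.to_json() + "\n")
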