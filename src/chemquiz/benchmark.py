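"""Benchmark assembly: reproducible generation of the full question set.

The default configuration emits 816 questions across eleven category slots
(eight task families); every per-question seed is derived from the master
seed, so one integer reproduces the whole benchmark byte for byte.
Categories marked as mixed-representation are split half canonical, half
randomized SMILES.
"""

from __future__ import annotations

import hashlib
import json
from typing import Iterable

import numpy as np
from pydantic import BaseModel, Field, model_validator

from . import core, freewilson, naming, nmr, reactions, structure
from .records import QuestionRecord

DEFAULT_COUNTS: dict[str, int] = {
    "carbon_count": 60,
    "ring_count": 60,
    "shortest_path": 120,  # 50% canonical / 50% randomized
    "atom_map": 72,  # 50% randomized / 50% semicanonical
    "iupac_zinc": 200,  # 100 molecules, canonical + randomized each
    "iupac_fg": 40,
    "iupac_locant": 40,
    "free_wilson": 40,  # 50% noise-free / 50% noisy
    "reaction": 90,  # 9 classes x 5 questions x 2 modes
    "nmr_1d": 44,
    "nmr_2d": 50,
}


class BenchmarkConfig(BaseModel):
    """Reproducible benchmark recipe (the default totals 816 questions)."""

    master_seed: int = 0
    counts: dict[str, int] = Field(default_factory=lambda: dict(DEFAULT_COUNTS))
    mixed_mode_fraction: float = 0.5
    free_wilson_noise_fraction: float = 0.5

    @model_validator(mode="after")
    def _check(self):
        for cat, n in self.counts.items():
            if cat not in DEFAULT_COUNTS:
                raise ValueError(f"unknown category: {cat}")
            if n < 0:
                raise ValueError(f"negative count for {cat}")
        if not 0.0 <= self.mixed_mode_fraction <= 1.0:
            raise ValueError("mixed_mode_fraction must be in [0, 1]")
        return self

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _seed_stream(master_seed: int, label: str) -> np.random.Generator:
    digest = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big"))


def _sub_seeds(master_seed: int, label: str, n: int) -> list[int]:
    rng = _seed_stream(master_seed, label)
    return [int(s) for s in rng.integers(2**31, size=n)]


def _pick(rng: np.random.Generator, pool: list, n: int, replace=False) -> list:
    if not replace and n > len(pool):
        raise ValueError(f"requested {n} items from a pool of {len(pool)}")
    idx = rng.choice(len(pool), size=n, replace=replace)
    return [pool[int(i)] for i in idx]


def build_benchmark(config: BenchmarkConfig) -> list[QuestionRecord]:
    records: list[QuestionRecord] = []
    druglike = list(core.druglike_library())
    small = list(core.small_molecule_library())
    counts = config.counts
    frac = config.mixed_mode_fraction

    def cat_rng(cat: str) -> np.random.Generator:
        return _seed_stream(config.master_seed, f"pool:{cat}")

    # --- counting -----------------------------------------------------
    for cat, kind in (("carbon_count", "carbon"), ("ring_count", "ring")):
        n = counts.get(cat, 0)
        pool = druglike
        if kind == "ring":
            pool = [m for m in druglike if core.cycle_rank(m) <= 6]
        mols = _pick(cat_rng(cat), pool, n)
        for i, (mol, seed) in enumerate(
            zip(mols, _sub_seeds(config.master_seed, cat, n))
        ):
            records.append(
                structure.gen_count_question(mol, kind, seed, f"{cat}-{i:04d}")
            )

    # --- shortest path ------------------------------------------------
    n = counts.get("shortest_path", 0)
    n_canon = round(n * frac)
    path_pool = [
        m
        for m in druglike
        if sum(a.GetTotalNumHs() >= 1 for a in m.GetAtoms()) >= 2
    ]
    mols = _pick(cat_rng("shortest_path"), path_pool, n)
    for i, (mol, seed) in enumerate(
        zip(mols, _sub_seeds(config.master_seed, "shortest_path", n))
    ):
        mode = "canonical" if i < n_canon else "randomized"
        records.append(
            structure.gen_shortest_path_question(
                mol, mode, seed, f"shortest_path-{i:04d}"
            )
        )

    # --- atom mapping ---------------------------------------------------
    n = counts.get("atom_map", 0)
    pool = [m for m in druglike if 8 <= core.heavy_atom_count(m) <= 24]
    n_rand = round(n * frac)
    mols = _pick(cat_rng("atom_map"), pool, n)
    for i, (mol, seed) in enumerate(
        zip(mols, _sub_seeds(config.master_seed, "atom_map", n))
    ):
        mode = "randomized" if i < n_rand else "semicanonical"
        records.append(
            structure.gen_atom_mapping_question(mol, mode, seed, f"atom_map-{i:04d}")
        )

    # --- naming ---------------------------------------------------------
    n = counts.get("iupac_zinc", 0)
    n_mols = (n + 1) // 2
    mols = _pick(cat_rng("iupac_zinc"), druglike, n_mols)
    seeds = _sub_seeds(config.master_seed, "iupac_zinc", n)
    i = 0
    for mol in mols:
        for mode in ("canonical", "randomized"):
            if i >= n:
                break
            records.append(
                naming.gen_iupac_sample_question(
                    mol, mode, seeds[i], f"iupac_zinc-{i:04d}"
                )
            )
            i += 1
    for i, seed in enumerate(
        _sub_seeds(config.master_seed, "iupac_fg", counts.get("iupac_fg", 0))
    ):
        records.append(naming.gen_iupac_fg_question(seed, f"iupac_fg-{i:04d}"))
    n = counts.get("iupac_locant", 0)
    scaffolds = ("benzene", "pyridine", "naphthalene", "quinoline")
    for i, seed in enumerate(_sub_seeds(config.master_seed, "iupac_locant", n)):
        scaffold = scaffolds[i % len(scaffolds)]
        records.append(
            naming.gen_iupac_locant_question(scaffold, seed, f"iupac_locant-{i:04d}")
        )

    # --- Free-Wilson ------------------------------------------------------
    n = counts.get("free_wilson", 0)
    n_clean = round(n * (1.0 - config.free_wilson_noise_fraction))
    for i, seed in enumerate(_sub_seeds(config.master_seed, "free_wilson", n)):
        noise = i >= n_clean
        records.append(
            freewilson.gen_free_wilson_question(seed, noise, f"free_wilson-{i:04d}")
        )

    # --- reactions --------------------------------------------------------
    n = counts.get("reaction", 0)
    templates = reactions.reaction_template_set()
    seeds = _sub_seeds(config.master_seed, "reaction", n)
    per_cell = n // (len(templates) * 2) if n else 0
    i = 0
    for mode in ("canonical", "randomized"):
        for template in templates:
            for _ in range(per_cell):
                records.append(
                    reactions.gen_reaction_question(
                        template, mode, seeds[i], f"reaction-{i:04d}"
                    )
                )
                i += 1
    while i < n:  # remainder after the even class/mode split
        template = templates[i % len(templates)]
        records.append(
            reactions.gen_reaction_question(
                template, "canonical", seeds[i], f"reaction-{i:04d}"
            )
        )
        i += 1

    # --- NMR --------------------------------------------------------------
    for cat, mode, pool in (
        ("nmr_1d", "1d", small),
        ("nmr_2d", "2d", [m for m in druglike if core.heavy_atom_count(m) <= 30]),
    ):
        n = counts.get(cat, 0)
        if not n:
            continue
        rng = cat_rng(cat)
        order = [int(i) for i in rng.permutation(len(pool))]
        seeds = _sub_seeds(config.master_seed, cat, n)
        seen_renderings: set[str] = set()
        emitted = 0
        for j in order:
            if emitted >= n:
                break
            mol = pool[j]
            spec = nmr.simulate(mol, with_2d=(mode == "2d"))
            rendered = nmr.render_spectrum_set(spec)
            if rendered in seen_renderings:
                continue  # non-discriminating within this question set
            seen_renderings.add(rendered)
            records.append(
                nmr.gen_nmr_question(mol, mode, seeds[emitted], f"{cat}-{emitted:04d}")
            )
            emitted += 1
        if emitted < n:
            raise ValueError(
                f"library capacity exhausted for {cat}: got {emitted} of {n}"
            )

    ids = [r.id for r in records]
    assert len(ids) == len(set(ids))
    return records


def manifest(config: BenchmarkConfig, records: Iterable[QuestionRecord]) -> dict:
    records = list(records)
    payload = json.dumps(config.model_dump(), sort_keys=True)
    return {
        "schema_version": 1,
        "config": config.model_dump(),
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "n_questions": len(records),
        "per_category": {
            cat: sum(r.category == cat for r in records)
            for cat in sorted({r.category for r in records})
        },
        "library_sizes": {
            "druglike": len(core.druglike_library()),
            "small_chno": len(core.small_molecule_library()),
        },
    }
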