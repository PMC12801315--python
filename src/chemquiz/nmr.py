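"""Rule-based simulation of 1D and 2D NMR peak lists from a molecular graph.

The simulator is deterministic and additive: symmetry-equivalent nuclei are
grouped into classes (graph-automorphism orbits via canonical atom ranking),
each class gets a chemical shift from environment base values plus neighbor
increments, proton multiplicities follow the n+1 rule over adjacent-carbon
protons, and the 2D experiments are derived purely from bond-path lengths
(COSY: three-bond H-H; HSQC: one-bond C-H; HMBC: two- and three-bond C-H).

Shift values are chemically plausible window placements, not predictions of
experimental spectra: the elucidation task is scored on the structure, so
what matters is that classes land in the right region and that the peak-list
combinatorics (integrations, multiplicities, cross peaks) are exact for the
graph.  Exchangeable protons (on O, N, S) are omitted from the proton list
and reported only through the gap between the listed integrations and the
molecular formula, and they never contribute to coupling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from rdkit import Chem

from . import core
from .records import ANSWER_INSTRUCTION, QuestionRecord


@dataclass(frozen=True)
class NucleusClass:
    """A set of symmetry-equivalent nuclei of one kind.

    For kind "H" the atom ids are the heavy atoms carrying the protons.
    """

    kind: Literal["H", "C"]
    atom_ids: tuple[int, ...]
    n_h: int = 0  # total protons in the class (H classes only)
    exchangeable: bool = False


@dataclass(frozen=True)
class Peak1H:
    shift: float
    multiplicity: str
    integration: int


@dataclass(frozen=True)
class Spectrum1D:
    protons: tuple[Peak1H, ...]  # sorted by descending shift
    carbons: tuple[float, ...]  # sorted descending
    n_exchangeable: int


@dataclass(frozen=True)
class Spectrum2D:
    cosy: tuple[tuple[float, float], ...]  # unordered H-H pairs, (high, low)
    hsqc: tuple[tuple[float, float], ...]  # (delta_C, delta_H)
    hmbc: tuple[tuple[float, float], ...]  # (delta_C, delta_H), 2-3 bonds


@dataclass(frozen=True)
class SpectrumSet:
    formula: str
    one_d: Spectrum1D
    two_d: Spectrum2D | None = None


def nucleus_classes(mol: core.Molecule) -> list[NucleusClass]:
    """Partition protons and carbons into symmetry-equivalence classes."""
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=False))
    by_rank: dict[int, list[int]] = {}
    for idx, r in enumerate(ranks):
        by_rank.setdefault(r, []).append(idx)
    classes: list[NucleusClass] = []
    for r in sorted(by_rank):
        ids = tuple(sorted(by_rank[r]))
        sym = mol.GetAtomWithIdx(ids[0]).GetSymbol()
        n_h = sum(mol.GetAtomWithIdx(i).GetTotalNumHs() for i in ids)
        if sym == "C":
            classes.append(NucleusClass("C", ids))
            if n_h:
                classes.append(NucleusClass("H", ids, n_h=n_h, exchangeable=False))
        elif n_h:
            classes.append(
                NucleusClass("H", ids, n_h=n_h, exchangeable=sym in {"N", "O", "S"})
            )
    return classes


# ---------------------------------------------------------------------------
# chemical-shift estimation (additive increments, deterministic)
# ---------------------------------------------------------------------------


def _bond_order_to(atom, symbol, order) -> int:
    n = 0
    for bond in atom.GetBonds():
        other = bond.GetOtherAtom(atom)
        if other.GetSymbol() == symbol and bond.GetBondType() == order:
            n += 1
    return n


def carbon_shift(mol: core.Molecule, idx: int) -> float:
    """Estimated 13C shift (ppm) of one carbon, rounded to 0.1."""
    atom = mol.GetAtomWithIdx(idx)
    dbl_o = _bond_order_to(atom, "O", Chem.BondType.DOUBLE)
    if dbl_o:
        single_o = _bond_order_to(atom, "O", Chem.BondType.SINGLE)
        has_n = any(n.GetSymbol() == "N" for n in atom.GetNeighbors())
        if atom.GetIsAromatic():
            value = 162.0  # aromatic carbonyl-like (pyranone etc.)
        elif single_o:
            value = 170.5  # acid / ester
        elif has_n:
            value = 171.8  # amide / urea
        elif atom.GetTotalNumHs() >= 1:
            value = 200.5  # aldehyde
        else:
            value = 206.0  # ketone
        return round(value, 1)
    if _bond_order_to(atom, "N", Chem.BondType.TRIPLE):
        return 118.5
    if atom.GetIsAromatic():
        value = 128.0
        for nbr in atom.GetNeighbors():
            bond = mol.GetBondBetweenAtoms(idx, nbr.GetIdx())
            sym = nbr.GetSymbol()
            if nbr.GetIsAromatic() and bond.GetIsAromatic():
                if sym == "N":
                    value += 10.0
                elif sym == "O":
                    value += 7.0
                elif sym == "S":
                    value += 1.0
            else:  # exocyclic substituent
                value += {
                    "O": 22.0, "N": 15.0, "F": 30.0, "Cl": 5.0,
                    "Br": -6.0, "I": -32.0, "S": 6.0,
                }.get(sym, 7.0 if sym == "C" else 0.0)
        return round(value, 1)
    if any(b.GetBondType() == Chem.BondType.TRIPLE for b in atom.GetBonds()):
        return round(70.0 + 8.0 * (1 - atom.GetTotalNumHs()), 1)
    if any(b.GetBondType() == Chem.BondType.DOUBLE for b in atom.GetBonds()):
        value = 124.0 + 5.0 * (2 - atom.GetTotalNumHs())
        return round(value, 1)
    # sp3
    value = {3: 14.0, 2: 23.0, 1: 32.0, 0: 36.0}[min(atom.GetTotalNumHs(), 3)]
    for nbr in atom.GetNeighbors():
        sym = nbr.GetSymbol()
        if sym == "O":
            value += 45.0
        elif sym == "N":
            value += 22.0
        elif sym == "S":
            value += 12.0
        elif sym == "F":
            value += 55.0
        elif sym == "Cl":
            value += 24.0
        elif sym == "Br":
            value += 12.0
        elif sym == "I":
            value += -10.0
        elif sym == "C":
            if nbr.GetIsAromatic():
                value += 9.0
            elif _bond_order_to(nbr, "O", Chem.BondType.DOUBLE):
                value += 10.0
            elif nbr.GetSymbol() == "C" and any(
                b.GetBondType() != Chem.BondType.SINGLE for b in nbr.GetBonds()
            ):
                value += 6.0
            else:
                value += 2.0
    return round(min(value, 95.0), 1)


def proton_shift(mol: core.Molecule, carrier_idx: int) -> float:
    """Estimated 1H shift (ppm) for protons on one heavy atom, rounded 0.01."""
    atom = mol.GetAtomWithIdx(carrier_idx)
    if atom.GetSymbol() != "C":  # exchangeable; placement is nominal
        return {"O": 2.50, "N": 1.80, "S": 1.30}.get(atom.GetSymbol(), 2.0)
    if _bond_order_to(atom, "O", Chem.BondType.DOUBLE):
        return 9.75  # aldehyde / formyl
    if atom.GetIsAromatic():
        value = 7.25
        for nbr in atom.GetNeighbors():
            bond = mol.GetBondBetweenAtoms(carrier_idx, nbr.GetIdx())
            sym = nbr.GetSymbol()
            if nbr.GetIsAromatic() and bond.GetIsAromatic():
                if sym == "N":
                    value += 0.70
                elif sym == "O":
                    value -= 0.65
                elif sym == "S":
                    value -= 0.15
                elif _bond_order_to(nbr, "O", Chem.BondType.DOUBLE):
                    value += 0.30
            else:
                if sym == "O":
                    value -= 0.35
                elif sym == "N":
                    value -= 0.50
                elif sym == "C":
                    value += 0.05
        return round(max(5.9, min(value, 9.4)), 2)
    if any(b.GetBondType() == Chem.BondType.TRIPLE for b in atom.GetBonds()):
        return 2.55
    if any(b.GetBondType() == Chem.BondType.DOUBLE for b in atom.GetBonds()):
        value = 5.55
        if any(n.GetIsAromatic() for n in atom.GetNeighbors()):
            value += 0.80
        if any(n.GetSymbol() == "O" for n in atom.GetNeighbors()):
            value += 0.90
        return round(value, 2)
    # sp3
    value = {3: 0.90, 2: 1.25, 1: 1.55, 0: 1.55}[min(atom.GetTotalNumHs(), 3)]
    for nbr in atom.GetNeighbors():
        sym = nbr.GetSymbol()
        if sym == "O":
            # ester oxygen deshields more than ether/alcohol oxygen
            ester = any(
                _bond_order_to(o, "O", Chem.BondType.DOUBLE)
                for o in nbr.GetNeighbors()
                if o.GetIdx() != carrier_idx
            )
            value += 2.95 if ester else 2.40
        elif sym == "N":
            value += 1.60
        elif sym == "S":
            value += 1.30
        elif sym == "F":
            value += 3.40
        elif sym == "Cl":
            value += 2.10
        elif sym == "Br":
            value += 1.95
        elif sym == "I":
            value += 1.70
        elif sym == "C":
            if nbr.GetIsAromatic():
                value += 1.40
            elif _bond_order_to(nbr, "O", Chem.BondType.DOUBLE):
                value += 1.15
            elif _bond_order_to(nbr, "N", Chem.BondType.TRIPLE):
                value += 1.30
            elif any(
                b.GetBondType() == Chem.BondType.DOUBLE for b in nbr.GetBonds()
            ):
                value += 0.65
    return round(min(value, 6.40), 2)


_MULT_LABELS = {0: "s", 1: "d", 2: "t", 3: "q", 4: "quint"}


def multiplicity(
    mol: core.Molecule, cls: NucleusClass, classes: list[NucleusClass] | None = None
) -> str:
    """n+1 multiplicity label for a proton class.

    Coupling partners are non-exchangeable protons on adjacent carbons that
    belong to a different equivalence class; equivalent neighbors do not
    split.  More than one distinct partner class, or n > 4, buckets to "m".
    """
    if cls.kind != "H":
        raise ValueError("multiplicity is defined for proton classes")
    if cls.exchangeable:
        return "br s"
    if classes is None:
        classes = nucleus_classes(mol)
    h_class_of: dict[int, NucleusClass] = {}
    for c in classes:
        if c.kind == "H" and not c.exchangeable:
            for i in c.atom_ids:
                h_class_of[i] = c
    carrier = cls.atom_ids[0]
    partners: dict[tuple[int, ...], int] = {}
    for nbr in mol.GetAtomWithIdx(carrier).GetNeighbors():
        j = nbr.GetIdx()
        if nbr.GetSymbol() != "C" or j not in h_class_of:
            continue
        other = h_class_of[j]
        if other.atom_ids == cls.atom_ids:
            continue  # same class: equivalent, no splitting
        partners[other.atom_ids] = partners.get(other.atom_ids, 0) + (
            mol.GetAtomWithIdx(j).GetTotalNumHs()
        )
    if not partners:
        return "s"
    if len(partners) > 1:
        return "m"
    n = next(iter(partners.values()))
    return _MULT_LABELS.get(n, "m")


def _separate(shifts: dict[tuple[int, ...], float], min_gap: float, digits: int):
    """Deterministically nudge colliding class shifts apart (by class order)."""
    ordered = sorted(shifts.items(), key=lambda kv: (kv[1], kv[0]))
    prev = None
    for key, val in ordered:
        if prev is not None and val - prev < min_gap:
            val = round(prev + min_gap, digits)
        shifts[key] = val
        prev = val


def simulate_1d(mol: core.Molecule) -> Spectrum1D:
    classes = nucleus_classes(mol)
    h_classes = [c for c in classes if c.kind == "H" and not c.exchangeable]
    c_classes = [c for c in classes if c.kind == "C"]
    h_shifts = {c.atom_ids: proton_shift(mol, c.atom_ids[0]) for c in h_classes}
    c_shifts = {c.atom_ids: carbon_shift(mol, c.atom_ids[0]) for c in c_classes}
    _separate(h_shifts, 0.05, 2)
    _separate(c_shifts, 0.5, 1)
    peaks = [
        Peak1H(h_shifts[c.atom_ids], multiplicity(mol, c, classes), c.n_h)
        for c in h_classes
    ]
    peaks.sort(key=lambda p: -p.shift)
    carbons = tuple(sorted(c_shifts.values(), reverse=True))
    n_exch = sum(c.n_h for c in classes if c.kind == "H" and c.exchangeable)
    return Spectrum1D(tuple(peaks), carbons, n_exch)


def simulate_2d(mol: core.Molecule) -> Spectrum2D:
    classes = nucleus_classes(mol)
    h_classes = [c for c in classes if c.kind == "H" and not c.exchangeable]
    c_classes = [c for c in classes if c.kind == "C"]
    h_shifts = {c.atom_ids: proton_shift(mol, c.atom_ids[0]) for c in h_classes}
    c_shifts = {c.atom_ids: carbon_shift(mol, c.atom_ids[0]) for c in c_classes}
    _separate(h_shifts, 0.05, 2)
    _separate(c_shifts, 0.5, 1)
    dmat = Chem.GetDistanceMatrix(mol)

    cosy = set()
    for i, a in enumerate(h_classes):
        for b in h_classes[i + 1 :]:
            if any(dmat[x][y] == 1 for x in a.atom_ids for y in b.atom_ids):
                pair = tuple(
                    sorted((h_shifts[a.atom_ids], h_shifts[b.atom_ids]), reverse=True)
                )
                cosy.add(pair)

    hsqc = set()
    for c in c_classes:
        if any(mol.GetAtomWithIdx(i).GetTotalNumHs() for i in c.atom_ids):
            hsqc.add((c_shifts[c.atom_ids], h_shifts[c.atom_ids]))

    hmbc = set()
    for h in h_classes:
        for c in c_classes:
            dists = {
                int(dmat[x][y]) for x in h.atom_ids for y in c.atom_ids
            }
            if dists & {1, 2}:
                pair = (c_shifts[c.atom_ids], h_shifts[h.atom_ids])
                if pair not in hsqc:
                    hmbc.add(pair)

    return Spectrum2D(
        tuple(sorted(cosy, reverse=True)),
        tuple(sorted(hsqc, reverse=True)),
        tuple(sorted(hmbc, reverse=True)),
    )


def simulate(mol: core.Molecule, with_2d: bool = False) -> SpectrumSet:
    return SpectrumSet(
        formula=core.molecular_formula(mol),
        one_d=simulate_1d(mol),
        two_d=simulate_2d(mol) if with_2d else None,
    )


def render_spectrum_set(spec: SpectrumSet) -> str:
    """Plain-text rendering used verbatim inside prompts (stable format)."""
    lines = [f"Molecular formula: {spec.formula}"]
    one_d = spec.one_d
    h_parts = [
        f"d {p.shift:.2f} ({p.multiplicity}, {p.integration}H)"
        for p in one_d.protons
    ]
    lines.append("1H NMR: " + ("; ".join(h_parts) if h_parts else "no signals"))
    if one_d.n_exchangeable:
        plural = "s" if one_d.n_exchangeable > 1 else ""
        lines.append(
            f"({one_d.n_exchangeable} exchangeable proton{plural} not shown)"
        )
    c_parts = [f"d {s:.1f}" for s in one_d.carbons]
    lines.append("13C NMR: " + ("; ".join(c_parts) if c_parts else "no signals"))
    if spec.two_d is not None:
        lines.append(
            "COSY (1H-1H): "
            + "; ".join(f"({a:.2f}, {b:.2f})" for a, b in spec.two_d.cosy)
        )
        lines.append(
            "HSQC (13C-1H, one bond): "
            + "; ".join(f"({c:.1f}, {h:.2f})" for c, h in spec.two_d.hsqc)
        )
        lines.append(
            "HMBC (13C-1H, two to three bonds): "
            + "; ".join(f"({c:.1f}, {h:.2f})" for c, h in spec.two_d.hmbc)
        )
    return "\n".join(lines)


def gen_nmr_question(
    mol: core.Molecule, mode: Literal["1d", "2d"], seed: int, qid: str
) -> QuestionRecord:
    spec = simulate(mol, with_2d=(mode == "2d"))
    rendered = render_spectrum_set(spec)
    extra = " and the 2D spectra" if mode == "2d" else ""
    prompt = (
        f"The following NMR data{extra} were recorded for an unknown compound "
        "(shifts in ppm, d denotes delta):\n"
        f"{rendered}\n"
        "Determine the structure and write it as a SMILES string.\n"
        f"{ANSWER_INSTRUCTION}"
    )
    return QuestionRecord(
        id=qid,
        category="nmr_1d" if mode == "1d" else "nmr_2d",
        prompt=prompt,
        truth=core.canonical_smiles(mol),
        meta={
            "seed": seed,
            "source_smiles": core.canonical_smiles(mol),
            "mode": mode,
            "rendered_spectra": rendered,
        },
    )
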