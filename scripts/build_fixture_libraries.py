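"""Build the bundled fixture molecule libraries.

Run from the repository root:

    python scripts/build_fixture_libraries.py

Writes ``src/chemquiz/data/druglike.smi`` (synthetic drug-like set,
10-30 heavy atoms, organic-subset elements) and
``src/chemquiz/data/small_chno.smi`` (C/H/N/O molecules of <= 10 heavy
atoms).  Fully deterministic; the committed files are its output.
Both libraries are synthetic stand-ins assembled combinatorially, not
samples of any external compound collection.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import RWMol

RDLogger.DisableLog("rdApp.*")

OUT = Path(__file__).resolve().parents[1] / "src" / "chemquiz" / "data"

# Scaffolds: common (hetero)aromatic and saturated ring systems, incl. fused
# bicyclics so shortest-path questions can cross ring fusions.
SCAFFOLDS = [
    "c1ccccc1",            # benzene
    "c1ccncc1",            # pyridine
    "c1cncnc1",            # pyrimidine
    "c1ccc2ccccc2c1",      # naphthalene
    "c1ccc2ncccc2c1",      # quinoline
    "c1ccc2[nH]ccc2c1",    # indole
    "c1ccc2occc2c1",       # benzofuran
    "c1ccc2sccc2c1",       # benzothiophene
    "c1ccsc1",             # thiophene
    "c1ccoc1",             # furan
    "c1cc[nH]c1",          # pyrrole
    "c1cnc[nH]1",          # imidazole
    "c1cn[nH]c1",          # pyrazole
    "c1ocnc1",             # oxazole
    "c1scnc1",             # thiazole
    "C1CCNCC1",            # piperidine
    "C1CNCCN1",            # piperazine
    "C1COCCN1",            # morpholine
    "C1CCCCC1",            # cyclohexane
    "C1CCNC1",             # pyrrolidine
    "c1ccc2[nH]cnc2c1",    # benzimidazole
    "c1ccc2ncncc2c1",      # quinazoline-like
    "c1cc2ccccc2cn1",      # isoquinoline
    "C1Cc2ccccc2C1",       # indane
    "C1CCc2ccccc2C1",      # tetralin
    "O=c1ccoc2ccccc12",    # chromone
    "O=c1ccc2ccccc2o1",    # coumarin
]

# Substituent fragments; attachment atom is atom 0 of the fragment SMILES.
SUBSTITUENTS = [
    "C", "CC", "CCC", "C(C)C", "C(C)(C)C", "CC(C)C",
    "F", "Cl", "Br", "I",
    "O", "OC", "OCC", "OC(F)(F)F",
    "N", "NC", "N(C)C", "NC(C)=O",
    "C#N", "[N+](=O)[O-]",
    "C(F)(F)F",
    "C=O", "C(C)=O", "C(=O)O", "C(=O)OC", "C(=O)N", "C(=O)NC",
    "S(C)(=O)=O", "S(N)(=O)=O", "SC",
    "c1ccccc1", "c1ccncc1", "Cc1ccccc1",
    "N1CCOCC1", "N1CCNCC1", "N1CCCC1", "C1CC1",
    "CO",            # hydroxymethyl (attach at C)
    "CN",            # aminomethyl
    "C=C",
]


def _attach(scaffold: Chem.Mol, site: int, frag_smiles: str) -> Chem.Mol | None:
    frag = Chem.MolFromSmiles(frag_smiles)
    if frag is None:
        return None
    combo = RWMol(Chem.CombineMols(scaffold, frag))
    combo.AddBond(site, scaffold.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        mol = combo.GetMol()
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def _open_sites(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() >= 1]


def _ok_rings(mol: Chem.Mol) -> bool:
    # cycle rank must agree with SSSR: keeps ring-count truths unambiguous
    rank = mol.GetNumBonds() - mol.GetNumAtoms() + len(Chem.GetMolFrags(mol))
    return rank == len(Chem.GetSSSR(mol))


def build_druglike(n_target: int = 560, seed: int = 20240901) -> list[str]:
    rng = np.random.default_rng(seed)
    seen: dict[str, None] = {}
    attempts = 0
    while len(seen) < n_target and attempts < 100_000:
        attempts += 1
        scaffold = Chem.MolFromSmiles(SCAFFOLDS[int(rng.integers(len(SCAFFOLDS)))])
        n_sub = int(rng.integers(1, 4))
        mol = scaffold
        ok = True
        for _ in range(n_sub):
            sites = _open_sites(mol)
            if not sites:
                ok = False
                break
            site = int(sites[int(rng.integers(len(sites)))])
            frag = SUBSTITUENTS[int(rng.integers(len(SUBSTITUENTS)))]
            nxt = _attach(mol, site, frag)
            if nxt is None:
                ok = False
                break
            mol = nxt
        if not ok:
            continue
        if not (10 <= mol.GetNumHeavyAtoms() <= 30):
            continue
        if not _ok_rings(mol):
            continue
        Chem.RemoveStereochemistry(mol)
        smi = Chem.MolToSmiles(mol)
        seen.setdefault(smi, None)
    return list(seen)


SMALL_PARENTS = [
    # open-chain skeletons with a functional head; R attaches at first atom
    "{r}O", "{r}OC", "{r}N", "{r}NC", "{r}C=O", "{r}C(C)=O",
    "{r}C(=O)O", "{r}C(=O)OC", "{r}C(=O)N", "{r}C#N", "{r}OC=O",
    "{r}N(C)C", "{r}CO", "{r}C(C)O",
]
SMALL_R = ["C", "CC", "CCC", "C(C)C", "CCCC", "CC(C)C", "CCCCC", "C(C)(C)C"]
SMALL_EXTRA = [
    "C", "CC", "CCC", "CCCC", "CCCCC", "CCCCCC", "CC(C)C", "CC(C)(C)C",
    "C=C", "C=CC", "CC=CC", "C#C", "C#CC", "C=CC=C",
    "C1CC1", "C1CCC1", "C1CCCC1", "C1CCCCC1", "C1CCCCCC1",
    "C1CCOC1", "C1CCOCC1", "C1COCCO1", "C1CCNC1", "C1CCNCC1", "C1COCCN1",
    "C1CNCCN1", "O=C1CCCC1", "O=C1CCCCC1", "O=C1CCC1", "C1CCC(=O)NC1",
    "O=C1CCCO1", "O=C1CCCN1",
    "c1ccccc1", "Cc1ccccc1", "CCc1ccccc1", "Cc1ccccc1C", "Cc1ccc(C)cc1",
    "Oc1ccccc1", "COc1ccccc1", "Nc1ccccc1", "CNc1ccccc1", "Cc1ccc(O)cc1",
    "O=Cc1ccccc1", "CC(=O)c1ccccc1", "OCc1ccccc1", "NCc1ccccc1",
    "Cc1ccc(N)cc1", "C=Cc1ccccc1", "N#Cc1ccccc1", "OC(=O)c1ccccc1",
    "c1ccncc1", "Cc1ccncc1", "Cc1cccnc1", "Cc1ccccn1", "c1cncnc1",
    "c1ccoc1", "Cc1ccco1", "c1cc[nH]c1", "Cc1ccc[nH]1", "c1cnc[nH]1",
    "O=Cc1ccco1", "CC(=O)c1ccco1", "Nc1ccncc1", "Oc1ccncc1",
    "OCC(O)CO", "OCCO", "OCCCO", "OCCN", "OCCOC", "NCCN", "OCC=C",
    "CC(O)C", "CC(O)CC", "CC(N)C", "CC(O)C(C)O", "CC(=O)CC(C)=O",
    "COC(=O)C=C", "CC=CC=O", "C=CC=O", "C=CC(C)=O", "CC(=O)OCC",
    "O=CC=O", "CC(=O)C(C)=O", "OCC#C", "NCC#N", "OC(=O)CC(=O)O",
    "CC(=O)NC", "CN(C)C=O", "CNC=O", "NC(N)=O", "CNC(N)=O", "O=C(N)N(C)C",
    "COCOC", "CC(OC)OC", "C1OCOC1", "CC1CO1", "C1CO1", "CC1CCCO1",
]


def build_small(druglike: set[str]) -> list[str]:
    cands: list[str] = list(SMALL_EXTRA)
    for tpl, r in itertools.product(SMALL_PARENTS, SMALL_R):
        cands.append(tpl.format(r=r))
    seen: dict[str, None] = {}
    for smi in cands:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        if mol.GetNumHeavyAtoms() > 10:
            continue
        if any(a.GetSymbol() not in {"C", "H", "N", "O"} for a in mol.GetAtoms()):
            continue
        if not _ok_rings(mol):
            continue
        Chem.RemoveStereochemistry(mol)
        can = Chem.MolToSmiles(mol)
        if can in druglike:
            continue
        seen.setdefault(can, None)
    return list(seen)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    druglike = build_druglike()
    small = build_small(set(druglike))
    assert len(druglike) >= 500, len(druglike)
    assert len(small) >= 100, len(small)
    header_d = (
        "# synthetic drug-like fixture library (combinatorial scaffold "
        "decoration, 10-30 heavy atoms)\n"
    )
    header_s = "# enumerated C/H/N/O molecules, <= 10 heavy atoms\n"
    (OUT / "druglike.smi").write_text(header_d + "\n".join(druglike) + "\n")
    (OUT / "small_chno.smi").write_text(header_s + "\n".join(small) + "\n")
    print(f"druglike: {len(druglike)}  small: {len(small)}")


if __name__ == "__main__":
    main()
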