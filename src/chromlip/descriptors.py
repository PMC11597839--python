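"""Molecular descriptors for drug-likeness screening.

Computes, from a SMILES-parsed structure, the property sheet a
Rule-of-Five-style screen needs: average molecular weight, monoisotopic
adduct mass, Ertl TPSA, Wildman-Crippen molar refraction, hydrogen-bond
donor/acceptor counts under two documented conventions, rotatable bonds and
atom counts.

Structure handling (parsing, aromaticity perception, implicit hydrogens,
ring perception) is delegated to RDKit; the molecule container throughout is
``rdkit.Chem.Mol``. Masses use the packaged element table
(IUPAC 2021 average weights, principal-isotope monoisotopic masses). TPSA is
the in-package Ertl fragment summation (:mod:`chromlip.tpsa`). Molar
refraction is the Wildman-Crippen atomic-contribution model as implemented
by Open Babel (the ``obabel`` executable), whose resolution of the published
atom-typing table matches the values the common web platforms report;
RDKit's reading of the same table differs by a few tenths of an MR unit on
aromatic amines and by ~2.6 units on nitroarenes.

Descriptor computation is pure: the same SMILES yields the identical
DescriptorSet on every run. Values are carried at full precision; rounding
conventions (two decimals for MW/TPSA/MR, four for m/z) apply at report
time only.
"""

from __future__ import annotations

import csv
import shutil
import subprocess
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from .errors import ConfigurationError, StructureParseError
from .tpsa import ertl_tpsa

PROTON_MASS = 1.00782503207  # monoisotopic mass of 1H; "calcd" HRMS
# convention: no electron-mass correction

_HILL_FIRST = ("C", "H")


def load_element_masses() -> Dict[str, Tuple[float, float]]:
    """Element symbol -> (average mass g/mol, monoisotopic mass Da)."""
    path = resources.files("chromlip.data").joinpath("element_masses.csv")
    with path.open() as handle:
        rows = [r for r in csv.reader(handle) if r and not r[0].startswith("#")]
    table = {}
    for row in rows[1:]:
        table[row[0]] = (float(row[1]), float(row[2]))
    return table


_MASSES = load_element_masses()


def parse_structure(smiles: str, compound_id: str = "") -> Chem.Mol:
    """Parse a SMILES string into a sanitised molecule.

    Aromaticity is perceived and implicit hydrogens assigned. A parse
    failure raises :class:`StructureParseError` naming the offending input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureParseError(
            f"could not parse SMILES {smiles!r}"
            + (f" for compound {compound_id!r}" if compound_id else "")
        )
    if compound_id:
        mol.SetProp("_Name", compound_id)
    return mol


def molecular_formula(mol: Chem.Mol) -> Dict[str, int]:
    """Element -> count map, implicit hydrogens included."""
    counts: Dict[str, int] = {}
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
        n_h = atom.GetTotalNumHs()
        if n_h:
            counts["H"] = counts.get("H", 0) + n_h
    return counts


def hill_formula(formula: Mapping[str, int]) -> str:
    """Deterministic Hill-order display string (C, H, then alphabetical)."""
    parts = []
    rest = sorted(k for k in formula if k not in _HILL_FIRST)
    for sym in (*_HILL_FIRST, *rest) if "C" in formula else sorted(formula):
        n = formula.get(sym, 0)
        if n:
            parts.append(sym + (str(n) if n > 1 else ""))
    return "".join(parts)


def average_mass(mol: Chem.Mol, masses: Optional[Mapping[str, Tuple[float, float]]] = None) -> float:
    """Average molecular weight (g/mol) from standard atomic weights."""
    masses = masses or _MASSES
    total = 0.0
    for sym, n in molecular_formula(mol).items():
        if sym not in masses:
            raise ConfigurationError(f"element {sym!r} missing from the mass table")
        total += n * masses[sym][0]
    return total


_ADDUCTS: Dict[str, Tuple[Dict[str, int], int]] = {
    # adduct -> (formula delta, charge); masses summed without
    # electron-mass correction, per the synthetic-chemistry "calcd" habit
    "[M]": ({}, 0),
    "[M+H]+": ({"H": 1}, 1),
    "[M+Na]+": ({"Na": 1}, 1),
    "[M-H]-": ({"H": -1}, -1),
}


def monoisotopic_mz(
    formula: Mapping[str, int],
    adduct: str = "[M+H]+",
    masses: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> float:
    """Theoretical monoisotopic m/z of an adduct of the given formula.

    Sums principal-isotope masses of the adduct formula with no
    electron-mass correction; report to four decimals.
    """
    masses = masses or _MASSES
    if adduct not in _ADDUCTS:
        raise ConfigurationError(
            f"unknown adduct {adduct!r}; known: {sorted(_ADDUCTS)}"
        )
    delta, _charge = _ADDUCTS[adduct]
    counts = dict(formula)
    for sym, n in delta.items():
        counts[sym] = counts.get(sym, 0) + n
    total = 0.0
    for sym, n in counts.items():
        if sym not in masses:
            raise ConfigurationError(f"element {sym!r} missing from the mass table")
        total += n * masses[sym][1]
    return total


def count_hbd(mol: Chem.Mol) -> int:
    """Hydrogen-bond donors: N or O atoms bearing >= 1 hydrogen.

    Heteroatom-counted convention: an NH2 group is one donor.
    """
    return sum(
        1
        for atom in mol.GetAtoms()
        if atom.GetSymbol() in ("N", "O") and atom.GetTotalNumHs() >= 1
    )


# Acceptor exclusions for the pharmacophore-style convention, as SMARTS.
# Pyrrole-type aromatic N (three connections), amide/sulfonamide N, aromatic
# amine N and the nitro N itself are poor acceptors and are excluded; all
# remaining neutral N and O (nitro oxygens included) count.
_PHARMA_EXCLUSIONS = [
    "[n;X3;+0]",                # pyrrole-type / substituted aromatic N
    "[N;+0][C,S]=[O,S]",        # amide- / thioamide- / sulfonamide-like N
    "[N;+0;!$(N=*)]c",          # aromatic amine N
    "[N;$([N+](=O)[O-]),$(N(=O)=O)]",  # nitro N
    "[N+,O+]",                  # cationic
]
_PHARMA_PATTERNS = [Chem.MolFromSmarts(s) for s in _PHARMA_EXCLUSIONS]


def count_hba(mol: Chem.Mol, convention: str = "lipinski_n_plus_o") -> int:
    """Hydrogen-bond acceptor count under a named convention.

    ``lipinski_n_plus_o``
        Count of all N and O atoms — the original Rule-of-Five definition
        and the default for rule evaluation.
    ``pharma_acceptor``
        N/O acceptors excluding pyrrole-type aromatic N, amide N, aromatic
        amine N and nitro N (pattern set in the module source).
    """
    if convention == "lipinski_n_plus_o":
        return sum(1 for a in mol.GetAtoms() if a.GetSymbol() in ("N", "O"))
    if convention == "pharma_acceptor":
        excluded = set()
        for patt in _PHARMA_PATTERNS:
            for match in mol.GetSubstructMatches(patt):
                excluded.add(match[0])
        return sum(
            1
            for a in mol.GetAtoms()
            if a.GetSymbol() in ("N", "O") and a.GetIdx() not in excluded
        )
    raise ConfigurationError(f"unknown HBA convention {convention!r}")


def rotatable_bonds(mol: Chem.Mol) -> int:
    """Count of rotatable bonds (acyclic single bonds between non-terminal
    heavy atoms, amide C-N excluded — the standard strict convention)."""
    return rdMolDescriptors.CalcNumRotatableBonds(mol)


def _run_obabel(args: Sequence[str], stdin: str) -> str:
    exe = shutil.which("obabel")
    if exe is None:
        raise ConfigurationError(
            "the 'obabel' executable (Open Babel) is required for molar "
            "refraction but was not found on PATH"
        )
    proc = subprocess.run(
        [exe, *args], input=stdin, capture_output=True, text=True, check=False
    )
    if proc.returncode != 0:
        raise ConfigurationError(f"obabel failed: {proc.stderr.strip()}")
    return proc.stdout


def molar_refraction_batch(smiles: Sequence[str]) -> List[float]:
    """Wildman-Crippen molar refraction for a batch of SMILES (one obabel
    call)."""
    if not smiles:
        return []
    out = _run_obabel(["-ismi", "-osmi", "--append", "MR"], "\n".join(smiles) + "\n")
    values = []
    for line in out.strip().splitlines():
        values.append(float(line.split()[-1]))
    if len(values) != len(smiles):
        raise ConfigurationError(
            f"obabel returned {len(values)} MR values for {len(smiles)} inputs"
        )
    return values


def molar_refraction(mol: Chem.Mol) -> float:
    """Wildman-Crippen molar refraction of one molecule (MR units)."""
    return molar_refraction_batch([Chem.MolToSmiles(mol)])[0]


def heavy_atoms(mol: Chem.Mol) -> int:
    return mol.GetNumHeavyAtoms()


def aromatic_heavy_atoms(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())


@dataclass(frozen=True)
class DescriptorSet:
    """One compound's descriptor sheet row.

    ``logp_inputs`` holds externally supplied logP estimates (experimental
    or from prediction services) keyed by method name; this package computes
    no logP of its own.
    """

    compound_id: str
    mw: float
    monoisotopic_mass: float
    tpsa: float
    molar_refraction: float
    hba_lipinski: int
    hba_pharma: int
    hbd: int
    rotatable_bonds: int
    heavy_atoms: int
    total_atoms: int
    aromatic_heavy_atoms: int
    formula: str
    logp_inputs: Mapping[str, float] = field(default_factory=dict)

    @property
    def aromatic_proportion(self) -> float:
        return self.aromatic_heavy_atoms / self.heavy_atoms if self.heavy_atoms else 0.0


def compute_descriptors(
    mol: Chem.Mol,
    compound_id: str = "",
    logp_inputs: Optional[Mapping[str, float]] = None,
    _mr: Optional[float] = None,
) -> DescriptorSet:
    """Full DescriptorSet for one molecule."""
    formula = molecular_formula(mol)
    cid = compound_id or (mol.GetProp("_Name") if mol.HasProp("_Name") else "")
    return DescriptorSet(
        compound_id=cid,
        mw=average_mass(mol),
        monoisotopic_mass=monoisotopic_mz(formula, "[M]"),
        tpsa=ertl_tpsa(mol),
        molar_refraction=_mr if _mr is not None else molar_refraction(mol),
        hba_lipinski=count_hba(mol, "lipinski_n_plus_o"),
        hba_pharma=count_hba(mol, "pharma_acceptor"),
        hbd=count_hbd(mol),
        rotatable_bonds=rotatable_bonds(mol),
        heavy_atoms=heavy_atoms(mol),
        total_atoms=heavy_atoms(mol) + formula.get("H", 0),
        aromatic_heavy_atoms=aromatic_heavy_atoms(mol),
        formula=hill_formula(formula),
        logp_inputs=dict(logp_inputs or {}),
    )


def descriptor_sheet(
    structures: Iterable[Tuple[str, str]],
    logp_inputs: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> List[DescriptorSet]:
    """Descriptor sets for ``(compound_id, smiles)`` pairs.

    Molar refraction is computed in a single Open Babel batch call.
    """
    pairs = list(structures)
    mols = [parse_structure(smi, cid) for cid, smi in pairs]
    mrs = molar_refraction_batch([Chem.MolToSmiles(m) for m in mols])
    out = []
    for (cid, _), mol, mr in zip(pairs, mols, mrs):
        inputs = (logp_inputs or {}).get(cid, {})
        out.append(compute_descriptors(mol, cid, inputs, _mr=mr))
    return out


def sheet_frame(descs: Sequence[DescriptorSet]):
    """Descriptor sets as a report-ready pandas DataFrame (rounded)."""
    import pandas as pd

    rows = []
    for d in descs:
        rows.append(
            {
                "compound_id": d.compound_id,
                "formula": d.formula,
                "mw": round(d.mw, 2),
                "monoisotopic_mass": round(d.monoisotopic_mass, 4),
                "hba_lipinski": d.hba_lipinski,
                "hba_pharma": d.hba_pharma,
                "hbd": d.hbd,
                "molar_refraction": round(d.molar_refraction, 2),
                "tpsa": round(d.tpsa, 2),
                "rotatable_bonds": d.rotatable_bonds,
                "heavy_atoms": d.heavy_atoms,
                "total_atoms": d.total_atoms,
            }
        )
    return pd.DataFrame(rows)
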