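"""Topological polar surface area by Ertl fragment-contribution summation.

TPSA is estimated as a sum of tabulated surface contributions over the
polar-atom environments (N, O and, with the extension used here, S and P) of
a 2D structure. Each polar atom is assigned an environment *signature* —
element, aromaticity, formal charge, attached hydrogen count, counts of
single/double/triple/aromatic bonds and three-membered-ring membership — and
looked up in the packaged contribution table
(``data/tpsa_fragments.csv``, table version 1.0).

Nitro groups are normalised to their neutral pentavalent form
(N(=O)=O, contribution 11.68 + 2 x 17.07 = 45.82 A^2) before assignment,
the convention of the original parameterisation and of the common web
calculators; the charge-separated form produced by most SMILES toolkits
would otherwise be typed as an N-oxide-like environment and undercount the
group by 2.68 A^2.

An environment with no table entry raises
:class:`~chromlip.errors.UnsupportedEnvironmentError` — a polar atom never
silently contributes zero.
"""

from __future__ import annotations

import csv
from importlib import resources
from typing import Dict, List, Tuple

from rdkit import Chem

from .errors import UnsupportedEnvironmentError

TPSA_TABLE_VERSION = "1.0"

_POLAR_ELEMENTS = {"N", "O", "S", "P"}

# signature: (element, aromatic, charge, n_h, n_single, n_double, n_triple,
#             n_aromatic, ring3)
Signature = Tuple[str, int, int, int, int, int, int, int, int]


def _load_table() -> Dict[Signature, float]:
    table: Dict[Signature, float] = {}
    path = resources.files("chromlip.data").joinpath("tpsa_fragments.csv")
    with path.open() as handle:
        rows = [r for r in csv.reader(handle) if r and not r[0].startswith("#")]
    header = rows[0]
    for row in rows[1:]:
        rec = dict(zip(header, row))
        sig: Signature = (
            rec["element"],
            int(rec["aromatic"]),
            int(rec["charge"]),
            int(rec["n_h"]),
            int(rec["n_single"]),
            int(rec["n_double"]),
            int(rec["n_triple"]),
            int(rec["n_aromatic"]),
            int(rec["ring3"]),
        )
        table[sig] = float(rec["contribution"])
    return table


_TABLE = _load_table()


def _is_nitro_nitrogen(atom: Chem.Atom) -> bool:
    if atom.GetSymbol() != "N" or atom.GetFormalCharge() != 1:
        return False
    oxygens = [n for n in atom.GetNeighbors() if n.GetSymbol() == "O" and n.GetDegree() == 1]
    charges = sorted(o.GetFormalCharge() for o in oxygens)
    return len(oxygens) == 2 and charges == [-1, 0]


def _is_nitro_oxide(atom: Chem.Atom) -> bool:
    if atom.GetSymbol() != "O" or atom.GetFormalCharge() != -1 or atom.GetDegree() != 1:
        return False
    return _is_nitro_nitrogen(atom.GetNeighbors()[0])


def atom_signature(atom: Chem.Atom) -> Signature:
    """Environment signature of one atom, after nitro normalisation."""
    n_single = n_double = n_triple = n_arom = 0
    for bond in atom.GetBonds():
        if bond.GetIsAromatic():
            n_arom += 1
        elif bond.GetBondType() == Chem.BondType.SINGLE:
            n_single += 1
        elif bond.GetBondType() == Chem.BondType.DOUBLE:
            n_double += 1
        elif bond.GetBondType() == Chem.BondType.TRIPLE:
            n_triple += 1
    charge = atom.GetFormalCharge()
    # pentavalent-nitro normalisation: the charge-separated form has one
    # single bond to O(-); rewrite it as a second N=O double bond
    if _is_nitro_nitrogen(atom):
        charge, n_single, n_double = 0, n_single - 1, 2
    elif _is_nitro_oxide(atom):
        charge, n_single, n_double = 0, 0, 1
    return (
        atom.GetSymbol(),
        int(atom.GetIsAromatic()),
        charge,
        atom.GetTotalNumHs(),
        n_single,
        n_double,
        n_triple,
        n_arom,
        int(atom.IsInRingSize(3)),
    )


def atom_contributions(mol: Chem.Mol) -> List[Tuple[int, float]]:
    """Per-atom TPSA contributions as ``(atom index, contribution)`` pairs.

    Only polar atoms appear; carbons, hydrogens and halogens contribute
    nothing under this model.
    """
    out: List[Tuple[int, float]] = []
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in _POLAR_ELEMENTS:
            continue
        sig = atom_signature(atom)
        contrib = _TABLE.get(sig)
        if contrib is None and sig[-1] == 1:
            # environments parameterised without regard to 3-ring membership
            contrib = _TABLE.get(sig[:-1] + (0,))
        if contrib is None:
            raise UnsupportedEnvironmentError(
                f"no TPSA fragment contribution for atom {atom.GetIdx()} "
                f"({atom.GetSymbol()}) with environment signature {sig}"
            )
        out.append((atom.GetIdx(), contrib))
    return out


def ertl_tpsa(mol: Chem.Mol) -> float:
    """Topological polar surface area (A^2) of a molecule.

    Requires aromaticity to have been perceived (any sanitised RDKit
    molecule qualifies). Full precision is returned; round to two decimals
    at report time.
    """
    return sum(c for _, c in atom_contributions(mol))
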