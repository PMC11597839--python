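"""Packaged reference fixtures.

* the fifteen 1-substituted 4-[(aminophenoxy)methyl]-1,2,3-triazole aniline
  derivatives (compound ids 2a-6c) as SMILES;
* the seven-substance RP-TLC calibration panel (literature logP, extrapolated
  R_M0, per-compound fit diagnostics and the reported logP_TLC), with the
  internally inconsistent benzamide row flagged;
* the experimentally determined logP_TLC of the fifteen derivatives.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, List, Tuple

import pandas as pd


def _data_path(name: str):
    return resources.files("chromlip.data").joinpath(name)


def load_triazole_panel() -> List[Tuple[str, str]]:
    """``(compound_id, smiles)`` pairs for the fifteen derivatives."""
    pairs = []
    with _data_path("triazole_anilines.smi").open() as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cid, smi = line.split()
            pairs.append((cid, smi))
    return pairs


def load_tlc_standards() -> pd.DataFrame:
    """Calibration-standards panel (Table-1-style fixture).

    Columns: compound_id, name, logp_lit, r_m0, minus_b, fit_r,
    logp_tlc_reported, flagged. ``flagged`` marks the benzamide row, whose
    reported logP_TLC is inconsistent with the published calibration line.
    """
    with _data_path("tlc_standards.csv").open() as handle:
        df = pd.read_csv(handle, comment="#")
    return df


def load_experimental_logp() -> pd.DataFrame:
    """Experimentally determined logP_TLC of the fifteen derivatives."""
    with _data_path("experimental_logp.csv").open() as handle:
        return pd.read_csv(handle, comment="#")


def experimental_logp_inputs() -> Dict[str, Dict[str, float]]:
    """Per-compound ``logp_inputs`` mapping for descriptor/rule evaluation."""
    df = load_experimental_logp()
    return {
        row.compound_id: {"logp_tlc": float(row.logp_tlc)} for row in df.itertuples()
    }
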