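"""File formats and provenance.

Input tables are comma-separated, reports tab-separated; UTF-8 throughout
with '.' as the decimal separator regardless of locale. Every pipeline run
can write a machine-readable provenance record: input digests, the
configuration, package and contribution-table versions and the seed.
"""

from __future__ import annotations

import hashlib
import json
import subprocess
import shutil
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .errors import InputError
from .rp_tlc import PLATE_COLUMNS
from .tpsa import TPSA_TABLE_VERSION


def read_plates_csv(path) -> pd.DataFrame:
    """Plate-measurement table (see :data:`chromlip.rp_tlc.PLATE_COLUMNS`)."""
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as err:  # pandas raises several parse error types
        raise InputError(f"{path}: {err}") from err
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    for col in ("organic_fraction", "d_compound_cm", "d_front_cm"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header + 1-based
            raise InputError(f"{path}: non-numeric {col!r} near line {line}")
        df[col] = pd.to_numeric(df[col])
    return df


def read_standards_csv(path) -> pd.DataFrame:
    """Standards table: compound_id, logp_lit (extra columns pass through)."""
    df = pd.read_csv(path, comment="#")
    for col in ("compound_id", "logp_lit"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    return df


def read_structures(path) -> List[Tuple[str, str]]:
    """Two-column delimited structures file: compound_id, SMILES.

    '#' comments and blank lines are allowed; duplicate ids are an error.
    """
    pairs: List[Tuple[str, str]] = []
    seen = set()
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 2:
                raise InputError(f"{path}:{lineno}: expected 'compound_id SMILES'")
            cid, smi = fields
            if cid in seen:
                raise InputError(f"{path}:{lineno}: duplicate compound id {cid!r}")
            seen.add(cid)
            pairs.append((cid, smi))
    return pairs


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True, default=float)
        handle.write("\n")


def _sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _obabel_version() -> Optional[str]:
    exe = shutil.which("obabel")
    if exe is None:
        return None
    out = subprocess.run([exe, "-V"], capture_output=True, text=True)
    return out.stdout.strip() or None


def provenance_record(
    inputs: Optional[Dict[str, str]] = None,
    config: Optional[Dict] = None,
    seed: Optional[int] = None,
) -> Dict:
    """Machine-readable record of what produced an output."""
    import numpy
    import pandas
    import rdkit
    import scipy

    from . import __version__

    record: Dict = {
        "package": {"name": "chromlip", "version": __version__},
        "tpsa_table_version": TPSA_TABLE_VERSION,
        "libraries": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "rdkit": rdkit.__version__,
            "openbabel": _obabel_version(),
        },
        "seed": seed,
        "config": config or {},
        "inputs": {},
    }
    for name, path in (inputs or {}).items():
        record["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}
    return record
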