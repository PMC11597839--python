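"""Chromatographic lipophilicity from reversed-phase TLC plates.

The measurement chain:

1. ``Rf = d_compound / d_front`` — retardation factor of a spot.
2. ``R_M = log10(1/Rf - 1)`` — the Bate-Smith-Westall transform, linear in
   the organic-modifier volume fraction of the mobile phase under the
   Soczewinski-Wachtmeister model ``R_M = R_M0 + b * phi`` with ``b < 0``.
3. ``R_M0`` — the intercept at ``phi = 0`` (purely aqueous mobile phase),
   the chromatographic lipophilicity parameter, obtained by ordinary least
   squares over >= 3 mobile-phase compositions.
4. ``logP_TLC = slope * R_M0 + intercept`` — calibration of R_M0 against a
   panel of standards with literature logP, fitted by unweighted OLS of
   logP_lit on R_M0.

Replicate spots are averaged on the Rf scale before the (nonlinear) R_M
transform by default; averaging on the R_M scale is available behind the
``average_on`` flag. A spot that did not migrate or ran with the solvent
front is a flagged, excluded record — never a clamped Rf.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateDesignError,
    InputError,
    InsufficientDataError,
    InvalidSpotError,
)

PLATE_COLUMNS = [
    "compound_id",
    "role",
    "organic_fraction",
    "replicate",
    "d_compound_cm",
    "d_front_cm",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (1.245 -> 1.25), the convention of the
    reported tables; Python's built-in round is half-even."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def retardation_factor(d_compound: float, d_front: float) -> float:
    """Rf of one spot. Defined only for 0 < d_compound < d_front."""
    if not (0 < d_compound < d_front):
        raise InvalidSpotError(
            f"spot distance {d_compound} cm invalid for front {d_front} cm: "
            "R_M is undefined at Rf in {0, 1}"
        )
    return d_compound / d_front


def rm_value(rf: float) -> float:
    """Bate-Smith-Westall transform R_M = log10(1/Rf - 1).

    Strictly decreasing in Rf, zero at Rf = 0.5, antisymmetric about it:
    rm(x) = -rm(1 - x).
    """
    if not (0 < rf < 1):
        raise InvalidSpotError(f"Rf {rf} outside the open interval (0, 1)")
    return math.log10(1.0 / rf - 1.0)


@dataclass(frozen=True)
class RetentionSeries:
    """One compound's replicate-averaged (phi, R_M) points."""

    compound_id: str
    phi: Tuple[float, ...]
    r_m: Tuple[float, ...]
    n_replicates: Tuple[int, ...]

    def __post_init__(self):
        if len(set(self.phi)) != len(self.phi):
            raise InputError(f"{self.compound_id}: phi values must be distinct")


@dataclass(frozen=True)
class ExtrapolationFit:
    """OLS fit of R_M on phi: intercept R_M0, slope b (expected < 0)."""

    compound_id: str
    r_m0: float
    b: float
    r: float
    n_points: int


@dataclass(frozen=True)
class CalibrationModel:
    """Unweighted OLS of logP_lit on R_M0 over the standards panel."""

    slope: float
    intercept: float
    r: float
    n_standards: int
    residual_sd: float

    def predict(self, r_m0: float) -> float:
        return self.slope * r_m0 + self.intercept


@dataclass(frozen=True)
class LipophilicityResult:
    compound_id: str
    r_m0: float
    b: float
    fit_r: float
    n_phases: int
    logp_tlc: float


@dataclass
class PipelineReport:
    """Everything a run produces: the calibration, per-compound results and
    diagnostics, and the records excluded with reasons."""

    calibration: CalibrationModel
    results: List[LipophilicityResult]
    standard_fits: List[ExtrapolationFit]
    excluded: List[Tuple[str, str]] = field(default_factory=list)
    flagged_rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "compound_id": res.compound_id,
                "r_m0": round(res.r_m0, 4),
                "b": round(res.b, 4),
                "fit_r": round(res.fit_r, 4),
                "n_phases": res.n_phases,
                "logp_tlc": round_half_up(res.logp_tlc, 2),
            }
            for res in self.results
        ]
        return pd.DataFrame(rows)


def _normalise_fractions(phi: pd.Series) -> pd.Series:
    """Accept percent compositions (e.g. 40..80) and normalise to volume
    fractions, with a warning."""
    if (phi > 1).any():
        warnings.warn(
            "organic_fraction values > 1 interpreted as percent and divided by 100",
            stacklevel=3,
        )
        phi = phi / 100.0
    if not ((phi > 0) & (phi < 1)).all():
        raise InputError("organic_fraction values must lie in (0, 1) after normalisation")
    return phi


def validate_plates(plates: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Check the plate table; split off physically invalid spots.

    Returns ``(valid, flagged)`` where flagged rows have a ``reason``
    column. Conflicting roles for one compound are an input error.
    """
    missing = [c for c in PLATE_COLUMNS if c not in plates.columns]
    if missing:
        raise InputError(f"plate table missing columns: {missing}")
    df = plates.copy()
    df["organic_fraction"] = _normalise_fractions(df["organic_fraction"].astype(float))
    roles = df.groupby("compound_id")["role"].nunique()
    conflicted = roles[roles > 1].index.tolist()
    if conflicted:
        raise InputError(f"conflicting roles for compounds: {conflicted}")
    bad = ~(
        (df["d_compound_cm"] > 0)
        & (df["d_front_cm"] > 0)
        & (df["d_compound_cm"] < df["d_front_cm"])
    )
    flagged = df[bad].copy()
    if not flagged.empty:
        flagged["reason"] = "spot at or beyond solvent front, or non-positive distance"
    return df[~bad].copy(), flagged


def average_replicates(
    plates: pd.DataFrame, compound_id: str, average_on: str = "rf"
) -> RetentionSeries:
    """Collapse replicates into one (phi, R_M) point per mobile phase.

    ``average_on='rf'`` (default) averages Rf before the R_M transform;
    ``'rm'`` transforms each replicate first and averages R_M.
    """
    if average_on not in ("rf", "rm"):
        raise InputError(f"average_on must be 'rf' or 'rm', got {average_on!r}")
    sub = plates[plates["compound_id"] == compound_id]
    if sub.empty:
        raise InputError(f"no measurements for compound {compound_id!r}")
    phis, rms, counts = [], [], []
    for phi, grp in sorted(sub.groupby("organic_fraction"), key=lambda kv: kv[0]):
        rfs = [
            retardation_factor(d, f)
            for d, f in zip(grp["d_compound_cm"], grp["d_front_cm"])
        ]
        if average_on == "rf":
            rm = rm_value(float(np.mean(rfs)))
        else:
            rm = float(np.mean([rm_value(rf) for rf in rfs]))
        phis.append(float(phi))
        rms.append(rm)
        counts.append(len(rfs))
    return RetentionSeries(compound_id, tuple(phis), tuple(rms), tuple(counts))


def fit_retention_series(series: RetentionSeries) -> ExtrapolationFit:
    """OLS of R_M on phi; the intercept is R_M0, the slope is b."""
    if len(series.phi) < 3:
        raise InsufficientDataError(
            f"{series.compound_id}: {len(series.phi)} mobile phases; >= 3 required"
        )
    phi = np.asarray(series.phi, dtype=float)
    if np.ptp(phi) == 0:
        raise DegenerateDesignError(f"{series.compound_id}: zero variance in phi")
    fit = stats.linregress(phi, np.asarray(series.r_m, dtype=float))
    return ExtrapolationFit(
        compound_id=series.compound_id,
        r_m0=float(fit.intercept),
        b=float(fit.slope),
        r=float(fit.rvalue),
        n_points=len(series.phi),
    )


def fit_calibration(standards: Sequence[Tuple[float, float]]) -> CalibrationModel:
    """Fit logP_lit = slope * R_M0 + intercept over ``(logp_lit, r_m0)``
    pairs by unweighted OLS (direction fixed by the reporting convention)."""
    if len(standards) < 3:
        raise InsufficientDataError(f"{len(standards)} standards; >= 3 required")
    logp = np.array([s[0] for s in standards], dtype=float)
    r_m0 = np.array([s[1] for s in standards], dtype=float)
    if np.ptp(r_m0) == 0:
        raise DegenerateDesignError("zero variance in standards' R_M0")
    for value in np.unique(r_m0):
        ys = logp[r_m0 == value]
        if len(ys) > 1 and np.ptp(ys) > 0:
            warnings.warn(
                f"duplicate R_M0 {value} with conflicting logP_lit; fit proceeds",
                stacklevel=2,
            )
    fit = stats.linregress(r_m0, logp)
    resid = logp - (fit.slope * r_m0 + fit.intercept)
    dof = len(standards) - 2
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else float("nan")
    return CalibrationModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        n_standards=len(standards),
        residual_sd=residual_sd,
    )


def apply_calibration(model: CalibrationModel, r_m0: float) -> float:
    """logP_TLC for one R_M0 (full precision; round half-up to 2 decimals at
    report time)."""
    return model.predict(r_m0)


def run_pipeline(
    plates: pd.DataFrame,
    standards: pd.DataFrame,
    average_on: str = "rf",
) -> PipelineReport:
    """Standards -> calibration; test compounds -> logP_TLC.

    ``plates`` follows :data:`PLATE_COLUMNS`; ``standards`` maps
    ``compound_id`` to ``logp_lit``. Compounds whose series cannot be fitted
    (too few usable spots) are reported in ``excluded`` rather than silently
    dropped.
    """
    if "compound_id" not in standards.columns or "logp_lit" not in standards.columns:
        raise InputError("standards table needs columns compound_id, logp_lit")
    valid, flagged = validate_plates(plates)
    roles = dict(zip(valid["compound_id"], valid["role"]))
    std_ids = [cid for cid, role in roles.items() if role == "standard"]
    test_ids = [cid for cid, role in roles.items() if role == "test"]
    if not std_ids or not test_ids:
        raise InputError("pipeline needs both standard and test compounds")
    logp_lit = dict(zip(standards["compound_id"], standards["logp_lit"]))

    excluded: List[Tuple[str, str]] = []
    fits: Dict[str, ExtrapolationFit] = {}
    for cid in (*std_ids, *test_ids):
        try:
            series = average_replicates(valid, cid, average_on=average_on)
            fits[cid] = fit_retention_series(series)
        except (InsufficientDataError, DegenerateDesignError, InputError) as err:
            excluded.append((cid, str(err)))

    pairs = []
    for cid in std_ids:
        if cid not in fits:
            continue
        if cid not in logp_lit:
            excluded.append((cid, "standard missing from the logP_lit table"))
            continue
        pairs.append((float(logp_lit[cid]), fits[cid].r_m0))
    calibration = fit_calibration(pairs)

    results = [
        LipophilicityResult(
            compound_id=cid,
            r_m0=fits[cid].r_m0,
            b=fits[cid].b,
            fit_r=fits[cid].r,
            n_phases=fits[cid].n_points,
            logp_tlc=apply_calibration(calibration, fits[cid].r_m0),
        )
        for cid in test_ids
        if cid in fits
    ]
    return PipelineReport(
        calibration=calibration,
        results=results,
        standard_fits=[fits[cid] for cid in std_ids if cid in fits],
        excluded=excluded,
        flagged_rows=flagged,
    )
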