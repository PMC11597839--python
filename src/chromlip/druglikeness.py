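"""Threshold-based oral drug-likeness rules and ESOL solubility banding.

Implements the Lipinski (Rule of Five), Ghose and Veber filters over a
:class:`~chromlip.descriptors.DescriptorSet`, plus the Delaney ESOL linear
model for aqueous solubility (log S, mol/L) and its conventional solubility
bands.

All thresholds are data, not code: override any of them through the
``*Thresholds`` dataclasses. Verdicts are pure functions of the descriptor
set and thresholds. Strict mode (the default) requires every criterion; the
classical "at most one violation" Lipinski variant is available behind
``max_violations``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .descriptors import DescriptorSet
from .errors import ConfigurationError, MissingDescriptorError


@dataclass(frozen=True)
class LipinskiThresholds:
    mw_max: float = 500.0
    hba_max: int = 10
    hbd_max: int = 5
    logp_max: float = 5.0
    mlogp_max: float = 4.15


@dataclass(frozen=True)
class GhoseThresholds:
    mw_min: float = 160.0
    mw_max: float = 480.0
    mr_min: float = 40.0
    mr_max: float = 130.0
    logp_min: float = -0.4
    logp_max: float = 5.6
    atoms_min: int = 20
    atoms_max: int = 70


@dataclass(frozen=True)
class VeberThresholds:
    tpsa_max: float = 140.0
    rotb_max: int = 10


@dataclass(frozen=True)
class RuleVerdict:
    """Outcome of one rule on one compound.

    ``violations`` lists ``(criterion, observed, threshold)`` triples;
    in strict mode ``passed`` is equivalent to an empty list.
    """

    compound_id: str
    rule: str
    passed: bool
    violations: Tuple[Tuple[str, float, str], ...] = ()


def _logp_from(desc: DescriptorSet, logp_choice: str, rule: str) -> Tuple[str, float]:
    """Resolve the logP estimate a rule should use.

    ``mlogp`` demands a Moriguchi estimate under that key; ``any_logp``
    takes the first available input (deterministic: sorted by name).
    """
    if logp_choice == "mlogp":
        if "mlogp" not in desc.logp_inputs:
            raise MissingDescriptorError(
                f"{rule}: logp_choice='mlogp' but no 'mlogp' among logp_inputs "
                f"for {desc.compound_id!r}"
            )
        return "mlogp", desc.logp_inputs["mlogp"]
    if logp_choice == "any_logp":
        if not desc.logp_inputs:
            raise MissingDescriptorError(
                f"{rule}: no logP estimate supplied for {desc.compound_id!r}"
            )
        name = sorted(desc.logp_inputs)[0]
        return name, desc.logp_inputs[name]
    if logp_choice in desc.logp_inputs:
        return logp_choice, desc.logp_inputs[logp_choice]
    raise ConfigurationError(f"unknown logp_choice {logp_choice!r}")


def lipinski(
    desc: DescriptorSet,
    thresholds: LipinskiThresholds = LipinskiThresholds(),
    logp_choice: str = "any_logp",
    max_violations: int = 0,
) -> RuleVerdict:
    """Rule of Five: MW <= 500, N+O acceptors <= 10, donors <= 5 and
    logP <= 5 (or MlogP <= 4.15 when ``logp_choice='mlogp'``).

    Boundaries are inclusive. ``max_violations=0`` is strict mode;
    ``max_violations=1`` is the classical formulation.
    """
    name, logp = _logp_from(desc, logp_choice, "lipinski")
    logp_max = thresholds.mlogp_max if logp_choice == "mlogp" else thresholds.logp_max
    checks = [
        ("mw", desc.mw, desc.mw <= thresholds.mw_max, f"<= {thresholds.mw_max}"),
        ("hba", desc.hba_lipinski, desc.hba_lipinski <= thresholds.hba_max, f"<= {thresholds.hba_max}"),
        ("hbd", desc.hbd, desc.hbd <= thresholds.hbd_max, f"<= {thresholds.hbd_max}"),
        (f"logp[{name}]", logp, logp <= logp_max, f"<= {logp_max}"),
    ]
    violations = tuple((c, obs, thr) for c, obs, ok, thr in checks if not ok)
    return RuleVerdict(desc.compound_id, "lipinski", len(violations) <= max_violations, violations)


def ghose(
    desc: DescriptorSet,
    thresholds: GhoseThresholds = GhoseThresholds(),
    logp_choice: str = "any_logp",
) -> RuleVerdict:
    """Ghose filter: MW in [160, 480], MR in [40, 130], logP in [-0.4, 5.6],
    atom count in [20, 70]. Intervals closed."""
    name, logp = _logp_from(desc, logp_choice, "ghose")
    checks = [
        ("mw", desc.mw, thresholds.mw_min <= desc.mw <= thresholds.mw_max,
         f"[{thresholds.mw_min}, {thresholds.mw_max}]"),
        ("mr", desc.molar_refraction,
         thresholds.mr_min <= desc.molar_refraction <= thresholds.mr_max,
         f"[{thresholds.mr_min}, {thresholds.mr_max}]"),
        (f"logp[{name}]", logp, thresholds.logp_min <= logp <= thresholds.logp_max,
         f"[{thresholds.logp_min}, {thresholds.logp_max}]"),
        ("atoms", desc.total_atoms,
         thresholds.atoms_min <= desc.total_atoms <= thresholds.atoms_max,
         f"[{thresholds.atoms_min}, {thresholds.atoms_max}]"),
    ]
    violations = tuple((c, obs, thr) for c, obs, ok, thr in checks if not ok)
    return RuleVerdict(desc.compound_id, "ghose", not violations, violations)


def veber(
    desc: DescriptorSet, thresholds: VeberThresholds = VeberThresholds()
) -> RuleVerdict:
    """Veber filter: TPSA <= 140 A^2 and rotatable bonds <= 10."""
    checks = [
        ("tpsa", desc.tpsa, desc.tpsa <= thresholds.tpsa_max, f"<= {thresholds.tpsa_max}"),
        ("rotb", desc.rotatable_bonds, desc.rotatable_bonds <= thresholds.rotb_max,
         f"<= {thresholds.rotb_max}"),
    ]
    violations = tuple((c, obs, thr) for c, obs, ok, thr in checks if not ok)
    return RuleVerdict(desc.compound_id, "veber", not violations, violations)


# Delaney ESOL coefficients: intercept, logP, MW, rotatable bonds, aromatic
# proportion (aromatic heavy atoms / heavy atoms).
ESOL_COEFFS = (0.16, -0.63, -0.0062, 0.066, -0.74)


def esol_logs(desc: DescriptorSet, logp_name: str = "any_logp") -> float:
    """Estimated aqueous solubility log S (mol/L) from the Delaney model:

    log S = 0.16 - 0.63 logP - 0.0062 MW + 0.066 RB - 0.74 AP
    """
    _, logp = _logp_from(desc, logp_name, "esol")
    c0, c_logp, c_mw, c_rotb, c_ap = ESOL_COEFFS
    return (
        c0
        + c_logp * logp
        + c_mw * desc.mw
        + c_rotb * desc.rotatable_bonds
        + c_ap * desc.aromatic_proportion
    )


# Conventional ESOL band boundaries on log S. Reports sometimes call the
# (-4, -2] band "highly soluble"; the conventional label "soluble" is used
# here, with the synonym noted in the docs.
SOLUBILITY_BANDS: Tuple[Tuple[float, str], ...] = (
    (-10.0, "insoluble"),
    (-6.0, "poorly"),
    (-4.0, "moderately"),
    (-2.0, "soluble"),
    (0.0, "very"),
    (float("inf"), "highly"),
)


def solubility_band(logs: float) -> str:
    """Band label for a log S value (monotone step function partitioning
    the real line)."""
    if not (logs == logs and abs(logs) != float("inf")):
        raise ConfigurationError(f"log S must be finite, got {logs}")
    for upper, label in SOLUBILITY_BANDS:
        if logs < upper:
            return label
    return SOLUBILITY_BANDS[-1][1]


def screen(
    descs: Sequence[DescriptorSet],
    lipinski_thresholds: LipinskiThresholds = LipinskiThresholds(),
    ghose_thresholds: GhoseThresholds = GhoseThresholds(),
    veber_thresholds: VeberThresholds = VeberThresholds(),
    logp_choice: str = "any_logp",
    max_violations: int = 0,
) -> pd.DataFrame:
    """Rule report: one row per compound x rule, plus per-compound errors
    propagated as failed rows with a reason (non-fatal)."""
    rows: List[Dict] = []
    for desc in descs:
        for rule_fn, kwargs in (
            (lipinski, dict(thresholds=lipinski_thresholds, logp_choice=logp_choice,
                            max_violations=max_violations)),
            (ghose, dict(thresholds=ghose_thresholds, logp_choice=logp_choice)),
            (veber, dict(thresholds=veber_thresholds)),
        ):
            try:
                verdict = rule_fn(desc, **kwargs)
                rows.append(
                    {
                        "compound_id": verdict.compound_id,
                        "rule": verdict.rule,
                        "passed": verdict.passed,
                        "violations": "; ".join(v[0] for v in verdict.violations),
                        "error": "",
                    }
                )
            except MissingDescriptorError as err:
                rows.append(
                    {
                        "compound_id": desc.compound_id,
                        "rule": rule_fn.__name__,
                        "passed": False,
                        "violations": "",
                        "error": str(err),
                    }
                )
    return pd.DataFrame(rows)
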