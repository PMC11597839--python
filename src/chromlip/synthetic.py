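"""Synthetic data with the statistical structure the analysis assumes.

Two generators:

* :func:`simulate_tlc` inverts the retention forward model. For each
  compound a true lipophilicity and retention slope are drawn, converted to
  per-phase retardation factors through ``R_M = R_M0 + b * phi`` and
  ``Rf = 1 / (1 + 10^R_M)``, and turned into measured migration distances
  with Gaussian noise on the distance scale — that is what a ruler reads —
  truncated to the plate. The emitted table is exactly the plate-CSV
  dialect the analysis pipeline consumes, and the ground truth travels
  alongside for recovery tests.

* :func:`simulate_logp_panel` draws a latent true-logP vector, applies
  method-specific linear distortions plus Gaussian noise calibrated so the
  expected pairwise correlation between methods equals a target, and can
  inject substituent-class structure for cluster/PCA tests.

Defaults mirror the laboratory design the package models: five
acetone:buffer mobile phases (volume fractions 0.4-0.8), three replicates,
7 x 10 cm plates, a seven-standard calibration panel spanning logP
0.64-4.79, and a calibration line logP = 1.0587 R_M0 - 0.0267. All
randomness flows from the explicit seed; there is no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ParameterError

DEFAULT_PHI_GRID = (0.4, 0.5, 0.6, 0.7, 0.8)
USABLE_RF_WINDOW = (0.03, 0.97)


@dataclass(frozen=True)
class TlcSimSpec:
    """Design of one simulated RP-TLC experiment."""

    n_standards: int = 7
    n_tests: int = 15
    phi_grid: Tuple[float, ...] = DEFAULT_PHI_GRID
    replicates: int = 3
    standards_logp_range: Tuple[float, float] = (0.64, 4.79)
    tests_logp_range: Tuple[float, float] = (1.15, 3.28)
    b_range: Tuple[float, float] = (-6.0, -1.5)
    calibration_slope: float = 1.0587
    calibration_intercept: float = -0.0267
    noise_sd_cm: float = 0.05
    plate_length_cm: float = 10.0
    rf_window: Tuple[float, float] = USABLE_RF_WINDOW
    seed: int = 0

    def __post_init__(self):
        if not all(0 < p < 1 for p in self.phi_grid):
            raise ParameterError("phi grid must lie in (0, 1)")
        if len(set(self.phi_grid)) != len(self.phi_grid):
            raise ParameterError("phi grid values must be distinct")
        if self.noise_sd_cm < 0:
            raise ParameterError("noise sd must be >= 0")
        if self.plate_length_cm <= 0:
            raise ParameterError("plate length must be > 0")
        if not (self.b_range[0] < self.b_range[1] <= 0):
            raise ParameterError("b range must be negative")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth behind one simulated experiment."""

    per_compound: pd.DataFrame  # compound_id, role, logp, r_m0, b
    calibration_slope: float
    calibration_intercept: float
    n_resampled: int = 0

    def to_json_dict(self) -> Dict:
        return {
            "calibration": {
                "slope": self.calibration_slope,
                "intercept": self.calibration_intercept,
            },
            "n_resampled": self.n_resampled,
            "compounds": self.per_compound.to_dict(orient="records"),
        }


def _draw_slope(
    rng: np.random.Generator, r_m0: float, spec: TlcSimSpec, max_tries: int = 500
) -> Tuple[float, np.ndarray, int]:
    """Draw a retention slope leaving at least three usable plates.

    The usable-Rf window is enforced per plate, the way a bench chemist
    discards a plate whose spot sat at the origin or ran with the front:
    out-of-window phases are dropped rather than clamped, and the slope is
    resampled only when fewer than three phases survive (extreme
    lipophilicity only yields usable spots at high organic fraction).
    Returns ``(b, usable-phase mask, redraw count)``.
    """
    lo, hi = spec.rf_window
    for attempt in range(max_tries):
        b = rng.uniform(*spec.b_range)
        rm = r_m0 + b * np.asarray(spec.phi_grid)
        rf = 1.0 / (1.0 + 10.0**rm)
        usable = (rf > lo) & (rf < hi)
        if usable.sum() >= 3:
            return b, usable, attempt
    raise ParameterError(
        f"no retention slope leaves >= 3 usable plates for R_M0={r_m0:.3f} "
        f"within {max_tries} draws; the logP range and phi grid are "
        "inconsistent with the usable-Rf window"
    )


def simulate_tlc(spec: TlcSimSpec) -> Tuple[pd.DataFrame, SimTruth]:
    """Simulate a plate experiment; returns ``(plates, truth)``.

    ``plates`` has the pipeline's input columns (compound_id, role,
    organic_fraction, replicate, d_compound_cm, d_front_cm). Reproducible:
    the same spec (including seed) yields identical output.
    """
    rng = np.random.default_rng(spec.seed)
    slope, intercept = spec.calibration_slope, spec.calibration_intercept

    compounds: List[Tuple[str, str, float]] = []
    std_logps = np.linspace(*spec.standards_logp_range, spec.n_standards)
    for i, logp in enumerate(std_logps):
        compounds.append((f"STD{i + 1:02d}", "standard", float(logp)))
    test_logps = rng.uniform(*spec.tests_logp_range, spec.n_tests)
    for i, logp in enumerate(test_logps):
        compounds.append((f"T{i + 1:02d}", "test", float(logp)))

    rows = []
    truth_rows = []
    n_resampled = 0
    L = spec.plate_length_cm
    for cid, role, logp in compounds:
        r_m0 = (logp - intercept) / slope
        b, usable, redraws = _draw_slope(rng, r_m0, spec)
        n_resampled += redraws
        truth_rows.append(
            {"compound_id": cid, "role": role, "logp": logp, "r_m0": r_m0, "b": b}
        )
        for phi, keep in zip(spec.phi_grid, usable):
            if not keep:
                continue
            rf = 1.0 / (1.0 + 10.0 ** (r_m0 + b * phi))
            for rep in range(1, spec.replicates + 1):
                d = rf * L
                if spec.noise_sd_cm > 0:
                    d_noisy = d + rng.normal(0.0, spec.noise_sd_cm)
                    while not (0.0 < d_noisy < L):  # truncation by redraw
                        d_noisy = d + rng.normal(0.0, spec.noise_sd_cm)
                    d = d_noisy
                rows.append(
                    {
                        "compound_id": cid,
                        "role": role,
                        "organic_fraction": phi,
                        "replicate": rep,
                        "d_compound_cm": d,
                        "d_front_cm": L,
                    }
                )
    plates = pd.DataFrame(rows)
    truth = SimTruth(
        per_compound=pd.DataFrame(truth_rows),
        calibration_slope=slope,
        calibration_intercept=intercept,
        n_resampled=n_resampled,
    )
    return plates, truth


def simulate_logp_panel(
    n_compounds: int = 15,
    n_methods: int = 12,
    target_correlation: float = 0.8,
    n_classes: int = 0,
    class_separation: float = 2.0,
    class_sd: float = 1.0,
    seed: int = 0,
) -> Tuple[pd.DataFrame, Optional[pd.Series]]:
    """Panel of correlated lipophilicity estimates.

    Model: latent ``z_i ~ N(mu_class(i), class_sd^2)``; method j reports
    ``a_j + s_j (z_i + class_sd sigma eps_ij)`` with
    ``sigma = sqrt(1/rho - 1)`` (noise scaled to the latent spread) so
    that the expected pairwise Pearson correlation between methods is
    ``rho = target_correlation`` (exactly, for the class-free case); the
    noise-free limit ``rho = 1`` makes every pairwise correlation exactly 1.
    The affine per-method distortion leaves correlations untouched.

    With ``n_classes > 0``, compounds are assigned round-robin to classes
    whose latent means are ``class_separation`` apart with within-class
    spread ``class_sd``, giving cluster analysis a recoverable partition
    when ``class_separation >> class_sd``. Returns ``(panel, labels)``;
    ``labels`` is None without classes.
    """
    if not (0.0 < target_correlation <= 1.0):
        raise ParameterError("target correlation must lie in (0, 1]")
    if n_compounds < 3 or n_methods < 2:
        raise ParameterError("need >= 3 compounds and >= 2 methods")
    rng = np.random.default_rng(seed)
    labels = None
    mu = np.zeros(n_compounds)
    if n_classes > 0:
        assignment = np.arange(n_compounds) % n_classes
        centered = assignment - (n_classes - 1) / 2.0
        mu = centered * class_separation
        labels = pd.Series(
            assignment, index=[f"CPD{i + 1:02d}" for i in range(n_compounds)],
            name="class",
        )
    if class_sd <= 0:
        raise ParameterError("class_sd must be > 0")
    z = mu + class_sd * rng.standard_normal(n_compounds)
    sigma = class_sd * np.sqrt(1.0 / target_correlation - 1.0)
    offsets = rng.normal(0.0, 0.5, n_methods)
    scales = rng.uniform(0.8, 1.2, n_methods)
    data = {}
    for j in range(n_methods):
        eps = rng.standard_normal(n_compounds)
        data[f"method_{j + 1:02d}"] = offsets[j] + scales[j] * (z + sigma * eps)
    panel = pd.DataFrame(data, index=[f"CPD{i + 1:02d}" for i in range(n_compounds)])
    return panel, labels
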