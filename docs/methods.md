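# Methods

This note documents the models, conventions and numerical choices behind
`chromlip`, and what its synthetic-data validation does and does not show.

## Retention model and lipophilicity calibration

The package assumes the standard linear solvent-strength picture for
reversed-phase TLC: the Bate-Smith–Westall retention parameter
`R_M = log10(1/Rf − 1)` is linear in the volume fraction φ of organic
modifier, `R_M = R_M0 + b·φ` with `b < 0`. `R_M0` — the intercept at a
purely aqueous mobile phase — is the chromatographic lipophilicity
parameter. Both the per-compound extrapolation and the calibration of
literature log P on `R_M0` are unweighted ordinary least squares
(via `scipy.stats.linregress`); the calibration direction (log P regressed
on R_M0) is fixed by the reporting convention of the field.

Conventions and edge cases:

* **Replicate averaging** happens on the Rf scale before the R_M
  transform (default). The transform is nonlinear, so the order matters;
  averaging the raw ratio treats replicate spots as repeated measurements
  of one migration distance, which matches how plates are read. The
  alternative (`average_on="rm"`) is available for sensitivity analysis.
* **Unusable spots.** A spot with `d = 0` or `d = d_front` has `R_M`
  undefined (±∞). Such rows are flagged and excluded, never clamped; a
  compound is excluded (and reported) if fewer than three usable phases
  remain.
* **φ units.** Volume fraction in (0, 1); percent input (e.g. 40) is
  auto-normalised with a warning.
* **Rounding.** Everything is carried at full precision; reported
  `logP_TLC` is rounded half-up to two decimals (the convention of the
  reference tables — half-even rounding would report 1.245 as 1.24).

The packaged standards panel spans log P 0.64–4.79 across seven
substances. Its benzamide row is flagged: the published calibration
applied to benzamide's R_M0 gives 0.98, not the 0.66 the source reports
(consistency would need R_M0 ≈ 0.649). The row ships as printed, flagged
for exclusion; no corrected value is guessed. Refitting the six clean
standards gives slope ≈ 1.054, intercept ≈ −0.010; including the
inconsistent row shifts the slope to ≈ 1.099.

## Descriptors

* **Masses.** Average MW uses the IUPAC 2021 abridged standard atomic
  weights; monoisotopic masses are principal-isotope masses (AME2020),
  both in a packaged CSV. The "calcd" adduct m/z applies no electron-mass
  correction, matching how synthetic chemists report HRMS values
  (301.0856 for the protonated chlorophenyl derivative, not 301.0851).
  Reference MW values published for this panel are reproduced to ±0.01;
  three of the fifteen differ by exactly 0.01 (their source evidently
  rounded once more along the way).
* **TPSA** is an in-package implementation of the Ertl
  fragment-contribution sum, including the S/P extension, with the
  contribution table shipped as a versioned CSV. Atoms are classified by
  an environment signature (element, aromaticity, formal charge, attached
  H, bond-order counts, 3-ring membership). Charge-separated nitro groups
  are normalised to the neutral pentavalent form before assignment, so a
  nitro group contributes the classical 45.82 Å²; toolkits that type the
  charged form directly report 43.14 Å² for the same group. A polar atom
  with no table entry raises an error rather than contributing zero.
* **Molar refraction** is the Wildman–Crippen atomic-contribution model
  as implemented by Open Babel (`obabel` subprocess, batched; version
  recorded in provenance). Open Babel's resolution of the published
  atom-typing table matches the reference values for this panel exactly;
  RDKit's resolution of the same table differs by 0.4–2.6 MR units on
  aromatic-amine and nitroarene environments, and serves as an
  independent cross-check (3% tolerance) in the tests.
* **H-bond counts.** Donors: N/O atoms bearing ≥ 1 H (NH₂ = one donor).
  Acceptors come in two documented conventions: `lipinski_n_plus_o`
  (all N+O, the original Rule-of-Five definition, default for rule
  evaluation) and `pharma_acceptor` (excludes pyrrole-type aromatic N,
  amide N, aromatic-amine N and nitro N). Published acceptor counts for
  this panel mix the two conventions, so no attempt is made to reproduce
  every printed cell; each convention is exposed explicitly.
* **Rotatable bonds:** RDKit's strict definition (acyclic single bonds
  between non-terminal heavy atoms, amide C–N excluded).

## Drug-likeness and solubility

Lipinski (MW ≤ 500, N+O ≤ 10, donors ≤ 5, log P ≤ 5 or Mlog P ≤ 4.15),
Ghose (MW 160–480, MR 40–130, log P −0.4–5.6, 20–70 atoms) and Veber
(TPSA ≤ 140 Å², ≤ 10 rotatable bonds), all boundaries inclusive, all
thresholds overridable. Strict mode (no violations) is the default;
the classical ≤ 1-violation Lipinski variant sits behind
`max_violations`. The package computes no log P of its own: rule
evaluation consumes named, externally supplied estimates (experimental or
theoretical), chosen per call.

ESOL solubility uses the published Delaney equation
`log S = 0.16 − 0.63·logP − 0.0062·MW + 0.066·RB − 0.74·AP` with
aromatic proportion AP = aromatic heavy atoms / heavy atoms. Because the
reference sheet's log S came from an external service whose exact fit is
unknown, validation asserts band membership ((−4, −2] "soluble"), not the
printed number; some sources call that band "highly soluble" — the
conventional label is used here. Band boundaries: −10, −6, −4, −2, 0.

## Chemometrics

Standardisation is per-column z-scoring (sample sd, n−1); constant
columns are dropped with a warning (they carry no information and break
z-scoring). Correlation p-values use the t transform with n−2 df,
two-sided, with no multiple-testing correction — raw p against the
conventional 0.05 gate, as comparison tables in this field report them.
Regression reports carry coefficient ± SE, r, residual standard error s,
F and p; `F = (r²/(1−r²))(n−2)` holds by construction and is asserted in
tests.

Cluster analysis is agglomerative over Euclidean distances
(`scipy.cluster.hierarchy`); Ward linkage is the default because the
compact spherical clusters it prefers match the substituent-class
structure such panels carry, with single/complete/average exposed. Rows
are sorted by id before linkage so ties break lexicographically.

PCA is the eigendecomposition of the correlation matrix (equivalent to
covariance PCA of the standardised panel). Component signs are fixed by
making each loading vector's largest-magnitude entry positive — the usual
remedy for LAPACK sign indeterminacy. Component selection offers the
Kaiser rule (eigenvalues ≥ 1) and a cumulative-variance threshold.

The original study's correlation/regression tables and its
six-component/96.6% PCA result depend on per-program theoretical log P
panels that live in an unpublished appendix, so they are not reproduction
targets; the machinery is instead validated against independent
closed-form oracles (normal equations, covariance formula, brute-force
linkage, reconstruction identities) at 1e-10/1e-9 and on synthetic panels
with known structure.

## Synthetic data: what it emulates and what it does not

`simulate_tlc` inverts the retention model: truth log P → R_M0 via the
calibration line → per-phase Rf → distances, with Gaussian noise
(default sd 0.05 cm) added on the measured-distance scale and truncated
to the plate by redrawing. Defaults reproduce the reference experimental
design: five acetone fractions 0.4–0.8, three replicates, 7 standards
spanning log P 0.64–4.79, 15 unknowns in 1.15–3.28, 10 cm plates,
calibration (1.0587, −0.0267). Retention slopes are drawn from
(−6.0, −1.5) per unit fraction, the range the reference standards span.
The usable-Rf window (0.03, 0.97) is enforced per plate: out-of-window
spots are not emitted (a bench chemist discards those plates), each
compound keeps ≥ 3 usable phases, and the slope is redrawn when that
fails. A strongly lipophilic standard (R_M0 ≈ 4.5) has no slope in a
realistic range that keeps all five phases in-window — at 40% acetone its
Rf is of order 10⁻², exactly as the reference data imply — so the
per-plate rule is the only self-consistent reading of the window.

`simulate_logp_panel` draws a latent log P (within-class sd `class_sd`),
adds method-specific affine distortions and Gaussian noise scaled so the
expected pairwise correlation equals the target exactly in the class-free
case (`σ = class_sd·sqrt(1/ρ − 1)`; affine maps leave r untouched).
Class structure (means `class_separation` apart) makes the partition
recoverable when separation ≫ within-class sd.

What passing these tests shows: the estimation chain is unbiased and
correctly implemented under the model's own assumptions (linear R_M–φ,
Gaussian distance noise, linear calibration). What it does not show:
robustness to real-plate pathologies — nonlinear R_M–φ curvature at
extreme φ, spot tailing, temperature drift, correlated replicate error —
none of which the generator emulates.

## Problem sizes

The statistical validation battery uses 200 simulated experiments
(22 compounds × up to 15 plates each) for the noisy-recovery study,
100 seeds for the panel-correlation calibration check, 10 labelled panels
for cluster recovery, and n ≤ 20 random inputs for each closed-form
oracle comparison; the whole suite runs in well under a minute.
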