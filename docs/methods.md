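# Methods

## Scope and data flow

The pipeline starts from two delimited tables: a clinical cohort (one
row per proband: age at last evaluation, per-eye logMAR BCVA,
protein-level variant) and a per-variant energy table (relative
dimerization and calcium-binding energies in kcal/mol). The
molecular-mechanics minimizations that produce total energies are out
of scope; when raw component totals are available the package evaluates
the defining differences (`energetics`), but the bundled reference
analysis consumes the relative energies directly. Both bundled tables
transcribe a published 36-proband Italian BVMD case series; the
per-variant mean severities in the energy table are the published
values and are used verbatim for the regression (recomputing them from
the cohort's BCVA and ages agrees to ~0.1–0.3 percent-points, the
residual being consistent with marginally different evaluation ages
between the two tables).

## Severity index

`BDSI_i = (logMAR_LE + logMAR_RE)/2.6 · 100% · e^(−A_i/100)`, averaged
per variant. Probands missing either eye's BCVA are excluded from the
mean (never imputed or zeroed) and surface in the validation report; a
variant with no usable proband gets a missing severity. Two-eye sums
above the 2.6 full scale (possible since single-eye values above 1.3
occur clinically) are clamped with a warning so the index stays in
[0, 100]. Full double precision is kept internally; rounding to the
2-decimal presentation convention happens only at output. Note the
index discounts *late* observation (factor e^(−A/100)); the forward
acuity prediction below re-inflates with e^(+A/100). The asymmetry is
deliberate: severity observed young is weighted up, predicted acuity
grows with age.

## Regression and outlier handling

Unweighted OLS of mean BDSI on |ΔΔE_dim| (group sizes of 1–3 probands
are not used as weights). Leave-one-out residuals are computed by the
leverage identity `e_i/(1−h_ii)`, which for linear least squares equals
the explicit drop-one refit (asserted against a brute-force oracle in
the tests). A point is flagged when its |LOO residual| strictly exceeds
2× the SD of the LOO residuals; the SD uses the sample convention
(ddof = 1, configurable), and an exact fit (SD at rounding-noise level)
flags nothing.

Deletion is iterative but stops on *adequacy*, not on convergence:
flagged points are removed and the model refitted only while both
R² < 0.75 and LOO q² (PRESS-based predicted R²) < 0.70, with a
cumulative cap of 25% of the initial points and at most 10 rounds.
Iterating a 2-SD rule to convergence is statistically unsound at these
sample sizes — among ~20 Gaussian LOO residuals the largest exceeds
twice their SD about half the time, so convergence iteration keeps
nibbling at clean data (simulations here: it deletes spurious points
from ~70% of clean σ=3 cohorts, and 7 rather than 5 points from the
reference dataset). The adequacy stop expresses the intended semantics
— outliers are points a *good* model cannot explain; once the model is
good, remaining 2-σ excursions are noise. The levels 0.75/0.70 are
stricter than the classical q² > 0.5 acceptability minimum and are the
package's calibration: they reproduce the published five-point deletion
endpoint of the reference analysis, and in simulation at the reference
conditions (n = 20, σ = 3, two +40-point outliers) the procedure
recovers exactly the planted set in ≈96–97% of replicates while leaving
≈96% of clean cohorts untouched. The survivor-set fit is idempotent
under re-running, which convergence iteration also fails.

Reported statistics: R² = 1 − SS_res/SS_tot, q² (= R²_xv) =
1 − PRESS/SS_tot with PRESS from LOO prediction errors on the survivor
set, F = R²/(1−R²)·(n−2) with significance from F(1, n−2) at 95%. On
the reference survivors the package computes R²_xv = 0.809 against a
published 0.827; the software originally used for the validation does
not document its exact cross-validated formula, and the PRESS-based
definition (the standard one, asserted here) is retained. A perfect
fit reports F as +inf.

## Acuity prediction and classification

`PMVA = (2.6/200)·[slope·|ΔΔE_dim| + intercept]·e^(A/100)`, evaluated
by default with the bundled reference coefficients (0.24935, 6.56527)
at the reference age of 40 years. Classification compares PMVA rounded
half-up to 2 decimals against the 0.5 logMAR cut: exact arithmetic at
the published 77 kcal/mol integer bound gives 0.4997, and the rounding
rule is what reconciles the 0.5 cut with that integer bound (the exact
real root is 77.065). Rounding mode, decimals, cut and reference age
are all parameters. Stop-gain variants carry no energies and are
reported as not-scorable, never classified.

## Synthetic cohorts

The generator inverts the model: per variant, signed ΔΔE_dim is uniform
on [−100, 100] kcal/mol (moduli spanning the observed range), a target
severity is drawn as slope·|ΔΔE| + intercept + N(0, σ) (+ a gross
offset for planted outliers; defaults slope/intercept as above, σ = 3,
offset 40), and each of 1–3 probands per variant receives an age
uniform on the cohort's 9–85-year range and eye acuities summing to
`target/100·2.6·e^(age/100)` with a ±jitter split that cancels in the
sum — so the pipeline-recomputed mean severity equals the target to
machine precision and noise is controlled exactly where the regression
operates. Ages implying a per-eye acuity above 1.3 are redrawn and
counted; severity targets outside [0, 100] are redrawn likewise. All
randomness derives from `numpy.random.default_rng(seed)` (PCG64), so a
fixed seed is byte-reproducible across platforms.

What the generator does **not** emulate: measurement error in BCVA,
age-dependent disease progression within a proband, correlation between
ΔΔE_dim and ΔΔE_Cabin, non-Gaussian severity noise, and truncating
variants. Passing recovery tests therefore demonstrate the procedure's
statistical behaviour under the model's own assumptions, not robustness
to clinical measurement pathology.

## Structure annotation

Reduced-scope and heuristic: residue-location labels are derived from
explicit distances in a parsed multimer (gemmi; waters dropped, ions
read from single-atom CA/K/CL residues). Interfaces use a 5 Å
heavy-atom cutoff, ion proximity 8 Å, pore lining 12 Å radial distance
from the pore axis, all configurable; the pore axis is the first
principal axis of the protein heavy-atom cloud (sign-canonicalized),
which approximates the five-fold symmetry axis without symmetry
detection. The membrane test is an axial-coordinate band supplied by
the caller. Labels are monotone in the cutoffs. Validation uses
synthetic ring multimers with planted ions and constructed ground truth
(`make_fixture_structure`); annotating real chicken/human BEST1
structures against published qualitative labels is out of scope, and
residue numbering follows the model file without cross-species
renumbering.

## Cohort descriptives

Positivity is 100·positive/tested. Penetrance counts probands as
affected carriers alongside affected relatives — with the reference
family data, (13 probands + 8 affected relatives)/(21 + 8 unaffected
carriers) = 72.4%, the only decomposition consistent with the published
per-sex values (71.4% F, 73.3% M); this inference is flagged in output
rather than silent.

## Problem sizes and runtime

All reference computations are closed-form or n ≤ 20 regressions and
run in milliseconds. The simulation studies in the test suite use 200
replicates (outlier recovery, the size at which a ≥95% exact-recovery
rate is asserted) and 500 replicates (slope bias within ±0.01); both
finish in seconds. Replicate seeds are spawned from fixed master seeds
(`SeedSequence(0)` and `SeedSequence(1)`).

## Known limitations

- The regression has 15 effective points and one predictor; the
  pathogenicity bound (77 kcal/mol) should be treated as a calibration
  on this cohort, not a transferable constant.
- The energy inputs come from one force field/minimization protocol;
  the pipeline neither checks nor converts units beyond kcal/mol.
- The adequacy levels in the outlier rule are calibrated to the
  reference endpoint (see above); datasets with genuinely low
  signal-to-noise will stop deleting while still inadequate once the
  removal cap is reached.
- Pore-axis estimation by PCA fails for assemblies whose long axis is
  not the pore (e.g. highly oblate complexes); supply cutoffs and
  interpret labels accordingly.
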