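# Methods

## Data model

A survey is a table of n topsoil samples by m = 8 elements (Cd, Cr, Cu, Ni,
Pb, Zn, As, Hg; mg/kg) with per-sample pH and optional categorical metadata
(parent rock, land use, crop). Concentrations are stored exactly as
measured; values below the method detection limit (MDL) are only *flagged*.
The MDL/2 substitution that receptor modelling conventionally applies
happens inside the uncertainty construction, never in the stored table, so
raw data stay auditable. Rows with negative concentrations are rejected at
load with a logged error; unknown columns are a hard error.

The element registry carries, per element: MDL (Cd 0.03, Cr 5, Cu 1, Ni 2,
Pb 2, Zn 4, As 1, Hg 0.0005 mg/kg), national and Shandong-province
background values, NOAA ERL/ERM sediment-quality thresholds, pH-banded
agricultural screening values, and pathway-specific reference doses. Two
deliberate choices:

* **pH bands are half-open** — pH ≤ 5.5; 5.5 < pH ≤ 6.5; 6.5 < pH ≤ 7.5;
  pH > 7.5 — because the standard's printed band bounds overlap at the
  edges; half-open intervals make the lookup deterministic.
* **Screening values are not required to be monotone in pH.** For As they
  genuinely decrease with pH (40/40/30/25 mg/kg), reflecting arsenic's
  higher mobility in alkaline soils; validation only demands four positive
  values per element.
* Where the provincial background is printed at two precisions in different
  places (Cd 0.13 vs 0.132), the registry keeps the higher-precision table
  value.
* Screening-value exceedance uses strict inequality (conc > SV); the
  standard's convention at equality is not documented, and strict comparison
  is the conservative reading for a *screening* count.

## Synthetic survey generator

The generator emulates a dense regional survey with four latent sources:
industrial (Hg-dominated), coal combustion (As-dominated), natural
parent-rock weathering (Cr/Ni/Cu and part of Zn), and mixed
traffic–agricultural inputs (Pb/Cd/Zn and part of Cu). Concentrations are

```
conc = (G · F) ⊙ (1 + ε_mult) + ε_add,  clipped at 0
```

with per-sample contributions G drawn as independent unit-mean lognormals
(log-sd σ = 1 by default, giving sample CVs around 130%, inside the 41–208%
range of the emulated survey), ε_mult Gaussian with sd 0.10 and ε_add
Gaussian with sd MDL/2 per element. The noise model intentionally mirrors
the PMF uncertainty equation, so the fitted weights are correctly specified
on synthetic data; the residual-diagnostic expectations (≥ 95% of scaled
residuals in [−3, 3]) are meaningful under that match and would be weaker
under real, mis-specified noise.

**Profile construction.** Each element's mass is split across factors
according to the dominant loadings above (e.g. 93.59% of Cr in the natural
factor), with the stated remainder spread evenly over the other factors;
column shares sum to one exactly. The absolute scale must then satisfy two
wishes at once: element means near the emulated survey's means, and factor
shares of total mass at 11.69/17.32/36.79/34.20%. These are mathematically
incompatible — applied to the survey means, the loadings force mass shares
of roughly 59/31/3/1%, because As and Hg carry negligible mass (the
published factor totals are normalized-contribution shares, not mass
shares). The generator resolves this in favour of the factor-share targets,
which the recovery tests compare against: elements are scaled in groups by
their dominant factor, and the four group multipliers are the positive null
vector of the 4×4 linear system that pins the mass shares exactly (total
mass is kept at the survey total). Within-group concentration ratios are
preserved; the price is that the synthetic As (~38 mg/kg) and Hg (~30 mg/kg)
means sit far above their survey values, which also makes the synthetic
total HI incomparable to field risk levels. This is a property of the test
bed, not of the risk model.

What the generator does **not** emulate: spatial autocorrelation (no
variograms, no kriging), correlated noise across elements, heavy censoring
(with the default scale, below-MDL cells are rare), non-lognormal
contribution shapes, and covariate structure linking metadata to sources.
Passing recovery tests therefore demonstrate correctness of the estimator
under a well-specified model, not robustness to every field pathology.

## PMF numerics

* **Uncertainty.** u = sqrt((EF·conc)² + (0.5·MDL)²) strictly above the MDL;
  at or below it, the working value is MDL/2 with u = (5/6)·MDL. The error
  fraction EF defaults to 0.10 (the conventional 5–20% range; configurable).
  Equality with the MDL goes to the below-detection branch, following the
  strict "greater than" wording of the rule.
* **Optimizer.** Weighted multiplicative updates (weights 1/u²), which are
  monotone in Q and preserve non-negativity; convergence when the relative
  ΔQ stays below 1e−8 for 20 consecutive iterations, capped at 5,000
  iterations. The winning start is then polished by exact alternating
  weighted non-negative least squares (each half-sweep is a global minimum
  in one matrix, so Q remains monotone); the polish fixes the slow 1/t tail
  of multiplicative updates on (near-)exact-rank data and drives Q to
  numerical zero when an exact factorization exists.
* **Multistart.** 20 uniform-random starts by default, scaled to the data
  magnitude; a base seed spawns per-start seeds deterministically, and ties
  go to the lowest start index. The recovery-scale experiments in the test
  suite and acceptance script use 5 starts — on the default scenario the
  basin of attraction is wide and all starts agree to three digits, so the
  extra starts buy nothing at five times the cost.
* **Robust mode.** Cells with |scaled residual| > 4 get u inflated by
  sqrt(|r|/4), refit from the current solution, repeated until the flagged
  set stabilizes (max 10 rounds). Off by default.
* **Model selection.** Q is scanned over p = 2–6 and compared with the
  degrees-of-freedom value Q_th = nm − p(n+m); the scan reports the Q/Q_th
  ratio and the fraction of scaled residuals within [−3, 3], and flags the
  smallest p whose relative Q drop to the next p is below 10% — advisory
  only, never auto-applied.
* **Identifiability.** Factor order and scale are not identifiable; all
  comparisons against reference profiles go through an optimal one-to-one
  assignment (Hungarian algorithm) on row-normalized profiles, reporting
  per-factor cosines. Bootstrap stability resamples rows with replacement,
  refits warm-started from the base solution (20 replicates by default) and
  reports the fraction of replicates mapping onto each base factor at
  cosine ≥ 0.6.
* No factor rotation (FPEAK-style) and no displacement-based error
  estimation are implemented.

## Exposure model

Defaults are the standard USEPA residential-soil parameter set:

| parameter | children | adults | units |
|---|---|---|---|
| IR_ing | 200 | 100 | mg/day |
| IR_inh | 7.6 | 20 | m³/day |
| SA | 2800 | 5700 | cm² |
| AF | 0.2 | 0.07 | mg/(cm²·day) |
| ABS | 0.001 | 0.001 | – |
| PEF | 1.36e9 | 1.36e9 | m³/kg |
| EF | 350 | 350 | day/year |
| ED | 6 | 24 | year |
| BW | 15 | 70 | kg |
| AT | 2190 | 8760 | day |

with ingestion RfDs (mg/kg/day) Cd 1e−3, Cr 3e−3, Cu 4e−2, Ni 2e−2, Pb
3.5e−3, Zn 3e−1, As 3e−4, Hg 3e−4, and the matching inhalation/dermal sets
(all overridable via config). Hand-calculated against the emulated survey's
mean concentrations, this set reproduces six of the eight published child
hazard quotients (As, Pb, Ni, Cu, Zn, Hg) within a few percent. The
published children's Cr and Cd values, and the adult rows generally, are not
reproducible from any standard parameter set we tried — the published adult
Cr HQ exceeding the children's is anomalous under every USEPA-style
parameterization, in which children's unit doses are strictly larger — so
those are documented as out of reach rather than force-fitted.

Risk is computed on source-allocated **mean** concentrations (the table
granularity used in source-oriented assessments), with per-sample allocation
available. Allocation conserves mass exactly by construction, and the dose
equations are linear in concentration, so per-source risks add to the
total-concentration risk to machine precision; both properties are asserted
in the tests.

## Monte Carlo

Exposure parameters are sampled independently per iteration (default 10,000)
from configurable families (point, uniform, triangular, zero-truncated
normal, lognormal — the lognormal is parameterized by its natural-scale mean
and sd and moment-matched to the log scale). Defaults: BW lognormal
(children 15 ± 2 kg, adults 70 ± 10 kg), IR_ing triangular (100/200/300 and
50/100/150 mg/day), EF triangular (180/350/365 day/year), everything else at
its point value. If ED is sampled and AT is not, AT tracks ED·365.
Percentiles use linear interpolation between order statistics; the
"confidence band" is reported as the 5th–95th percentile interval, and
threshold exceedance uses strict HI > 1. Degenerate all-point configurations
reproduce the deterministic pipeline to 1e−12 relative, which the tests use
as the wiring check, and a body-weight-only lognormal scenario is checked
against its closed-form exceedance probability.

The emulated survey's published probabilistic results (mean child HI
2.66e−1, 2.53% exceedance) depend on its 19,484 proprietary samples and its
unpublished distribution choices; they are covered here by the closed-form
and degenerate oracles plus the synthetic recovery scenario, not by direct
reproduction.

## Problem sizes

The default synthetic scenario uses n = 500 samples — large enough that
lognormal sampling noise keeps realized factor mass shares within ~3 points
of their targets, small enough for interactive runs. The test suite fits at
n = 60–500 with 2–5 starts and capped iterations; the acceptance script uses
the full default scenario (n = 500, 5 starts, 10,000 Monte Carlo
iterations) and completes in seconds.

## Known limitations

* No carcinogenic (slope-factor) risk and no bioavailability adjustment —
  the model follows total-concentration, non-carcinogenic assessment.
* No spatial statistics: kriging, maps and spatial covariates are out of
  scope.
* The allocation fallback for zero-reconstruction cells (element-level
  factor mass shares, uniform if those are also zero) is a pragmatic rule;
  such cells are logged and essentially never occur on fitted models with
  positive data.
* The generator's mass-share compromise above means synthetic element means
  for As and Hg are unrealistic in absolute terms; any analysis that needs
  realistic absolute risk levels should use the survey mean concentrations
  directly, as the deterministic hazard-quotient entry point does.
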