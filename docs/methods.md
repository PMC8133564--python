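# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `ionuptake`, stage by stage in pipeline order.

## Solution chemistry

Recipes are lists of salts with µM concentrations and explicit ion
stoichiometries (e.g. one calcium and two dihydrogen phosphate per
Ca(H2PO4)2·H2O). Compositions are the stoichiometric sum over salts;
hydration water is ignored. Dihydrogen phosphate is reported as
"phosphate", matching the reporting granularity of ion chromatography for
these solutions. Micronutrient salts can be marked `trace`; they are
recorded in full compositions but excluded from focal-ion starting
concentrations — in particular the trace ammonium carried by ammonium
heptamolybdate in the deprivation solution does not count as macronutrient
supply. Charge balance is reported informationally and never enforced:
printed recipes need not balance once buffers and pH adjustment are
included. Activity coefficients, speciation and pH modeling are out of
scope.

Two design rules are encoded as checkable objects: calcium constant at
500 µM across the high/low treatment pair (membrane-potential control), and
an exact 10-fold step in every macronutrient ion (including magnesium)
between the two solutions (high- vs low-affinity transport contrast).

## Units and I/O conventions

Internal canonical units: µM (concentration), h (time), cm (length), g
(mass), mL (volume), µmol (amount); respiration in nmol CO₂ s⁻¹.
Conversions happen only at I/O boundaries. Long format
(chamber, time_h, ion, conc_um) is the canonical concentration layout; wide
instrument exports are melted on read. Number parsing is strict — decimal
commas and thousands separators raise a row-level error with a line number
rather than being guessed at, because silent misparsing of concentration
data is worse than a failed load. Missing timepoints are permitted
(sampling failures happen); downstream stages receive irregular series.
Trait tables are written with `%.17g` and read with round-trip float
parsing so values survive a write/read cycle bit-exactly.

## Uptake arithmetic

Net influx is the two-point concentration difference scaled by chamber
volume: I_n = (C_0 − C_t)·V/(t − t_0) in µmol h⁻¹. The volume term makes
the printed units (µmol cm⁻¹ h⁻¹ after length normalization) come out; the
default is the constant nominal chamber volume of 250 mL, consistent with a
sampling pump that expels dead-volume solution back after each draw. An
optional volume-ledger mode instead tracks the 1.5 mL permanently removed
per draw and computes an amount balance (remaining amount + withdrawn
samples); with 8 draws from 250 mL the two differ by a few percent at most.
Uptake is reported positive; negative values (net efflux) are retained and
QC-flagged, never dropped.

The sampling interval is selected per chamber: the earliest scheduled time
at which *every* focal ion shows fractional depletion ≥ the threshold
(default 0.10). A time at which an ion was not sampled cannot qualify. If
no time qualifies, the last sampled time is used and the records carry a
`fallback_interval` flag. The rule is monotone in the threshold. With the
simulator's default population (see below) the rule lands on 1 h for the
low solution and 4 h for the high solution.

Root length histograms are classified by diameter into secondary-lateral
[0, 0.15) mm, lateral [0.15, 0.8) mm and seminal [0.8, 4.25] mm. The
printed class ranges touch without stating boundary ownership, so a fixed
convention is required: intervals are half-open with a bin landing exactly
on a threshold going to the coarser class; bins above 4.25 mm are excluded
from all classes and flagged. Specific root respiration divides total
respiration by root length in meters (nmol CO₂ m⁻¹ s⁻¹); specific root
length is cm of root per g of root dry weight.

## Michaelis–Menten kinetics

The forward model for a chamber is dC/dt = −k(C − C_min)/(K_m + (C − C_min))
with k = I_max·L/V in µM h⁻¹, whose integral is the implicit relation
K_m·ln((C_0 − C_min)/(C − C_min)) + (C_0 − C) = k·t. Writing u = C − C_min
the closed-form solution is u = K_m·W₀(z) with
z = (u₀/K_m)·exp((u₀ − kt)/K_m). For low-affinity regimes (C_0 ≫ K_m) z
overflows double precision, so the solver computes ln z and switches to a
Newton iteration on w + ln w = ln z from the asymptotic start
w ≈ ln z − ln ln z. The trajectory is non-increasing, bounded below by
C_min, and agrees with a high-accuracy Runge–Kutta integration to 1e-6
relative over the sampling schedule (with a 1 nmol L⁻¹ absolute floor for
fully-depleted points — physically zero for ion chromatography, and a
regime where the integrator itself is limited by its absolute tolerance).

Fitting is nonlinear least squares **on concentrations**, not on derived
rates: rates are differences of the observable and carry correlated errors.
Initialization is data-driven and deterministic — I_max from the steepest
early two-point slope scaled by V/L, K_m at C_0/2, C_min (if freed) at half
the observed minimum — with an optional seeded multistart. C_min is fixed
at 0 by default: freeing it on an 8-point series costs identifiability.
K_m is bounded above at 10 × C_0 because half-saturation constants far above
the observed concentration range are structurally unidentifiable, and
unbounded fits diverge along the I_max/K_m ridge. An identifiability guard
flags K_m as unreliable whenever the series never leaves the saturating
regime (min C > 10 × the K_m estimate); non-convergence sets a flag rather
than raising.

**Identifiability caveat.** With 8 points, 2% multiplicative noise and a
series that stays well above K_m (e.g. C_0 = 1000 µM, K_m = 150 µM), the
Fisher information bounds the relative standard deviation of any unbiased
I_max estimator at roughly 130%: the curvature signal separating I_max from
K_m is smaller than the noise. Single-chamber estimates in that regime are
therefore reported with honest dispersion; the estimator is median-unbiased
(median of estimates over repeated noise draws tracks truth to ~2%), so
population summaries over many chambers remain accurate. Designs intending
per-plant kinetic parameters should deplete into the K_m region or pool
chambers.

## Trait battery

Each plant yields exactly 50 traits: a 35-column uptake block — per ion
(net uptake rate, SUR per length, SUR per mass, fractional depletion;
4 × 5 = 20), the 10 unordered pairwise uptake-rate ratios, and 5 molar
fractions of total focal uptake — plus a 15-column plant block (3 root
class lengths + total, 5 dry weights, specific root length, total and
specific root respiration, leaf area, leaf length, root:shoot dry-weight
ratio). The enumeration is a pinned reconstruction reproducing both
published counts and is versioned (`SCHEMA_VERSION`) so a revised list can
replace it without code changes elsewhere.

Ratios are ordered alphabetically by ion identifier; figure-parity
orderings (ammonium:nitrate, potassium:phosphate) are provided as named
aliases. A zero-denominator ratio is a missing value with a QC flag, not an
exception. Stoichiometric fractions divide each positive rate by the sum of
positive rates; efflux ions contribute 0 and are flagged, because fractions
of a signed total are uninterpretable. Missing measurements leave traits
missing with the row retained.

## Population statistics

Variance components default to method-of-moments from the one-way genotype
ANOVA: σ_e² = MS_residual, σ_g² = (MS_genotype − MS_residual)/r̄ truncated
at zero (the raw value is kept in diagnostics). The replication count r
entering h² = σ_g²/(σ_g² + σ_e²/r) is the arithmetic mean replicates per
genotype under missingness; a harmonic-mean option and an explicit override
are provided, as is a REML backend (random-intercept mixed model). Genotype
is treated as fixed for ANOVA p-values while its variance component feeds
h² — one decomposition serving both outputs.

The genotype × concentration ANOVA is fixed-effects least squares with
Type II sums of squares (robust to the unbalance failed chambers
introduce), an optional block term, and explicit errors for aliased
factors, zero-variance responses and missing residual degrees of freedom;
with a single concentration level it reduces to the classic one-way table.
Correlations are pairwise-complete Pearson with t-transform p-values, raw
by default (Benjamini–Hochberg optional). PCA uses listwise deletion and
unit-variance scaling by default; variance-explained fractions sum to 1
over the full component set.

## Simulator

The simulator emulates a diversity-panel experiment: G genotypes × r
replicates × two concentration levels (the packaged high/low focal
compositions), assigned to 48-chamber runs (two 24-chamber modules) with
per-run multiplicative effects on uptake capacity. Genotype-level
(I_max, K_m) per ion are lognormal with configurable genetic CV and an
equicorrelated Gaussian copula across ions on the log scale (so the
correlation-matrix stage has a non-trivial truth to recover); per-plant
root length is gamma-distributed; measurement noise is multiplicative
Gaussian on concentrations, truncated at zero — instrument-like relative
error, with the error model itself a modeling choice. Respiration is drawn
as specific respiration × root length, not modeled mechanistically; dry
weights and leaf measures follow simple allometric draws.

Default population parameters — mean I_max 0.019 µmol cm⁻¹ h⁻¹, mean K_m
100 µM, genetic CVs 0.30/0.20, root length 400 ± 25% cm, noise CV 0.02,
run-effect SD 0.05 — place fractional depletion at roughly 10–40% by 4 h
in the high solution and 10–50% by 1 h in the low solution, so the
interval-selection rule is exercised in its intended regime. All draws are
fully determined by one integer seed; fixtures are byte-stable per seed.

What the simulator does **not** emulate: temporal drift within a run,
ion-chromatography carry-over or calibration error structure, chamber
aeration failures, root growth during the 8 h assay, and genuine
C_min > 0 behavior. Passing recovery tests therefore demonstrates the
pipeline's correctness on its own generative model, not instrument-level
realism.

## Problem sizes used in tests

The test suite runs the full pipeline on 36- and 104-plant simulated
experiments, parameter-recovery studies at 200 noise seeds, and
heritability recovery at the panel scale (26 genotypes × 6 replicates,
500 simulations per true h² level) — sizes chosen so the whole suite
completes in well under a minute while keeping Monte-Carlo error small
relative to the tolerances asserted. The acceptance script reuses the same
sizes.

## Known limitations

- Two-point rates inherit the noise of exactly two samples; multi-point
  regression slopes are available inside the fitting module but are not
  the default, to match the standard two-sample computation.
- The moment estimator of h² is a ratio of noisy components; at small G·r
  its distribution is skewed, and truncation at σ_g² = 0 biases null-trait
  estimates slightly upward from zero on average.
- The volume-ledger correction assumes samples are withdrawn instantly at
  the scheduled times and the chamber is otherwise closed.
- Kinetic parameters from single chambers in saturating regimes carry the
  identifiability caveat above.
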