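# Methods

## The DRL statistic

All reference levels in this package are percentile-of-medians statistics:
for a view (CC or MLO) and a CBT window, the median AGD is computed per
center (left and right lateralities pooled), and the DRL is the 75th
percentile of those center medians. Centers with no records in the window are
omitted, never zero-filled, so the DRL is always bracketed by the
participating centers' medians.

Percentile convention matters with as few as nine centers. The default is
linear interpolation between closest ranks (the common default in scientific
software); a nearest-rank alternative is available
(`drl_percentile(..., method="nearest")`), and the method in force is
recorded in every serialized table and in the pipeline manifest.

Three reporting approaches are built on this statistic:

- **simplest**: one window, default 50 ± 5 mm ([45, 55) half-open);
- **range**: 10-mm bins [20, 30), …, [90, 100] (last bin closed), one DRL per
  bin, empty bins kept as flagged rows;
- **equation**: a parametric curve fitted to the per-bin DRLs at the nominal
  bin midpoints (25, 35, …, 95 mm — a per-bin mean-CBT alternative is
  configurable).

## Exclusion rules

Records or examinations are excluded before any statistic: non-CC/MLO views
(record-wise), then — per examination, whole exam removed if any view
violates — compression force above 200 N or exactly 0 N, tube load in
[0, 10) mAs, tube voltage of 0 kVp, CBT above 100 mm, and implant-present
exams. The mAs boundary is half-open (10 mAs retained) and the CBT rule is
strict (100 mm retained): both boundaries are consistent with surveys whose
per-center mAs minima are ≈ 11 and whose CBT ranges end exactly at 100 mm,
and both are configurable. Implant exclusion is on by default — the standard
survey convention — but can be disabled, as can exam-level (vs record-level)
removal. Every removal is attributed to the *first* rule that triggered, in a
fixed order, so the report satisfies `n_out = n_in − Σ removed` exactly; a
property test enforces this identity on randomly contaminated cohorts.

## Median confidence intervals

Per-bin median AGD CIs use the distribution-free order-statistic (binomial
rank) construction: the interval between the l-th and (n+1−l)-th order
statistics, with l the largest rank keeping each one-sided binomial tail
within (1−level)/2. It is exact, assumption-free and deterministic; a
percentile-bootstrap cross-check (10⁴ resamples) agrees within one
order-statistic step in the tests. Below n = 6 no 95% interval of this form
exists, so the full data range is returned with a `low_n` flag.

## Curve fitting

Five families are fitted to the (midpoint, DRL) points: `a+bt`, `a·t^b`,
`a·t^b+c`, `a·e^{bt}`, `a·e^{bt}+c·e^{dt}`. Minimization uses scipy's
trust-region-reflective least squares with xtol = ftol = gtol = 1e-10 and at
most 10⁴ evaluations per start (recorded in every `ModelFit`). Because the
published workflow leaves starting values to its software's internals, the
multi-start policy here is explicit and deterministic:

- data-driven heuristic starts (ordinary least squares for the linear family,
  log–log regression for powers, log-linear regression for the
  mono-exponential);
- for the bi-exponential, the mono-exponential optimum plus a small fast
  component, and a variable-projection scan over a log-spaced (slow, fast)
  rate grid with amplitudes solved linearly, best four kept;
- the nested family's optimum embedded in the richer family's space (c = 0),
  which guarantees SSE(exp2) ≤ SSE(exp1) and SSE(power2) ≤ SSE(power1);
- 20 random perturbations of the primary start from a fixed-seed generator.

The best SSE over all starts wins; non-convergence of every start returns
`converged=False` with the best parameters found rather than raising. The
bi-exponential is fitted in rate form `a·e^{bt}+c·e^{dt}` with the canonical
order b ≤ d (resolving the component-swap symmetry) and presented in
time-constant form `a·exp(t/τ)` with τ = 1/rate; equation strings render at
3 significant figures while full-precision parameters are always stored,
since re-evaluating a curve from rounded printed coefficients already shifts
values by ~0.01–0.02 mGy at large CBT.

No positivity constraints are imposed, but a selected curve that is not
strictly positive over its fitted domain is flagged invalid for DRL use.
Goodness of fit is reported as SSE, RMSE = √(SSE/(n−p)),
R² = 1 − SSE/SST (SST about the mean of the fitted points) and
adj-R² = 1 − (1−R²)(n−1)/(n−p); these identities hold to machine precision on
every fit and are themselves tested. Ranking is by ascending SSE, ties broken
by higher adjusted R² and then fewer parameters; non-converged fits rank last
regardless of SSE. With fewer than five non-empty bins fitting refuses and
recommends merging adjacent extreme bins (a wider `BinScheme`), the standard
mitigation when peripheral CBT data are sparse.

The bi-exponential's individual parameters are weakly identified from eight
points — very different (a, τ) pairs produce nearly identical curves over
20–100 mm — so recovery guarantees are stated for curve *values*, not raw
coefficients: under 5% lognormal noise on the eight points, the median
absolute relative error of curve values over the domain stays ≤ 5% across
100 seeded replicates. Noiseless self-consistency recovers parameters to
better than 1e-4 relative.

## Approach comparison

Percent differences between the equation value and the 10-mm-range value use
the equation value as denominator, evaluated on the integer-mm grid
20–100 mm (81 points; the bin containing each grid point supplies the step
value, so 50 mm reads from [50, 60)). Differences quoted against the simplest
approach use the simplest DRL as denominator — a deliberately different
convention matching how such comparisons are quoted in survey discussions.

The Wilcoxon signed-rank test on the signed grid differences
(range − equation) is implemented directly: zeros dropped, ties mid-ranked,
exact null distribution for n ≤ 25 by convolution over the (doubled) ranks —
valid in the presence of mid-ranks, where tabulated distributions are not —
and a continuity-corrected normal approximation with the tie-respecting
variance Σrᵢ²/4 above. All-zero differences return a degenerate result
(p = 1, zero pairs) rather than an error. One caveat documented here because
it is easy to misread: the signed differences between a least-squares-fitted
curve and the step function built from the same points are roughly symmetric
about zero by construction, so this two-sided test is *not* generically
significant for a well-fitting curve; it becomes decisive exactly when one
approach is systematically offset from the other (the tests demonstrate both
regimes).

Classification against guideline limit curves (acceptable/achievable,
supplied as two-column CSV tables and piecewise-linearly interpolated; the
guideline values themselves are not bundled) is pointwise with boundaries
inclusive downward: equal to the achievable limit classifies as
below_achievable, equal to the acceptable limit as between. Grid points
outside a limit table's span are flagged uncovered, and contiguous regions
are summarized so statements like "between the limits below 40 mm, below the
achievable limit above" fall out directly.

## Record ingestion

DICOM reading is header-only (`stop_before_pixels`), never touching pixel
data — verified by a truncated-pixel-data fixture. Attribute mapping: Body
Part Thickness → CBT, Organ Dose → AGD, View Position → view, Compression
Force, KVP, Exposure, laterality, implant flag, control mode,
target/filter/manufacturer/model. The Organ Dose attribute (0040,0316) is
defined in decigray, so the default conversion to mGy is ×100; because some
vendors store dose in private tags with other units, the unit is a per-source
declaration (`dGy`, `cGy`, `mGy`, `Gy`, `uGy`) in the CSV dialect or the
extraction call — a silent factor-of-100 misread would be catastrophic for a
dose audit, so it is never guessed. Records missing view, CBT or dose are
dropped and counted in provenance; unreadable files are skipped, never
aborting a batch; zero readable files is an explicit error. Exam identifiers
come from the accession number, falling back to (center, patient, study
date). CSV round-trips are lossless: floats are written as shortest
round-trip representations and parsed with correctly-rounded conversion.

## Synthetic cohorts

The generator emulates a nine-center national screening survey: per-center
exam counts (38028, 31092, 24000, 60899, 15584, 16321, 628, 493, 660, scaled
by `size_factor`), CBT truncated-normal (58, 12) on [13, 100] mm, age
truncated-normal (50, 8) on [30, 90] y, and exposure factors drawn within
realistic ranges (mAs ≈ 74 ± 31 clipped to [11, 404], kVp ≈ 29 ± 1, force
≈ 135 ± 37 N clipped to [14, 200]). Each exam produces four records
(CC/MLO × L/R); both views of a breast share one CBT draw (optional jitter).
Doses follow

    AGD = truth(view, CBT) × center_factor × exp(N(0, σ_record)),

with the CC truth a bi-exponential (amplitudes 0.94 and 7.30e-4 mGy, time
constants 118.65 and 15.85 mm), MLO a constant ×1.12 over CC (surveys show
MLO above CC but no established functional relationship), center factors
lognormal with σ = 0.10 and record noise σ = 0.25. Multiplicative median-1
noise is chosen deliberately: it makes the per-center median AGD equal
truth × factor exactly, so the implied DRL curve is available in closed form
(`analytic_drl` = truth × 75th percentile of the realized center factors) and
end-to-end recovery is checkable without simulation error in the target. A
`contamination` fraction of exams (default 1%) receives one rule-violating
record, uniformly over violation types, to exercise the filter.

What the generator does **not** emulate: breast-composition physics (no
target/filter-dependent dose model, no glandularity), per-center CBT or
protocol differences, scanner-specific AEC behavior, repeat/reject
exposures, or temporal drift. Passing recovery tests therefore demonstrate
that the *statistical pipeline* is unbiased and stable under realistic
sampling noise and multi-center spread — not that any particular clinical
dataset follows a bi-exponential, which remains an empirical question per
dataset (the per-vendor stratified machinery exists precisely because the
best second-ranked family differs across machine technologies).

## Problem sizes and determinism

Tests and the end-to-end recovery checks run at `size_factor` 0.02–0.53
(≈ 3.8k–100k exams) — large enough that per-bin medians sit within ~2% of
truth in well-populated bins, small enough for routine runs; the 20-seed
recovery check uses size_factor 0.1 (≈ 18.8k exams per seed) and requires the
bi-exponential selected in ≥ 95% of seeds with ≤ 5% median absolute relative
curve deviation over 25–95 mm. Every stochastic component (generator,
restart perturbations) flows from explicit integer seeds through
`numpy.random.default_rng`; the same seed yields bit-identical cohorts,
parameters and manifests (timestamps aside).

## Known limitations

- The DRL percentile convention is consequential at 9 centers; both supported
  conventions are honest, and outputs always record which was used.
- The exact-Wilcoxon cutoff (n = 25) is a speed/memory choice; the normal
  approximation above it carries a continuity correction but no exactness
  guarantee at moderate n with heavy ties.
- The bi-exponential's second component can collapse to numerically extreme
  coefficients (tiny amplitude, tiny time constant) when it only shapes the
  last one or two bins; curve values remain stable, but raw coefficients
  should never be compared across fits.
- Limit-curve classification interpolates linearly between supplied knots;
  guideline documents sometimes tabulate sparse points, and curvature between
  knots is not modeled.
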