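# Methods

## Inventory model

Emissions are computed per (year, source, technology) cell as

    E_k = A · s · EF_TSP · f_k · (1 − Σ_m φ_m η_m,k)

with activity `A` (kg/yr), technology share `s` (per-source shares sum
to 1), uncontrolled TSP emission factor `EF_TSP` (g/kg), size fractions
`f_fine + f_mid + f_coarse = 1`, and per-device control penetration `φ`
and size-resolved removal efficiency `η`. Cells are summed to
(year, sector, source, species). Assumptions worth stating explicitly:

- **Controls combine additively.** Penetrations of different devices on
  one source are treated as disjoint shares of equipped capacity, so
  total removal is `Σ φ_m η_m,k`, capped at 1. A combined removal above
  1 is physically an over-specification of the input data; it is capped
  and logged rather than allowed to produce negative emissions.
- **BC and OC ride on the fine fraction.** Both are fixed fractions of
  the PM2.5 portion (`bc_frac + oc_frac ≤ 1`) and are removed with the
  fine-size efficiency, reflecting that primary combustion BC/OC is
  essentially all fine PM. No species-specific control data is invented.
- **Units.** All masses are grams internally; reporting converts to Tg
  (1 Tg = 1e12 g) at the IO layer only. Years are calendar integers,
  default span 1960–2019.
- **Missing records are errors, not zeros.** A (source, technology)
  with activity but no EF record, or a (year, source) with activity but
  no technology split, aborts with the offending key; silent zero-fill
  only applies to controls (no record means uncontrolled).

## Driver decomposition

The change of an aggregate `E = Σ_cells Π_factors x_f` between two
snapshots is attributed to its factors with the Shapley (Sun)
decomposition: the effect of factor `f` is its marginal contribution
averaged over all K! orders in which the factors could be switched from
start to end values. This variant was chosen over log-mean Divisia
because it is exactly additive (effects sum to ΔE to machine precision),
symmetric under relabeling, and — decisively for this domain — finite at
zero factor values, which occur whenever a technology or control phases
in or out. The implementation enumerates the 2^K subsets with the
standard |S|!(K−1−|S|)!/K! weights, which is algebraically identical to
ordering enumeration; K ≤ 8 is enforced as a combinatorial guard. The
test suite checks the subset form against an independent
ordering-enumeration oracle.

Consecutive annual steps are decomposed and summed ("chained"), so each
driver's cumulative effect since the baseline is available for every
year and mid-period timing is visible. The additivity invariant —
cumulative effects sum to `E(year) − E(baseline)` — then holds by
construction and is asserted at 1e-9 relative tolerance in tests.

The default factor grouping per (source, technology) cell is activity,
technology mix, species-resolved emission factor (`EF_TSP · f_k`, times
`bc_frac`/`oc_frac` for BC/OC), and the control survival term
`1 − min(1, Σφη)`. For multi-class species (TSP, PM>2.5) the control
term is the size-fraction-weighted survival, so the factor product still
reproduces the inventory series exactly. The grouping is configurable;
passing a population series splits activity into population ×
per-capita-activity as a demonstration.

Counterfactual series (selected factors frozen at their baseline values)
are related to, but not identical with, the cumulative Shapley effects;
both are provided. The pipeline's "negative drivers" default is
{technology_mix, control}.

## Monte Carlo uncertainty

All perturbations are mean-parameterized by a coefficient of variation:

- activities — uniform on `[m(1−√3·cv), m(1+√3·cv)]` so sd/mean = cv;
  cv > 1/√3 is rejected (support would go negative). Defaults: 5%, and
  10% for residential biomass.
- emission factors — lognormal, moment-matched on the natural scale
  (`σ² = ln(1+cv²)`, `μ = ln m − σ²/2`), cv taken from each EF record.
- penetrations — normal with 5% cv, truncated to [0,1] by resampling.
  Truncation is negligible for rates a few sd from the boundary but
  biases the mean downward for nominal rates very close to 1 (a 0.99
  rate at 5% cv has its upper tail cut 0.2 sd above the mean); the
  tests assert mean preservation only away from the boundary.

Perturbed inputs are independent; no correlation structure is imposed.
Size splits and BC/OC fractions are left fixed by default (specs can
target only activities, EFs and penetrations). Outputs are empirical
25th/50th/75th percentiles; the default is 10,000 draws.

Two routes exist deliberately: `sample_inputs` yields perturbed table
sets for the generic path, while `run_mc` compiles the table merges into
index maps once and evaluates each draw in numpy, making 10,000 draws a
seconds-scale operation. A test asserts the compiled engine matches,
percentile for percentile, the slow route that maps the full inventory
over `sample_inputs` draws with the same seed — the fast path cannot
silently diverge from the table-level contract.

## Trend metrics

- Ternary shares are species totals normalized by their sum, so they
  close to exactly 1; a zero denominator yields an undefined flag, not
  an exception.
- The fine/coarse ratio defaults to PM2.5 / (PM2.5–10 + PM>10), the
  convention consistent with treating everything coarser than 2.5 μm as
  one class; PM2.5 / PM>10 is available as an option since both
  conventions appear in the literature on such ratios.
- Kuznets peak detection is a raw argmax (optional centered 3-year
  moving average, off by default), earliest year on ties, with a
  boundary flag when the maximum sits on the span edge (no interior
  inverted-U apex). No quadratic-in-log-GDP regression is attempted.
- Piecewise dependence fits two independent OLS segments (years ≤ and >
  the breakpoint, default 1995) with no continuity constraint, plus a
  pooled Pearson correlation; each segment requires ≥ 3 points.
- Percentages are rounded only at reporting time, never internally.

## Synthetic scenario generator

The generator emulates the statistical structure of a multi-decade
national inventory compilation: logistic activity growth per source,
logistic old→new technology transitions (shares are normalized logistic
weights, hence sum to 1 by construction), and monotone logistic control
rollouts per device type. It is the fixture factory for every test: its
output always satisfies the full set of table invariants.

Nominal parameters equal published anchors where available: residential
OC emission factor 2.82 g/kg (sd 1.88) versus 0.25 g/kg (sd 0.18) for
other sources — implemented by deriving `oc_frac` from the target OC EF;
electrostatic-precipitator removal 97.1% (fine) / 99.0% (PM2.5–10);
cyclone removal 15% (fine) / 70% (coarse); the power-sector penetration
logistic passes exactly through 86.5% in 1995 and 95.6% in 2005 (a
two-point logistic fit with asymptote 0.98); GDP per capita is an
exponential path anchored at US$1023 in 1995. Where only qualitative
guidance exists, defaults follow it: cement/brick/lime/power sources are
coarse-heavy (>70% PM>10 uncontrolled for cement), transportation is
fine-heavy (78.5% PM2.5), residential solid fuel dominates early fine
PM. Growth and rollout timing are chosen so the total PM2.5 series is
bell-shaped with its single interior maximum in 1995; absolute
magnitudes are order-of-magnitude plausible only (peak near 10 Tg).

Seeds control small (3% cv) lognormal jitters on per-source activity
scales and per-record EF means. Jitter is deliberately applied to scale
parameters, not year-by-year, so replicates stay smooth and the interior
peak location is stable across seeds; the peak-recovery test runs across
multiple seeds.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: the real source granularity
(hundreds of sources vs 9 here), year-to-year irregularity of real
activity statistics (economic shocks, data revisions), correlated input
uncertainties, spatial/monthly structure, species-specific EF records
for BC/OC, and any real inventory's absolute magnitudes.

## Numerical choices

- Invariant tolerances: technology shares and size fractions must sum to
  1 within 1e-9; emission mass closure (sizes sum to controlled TSP) is
  asserted at 1e-9 relative; the vectorized inventory is held to the
  loop reference at 1e-12 relative.
- The driver-ratio denominator guard defaults to ε = 1e-6 Tg; smaller
  coarse effects are flagged undefined rather than divided by.
- Degenerate inputs: cv = 0 leaves values exactly nominal; zero nominal
  means stay zero under every family (all families are
  mean-parameterized with sd ∝ mean).
- The pipeline derives per-stage seeds from one global seed via
  `SeedSequence.generate_state`, keeping all derived seeds below 2^31;
  reruns with the same config and seed are byte-identical on every
  numeric output (the manifest carries wall-clock timestamps and is the
  one exception).
- Problem sizes in the test suite and acceptance script are kept small
  by design: the default scenario has 9 sources × 60 years, property
  tests use randomized tables of 1–3 sources × 1–4 years, and the
  acceptance Monte Carlo uses 2000 draws (the calibration check uses the
  full 10,000 on a single cell, where closed-form quantiles exist).

## Known limitations

- The additive-removal cap means inventories with heavily overlapping
  control programs (Σφ > 1) are modelled conservatively; a
  device-hierarchy model (newest device replaces older on the equipped
  share) is not implemented.
- No uncertainty is propagated through the decomposition or the trend
  metrics; the Monte Carlo covers the inventory only.
- Peak detection is descriptive (argmax), not inferential; it reports
  where the maximum is, not whether a bell shape is statistically
  supported.
- The YAML/JSON scenario schema mirrors the internal dataclasses and
  will evolve with them; it is a configuration format, not a stable
  interchange format.
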