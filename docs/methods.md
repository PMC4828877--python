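# Methods

## Supply sub-model

The supply side is a deterministic state-transition cohort model. The
state space is the product of sex × age band (`<35`, `35–44`, `45–54`,
`55–64`, `65+` by default) × location (urban/rural) × work status
(full-time ≥ 35 weekly clinical hours, part-time < 35, temporary exit,
permanent exit), giving 40 active states plus exits. Counts are
continuous expected values; the model propagates proportions, not
sampled individuals, so a probability of 0.05 applied to 100 GPs moves
exactly 5.

Allowed moves keep sex and age band fixed and change one attribute at
a time: full↔part time within a location, urban↔rural within a status,
active→temporary exit, active→permanent exit, temporary exit→active
(with an explicit destination location/status) and temporary
exit→permanent exit. Permanent exit is absorbing. Temporary-exit
states are keyed by the location held at exit; the full/part status
before exit is not remembered, so re-entry transitions name their
destination status explicitly (fixtures split the default 0.5/yr
return 60/40 between full- and part-time).

**Annual cycle order.** Within each simulated year the model applies,
in this fixed order: (1) entries (graduates and in-migrants) allocated
over active states, using the entry counts of the year being
simulated; (2) transition flows computed simultaneously from the
start-of-year stock, with per-state outbound probability sums above
one rescaled proportionally (and warned about); (3) aging, which moves
a fixed fraction of each band's survivors (active and temporary-exit
states) to the next band. The ordering is a modelling convention; the
alternatives differ at second order in the (small) annual
probabilities.

**Time variation.** Each transition carries a multiplier `m` drawn
from a uniform prior on [-10%, +10%] per year; the effective
probability after `k` years is `clamp(p(1+m)^k, 0, 1)` (compounding,
matching an "annual percentage change"; a one-off shift is the main
alternative reading and is not implemented).

**Aging.** Defaults to the steady-state approximation 1/width per band
per year (1/10 for the ten-year bands), 0 for the terminal open band;
fully configurable.

**Entries.** Held constant at base-year values (defaults: 42 graduates,
47 in-migrants a year) unless a per-year series is supplied. Graduates
enter the two youngest bands 70/30 and follow the base stock's
location/status mix within each band; in-migrants follow the base
stock's full joint distribution over active states.

**Conservation.** Active + temporary + permanent headcount at `t+1`
equals that at `t` plus entries, exactly (verified to 1e-9 relative
against a brute-force flow enumeration).

## Calibration

Accept–reject sampling of full parameter vectors: base probabilities
from per-transition beta priors, multipliers from uniform ranges. Each
candidate is projected over the observation window (2004–2011 by
default) and compared with the observed stock per `(year, sex, age
band, location, status)`. Observed series are first smoothed with a
per-stratum ordinary-least-squares linear trend, absorbing
definitional breaks in survey series. A candidate converges iff
`|predicted − smoothed| / smoothed < 0.05` at **every** target; all
convergent sets are retained to represent the joint parameter
uncertainty, and the summed absolute headcount deviation is reported
alongside. With zero convergent sets the result is empty but carries
the minimum-max-deviation candidate as a diagnostic. Targets with a
zero smoothed value carry no relative information and are dropped with
a warning.

A spreadsheet-solver search could find convergent sets faster; plain
seeded accept–reject sampling was chosen for reproducibility and
independence from proprietary tooling.

## Need sub-model

Within each `(sex, age band)` cell the base-year fit divides the share
of consultations managing each of the 17 ICPC-2 condition chapters by
the chapter's incident plus prevalent cases, giving annual
consultations per case; the prevent/admin share of consultations is
expressed per capita. Shares may sum above one across chapters
(consultations can manage several problems); each chapter share is
treated independently and no renormalisation is applied, so the
reconstruction identity — projecting at `k = 0` reproduces base-year
attendances exactly — holds whenever chapter shares plus the
prevent/admin share sum to one per cell, which the synthetic fixtures
guarantee by construction. Users supplying only prevalence can zero
the incidence column; burden sources grouped by other classifications
map onto chapters via a two-column mapping file.

Projection applies base-year per-capita case rates to the projected
population, compounds an optional burden growth factor, multiplies by
per-case norms with an optional utilisation multiplier `u^k`, scales
prevent/admin volume with population, and converts to FTE via mean
consultation minutes per cell and the 1760-hour FTE year
(40 h standard week × 44 working weeks, the conventional allowance for
leave and training). Scenario presets: (1) demography only, (2)
`u = 1.0112`, (3) burden growth 1.02 — both compounding annually from
the base year.

## Synthetic data

Fixtures are structural stand-ins, not epidemiological estimates: they
mirror the shape of the real data landscape (survey stocks, burden
cases, problem-management shares, claimed attendances, population
projections) with internally consistent known truth.

Supply fixtures use demographically graded truth probabilities
(participation moves 3–7%/yr, temporary exits 2–4%/yr, permanent exits
anchored to band-midpoint ages between 0.5%/yr at 30 and 12%/yr at
70), true multipliers of ±2%/yr, and a seed stock burned in for ten
years under the truth dynamics then rescaled to 1789 active GPs — an
observed workforce sits near the quasi-stationary profile of its own
dynamics, and starting there keeps target series free of artificial
transients (and hence close to their own linear trends). Observed
targets are the truth projection under optional multiplicative
lognormal noise. Priors are beta distributions centred on the truth
with concentration α+β = 2000, the precision of pooled
administrative-scale evidence; with the 5% all-targets rule and the
full ±10% multiplier priors this yields a practical acceptance rate of
roughly 0.3–0.5% at 2% target noise. The toy preset (2 sexes × 2
bands × 1 location, 16 states, 64 calibration targets) backs the
oracle and recovery suites; the paper-like preset (2 × 5 × 2 × 2, 80
states) exercises full-scale plumbing.

Need fixtures draw per-case truth rates of 0.8–2.3 consultations/case,
prevent/admin rates near 1.5/person, lengths of 14–17.6 minutes, and a
1 529 424-person base population growing 1%/yr; attendances are
computed forward from the truth so that the fit round-trips to
machine precision.

What passing these tests shows: the arithmetic chain, conservation,
determinism and recoverability are correct. What they do not show:
that any particular jurisdiction's priors, burden tables or hours
profiles are well estimated — real series have definitional breaks,
non-lognormal noise and trend changes the generator does not emulate.

## Numerical choices and limitations

* Counts are continuous; rounding happens only in rendered reports
  (FTE to one decimal, headcounts to integers).
* Outbound probability sums above one are rescaled proportionally with
  a warning; clamping of effective probabilities at [0, 1] is silent.
* Percent differences use the observed (or smoothed observed) value as
  denominator throughout.
* Problem sizes in the shipped suites (toy state space, 5000
  calibration samples, 1000 oracle trials) are chosen to exercise every
  code path at interactive runtimes.
* Not modelled, by design: microsimulation stochasticity,
  condition-specific consultation lengths, multimorbidity, sub-state
  geography of need, and non-clinical workload beyond the aggregate
  44-week year.
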