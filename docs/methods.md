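# Methods

## Model structure

The decision model is a deterministic cohort simulation over three health
states — progression-free on first-line therapy (PF), progressed disease
(PD) and death — with weekly cycles and a 10-year horizon (520 weeks),
after which essentially no cohort mass remains alive under realistic
inputs. Transitions are governed by three constant weekly probabilities:
PF→PD (`p_pf_pd`), PF→death (`p_pf_dead`) and PD→death (`p_pd_dead`).
Within a cycle the PF cohort splits multinomially (progress, die, stay);
there is no same-week PF→PD→death chaining. The alternative (chained)
ordering was considered and rejected as the default because the
multinomial split is the simplest chain consistent with a three-state
diagram, and at weekly resolution the difference is far below every other
source of uncertainty.

PD occupancy is expanded by weeks-since-entry ("tunnel" accounting).
Transitions remain memoryless; the expansion exists only so that PD time
can be valued differently by sojourn: the first `second_line_duration_weeks`
(default 52) are costed and valued as second-line therapy, the remainder
as palliative care. No published value pins down when second-line therapy
ends, so this is an explicit, documented configuration input rather than
a constant.

Cohort traces are validated against an independent analytic oracle: the
matrix power of the one-week transition matrix, and the closed-form
occupancy

    PF(t) = (1−q)^t,  PD(t) = a·((1−c)^t − (1−q)^t)/(q−c),  q = a + b,

with the l'Hôpital limit `a·t·(1−q)^(t−1)` when `q = c` (switched at
|q−c| ≤ 1e-9). Equality holds to 1e-12 over the full horizon.

## Parameter table

Every economic and utility parameter carries a base value, a one-way
low/high range, and a probabilistic-sensitivity distribution —
gamma(shape, scale) for costs, beta(α, β) for utilities and
probabilities. Drug costs are stored per administration, already scaled
to a 55.6 kg / 1.6 m² reference patient; the package performs no dose
arithmetic. The analytic distribution means reproduce the base values to
well under 2% for most rows; three printed rows (the XELOX regimen, the
per-day time cost and the round-trip transportation cost) deviate by
4.9%, 2.1% and 13.8% respectively. These are properties of the published
parameters themselves; the package reports the analytic means as they are
and does not re-fit the distributions.

Utilities: progression-free 0.72; progressed-on-second-line expressed as
a multiplier 0.88 (0.72 × 0.88 ≈ 0.63); palliative care at half the PF
utility; a grade 3–4 adverse-event decrement of 0.07 applied temporarily.

Adverse-event incidences per arm are **not** published. The defaults in
`data/default_config.yaml` (e.g. 17% grade 3–4 acneiform rash and 25%
neutropenia for the anti-EGFR arm; 22% neutropenia and no rash for the
bevacizumab arm) are in the range reported by first-line mCRC trials and
carry beta distributions with an effective sample size of 200; they are
intended to be overridden with trial-specific rates. AEs are applied once
to the newly treated cohort: a one-off expected management cost at
treatment start, and a utility decrement lasting
`ae_decrement_duration_weeks` (default 4) on the AE-affected fraction
(1 − Π(1 − pᵢ), independence assumed).

## Costing rules

Active-therapy states accrue, per week: drug + chemotherapy backbone at
(cost per administration)/(administration interval); per-visit
administration charges (consultation + laboratory test) at the same
visit frequency; imaging every `imaging_interval_weeks` (default 8,
a routine response-assessment schedule); and per-visit indirect costs
(one day of patient time + one round trip). PD beyond the second-line
window accrues the palliative per-diem charge × 7. Death accrues
nothing. All flows are discounted at `(1+r)^(−week/52)` with r = 3%/year,
and occupancy is valued at cycle start; a half-cycle correction flag is
available but off by default so that the valuation convention is
auditable rather than implicit.

A consequence worth stating plainly: at the published palliative charge
of US$1,173/day, a memoryless post-progression death rate leaves the
cohort in palliative care long enough that this component dominates total
cost (roughly 80% under the default synthetic configuration). Published
totals of comparable analyses are several-fold lower, which implies their
palliative accrual was restricted in some unreported way (e.g. to a
terminal episode). The package keeps the transparent per-diem rule;
analysts who want an episode-style palliative cost can shorten the
palliative window via `second_line_duration_weeks` or reduce the per-diem
parameter. Incremental results are affected much less than totals, since
both arms share the rule.

## Transition-probability estimation

**Step (a) — pseudo-IPD reconstruction.** A digitized KM curve
(time/survival pairs) plus its number-at-risk table is inverted into
per-patient (time, event) records. Within each inter-anchor interval the
number of censorings is solved by fixed-point iteration starting from
the no-censoring solution: censor times are spread uniformly over the
interval (administrative censoring), event counts are obtained by
inverting the KM steps with deterministic half-up integer rounding, and
ties within a week are resolved events-before-censorings (the standard
product-limit convention). The anchor constraint is enforced exactly: if
rounding overshoots, events are trimmed from the end of the interval.
Beyond the last anchor, censoring is assumed only after the last event;
an optional reported event total adjusts the final interval. Without a
risk table a single-interval fallback applies and is flagged in the
output metadata. Round trips on synthetic curves (n = 50–1000) stay
within a sup-norm of max(0.01, 1/n).

**Step (b) — posterior sampling.** PFS and OS pseudo-datasets enter the
likelihood as independent samples — reconstruction from separately
published curves destroys the within-patient linkage, so nothing better
is identified. PFS exit times are geometric in q = a + b; OS deaths
contribute occupancy increments D(t) − D(t−1) and OS censorings
1 − D(t). Impossible data (e.g. an event at week 0) yield −∞, not an
exception. The likelihood is verified against brute-force path
enumeration (≤10 patients, ≤20 weeks) to 1e-9.

Sampling is a Metropolis–Hastings Gaussian random walk on
logit-transformed coordinates with flat priors over the constrained
region (a + b ≤ 1), implemented directly (an ensemble sampler would be a
different algorithm, and this posterior is 3-dimensional and cheap). The
proposal scale adapts toward a 30% acceptance rate during burn-in only,
so the retained chain is a valid MH chain; everything is reproducible
under a seed. Defaults: 52,000 iterations, 2,000 burn-in, thinning 5
(10,000 kept draws); the pipeline preset uses 12,000/2,000/5 (2,000
draws), which parameter-recovery tests show is sufficient at trial-sized
datasets. Diagnostics report the acceptance rate and per-coordinate
effective sample sizes (initial-positive-sequence autocorrelation
estimator), with flags for extreme acceptance or ESS < 100. No published
priors, chain lengths or convergence criteria exist; these defaults are
this package's choices.

Calibration: for each posterior draw the analytic PFS survival (1−q)^t
and OS survival 1 − D(t) give pointwise median and 2.5/97.5% bands,
which are compared with the input KM curves at the risk-table anchors.
Band coverage allows a default absolute tolerance of one KM step (1/n),
the discretization error inherent in a digitized curve.

## Synthetic trial generator

The generator emulates a modern two-arm first-line mCRC trial: patient
paths follow the same weekly chain as the cohort model (so ground truth
is exactly recoverable in principle), accrual is uniform over 78 weeks
with a common data cutoff at 312 weeks (administrative censoring only),
and KM curves are emitted with risk tables every 26 weeks, mimicking
published figures. Population presets (KRAS wild-type, pan-RAS wild-type,
pan-RAS wild-type left-sided) are alternative transition-parameter
configurations chosen once from closed-form medians: PFS medians of
9–11.5 months and OS medians of 30–45 months, with the anti-EGFR arm's
OS median above 30 months in every preset and the benefit ordered
KRAS < pan-RAS < left-sided, consistent with reported gradients. The
generator does **not** emulate loss to follow-up, cure fractions,
non-proportional hazards, digitization error of real figures, or
within-patient PFS/OS correlation in the published-curve sense — so
passing tests demonstrate correctness of the machinery under the model's
own assumptions, not fidelity to any particular trial.

## Sensitivity analyses

- **PSA**: one joint parameter world per replication (all gamma/beta
  parameters and AE incidences resampled simultaneously, shared across
  strategies) plus one posterior transition draw per strategy, taken
  without replacement unless resampling is requested. Both 1,000 and
  10,000 replication presets are supported; the source material states
  both figures in different places, so neither is treated as canonical.
  Summaries are medians with 2.5/97.5 percentile intervals (means also
  reported). The ICER interval is computed from the per-replication ratio
  distribution restricted to replications with positive incremental QALY
  (the ratio is unstable near zero); the count of non-positive
  replications is reported separately. Whether the published intervals
  were percentile-of-ratios or ratio-of-percentiles is unstated;
  percentile-of-ratios is used and documented here.
- **CEAC**: at each WTP the strategy with the highest net monetary
  benefit (WTP·QALY − cost) wins the replication; exact ties split the
  win equally, so probabilities sum to one. Default grid 0–300,000 in
  steps of 2,500; default WTP 97,832 (2× GDP per capita).
- **Tornado**: each table row set alone to its low/high extreme; AE
  incidences varied over their beta 2.5/97.5 quantiles; each transition
  coordinate varied over its posterior 2.5/97.5 interval (no published
  ranges exist for the survival parameters). Dominance at an extreme is
  recorded as a flag, and flagged rows sort after numeric ones.
- **Price threshold**: the comparator's first-line drug price (base,
  range and gamma scale) is multiplied by each factor in (0, 1]; the PSA
  re-runs with the same seed, so common random numbers make the
  cost-effective fraction exactly monotone in the multiplier.

## Numerical and testing choices

Deterministic half-up rounding in the reconstruction; logit-scale
proposals never touch the boundary, and −∞ handles impossible data;
occupancy conservation is asserted to 1e-12 per cycle; CSV round trips
use full float precision (`float_precision="round_trip"` on read). Test
and acceptance problem sizes — 300–1,000 patients per arm, 1,000 PSA
replications, 12,000-iteration chains, 20 recovery replicates at
n = 500 — were chosen as the smallest sizes at which the Monte Carlo
properties under test are stable.

## Limitations

Constant weekly hazards (no Weibull/log-normal alternatives, by design);
no microsimulation, resection or maintenance pathways; no currency
conversion or inflation adjustment; AE incidences and second-line
duration are user inputs with documented placeholders; the synthetic
generator cannot reproduce any specific published trial, so absolute
cost/QALY levels of the default configuration are illustrative rather
than estimates for any real population.
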