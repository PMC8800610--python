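# Methods

## Model structure and assumptions

The engine implements a discrete-time Markov cohort model with four states:
`IMPROVED_ON_TX`, `NOCHANGE_ON_TX`, `DISCONTINUED`, `DEAD`. `DEAD` is
absorbing; `DISCONTINUED` can only persist or die; there are no
transitions between the two on-treatment states after the entry split (no
relapse or delayed response — the worked configuration publishes no such
probabilities). Background mortality applies uniformly to every alive
state and is independent of treatment.

Timing conventions (these matter for any comparison with other tools):

- Transitions occur at cycle boundaries; rewards accrue on the state
  occupied during the cycle.
- Cycle 1's occupancy is the post-entry-split distribution: entrants draw
  first-cycle mortality and then split into responders/non-responders with
  `p_improve_first`.
- Cycle k's discount weight is `(1+r)^(-(k-1)*L)` (cycle length `L` in
  years), i.e. rewards accrue at cycle start and cycle 1 is undiscounted.
- Annual mortality converts per cycle as `1-(1-q)^L`, with the age for
  cycle k taken as `floor(start_age + (k-1)*L)` and life-table lookups
  clamped to the tabulated range.
- Half-cycle correction is off by default; switching it on applies
  trapezoid weights (half weight on cycle 1 plus a half-weighted extra
  cycle beyond the horizon).
- Costs accrue only in on-treatment states: cycle 1 carries the initial
  visit plus the induction injections, later cycles drug and maintenance
  injection costs; the societal perspective adds `halfday_wage_loss` per
  clinic visit. `DISCONTINUED` and `DEAD` accrue nothing; the dead accrue
  zero utility.

One published input row of the worked configuration is genuinely
ambiguous: non-responders have both a generic 50% per-cycle continuation
and a strategy-specific "off treatment" probability (0.29/0.22/0.20).
Both readings are implemented as `nochange_first_cycle_mode`:
`CONTINUE_50` (default) applies the generic continuation throughout;
`OFFTX_TABLE` applies the strategy-specific probability once, at the first
continuation decision. Neither is asserted as the original intent.
Similarly, the combined arm's printed initial-visit cost of $15 is treated
as a typo for the $150 charged in the other arms (configurable).

## Parameters of the worked configuration

Per strategy (minoxidil / minoxidil+PRP / PRP): first-cycle improvement
0.51 / 0.55 / 0.53; continuation after improvement 0.91 / 0.99 / 0.97
(cycle 2) then 0.98; non-responder continuation 0.50; improved-state
utility 0.89 / 0.92 / 0.89 against a 0.85 baseline that also applies off
treatment (no off-treatment utility is published, so discontinuation
reverts to baseline). Costs (2020 USD): initial visit $150; minoxidil
$96.60 per six-month cycle; PRP injection $717.67, three in cycle 1 (0, 4,
8 weeks) then one per on-treatment cycle; half-day wage $166.55 per visit
(one minoxidil visit in cycle 1; three then one per cycle for PRP arms).
Settings: 0.5-year cycles, 35-year horizon (70 cycles) from age 25, 3%
annual discount, WTP thresholds $50,000/$100,000 (PSA also reports
$200,000). Horizon, discounting, start age and perspective are all
settings, not constants.

## Synthetic life table

Mortality inputs are generated, not copied: a Gompertz–Makeham hazard
`mu(x) = a + b*exp(c*x)` with defaults `a = 5e-4`, `b = 3e-5`,
`c = 0.085`, tabulated for ages 25–74 as `q(x) = 1 - exp(-mu(x))`. This
gives q rising from ~8e-4 at 25 to ~2e-2 at 74 and 35-year survival from
age 25 above 90% — order-of-magnitude consistent with recent US adult-male
mortality, with no claim of demographic accuracy. Users supply a real
table as a two-column CSV (`age,annual_mortality_probability`) or inline
in the model configuration.

What this emulates and what it does not: level and curvature of adult-male
all-cause mortality, enough to give lifetime QALY totals the right scale;
it does not reproduce any specific national table, cohort effects, or
year-to-year noise. Consequences: results that depend on absolute
survival (total QALYs, anything accumulating over decades) carry a
life-table uncertainty of order 1%; incremental comparisons between
strategies are nearly insensitive to it because all arms share mortality.

## Fidelity to the externally published totals for this configuration

The originally published analysis of this configuration used a national
mortality appendix and a commercial decision-tree tool, neither of whose
internals are printed. With the conventions above, the package reproduces
closely everything that is mutually consistent in the published results:

- QALY totals to +1.4% and QALY increments almost exactly (0.261 vs
  0.264; 0.0262 vs 0.026);
- the minoxidil arm's costs to ~1% in both perspectives;
- the societal-minus-healthcare cost differences essentially exactly
  (166 / 2,907 / 2,780 computed vs 166 / 2,939 / 2,810 published) — these
  differences pin down the model's discounted on-treatment occupancy.

However, the published PRP-arm *healthcare* totals imply roughly one more
discounted injection-cycle per arm than those same published societal
differences allow. No occupancy convention can satisfy both, so the
package's PRP-arm costs come out 6–7% below the published totals, and
three knife-edge downstream results shift accordingly: the combination's
healthcare ICER vs minoxidil computes to ~$48.8k (published $52.0k),
placing it just below rather than just above a $50,000 threshold; and the
break-even injection price computes to ~$156 (published $86.71 — a figure
that is also inconsistent with the published tables' own arithmetic, which
implies ~$106). These are reported as computed; no parameter is adjusted
to force agreement.

## Probabilistic sensitivity analysis

Each uncertain parameter gets a distribution by method of moments: beta
(`alpha = m(m(1-m)/s^2 - 1)`, `beta = (1-m)(...)`) for probabilities and
utilities, gamma (`shape = m^2/s^2`, `scale = s^2/m`) for costs. One draw
per parameter per iteration; shared parameters (wildcard paths such as the
PRP injection price used by two arms) receive a single draw, since the
uncertainty is about the parameter, not the arm. Sampling order is fixed
by sorted parameter path and all randomness flows through one seeded
generator, so identical seeds give bit-identical results. Beta draws are
defensively clipped into [0,1] and clip events are counted and logged.

The default uncertain set mirrors the parameters the original analysis
reports varying: per-strategy first-cycle improvement probability and
improved-state utility, plus the shared drug and injection costs. The
original input SDs are unpublished; the defaults are relative — 10% of the
mean for probabilities/utilities (truncated to the beta-feasible region)
and 20% for costs — and fully overridable. Note the implied dispersion is
wider than the original analysis displays (its QALY scatter suggests
utility SDs nearer 2–3% of the mean), so acceptability fractions under the
defaults sit closer to equipoise than the published 51–66% and 75–91%
figures. Tie-breaks in the acceptability curves go to the cheaper strategy
in that iteration, making fractions sum to exactly 1.

## Numerical choices

- Pure floating-point currency, reported to the cent; presentation
  rounding only in display layers.
- Occupancy conservation holds to 1e-12 per cycle; totals are plain sums
  of the (already discounted) per-cycle vectors.
- Cost-sorting ties in the incremental analysis break by higher QALY;
  NMB ties by lower cost. Dominated strategies still receive a labelled
  ICER vs the cheapest comparator, as published tables customarily print.
- The threshold-price search uses bisection to $0.01 and cross-checks the
  affine closed form (NMB is linear in any unit cost); disagreement raises
  rather than returning a guess. An identically-zero NMB difference
  reports "no crossing".
- Degenerate sweep ranges (`lower == upper`, one point) are allowed and
  reproduce the base case exactly; grid defaults are 101 points one-way
  and 51×51 two-way.

## Known limitations

- Four fixed states; no tunnel states, no microsimulation, no
  adverse-event states (negligible for the worked configuration).
- No value-of-information analysis.
- PSA supports independent beta/gamma draws (with shared-parameter
  correlation) only; no copulas.
- The synthetic life table is a stand-in: analyses whose conclusions
  hinge on absolute mortality levels should supply a real table.

## Problem sizes used in tests and the acceptance script

Deterministic analyses run the full 70-cycle horizon. The acceptance
script's PSA uses 10,000 iterations (matching standard practice for this
kind of analysis); examples use 2,000 for speed. Property tests sweep
1,000 random model configurations for conservation invariants and use
10^6-draw moment-recovery checks for the distribution constructors.
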