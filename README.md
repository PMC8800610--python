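# markov-cea

Markov cohort cost-effectiveness modelling for treatment comparisons, with a
worked analysis of long-term therapy for male androgenetic alopecia (AGA):
topical minoxidil 5% monotherapy, minoxidil combined with platelet-rich
plasma (PRP) injections, and PRP monotherapy.

## Who this is for

Health-economics and outcomes researchers who need a scriptable,
reproducible alternative to spreadsheet or GUI decision-tree tools for
four-state cohort models of the common *treat → respond / not respond →
discontinue → die* shape: cohort simulation, incremental cost-effectiveness
analysis, and full deterministic and probabilistic sensitivity analysis.

## The model

A closed cohort moves through four health states — improved on treatment,
no change/worse on treatment, discontinued, dead — in fixed-length cycles
(six months by default). In cycle 1 the cohort splits into responders
(probability *p*) and non-responders; at later cycle boundaries, responders
continue treatment with an early and a steady-state continuation
probability, non-responders continue with their own probability, and
everyone faces age-specific background mortality from a life table
(annual *q* converted per cycle as 1 − (1 − *q*)^½). Each cycle accrues

- QALYs: occupancy × state utility × cycle length × discount weight, and
- costs: occupancy × per-cycle state cost (initial visit, drug,
  injections; plus lost half-day wages under the societal perspective),

discounted at rate *r* with weight (1 + *r*)^−(k−1)·½ for cycle *k*.
Strategies are compared by

- **ICER** = ΔCost / ΔQALY along the efficiency frontier, with strict and
  extended dominance handling, and
- **NMB** = WTP × QALY − Cost at chosen willingness-to-pay thresholds.

Uncertainty is handled by one-way/two-way sweeps and threshold (break-even
price) analysis, and by second-order Monte Carlo PSA: beta distributions
for probabilities and utilities, gamma for costs, both fitted by the method
of moments from a mean and SD, summarized as cost-effectiveness
acceptability curves (CEACs).

The bundled AGA configuration uses six-month cycles over 35 years from age
25, 3% annual discounting, 2020 USD, and a synthetic Gompertz–Makeham
adult-male life table (the package generates mortality inputs rather than
shipping a copied national table; see `docs/methods.md`).

## Worked example

```python
from markov_cea import Perspective, evaluate_model, load_aga_reference

model = load_aga_reference()
result = evaluate_model(model, wtp_list=(50_000.0, 100_000.0),
                        perspective=Perspective.SOCIETAL)
print(result.to_frame().round(2))
```

Running `python examples/base_case.py` prints (societal perspective shown):

```
     strategy    cost  incremental_cost   qaly  incremental_qaly  ce_ratio     icer comparator dominance  on_frontier  nmb_at_50000  nmb_at_100000
    minoxidil  1613.0               NaN 18.578               NaN      87.0      NaN       None      none         True      927276.0      1856164.0
          prp 14910.0           13297.0 18.604             0.026     801.0 508481.0  minoxidil  extended        False      915286.0      1845482.0
minoxidil_prp 17079.0           15465.0 18.839             0.261     907.0  59306.0  minoxidil      none         True      924849.0      1866776.0
efficiency frontier: minoxidil -> minoxidil_prp
highest NMB at $50,000/QALY: minoxidil
highest NMB at $100,000/QALY: minoxidil_prp
```

Over 35 years minoxidil monotherapy costs ~$1,600 for 18.58 QALYs; adding
PRP buys 0.26 extra QALYs at ~$59,000 each (societal). PRP monotherapy is
extendedly dominated — the combination buys QALYs more efficiently — so at
a $50,000/QALY threshold minoxidil has the highest net monetary benefit,
while at $100,000/QALY the combination becomes the most cost-effective.
The other examples show deterministic sweeps (the break-even PRP injection
price vs minoxidil, and the improved-state utility at which PRP monotherapy
becomes preferred — about 0.92) and the probabilistic analysis.

A thin CLI mirrors the library:

```bash
markov-cea run --perspective both --out results/
markov-cea dsa threshold --strategy prp --comparator minoxidil
markov-cea psa --n-iter 10000 --seed 1 --out psa/
markov-cea synth --out life_table.csv
```

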