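"""Deterministic sensitivity analysis on the bundled alopecia model.

Shows a one-way sweep (how the preferred strategy responds to PRP's
improved-state utility), the break-even PRP injection price against
minoxidil, and a small two-way grid.
"""

from markov_cea import (
    ParameterRange,
    Perspective,
    load_aga_reference,
    one_way,
    threshold_price,
    two_way,
)

model = load_aga_reference()
WTP = 50_000.0

# one-way: PRP improved-state utility from 0.85 (baseline) to 1.0
sweep = one_way(
    model, ParameterRange("prp/utility_improved", 0.85, 1.0, 31), WTP, Perspective.HEALTHCARE
)
print(sweep.round(0).to_string(index=False))
switch = sweep[sweep["preferred"] == "prp"]["prp/utility_improved"]
if not switch.empty:
    print(
        f"\nPRP monotherapy becomes the preferred strategy once its improved-state "
        f"utility exceeds ~{switch.min():.3f} (base case: 0.89)."
    )

# threshold: at what injection price does PRP match minoxidil's NMB?
price = threshold_price(
    model,
    "prp/cost_schedule.injection_unit_cost",
    strategy="prp",
    comparator="minoxidil",
    wtp=WTP,
    bracket=(0.0, 1000.0),
    perspective=Perspective.HEALTHCARE,
)
print(
    f"\nBreak-even PRP injection price vs minoxidil at ${WTP:,.0f}/QALY: "
    f"${price:,.2f} (base case: $717.67). Below this price, PRP monotherapy "
    f"has the higher net monetary benefit."
)

# two-way: utility vs injection price
grid = two_way(
    model,
    ParameterRange("prp/utility_improved", 0.85, 1.0, 7),
    ParameterRange("prp/cost_schedule.injection_unit_cost", 0.0, 1000.0, 7),
    WTP,
    Perspective.HEALTHCARE,
)
print("\nPreferred strategy over (utility x injection price):")
print(grid.to_frame().pivot(index=grid.y_path, columns=grid.x_path, values="preferred"))
print(
    "\nReading: rows are injection prices, columns improved-state utilities; each "
    "cell names the strategy with the highest NMB. PRP wins in the cheap/high-"
    "utility corner."
)
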