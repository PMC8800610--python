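"""Base-case incremental cost-effectiveness analysis.

Runs the bundled androgenetic-alopecia model (minoxidil monotherapy,
minoxidil+PRP, PRP monotherapy; six-month cycles over 35 years from age
25, 3% discounting) and prints the incremental analysis from both costing
perspectives.
"""

from markov_cea import Perspective, evaluate_model, load_aga_reference

model = load_aga_reference()

for perspective in (Perspective.HEALTHCARE, Perspective.SOCIETAL):
    result = evaluate_model(model, wtp_list=(50_000.0, 100_000.0), perspective=perspective)
    print(f"\n=== {perspective.value} perspective ===")
    with_fmt = result.to_frame().round(
        {"cost": 0, "incremental_cost": 0, "qaly": 3, "incremental_qaly": 3,
         "ce_ratio": 0, "icer": 0, "nmb_at_50000": 0, "nmb_at_100000": 0}
    )
    print(with_fmt.to_string(index=False))
    print("efficiency frontier:", " -> ".join(result.frontier))
    for wtp, winner in result.preferred.items():
        print(f"highest NMB at ${wtp:,.0f}/QALY: {winner}")

print(
    "\nReading: each strategy's lifetime discounted cost ($) and QALYs; the ICER is "
    "the extra cost per extra QALY vs the previous frontier strategy. A strategy "
    "flagged 'extended' is dominated: the next frontier option buys QALYs more "
    "efficiently. The strategy with the highest net monetary benefit "
    "(NMB = WTP x QALY - cost) is the most cost-effective at that threshold."
)
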