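"""Probabilistic sensitivity analysis and acceptability curves.

Samples the uncertain inputs (beta for response probabilities and
utilities, gamma for costs; method-of-moments from mean and SD), re-runs
the cohort model per draw, and summarizes the resulting uncertainty.
A modest iteration count keeps this example quick; production analyses
use 10,000.
"""

from markov_cea import (
    Perspective,
    default_distribution_specs,
    load_aga_reference,
    run_psa,
)
from markov_cea.plotting import plot_ceac, plot_psa_scatter

model = load_aga_reference()
specs = default_distribution_specs(model)
print("sampled parameters:")
for s in specs:
    print(f"  {s.path}: {s.family.value}(mean={s.mean:g}, sd={s.sd:g})")

result = run_psa(
    model,
    specs,
    n_iterations=2000,
    seed=42,
    wtp_grid=(25_000.0, 50_000.0, 100_000.0, 200_000.0),
    perspective=Perspective.HEALTHCARE,
)

print("\nper-strategy Monte Carlo summary (healthcare perspective):")
print(result.summary().round(3).to_string())

acc = result.acceptability()
print("\nacceptability (fraction of iterations with the highest NMB):")
print(acc.round(3).to_string())

plot_psa_scatter(result, "psa_scatter.png")
plot_ceac(acc, "ceac.png")
print(
    "\nWrote psa_scatter.png and ceac.png. Reading: the scatter shows each "
    "iteration's (QALY, cost) per strategy; the acceptability table/curve gives, "
    "at each willingness-to-pay, how often each strategy is the most "
    "cost-effective across parameter draws."
)
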