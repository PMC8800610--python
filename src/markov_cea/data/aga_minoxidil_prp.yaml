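# Worked configuration: long-term treatment of non-severe androgenetic
# alopecia (Hamilton-Norwood I-V) in men, comparing topical minoxidil 5%
# monotherapy, minoxidil combined with platelet-rich plasma (PRP)
# injections, and PRP monotherapy.  All costs in 2020 USD; six-month
# cycles over a 35-year horizon starting at age 25; 3% annual discounting.
#
# PRP arms receive a three-injection induction series in the first cycle
# (visits at 0, 4 and 8 weeks) and one maintenance injection per later
# on-treatment cycle; the societal perspective charges one lost half-day
# wage per clinic visit.  The combined arm's initial-visit cost is set to
# the standard new-patient visit of $150 (the published table's $15 entry
# is treated as a typo; override here if desired).
name: aga_minoxidil_prp
settings:
  cycle_length_years: 0.5
  horizon_years: 35.0
  discount_rate_annual: 0.03
  start_age_years: 25.0
  perspective: healthcare
  half_cycle_correction: false
  nochange_first_cycle_mode: continue_50
life_table:
  type: gompertz_makeham
  makeham_a: 5.0e-4
  gompertz_b: 3.0e-5
  gompertz_c: 0.085
  age_start: 25
  age_end: 74
strategies:
  - name: minoxidil
    p_improve_first: 0.51
    p_continue_improved_first: 0.91
    p_continue_improved_subsequent: 0.98
    p_continue_nochange: 0.50
    p_offtx_nochange_alt: 0.29
    utility_improved: 0.89
    utility_baseline: 0.85
    cost_schedule:
      initial_visit_cost: 150.0
      drug_cost_per_cycle: 96.60
      injection_unit_cost: 0.0
      injections_first_cycle: 0
      injections_subsequent_cycle: 0
      halfday_wage_loss: 166.55
      visits_first_cycle_societal: 1
      visits_subsequent_cycle_societal: 0
  - name: minoxidil_prp
    p_improve_first: 0.55
    p_continue_improved_first: 0.99
    p_continue_improved_subsequent: 0.98
    p_continue_nochange: 0.50
    p_offtx_nochange_alt: 0.22
    utility_improved: 0.92
    utility_baseline: 0.85
    cost_schedule:
      initial_visit_cost: 150.0
      drug_cost_per_cycle: 96.60
      injection_unit_cost: 717.67
      injections_first_cycle: 3
      injections_subsequent_cycle: 1
      halfday_wage_loss: 166.55
      visits_first_cycle_societal: 3
      visits_subsequent_cycle_societal: 1
  - name: prp
    p_improve_first: 0.53
    p_continue_improved_first: 0.97
    p_continue_improved_subsequent: 0.98
    p_continue_nochange: 0.50
    p_offtx_nochange_alt: 0.20
    utility_improved: 0.89
    utility_baseline: 0.85
    cost_schedule:
      initial_visit_cost: 150.0
      drug_cost_per_cycle: 0.0
      injection_unit_cost: 717.67
      injections_first_cycle: 3
      injections_subsequent_cycle: 1
      halfday_wage_loss: 166.55
      visits_first_cycle_societal: 3
      visits_subsequent_cycle_societal: 1
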