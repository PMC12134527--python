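# Packaged simulation scenarios: exponential survival, 7-month control
# median, subgroup prevalence 0.7 unless overridden.  hr_F is the marginal
# hazard-ratio target for the full population; hr_S the hazard ratio inside
# the subgroup.  The complement hazard ratio is derived at load time (see
# seamsel.simulate.hr_complement).  acceptable_selections lists the interim
# decisions considered correct for the scenario (first entry = preferred);
# target_populations are the populations whose rejection counts toward
# overall power.
scenarios:
  - id: 1
    hr_F: 1.0
    hr_S: 1.0
    acceptable_selections: [futility]
    target_populations: []
  - id: 2
    hr_F: 0.76
    hr_S: 0.7
    acceptable_selections: ["F&S", "S", "F"]
    target_populations: ["F", "S"]
  - id: 3
    hr_F: 0.7
    hr_S: 0.7
    acceptable_selections: ["F", "S", "F&S"]
    target_populations: ["F", "S"]
  - id: 4
    hr_F: 1.05
    hr_S: 0.7
    acceptable_selections: ["S", "F&S"]
    target_populations: ["S"]
  - id: 5
    hr_F: 0.75
    hr_S: 1.0
    acceptable_selections: ["F", "F&S"]
    target_populations: ["F"]
control_median: 7.0
t_ref: 12.0
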