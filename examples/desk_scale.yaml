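# Desk-scale study conditions: full program structure at 5% census with a
# genome whose chromosome count is scaled alongside the population (the
# per-chromosome causal/marker architecture keeps the full-scale values).
program:
  burnin_years: 10
  eval_years: 10
genome:
  n_chromosomes: 2
  bp_per_chromosome: 1.0e+8
  n_causal_per_chromosome: 1000
  n_marker_per_chromosome: 2000
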