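# Full-pipeline configuration: simulate a cohort, segment episodes,
# summarise burden and fit the association models in one run.
seed: 1
out_dir: results/example_run
missing_rule: free          # "free" or "pause" handling of missing diary days
window:
  start_day: 0
  end_day: 729
  completeness_threshold: 0.98
simulate:
  n_children: 288
  mean_episodes: 13.7
  missing_rate: 0.01
# To analyse real data instead of simulating, replace the `simulate`
# block with:
# inputs:
#   diary: path/to/diary.csv
#   covariates: path/to/covariates.csv
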