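# Example config for `commsync eta --config` / `commsync wavelet --config`.
# Either `input_path` (long-format counts: year,month,species,count) or a
# `simulation` block must be given, never both.
simulation:
  n_species_per_guild: 5
  n_months: 300
n_surrogates: 1000
alpha: 0.10
cut_year: 2006
seasons: [warm, cold]
seed: 2026
output_dir: results
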