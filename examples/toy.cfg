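[run]
out_dir = dmnfc_out
seed = 7
bands = slow-5,slow-4,slow-3
verbosity = INFO

[cohort]
n_group_a = 8
n_group_b = 8
n_volumes = 160
tr_seconds = 2.0
n_movers = 1

[preprocess]
n_discard = 4
filter_mode = butterworth
fd_threshold_mm = 0.5

[nbs]
t_threshold = 3.2
n_permutations = 500
tail = both

[association]
mmse_column = MMSE
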