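# Synthetic end-to-end pipeline fixture: simulate a decade of surveillance
# data, detect the threshold, fit the distributed-lag model, attribute the
# burden and project the four SSP scenarios.
n_years: 10
bin_width: 1.0
grid_step: 0.5
lag_max: 7
df_var: 5
df_lag: 4
df_doy: 4
df_time: 3
n_sim: 200
seed: 20260927
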