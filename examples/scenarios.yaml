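# End-of-century mean-temperature increases for Taiwan under the four
# shared socioeconomic pathways (delta in °C with 95% interval).
scenarios:
  - name: SSP1-2.6
    delta_mean: 1.4
    delta_ci: [0.9, 1.9]
    period: 2090-2099
  - name: SSP2-4.5
    delta_mean: 2.5
    delta_ci: [2.1, 3.0]
    period: 2090-2099
  - name: SSP3-7.0
    delta_mean: 4.3
    delta_ci: [3.8, 4.8]
    period: 2090-2099
  - name: SSP5-8.5
    delta_mean: 5.8
    delta_ci: [5.3, 6.3]
    period: 2090-2099
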