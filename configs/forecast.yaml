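# Input forecasting: Lorenz-driven three-channel profile, dt = 120 s.
kind: forecast
seed: 1
duration_min: 90
train_min: 30
dt_s: 120
out_dir: chemres_out/forecast
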