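# Lagged mutual information on a Lorenz-driven record.
kind: mi
seed: 1
forecast: {duration_min: 60}
n_trace_channels: 16
out_dir: chemres_out/mi
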