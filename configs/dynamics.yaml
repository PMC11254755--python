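# Metabolic emulation: 90-min Gaussian DHA drive, 30-min training window.
kind: dynamics
seed: 1
duration_min: 90
train_min: 30
out_dir: chemres_out/dynamics
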