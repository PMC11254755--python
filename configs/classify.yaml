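# Static classification demo: simulated reservoir, XOR + linear tasks,
# full 20 x 26 leave-five-out protocol on 132 inputs.
kind: classify
seed: 1
tasks: [xor, linear]
n_points: 132
repeats: 20
splits: 26
out_dir: chemres_out/classify
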