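# 1/12-scale smoke profile: completes in a couple of minutes on one CPU.
n_subjects: 2000
target_events: 56
panel: default
n_replicates: 20
k_folds: 10
thresholds: [0.01, 0.015, 0.02, 0.025, 0.03, 0.05, 0.10]
n_bootstrap: 50
seed: 0
out_dir: mammorisk_smoke_run
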