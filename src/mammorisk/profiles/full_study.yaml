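# Full-scale reference profile: screening cohort of 24,161 women,
# 680 incident cases, 1,000 genotype replicates, 10-fold CV.
# Expect a long run at this scale.
n_subjects: 24161
target_events: 680
panel: default
n_replicates: 1000
k_folds: 10
thresholds: [0.01, 0.015, 0.02, 0.025, 0.03, 0.05, 0.10]
n_bootstrap: 200
seed: 0
out_dir: mammorisk_full_run
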