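# Full synthetic study at the default dimensions:
# 10 patients + 10 controls, 52 ROIs, 227 true directed connections,
# three 90 s tracking runs per subject. Runs in about half a minute.
out_dir: runs/full_study
seed: 7
stages: [simulate, track, network, predict]

# cohort / networks
n_subjects_pd: 10
n_subjects_control: 10
n_rois: 52
n_connections: 227
n_true_edges: 9
roi_timepoints: 270
tr: 1.985

# tracking trials
runs_per_subject: 3
noise_levels: [0.0, 25.0, 50.0]
tracking_noise_sd: 0.1

# inference
fdr_level: 0.05
max_cond_size: 3
n_folds: 10
lasso_rule: min
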