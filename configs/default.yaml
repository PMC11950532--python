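# Default phantom experiment: 32^3 grid, 24 regions (6 disease),
# 300 subjects across the five cohort roles, two modality channels.
grid_shape: [32, 32, 32]
n_regions: 24
n_disease_regions: 6
n_channels: 2
disease_extra_years: 40.0
subject_sd: 0.05
region_sd: 0.03
voxel_sd: 0.05
age_min: 18.0
age_max: 88.0

n_pretrain: 60
n_train: 100
n_select: 20
n_correct: 40
n_clinical: 80
clinical_patient_fraction: 0.5

encoder_widths: [8, 16, 32]
latent_dim: 64
head_widths: [32]
cae_epochs: 12
cae_selection_window: 8
reg_epochs: 40
reg_selection_window: 30
batch_size: 16
cae_learning_rate: 0.001
reg_learning_rate: 0.01
cae_val_fraction: 0.1

saliency_n_samples: 25
calib_n_samples: 8
calib_max_subjects: 20

alpha: 0.05
brainage_covariates: [age, sex]
roi_covariates: [age]

seed: 0
write_volumes: true
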