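# Trabecular CTRL cohort preset: group means/SDs of the constitutive
# parameters, donor structure, noise level and donor/tissue metadata.
# k_D is calibrated so the mean specimen's end-of-record damage matches
# the group's reported D_end under the default trabecular protocol.
tissue: trabecular
group: CTRL
param_means:
  E_pr: 4.8e9
  E_mx: 3.3e9
  sigma_y: 29.0e6
  sigma_u: 89.0e6
  p: 39.0
  eta: 8.5e9
  k_D: 26.4
param_sds:
  E_pr: 2.3e9
  E_mx: 2.64e9
  sigma_y: 15.0e6
  sigma_u: 35.0e6
  p: 29.0
  eta: 4.8e9
  k_D: 12.3
n_donors: 10
specimens_per_donor: 8.9
donor_effect_frac: 0.5
noise_sd: 3.2e6
bmd_mean: 0.973
bmd_sd: 0.326
tmd_mean: 962.0
tmd_sd: 36.0
tmd_stiffness_rho: 0.6
age_mean: 69.5
age_sd: 9.2
female_frac: 0.5
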