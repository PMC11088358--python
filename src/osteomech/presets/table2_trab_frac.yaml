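tissue: trabecular
group: FRAC
param_means:
  E_pr: 4.7e9
  E_mx: 3.2e9
  sigma_y: 33.0e6
  sigma_u: 97.0e6
  p: 41.0
  eta: 8.3e9
  k_D: 25.7
param_sds:
  E_pr: 2.3e9
  E_mx: 2.64e9
  sigma_y: 13.0e6
  sigma_u: 33.0e6
  p: 31.0
  eta: 5.3e9
  k_D: 13.4
n_donors: 10
specimens_per_donor: 8.9
donor_effect_frac: 0.5
noise_sd: 3.2e6
bmd_mean: 0.581
bmd_sd: 0.092
tmd_mean: 964.0
tmd_sd: 35.0
tmd_stiffness_rho: 0.6
age_mean: 74.6
age_sd: 11.0
female_frac: 0.5
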