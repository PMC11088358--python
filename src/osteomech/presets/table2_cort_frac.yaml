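tissue: cortical
group: FRAC
param_means:
  E_pr: 10.9e9
  E_mx: 8.5e9
  sigma_y: 46.0e6
  sigma_u: 61.0e6
  p: 153.0
  eta: 17.0e9
  k_D: 62.2
param_sds:
  E_pr: 3.6e9
  E_mx: 8.9e9
  sigma_y: 9.0e6
  sigma_u: 18.0e6
  p: 102.0
  eta: 9.9e9
  k_D: 20.9
n_donors: 17
specimens_per_donor: 4.1
donor_effect_frac: 0.5
noise_sd: 4.2e6
bmd_mean: 0.655
bmd_sd: 0.091
tmd_mean: 1037.0
tmd_sd: 26.0
tmd_stiffness_rho: 0.6
age_mean: 80.0
age_sd: 9.7
female_frac: 0.71
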