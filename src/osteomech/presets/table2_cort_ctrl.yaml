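tissue: cortical
group: CTRL
param_means:
  E_pr: 13.1e9
  E_mx: 7.6e9
  sigma_y: 50.0e6
  sigma_u: 65.0e6
  p: 188.0
  eta: 15.6e9
  k_D: 82.3
param_sds:
  E_pr: 4.0e9
  E_mx: 6.11e9
  sigma_y: 10.0e6
  sigma_u: 18.0e6
  p: 113.0
  eta: 10.7e9
  k_D: 26.1
n_donors: 15
specimens_per_donor: 4.7
donor_effect_frac: 0.5
noise_sd: 4.2e6
bmd_mean: 1.019
bmd_sd: 0.291
tmd_mean: 1045.0
tmd_sd: 23.0
tmd_stiffness_rho: 0.6
age_mean: 68.1
age_sd: 10.2
female_frac: 0.6
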