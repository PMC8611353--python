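# Cell-line constants for the three classical Folkman-Hochberg spheroid
# assays, plus the prior settings derived from them.
#
# prior_alpha: mean doubling time converted to a rate under the
#   assumption that cells inside a colony divide ~2.4x slower than in
#   suspension; these are the authoritative config constants.
# prior_sigma_k: six cell diameters (the thickness of the proliferating
#   outer rim), in mm.
# profile_inflation_c, profile_exponent_q: shape of the mollified-ball
#   initial density, chosen so its 0.95-quantile radius is close to the
#   initial colony radius.
# reference_map: reference MAP calibration of the non-local growth
#   model against the measured growth curves (natural units: 1/day, mm).
# schedule: synthetic measurement template (days) spanning the
#   quasi-linear growth window of each line.
version: 1
sigma_o_prior: {median: 0.1, log_sd: 5.0}
log_sd_default: 1.0
cell_lines:
  L-5178Y:
    doubling_time_h: 11.3
    cell_diameter_um: 10.0
    initial_radius_mm: 0.264
    prior_alpha: 1.4
    prior_sigma_k: 0.06
    profile_inflation_c: 1.065
    profile_exponent_q: 13.0
    schedule: {start: 0.0, stop: 30.0, step: 2.0}
    reference_map: {alpha: 1.7264, sigma_k: 0.0806, sigma_o: 0.0957, sigma_i: 0.2469}
  V-79:
    doubling_time_h: 16.0
    cell_diameter_um: 10.0
    initial_radius_mm: 0.403
    prior_alpha: 1.04
    prior_sigma_k: 0.06
    profile_inflation_c: 1.065
    profile_exponent_q: 13.0
    schedule: {start: 0.0, stop: 38.0, step: 2.0}
    reference_map: {alpha: 0.3603, sigma_k: 0.0479, sigma_o: 0.0649, sigma_i: 0.3744}
  B-16:
    doubling_time_h: 18.0
    cell_diameter_um: 15.4
    initial_radius_mm: 0.733
    prior_alpha: 0.9
    prior_sigma_k: 0.09
    profile_inflation_c: 1.06
    profile_exponent_q: 13.0
    schedule: {start: 0.0, stop: 48.0, step: 2.0}
    reference_map: {alpha: 0.3616, sigma_k: 0.0342, sigma_o: 0.0256, sigma_i: 0.7518}
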