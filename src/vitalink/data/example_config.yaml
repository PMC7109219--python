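# Annotated example pipeline configuration.
#
# Omitted keys fall back to the calibrated defaults: birthweight /
# gestational-age bin proportions and per-bin mortality probabilities from
# the Ontario 2010-2011 linked-file structure, an age-at-death mixture over
# <24 h / 1-6 d / 7-27 d / 28-364 d, and corruption rates calibrated so
# ~3.6% of registered deaths have no reference birth record.
seed: 0

cohort:
  # total live births over the three birth years (the two-year
  # death-registration window then holds about two thirds of them)
  n_births: 42139          # 10% of the full-scale cohort
  years: [2009, 2011]      # birth reference window
  death_years: [2010, 2011]  # death-registration window
  stillbirth_fraction: 0.006
  rural_fraction: 0.14
  seed: 0

corruption:
  p_identifier_missing_on_death: 0.15  # forces the probabilistic pass
  p_postal_typo: 0.05
  p_dob_shift: 0.02                    # +/- 1 day, equal probability
  p_sex_missing: 0.01
  p_out_of_hospital: 0.02              # birth has no hospital abstract
  subthreshold_rule: true              # drop <500 g AND <20 wk births
  p_stillbirth_misclass: 0.01          # borderline-viability flag flips
  p_late_termination: 0.005

linkage:
  blocking_scheme: dob1        # dob1 | dob_year_fsa | none
  upper_posterior: 0.9         # link when posterior match prob >= 0.9
  lower_posterior: 0.1         # non-link below 0.1; between = "possible"
  em_tol: 1.0e-6
  em_max_iter: 200

alpha: 0.05          # CI level
suppress_at: 5       # suppress cells with numerator <= 5
ci_method: midp      # midp | clopper-pearson
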