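# Age-dependent system (physiology) parameters.
#
# These published, documented equations stand in for a commercial simulator's
# proprietary population models; results approximate, rather than equal, that
# machinery.  Constants are deliberately explicit so every choice is visible
# and overridable.
#
# body weight : sex-averaged reference-median growth table (WHO/CDC style),
#               linearly interpolated, anchored at 3.5 kg (birth), 70 kg (adult)
# BSA         : Livingston-Lee, BSA = 0.1173 * BW^0.6466 (m^2)
# liver       : BSA allometry in the spirit of Johnson 2005,
#               liver weight (g) = 780 * BSA^1.176
# Q_h         : adult 90 L/h scaled by (BW/70)^0.75 (cardiac-output allometry)
# MPPGL       : Barter 2008 cubic-in-age log10 polynomial (~26 mg/g birth,
#               ~39-40 mg/g adult)
# CPPGL       : constant 90 mg/g (reported range ~45-135; no accepted
#               ontogeny; value set with the IVIVE calibration, see docs)
# GFR         : fraction of adult = (BSA/BSA_adult) * PMA^3.4/(PMA^3.4+47.7^3.4)
#               (Rhodin 2009 maturation, PMA = 40 wk + postnatal age)
# enzyme ontogeny (non-SULT): exponential maturation
#               rel(age) = birth_fraction + (1-birth_fraction)*(1-exp(-age/tau)),
#               parameters chosen from published maturation patterns (UGT1A9
#               slowest, UGT1A1 fast postnatally, CYP2E1/CYP3A4 low at birth)
#               and calibrated so the default configuration reproduces the
#               neonatal/child pathway-contribution pattern of the APAP model.
adult_reference_age: 20.0
adult_body_weight_kg: 70.0
adult_hepatic_blood_flow_l_per_h: 90.0
flow_allometric_exponent: 0.75
fu_plasma_ontogeny: false     # optional albumin-based fu correction, off by default

body_weight_table:
  age_years:  [0.0, 0.0833, 0.25, 0.5, 1.0, 2.0, 3.0, 5.0, 7.0, 10.0, 12.0, 15.0, 18.0, 20.0]
  weight_kg:  [3.5, 4.4,    6.0,  7.5, 9.5, 12.2, 14.3, 18.0, 23.0, 32.0, 40.0, 55.0, 66.0, 70.0]

bsa: {coefficient: 0.1173, exponent: 0.6466}
liver: {bsa_coefficient: 780.0, bsa_exponent: 1.176}
mppgl_log10_poly: {a0: 1.407, a1: 0.0158, a2: -0.00038, a3: 0.0000024}
cppgl_mg_per_g: 90.0
gfr_maturation: {hill: 3.4, pma50_weeks: 47.7, gestation_weeks: 40.0}

enzyme_ontogeny:
  UGT1A1:  {birth_fraction: 0.15, tau_years: 0.25}
  UGT1A9:  {birth_fraction: 0.08, tau_years: 2.0}
  UGT2B15: {birth_fraction: 0.35, tau_years: 1.0}
  CYP1A2:  {birth_fraction: 0.05, tau_years: 1.5}
  CYP2C9:  {birth_fraction: 0.30, tau_years: 1.0}
  CYP2C19: {birth_fraction: 0.30, tau_years: 1.0}
  CYP2D6:  {birth_fraction: 0.20, tau_years: 1.0}
  CYP2E1:  {birth_fraction: 0.02, tau_years: 0.5}
  CYP3A4:  {birth_fraction: 0.20, tau_years: 0.3}
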