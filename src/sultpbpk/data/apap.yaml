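# Acetaminophen (APAP) compound profile for the minimal PBPK model.
# Vmax in pmol/min/mg of the pathway's protein pool (microsomal for CYP/UGT,
# cytosolic for SULT); Km in uM.  Absorption/dissolution entries are carried
# as metadata only: all simulations are intravenous.
name: acetaminophen
molecular_weight: 151.2     # g/mol
logp: 0.51
pka: 9.46
fu_plasma: 0.82
blood_plasma_ratio: 1.0
vss_l_per_kg: 0.8
kp_scalar: 1.63             # metadata; unused with a user-input Vss
cl_iv_reference: 19.7       # L/h, adult systemic clearance reference
cl_renal_adult: 1.12        # L/h
active_hepatic_scalar: 1.5
absorption:                 # metadata only (ADAM parameters; IV simulations)
  model: ADAM
  peff: 12.0
  ka: 5.24
  fa: 0.99
  solubility_mg_per_ml: 13.65
  solubility_ph: 8.94
kinetics:
  UGT1A1:  {vmax: 6654.0,  km: 5500.0,  pool: microsomal}
  UGT1A9:  {vmax: 11130.0, km: 9200.0,  pool: microsomal}
  UGT2B15: {vmax: 37101.0, km: 23000.0, pool: microsomal}
  SULT1A1: {vmax: 1549.0,  km: 2400.0,  pool: cytosolic}
  SULT1A3: {vmax: 231.0,   km: 1500.0,  pool: cytosolic}
  SULT1E1: {vmax: 167.2,   km: 1900.0,  pool: cytosolic}
  SULT2A1: {vmax: 814.1,   km: 3700.0,  pool: cytosolic}
  CYP1A2:  {vmax: 34.5,    km: 220.0,   pool: microsomal}
  CYP2C9:  {vmax: 9.86,    km: 660.0,   pool: microsomal}
  CYP2C19: {vmax: 29.87,   km: 2000.0,  pool: microsomal}
  CYP2D6:  {vmax: 6.57,    km: 440.0,   pool: microsomal}
  CYP2E1:  {vmax: 90.06,   km: 4020.0,  pool: microsomal}
  CYP3A4:  {vmax: 62.13,   km: 130.0,   pool: microsomal}
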