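# Default population-PK parameters for the two drugs amenable to
# concentration-based adherence assessment on daily dosing.
#
# These defaults were transcribed/representative values for adults with
# TB-HIV co-infection: one-compartment disposition, transit-compartment
# absorption, allometric scaling of disposition parameters to fat-free
# mass (clearance-type exponent 0.75, volume exponent 1.0, reference
# fat-free mass 42 kg for pyrazinamide and 40 kg for rifampicin).
# They imply a pyrazinamide elimination half-life of ~6.1 h at the
# reference size and a fully induced rifampicin half-life of ~2.3 h in
# the low-concentration (first-order) regime, consistent with the
# published clinical pharmacology of both drugs.  Edit and pass via
# --config / load_drug_models() to use a different parameterisation.
#
# Units: clearance L/h; vmax mg/h (pre-induction); km mg/L; volume L;
# mtt h; ka 1/h; bsv entries are log-normal variances (omega^2).

pyrazinamide:
  elimination: first-order
  clearance: 3.4
  volume: 30.0
  mtt: 0.5
  n_transit: 5
  ka: 3.0
  bioavailability: 1.0
  induction_fold: 1.0
  reference_ffm: 42.0
  bsv:
    clearance: 0.045
    bioavailability: 0.04
    ka: 0.3
    mtt: 0.1

rifampicin:
  elimination: michaelis-menten
  vmax: 60.0            # pre-induction; fully induced capacity = vmax * induction_fold
  km: 8.0
  volume: 50.0
  mtt: 0.7
  n_transit: 7
  ka: 1.2
  bioavailability: 1.0
  induction_fold: 2.0   # clearance doubles once autoinduction is complete (~2 weeks)
  reference_ffm: 40.0
  bsv:
    vmax: 0.05
    bioavailability: 0.04
    ka: 0.4
    mtt: 0.2
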