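# Default generating rate constants for the S. cerevisiae Tsa1/Tsa2 system
# (pH 7.4, 25 C).  Second-order constants in M^-1 s^-1, first-order in s^-1.
# kobs_intercept is the observable y-axis intercept of k_obs,1 vs [Trx1];
# the microscopic reverse rate k_rev is calibrated from it by the generator
# (see prxkit.synth.reverse_rate_for_intercept).
tsa2_oxidation:
  k1ox: 1.3e+7
  k2ox: 45.0
  k3ox: 3.6
tsa1_oxidation:
  k1ox: 1.3e+8     # tenfold faster sulfenylation than Tsa2
  k2ox: 45.0
  k3ox: 3.6
tsa2_reduction:
  k1red: 3.9e+6
  kobs_intercept: 10.8
  k2red: 10.0
tsa1_reduction:
  k1red: 3.0e+6    # slightly below the Tsa2 value; not independently reported
  kobs_intercept: 8.7
  k2red: 10.0
  k3red: 0.6      # slow third phase, Trx1-induced decamer dissociation
hetero_oxidation:
  k1oxA: 6.1e+7
  k1oxB: 2.8e+7
  k2ox: 45.0
  k3ox: 3.6
premixed_oxidation:
  k1oxA: 9.8e+7
  k1oxB: 1.2e+7
  k2ox: 45.0
  k3ox: 3.6
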