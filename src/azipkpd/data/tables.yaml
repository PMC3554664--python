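# Published one-compartment PK parameters and cascade turnover/driver
# parameters for the mouse LPS-challenge / azithromycin study conditions.
# Transit rates (ktr) and the linear transduction slopes are not published;
# ktr defaults to the variable's kout and slopes default to 0 (uncoupled)
# until calibrated against the disease-progression landmarks.
azi_pk:
  normal:        {ka: 0.78, ke: 0.040, v_over_f: 42.1}
  lps_challenged: {ka: 0.85, ke: 0.042, v_over_f: 28.5}
lps_pk:
  normal:      {ka: 1.51, ke: 0.082, v_over_f: 16.3}
  azi_treated: {ka: 1.63, ke: 0.088, v_over_f: 15.5}
lps_unit:
  eu_per_ng: 3.4
cascade:
  pc:  {baseline: 49.8,  kout: 0.234, ktr: 0.234}
  kyn: {baseline: 104.3, kout: 0.167, ktr: 0.167}
  fst: {baseline: 51.3,  kout: 0.253, ktr: 0.253}
  tst: {baseline: 108.2, kout: 0.143, ktr: 0.143}
  lps_stim:  {emax_like: 27.5, c50: 103.5}
  azi_inhib: {emax_like: 0.83, c50: 6.3}
  pc_to_kyn:  {slope: 0.0}
  kyn_to_fst: {slope: 0.0}
  kyn_to_tst: {slope: 0.0}
  inhibition_scope: stimulated_only
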