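{
 "seq_type": "triplet",
 "feature_names": [
  "one_minus_cwa",
  "one_minus_dcwa",
  "prematurity",
  "compensatory_ratio",
  "amp_ratio",
  "slew_ratio",
  "width_ratio"
 ],
 "means": [
  1.4403263635632495,
  0.7643360036556093,
  0.666511767179738,
  1.1533761100280537,
  1.2378674697844059,
  1.021151211318653,
  2.5393374741200825
 ],
 "scales": [
  0.48845234059548,
  0.28282390348754394,
  0.14609447947662157,
  0.7598951198280448,
  0.27884724343865785,
  0.20295071422364983,
  0.49845016112932694
 ],
 "weights": [
  1.0812779828751276,
  2.17264242261825,
  -0.280989249026516,
  -0.0076951668007486825,
  0.07908805915888392,
  1.4785816083187586,
  0.8531854218960402
 ],
 "intercept": 2.51795305527075,
 "decision_threshold": 0.5,
 "seed": 2026,
 "data_hash": "7b26edbe71f45fd8"
}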