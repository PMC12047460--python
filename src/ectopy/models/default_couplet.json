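{
 "seq_type": "couplet",
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
  1.3082314161039654,
  0.7062282990908335,
  0.7514764137291321,
  1.3501969504241764,
  1.418867060400733,
  0.9761630051092335,
  2.3954285714285697
 ],
 "scales": [
  0.6313260553263332,
  0.34947691537896447,
  0.20796577802569852,
  0.7653380606744772,
  0.6621750112771522,
  0.16096270747317473,
  0.6336511626426379
 ],
 "weights": [
  1.2201817676351796,
  3.074144495093734,
  -0.07514553325051872,
  0.012621362432395887,
  0.8997360490311209,
  0.8069127091528305,
  0.7021692805395282
 ],
 "intercept": 1.8384722975035044,
 "decision_threshold": 0.5,
 "seed": 2026,
 "data_hash": "c7b399a31e8ae8f5"
}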