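{
 "seq_type": "single",
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
  1.2587822599393934,
  0.6640486552976776,
  0.7507657415506799,
  2.075258651121915,
  2.0374385862838036,
  0.9643159287075749,
  2.320825515947464
 ],
 "scales": [
  0.6632106196053552,
  0.3710664793024708,
  0.09503299287298507,
  0.42968261059313484,
  0.8637039540463698,
  0.1758877386909641,
  0.6596587257132479
 ],
 "weights": [
  0.8191193561965642,
  2.20355686929901,
  -0.8295524715649358,
  -0.05880401316110806,
  2.656765371347822,
  0.6156076333256975,
  0.7008856319372855
 ],
 "intercept": 2.4673233489490753,
 "decision_threshold": 0.5,
 "seed": 2026,
 "data_hash": "d51a1ab857f2af85"
}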