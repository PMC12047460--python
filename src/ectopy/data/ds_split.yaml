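# Canonical inter-patient division of the 44 non-paced MIT-BIH Arrhythmia
# Database records into training (DS1) and testing (DS2) halves.
lead: MLII
excluded_symbols: [F]
ds1: ["101", "106", "108", "109", "112", "114", "115", "116", "118", "119",
      "122", "124", "201", "203", "205", "207", "208", "209", "215", "220",
      "223", "230"]
ds2: ["100", "103", "105", "111", "113", "117", "121", "123", "200", "202",
      "210", "212", "213", "214", "219", "221", "222", "228", "231", "232",
      "233", "234"]
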