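{
  "description": "Severity confusion tables (rows = predicted class No/Mild/Moderate/Severe, columns = true PSG class) and paired-comparison p-value families from a published 245-subject HSAT validation study. Used to exercise the evaluation statistics on real printed counts.",
  "n_subjects": 245,
  "confusion": {
    "rei": [[16, 0, 0, 0], [10, 38, 20, 0], [4, 7, 38, 26], [0, 0, 6, 80]],
    "ahi_cress": [[22, 4, 0, 0], [8, 34, 13, 0], [0, 7, 42, 15], [0, 0, 9, 91]],
    "ahi_cress_autar": [[20, 2, 0, 0], [10, 35, 9, 0], [0, 7, 43, 7], [0, 1, 12, 99]]
  },
  "pvalue_families": {
    "ahi_cress": ["0.705", "<0.001", "0.041", "0.074", "<0.001", "0.182",
                  "0.035", "0.110", "0.247", "0.168", "0.068", "0.013",
                  "0.147", "0.013", "0.296", "0.394", "0.028", "0.067",
                  "0.019", "0.022", "0.624", "0.014"],
    "ahi_cress_autar": ["0.705", "<0.001", "0.199", "0.205", "<0.001", "0.299",
                        "0.006", "0.007", "0.422", "0.245", "0.010", "<0.001",
                        "0.022", "<0.001", "0.015", "0.035", "0.001", "0.003",
                        "<0.001", "<0.001", "0.596", "<0.001"]
  }
}
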