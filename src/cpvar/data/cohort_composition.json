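{
  "n_cohort": 150,
  "trios": 18,
  "duos": 76,
  "duos_maternal": 62,
  "duos_paternal": 13,
  "singletons": 56,
  "male": 93,
  "female": 57,
  "comorbidity_data_available": 137,
  "trio_diagnosed": 7
}
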