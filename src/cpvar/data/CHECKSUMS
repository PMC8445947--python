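ec58d469ec5864b241ce43cd99be9643efb88501aee7a097b5f57a1dedfb0d4e  reported_variants.tsv
a8d815f621b805affa4c6a08d8e8a94332cc57ef262c756c664afa0bba9d9132  reported_genes.tsv
a5eeef14d0fb869bf5e0e51eca2ab2fbd728b4e7446cce19c115d0f24d45e06a  cohort_composition.json
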