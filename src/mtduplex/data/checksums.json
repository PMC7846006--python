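{
 "mini_haplotree.json": "a460dc19402f0675461fc74d0defcfcaf367a95a2c39dbc2b8bd0800a521a535",
 "mt_reference.fasta": "974e57126173a9f091283a7c97f5162665928e25e83766aded863225fc283611",
 "table2_total_snps.tsv": "e660e2e511a1ca92d4d8c96f10487e971ebc5997a62f8f27e376924980ba04a2",
 "table3_homoplasmy.tsv": "31552bc199557d94b1854c7164b1720443111fadfca2b6207f3cc99aa240ced5",
 "table5_heteroplasmy.tsv": "9845b381aa2da44ed3acc6e9f133c76e2ee420289d7daa7727786504222bedd5",
 "table7_annotations.tsv": "5fd3b77315066b75e7aab760f36b45bc86a2147a2b4b138cf27e6190fad24c3c",
 "table8_cohort.tsv": "07dd6f2c4cdba46b469c5a99363ee8a04201cac51b94dd77e9b09487fd96ac51"
}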