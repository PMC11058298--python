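{
 "oder_spree.yaml": "278569d8d8b75d32303c5d80cdcd01d91550114d4f44b77d93539a07041ee007",
 "diepholz.yaml": "3384af230cb23e45ae54b0b000cd5eecd6d18d1571042fcd46d08fbadeac5e01",
 "measures.yaml": "f287a105da34d286e9d7bf8bc3cbe0d64db1b6e52c3131f98957edd913827a44",
 "table_stage_impacts.csv": "1ce9f7d71fec640c74d695da35bf05b95b0d18b886d5e785afdde34c3a6c1dba",
 "table_gas_contributions.csv": "833e1c3858a89d2f46ee3801a4b90e750a97ab2d71439bc8e068cc3a53159ff5",
 "table_forage_acidification.csv": "459dcd8c275ee670e3f8348840e932a101be4faad9b41f483d0cef8ce41ad115"
}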