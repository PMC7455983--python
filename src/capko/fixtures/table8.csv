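manufacturer,product_no,kimchi_pct
CJ,1,9.83
CJ,2,21.14
DW,1,22.31
DW,2,32.18
HT,1,25.0
HT,2,13.9
PMW,1,39.53
PMW,2,24.23
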