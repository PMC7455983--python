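manufacturer,rpp_pct,chili_sauce_pct
DW,4.7,25.5
OTG,6.2,16.3
SZ,5.0,28.0
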