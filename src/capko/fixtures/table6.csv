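product,label_rpp_pct,paste_share
red pepper paste,11.3,1.0
red pepper paste with vinegar,11.3,0.80
red pepper paste with soybean paste,11.3,0.25
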