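item,product_no,rpp_pct
salted pollock roe,1,2.5
salted pollock roe,2,2.0
salted pollock roe,3,2.5
salted pollock roe,4,2.5
salted pollock roe,5,4.3
salted pollock roe,6,4.0
salted pollock roe,7,4.3
salted oyster,1,5.0
salted oyster,2,4.0
salted oyster,3,6.5
salted oyster,4,4.0
salted oyster,5,7.0
salted oyster,6,5.0
salted squid,1,6.0
salted squid,2,5.4
salted squid,3,4.0
salted squid,4,4.0
salted octopus,1,6.0
salted octopus,2,5.0
salted fish gut,1,6.2
salted fish gut,2,3.0
salted fish gut,3,4.0
salted fish gut,4,5.0
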