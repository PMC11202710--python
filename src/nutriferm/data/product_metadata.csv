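product_id,protein_pct
ST,14.5
RT,20.2
SH,18.0
RH,20.0
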