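item_code,flour_fraction
bread,0.70
buns_scones,0.65
mandasi,0.50
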