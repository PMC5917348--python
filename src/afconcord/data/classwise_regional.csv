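region_class,region,count
ECGI+/Sim+,lpv,7
ECGI+/Sim+,pla,4
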