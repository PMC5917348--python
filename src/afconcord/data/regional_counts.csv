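modality,la,ra,iag
ecgi,33,5,4
sim,17,9,2
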