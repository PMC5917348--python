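cell,count
ecgi_pos_sim_pos,19
ecgi_pos_sim_neg,23
ecgi_neg_sim_pos,9
ecgi_neg_sim_neg,33
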