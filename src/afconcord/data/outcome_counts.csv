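region_class,n_targets,positive_response,terminated
ECGI+/Sim+,23,13,7
ECGI+/Sim-,22,9,4
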