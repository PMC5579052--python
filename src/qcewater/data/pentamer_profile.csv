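label,E_hartree,G0_hartree,kind
W5c,-382.357737,-382.272495,minimum
W5p,-382.352160,-382.264707,minimum
W5x_ts,-382.323069,-382.234254,transition_state
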