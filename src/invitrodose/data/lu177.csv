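nuclide,half_life_s,parent,branching_ratio
Lu-177,574300.8,,
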