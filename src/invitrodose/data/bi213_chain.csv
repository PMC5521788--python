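nuclide,half_life_s,parent,branching_ratio
Bi-213,2735.4,,
Po-213,4.2e-6,Bi-213,0.9784
Tl-209,129.6,Bi-213,0.0216
Pb-209,11710.8,Po-213,1.0
Pb-209,11710.8,Tl-209,1.0
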