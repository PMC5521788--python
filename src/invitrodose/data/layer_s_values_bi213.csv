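nuclide,radiation_class,phi,s_mGy_per_MBq_s
Bi-213,alpha,0.0100,0.0082
Bi-213,beta,0.0056,0.0159
Bi-213,auger_ic,0.0061,0.0008
Bi-213,gamma,0.0003,0.0001
Po-213,alpha,0.0082,0.4570
Tl-209,beta,0.0050,0.0218
Tl-209,auger_ic,0.0072,0.0015
Tl-209,gamma,0.0001,0.0010
Pb-209,beta,0.0064,0.0084
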