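nuclide,s_self,s_surface,s_cross_50um,s_cross_100um
Bi-213,1.71,1.14,7.02e-3,3.03e-4
Po-213,49.2,33.0,0.40,OOR
Tl-209,0.73,0.44,1.31e-3,3.15e-4
Pb-209,0.34,0.22,1.61e-3,3.46e-4
Lu-177,0.67,0.42,2.00e-3,4.18e-4
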