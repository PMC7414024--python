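cell_type,protein,copies_per_cell,provenance
mouse_platelet,Gaq,27744.695081594433,native
mouse_platelet,smG,3483.0074441099623,native
mouse_platelet,PLCb,6162.529558059554,native
mouse_platelet,IP3E,2823.2001229205252,native
mouse_platelet,DGK,1993.647919160035,native
mouse_platelet,LPP,1122.260516754381,native
mouse_platelet,CDIPT,728.4430111883997,native
mouse_platelet,OCRL1,445.2526659113336,native
mouse_platelet,PI4K,648.8157258331798,native
mouse_platelet,PIP5K,6584.005571790591,native
mouse_platelet,SAC1,839.6343614992264,native
mouse_platelet,cPLA2,2095.8838182607096,native
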