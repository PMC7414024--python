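cell_type,protein,copies_per_cell,provenance
human_platelet,Gaq,40000.0,native
human_platelet,smG,50000.0,native
human_platelet,PLCb,20000.0,native
human_platelet,IP3E,15000.0,native
human_platelet,DGK,10000.0,native
human_platelet,LPP,5000.0,native
human_platelet,CDIPT,8000.0,native
human_platelet,OCRL1,2000.0,native
human_platelet,PI4K,4000.0,native
human_platelet,PIP5K,5000.0,native
human_platelet,SAC1,3000.0,native
human_platelet,cPLA2,10000.0,native
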