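cell_type,protein,copies_per_cell,provenance
u2os,smG,1990456.269574067,native
u2os,PLCb,473787.9310270893,native
u2os,DGK,103334.93708984823,native
u2os,LPP,30326.172714623845,native
u2os,CDIPT,184407.25030776698,native
u2os,PIP5K,22532.87101525875,native
u2os,SAC1,152726.11534733104,native
u2os,Gaq,270712.8759763781,scanned
u2os,IP3E,160894.12284244932,scanned
u2os,OCRL1,34000.000000000015,scanned
u2os,PI4K,68000.00000000004,scanned
u2os,cPLA2,269431.8427183895,scanned
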