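cell_type,protein,copies_per_cell,provenance
hela,Gaq,680669.5328236541,native
hela,smG,1079477.9023605853,native
hela,PLCb,273044.6495618377,native
hela,IP3E,125059.5562895898,native
hela,DGK,118162.61971774233,native
hela,LPP,38449.050932733604,native
hela,CDIPT,142703.6022688304,native
hela,OCRL1,99338.4514386172,native
hela,PI4K,45866.84341438652,native
hela,PIP5K,51742.07791373323,native
hela,SAC1,75467.28664384615,native
hela,cPLA2,226174.77555908315,native
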