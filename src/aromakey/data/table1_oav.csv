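compound,odor_notes,YJ-Yingde,HY-Yingde,Luokeng,Renhua,Meizhou,Heyuan,Lianshan,Chaozhou
linalool,"floral, lavender",42.48,19.50,6.32,5.31,6.00,6.05,7.56,4.07
geraniol,"rose, geranium",9.84,69.55,71.83,109.15,131.36,68.48,150.63,42.13
benzeneacetaldehyde,"honey, floral, rose, sweet",13.06,4.50,7.97,3.73,2.51,4.51,1.76,2.03
methyl salicylate,peppermint,2.35,3.87,1.72,4.22,2.07,1.25,1.09,1.03
p-cresol,"medicine, phenol, smoke",2.69,1.93,2.18,2.85,2.16,2.82,2.03,5.49
phenylethyl alcohol,"honey, spice, rose, lilac",2.57,2.66,4.19,1.69,2.89,10.13,1.18,2.39
3-methyl-butanoic acid,"sour, cheesy, disagreeable",<1,<1,<1,<1,2.68,2.13,2.88,4.07
benzaldehyde,"almond, burnt sugar",<1,<1,1.18,<1,<1,<1,<1,<1
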