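ciprofloxacin	second	C1CC1N2C=C(C(=O)C3=CC(=C(C=C32)N4CCNCC4)F)C(=O)O
enoxacin	second	CCN1C=C(C(=O)C2=CC(=C(N=C21)N3CCNCC3)F)C(=O)O
fleroxacin	second	CN1CCN(CC1)C2=C(C=C3C(=C2F)N(C=C(C3=O)C(=O)O)CCF)F
lomefloxacin	second	CCN1C=C(C(=O)C2=CC(=C(C(=C21)F)N3CCNC(C3)C)F)C(=O)O
norfloxacin	second	CCN1C=C(C(=O)C2=CC(=C(C=C21)N3CCNCC3)F)C(=O)O
ofloxacin	second	CC1COC2=C3N1C=C(C(=O)C3=CC(=C2N4CCN(CC4)C)F)C(=O)O
pefloxacin	second	CCN1C=C(C(=O)C2=CC(=C(C=C21)N3CCN(CC3)C)F)C(=O)O
rufloxacin	second	CN1CCN(CC1)C2=C(C=C3C4=C2SCCN4C=C(C3=O)C(=O)O)F
levofloxacin	third	C[C@H]1COC2=C3N1C=C(C(=O)C3=CC(=C2N4CCN(CC4)C)F)C(=O)O
sparfloxacin	third	CC1CN(CC(N1)C)C2=C(C(=C3C(=C2F)N(C=C(C3=O)C(=O)O)C4CC4)N)F
tosufloxacin	third	C1CN(CC1N)C2=C(C=C3C(=O)C(=CN(C3=N2)C4=C(C=C(C=C4)F)F)C(=O)O)F
gatifloxacin	fourth	CC1CNCCN1C2=C(C=C3C(=C2OC)N(C=C(C3=O)C(=O)O)C4CC4)F
moxifloxacin	fourth	COC1=C(C(=CC2=C1N(C=C(C2=O)C(=O)O)C3CC3)F)N4C[C@@H]5CCCN[C@@H]5C4
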