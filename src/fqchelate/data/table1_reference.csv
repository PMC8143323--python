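name,generation,mw,tpsa,logp
ciprofloxacin,second,331.13,74.57,1.58
enoxacin,second,320.13,87.46,0.66
fleroxacin,second,369.13,65.78,1.70
lomefloxacin,second,351.14,74.57,1.80
norfloxacin,second,319.13,74.57,1.27
ofloxacin,second,361.14,75.01,1.54
pefloxacin,second,333.15,65.78,1.61
rufloxacin,second,363.11,91.08,1.70
levofloxacin,third,361.14,75.01,1.54
sparfloxacin,third,392.17,100.59,2.08
tosufloxacin,third,404.11,101.45,2.04
gatifloxacin,fourth,375.16,83.80,1.98
moxifloxacin,fourth,401.18,83.80,2.37
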