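fq,metal,metal_source,pct_cmax,pct_auc,pct_ka,reference_tag
ciprofloxacin,Aluminum,Aluminum hydroxide,-81.1,-84.6,-14.3,72
ciprofloxacin,Aluminum,Aluminum hydroxide,-84.6,-87.5,-60.6,71
ciprofloxacin,Aluminum,Sucralfate,-90.0,-87.5,,10
ciprofloxacin,Aluminum/Magnesium,Maalox,-80.1,-84.9,157.9,9
ciprofloxacin,Aluminum/Magnesium,Didanosine,-92.6,-98.3,49.2,11
ciprofloxacin,Calcium,Titralac,-37.9,-41.1,5.9,12
enoxacin,Aluminum,Aluminum hydroxide,-78.3,-84.2,,71
enoxacin,Aluminum/Magnesium,Maalox,-70.0,-73.2,-52.1,15
fleroxacin,Aluminum,Aluminum hydroxide,-25.0,-17.2,-47.6,71
fleroxacin,Aluminum,Sucralfate,-26.4,-24.0,-40.3,24
lomefloxacin,Aluminum,Aluminum hydroxide,-54.5,-34.8,-55.1,71
lomefloxacin,Aluminum,Kolantyl,-46.1,-40.8,25.6,16
norfloxacin,Aluminum,Aluminum hydroxide,-93.3,-97.0,,71
norfloxacin,Aluminum,Sucralfate,-92.2,-91.3,-23.8,20
norfloxacin,Aluminum/Magnesium,Maalox,-95.1,,-6.1,21
norfloxacin,Calcium,Titralac,-65.9,-62.6,-80.2,21
ofloxacin,Aluminum,Aluminum hydroxide,-59.4,-47.9,-65.0,71
ofloxacin,Aluminum,Sucralfate,-69.5,-61.0,-46.2,20
pefloxacin,Aluminum/Magnesium,Maalox,-60.8,-54.3,-57.5,17
rufloxacin,Aluminum/Magnesium,Maalox,6.1,-15.2,-34.0,18
levofloxacin,Aluminum,Aluminum hydroxide,-66.7,-45.2,-55.5,71
sparfloxacin,Aluminum,Aluminum hydroxide,-22.2,-35.1,47.1,71
tosufloxacin,Aluminum,Aluminum hydroxide,-66.7,-70.8,-67.4,71
gatifloxacin,Aluminum/Magnesium,Maalox,-68.4,-60.8,-13.5,73
moxifloxacin,Aluminum,Sucralfate,-79.5,-59.9,-80.7,74
moxifloxacin,Calcium,Calcium-Sandoz,-15.5,-2.4,-74.1,75
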