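{
 "comment": "synthetic hartree-level energy ledger: values constructed so the displacement-reaction bookkeeping reproduces the reference Gibbs binding energies (-16.1/-5.3/+0.9 kcal/mol for Al/Mg/Ca); not DFT output",
 "temperature_K": 310,
 "species": [
  {
   "label": "water",
   "role": "water",
   "charge": 0,
   "formula": "H2O",
   "e_pcm_sp": -76.33,
   "g_thermal_corr": 0.0025
  },
  {
   "label": "ciprofloxacin_cation",
   "role": "fq_cation",
   "charge": 1,
   "formula": "C17H19FN3O3",
   "e_pcm_sp": -1010.5,
   "g_thermal_corr": 0.28
  },
  {
   "label": "al_hexahydrate",
   "role": "metal_hexahydrate",
   "charge": 3,
   "formula": "AlH12O6",
   "e_pcm_sp": -700.8,
   "g_thermal_corr": 0.11
  },
  {
   "label": "cipro_al_chelate",
   "role": "chelate_complex",
   "charge": 4,
   "formula": "C17H27AlFN3O7",
   "e_pcm_sp": -1558.685258279,
   "g_thermal_corr": 0.404601297
  },
  {
   "label": "mg_hexahydrate",
   "role": "metal_hexahydrate",
   "charge": 2,
   "formula": "MgH12O6",
   "e_pcm_sp": -658.2,
   "g_thermal_corr": 0.105
  },
  {
   "label": "cipro_mg_chelate",
   "role": "chelate_complex",
   "charge": 3,
   "formula": "C17H27MgFN3O7",
   "e_pcm_sp": -1516.060238737,
   "g_thermal_corr": 0.39179265
  },
  {
   "label": "ca_hexahydrate",
   "role": "metal_hexahydrate",
   "charge": 2,
   "formula": "CaH12O6",
   "e_pcm_sp": -1135.4,
   "g_thermal_corr": 0.1
  },
  {
   "label": "cipro_ca_chelate",
   "role": "chelate_complex",
   "charge": 3,
   "formula": "C17H27CaFN3O7",
   "e_pcm_sp": -1993.245099524,
   "g_thermal_corr": 0.381533766
  }
 ],
 "reactions": [
  {
   "label": "ciprofloxacin+Al",
   "complex": "cipro_al_chelate",
   "fq": "ciprofloxacin_cation",
   "metal_hexahydrate": "al_hexahydrate",
   "water": "water",
   "displaced_waters": 2
  },
  {
   "label": "ciprofloxacin+Mg",
   "complex": "cipro_mg_chelate",
   "fq": "ciprofloxacin_cation",
   "metal_hexahydrate": "mg_hexahydrate",
   "water": "water",
   "displaced_waters": 2
  },
  {
   "label": "ciprofloxacin+Ca",
   "complex": "cipro_ca_chelate",
   "fq": "ciprofloxacin_cation",
   "metal_hexahydrate": "ca_hexahydrate",
   "water": "water",
   "displaced_waters": 2
  }
 ]
}
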