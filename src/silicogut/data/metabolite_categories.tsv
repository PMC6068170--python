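metabolite_id	category
fiber_e	plant_polysaccharide
glc_e	sugar
ac_e	other
ppa_e	other
but_e	other
ibut_e	other
lac_e	other
waste_e	other
pectin	plant_polysaccharide
larch_arabinogalactan	plant_polysaccharide
amylose	plant_polysaccharide
lavanbiose	sugar
mucin_o_glycan	mucus_glycan
core2_mucin_glycan	mucus_glycan
heparan_sulfate_fragment	glycosaminoglycan
hyaluronan_fragment	glycosaminoglycan
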