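Onychiurus_orientalis	euedaphic
Orthonychiurus_folsomi	euedaphic
Gomphiocephalus_hodgsoni	hemiedaphic
Tullbergia_bisetosa	euedaphic
Anurida_maritima	hemiedaphic
Podura_aquatica	aquatic
Bilobella_aurantiaca	hemiedaphic
Friesea_grisea	hemiedaphic
Neanura_barbata	hemiedaphic
Oncopodura_yosiiana	hemiedaphic
Folsomia_candida	hemiedaphic
Cryptopygus_antarcticus	hemiedaphic
Cryptopygus_terranovus	hemiedaphic
Parisotoma_notabilis	hemiedaphic
Isotomurus_palustris	hemiedaphic
Tomocerus_ocreatus	hemiedaphic
Pogonognathellus_flavescens	hemiedaphic
Cyphoderus_albinus	myrmecophilous
Lepidocyrtus_fimetarius	hemiedaphic
Salina_celebensis	epiedaphic
Coecobrya_sp	hemiedaphic
Sinella_curviseta	hemiedaphic
Entomobrya_proxima	hemiedaphic
Homidia_fascia	hemiedaphic
Seira_dowlingi	hemiedaphic
Orchesella_villosa	hemiedaphic
Neelus_murinus	hemiedaphic
Megalothorax_incertus	hemiedaphic
Sminthurus_viridis	epiedaphic
Bourletiella_arvalis	epiedaphic
Allacma_fusca	epiedaphic
Dicyrtomina_minuta	epiedaphic
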