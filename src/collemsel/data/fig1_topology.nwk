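(Daphnia_pulex:510,((Japyx_solifugus:380,Trigoniophthalmus_alternatus:380):105,((((Onychiurus_orientalis:192,Orthonychiurus_folsomi:192):108,Gomphiocephalus_hodgsoni:300):50,((Tullbergia_bisetosa:287,Anurida_maritima:287):33,((Podura_aquatica:225,Bilobella_aurantiaca:225):55,(Friesea_grisea:180,Neanura_barbata:180):100):40):30):60,((Oncopodura_yosiiana:330,(((Folsomia_candida:120,(Cryptopygus_antarcticus:60,Cryptopygus_terranovus:60):60):130,(Parisotoma_notabilis:150,Isotomurus_palustris:150):100):50,((Tomocerus_ocreatus:190,Pogonognathellus_flavescens:190):90,(((Cyphoderus_albinus:170,Lepidocyrtus_fimetarius:170):30,(Salina_celebensis:115,Coecobrya_sp:115):85):60,((Sinella_curviseta:160,(Entomobrya_proxima:90,Homidia_fascia:90):70):60,(Seira_dowlingi:130,Orchesella_villosa:130):90):40):20):20):30):40,((Neelus_murinus:150,Megalothorax_incertus:150):190,((Sminthurus_viridis:110,Bourletiella_arvalis:110):180,(Allacma_fusca:140,Dicyrtomina_minuta:140):150):50):30):40):75):25);
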