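species	Algeria	Brazil	Cambodia	CentralAfricanRepublic	China	Colombia	DRCongo	France	Israel	Italy	Japan	Kenya	Mexico	Namibia	Nigeria	Pakistan	PapuaNewGuinea	Russia	Senegal	SouthAfrica	UnitedStates
Ascaris lumbricoides	0	0	1	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0
Trichuris trichiura	0	1	1	1	0	0	1	0	1	R	0	1	1	0	0	1	1	0	0	0	0
Necator americanus	0	0	0	R	0	0	0	R	0	0	0	R	R	R	1	1	1	0	0	0	0
Ancylostoma duodenale	1	1	1	1	1	1	0	0	1	1	1	0	1	0	1	0	0	0	0	1	0
Strongyloides stercoralis	0	0	1	0	0	1	1	0	0	0	0	0	0	0	0	1	0	0	0	R	0
Enterobius vermicularis	0	R	0	0	R	R	R	0	R	R	0	0	R	0	R	R	0	R	R	R	0
Trichinella spiralis	1	0	1	1	0	0	1	0	0	1	1	0	0	0	1	0	0	0	1	0	0
Toxocara canis	0	0	0	0	0	0	0	0	0	1	0	1	0	0	0	0	0	0	0	0	0
Toxocara cati	R	R	R	0	0	0	R	0	0	0	0	R	0	0	0	R	R	0	R	R	0
Anisakis simplex	0	0	0	R	1	1	R	0	0	0	0	1	0	0	0	0	0	1	R	0	0
Angiostrongylus cantonensis	0	R	R	R	0	1	R	0	0	0	1	1	0	1	0	R	1	0	R	0	0
Angiostrongylus costaricensis	0	0	0	1	0	0	0	0	0	0	0	0	1	1	0	0	1	0	0	1	0
Capillaria philippinensis	0	R	R	0	0	R	R	0	0	0	R	0	0	R	R	R	R	0	R	0	0
Capillaria hepatica	0	1	0	R	0	0	1	0	0	R	0	R	1	1	1	1	0	0	1	0	0
Gnathostoma spinigerum	0	R	R	R	R	0	R	0	0	0	0	R	R	R	R	R	R	0	R	0	R
Dracunculus medinensis	0	0	0	R	0	0	0	0	0	0	0	0	R	0	0	0	0	0	R	0	0
Wuchereria bancrofti	0	0	0	1	1	R	R	0	1	0	0	R	R	0	0	0	0	0	0	R	1
Brugia malayi	0	0	0	1	0	0	1	0	0	R	1	1	1	0	0	1	0	1	1	0	0
Brugia timori	0	0	1	0	0	0	1	0	0	0	0	0	0	1	1	0	0	0	1	0	0
Onchocerca volvulus	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	1	0	0
Loa loa	0	0	R	0	0	0	1	0	0	1	0	0	0	0	0	0	0	0	1	R	0
Mansonella perstans	0	1	1	1	0	R	0	0	0	0	0	R	0	0	0	0	0	1	0	0	0
Mansonella ozzardi	1	0	0	1	1	1	R	1	0	0	0	1	1	0	0	1	0	0	0	0	0
Mansonella streptocerca	0	1	1	0	1	0	0	0	0	0	0	R	0	0	0	0	0	0	1	0	0
Dirofilaria immitis	R	0	R	1	1	0	R	1	0	0	0	1	1	0	1	R	1	0	0	0	0
Dirofilaria repens	1	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Ternidens deminutus	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	1	0	1	0	0
Oesophagostomum bifurcum	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0
Trichostrongylus colubriformis	0	1	0	R	0	1	1	0	0	0	R	1	0	1	0	0	0	0	R	0	0
Ascaris suum	0	R	0	0	0	0	R	0	0	0	R	R	0	R	0	R	R	0	0	0	0
Baylisascaris procyonis	0	R	0	0	R	0	0	0	0	0	0	R	0	R	R	R	R	0	0	R	0
Schistosoma mansoni	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	1	0	0
Schistosoma haematobium	0	1	0	1	0	0	1	1	0	0	0	1	0	0	0	0	0	0	0	0	0
Schistosoma japonicum	0	0	1	0	0	1	0	0	0	0	1	1	0	0	0	1	0	0	1	0	0
Schistosoma intercalatum	0	1	1	0	0	R	0	0	0	0	0	0	R	0	0	0	1	0	0	1	0
Schistosoma mekongi	0	1	1	0	0	0	0	0	0	0	0	1	0	0	0	R	0	0	R	1	0
Clonorchis sinensis	R	1	0	1	R	R	0	1	0	0	1	0	R	0	1	0	0	0	1	1	1
Opisthorchis viverrini	1	1	1	0	1	1	1	0	0	0	0	0	0	1	0	0	0	0	0	1	0
Opisthorchis felineus	R	R	R	0	R	R	0	0	R	0	0	R	R	0	R	R	0	0	R	R	R
Fasciola hepatica	0	0	0	0	0	0	0	0	1	R	1	1	0	R	0	0	R	0	0	0	0
Fasciola gigantica	0	0	1	0	1	0	0	0	0	0	0	0	0	0	0	0	1	0	0	1	0
Fasciolopsis buski	0	1	0	0	R	0	0	0	0	0	0	1	0	0	1	0	0	0	0	0	0
Paragonimus westermani	0	1	0	1	0	0	0	0	0	0	0	0	1	0	0	0	1	0	0	0	0
Paragonimus mexicanus	0	0	0	0	0	R	R	0	0	0	R	R	0	0	0	0	0	0	R	0	0
Paragonimus africanus	0	0	0	1	1	0	0	0	0	0	0	0	0	1	1	0	1	0	0	0	0
Paragonimus kellicotti	0	0	1	0	1	0	0	0	0	0	0	1	1	1	1	0	1	0	0	R	0
Heterophyes heterophyes	0	0	0	0	R	0	0	0	0	R	1	0	1	1	0	0	1	0	1	0	0
Metagonimus yokogawai	0	0	0	0	0	1	0	0	R	1	0	1	0	1	0	0	0	1	1	0	0
Echinostoma ilocanum	0	0	0	1	1	0	R	0	0	0	0	0	0	0	1	1	0	1	R	0	0
Dicrocoelium dendriticum	0	0	R	R	0	R	R	0	R	R	R	R	0	R	0	0	R	0	R	0	0
Taenia solium	0	0	1	0	0	1	0	0	0	R	0	0	1	0	0	0	0	0	0	0	0
Taenia saginata	0	0	0	0	0	0	0	0	0	0	0	0	1	R	R	1	0	0	1	0	0
Taenia asiatica	0	R	R	0	0	R	0	R	0	0	0	0	0	0	0	R	0	0	0	R	R
Hymenolepis nana	0	0	0	1	0	0	0	1	0	0	R	R	0	R	0	R	0	0	0	0	0
Hymenolepis diminuta	1	0	R	R	0	0	1	R	0	0	0	0	1	1	1	R	0	0	R	0	0
Diphyllobothrium latum	0	0	0	0	0	0	0	0	0	0	0	R	0	R	0	0	0	0	0	0	0
Dipylidium caninum	0	1	0	1	0	0	0	0	0	0	0	0	1	0	1	1	1	0	0	1	0
Echinococcus granulosus	0	0	0	1	0	R	R	0	0	0	R	1	R	1	0	1	R	0	0	1	R
Echinococcus multilocularis	0	1	1	0	0	0	1	1	0	0	0	0	0	1	0	0	0	0	0	0	0
Spirometra mansonoides	0	0	0	0	0	R	R	R	0	R	R	R	0	R	0	0	0	0	0	0	0
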