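class	order	family	genera	species	percent
Oligohymenophorea	Pleuronematida	Pleuronematidae	1	1	0.50%
Oligohymenophorea	Pleuronematida	Cyclidiidae	2	10	5.03%
Oligohymenophorea	Sessilida	Scyphidiidae	1	1	0.50%
Oligohymenophorea	Sessilida	Operculariidae	1	2	1.01%
Oligohymenophorea	Sessilida	Epistylididae	1	3	1.51%
Oligohymenophorea	Sessilida	Vorticellidae	3	13	6.53%
Oligohymenophorea	Ophryoglenida	Ophryoglenidae	1	2	1.01%
Oligohymenophorea	Philasterida	Cohnilembidae	1	2	1.01%
Oligohymenophorea	Philasterida	Uronematidae	1	1	0.50%
Oligohymenophorea	Philasterida	Loxocephalidae	1	2	1.01%
Oligohymenophorea	Philasterida	Cinetochilidae	2	4	2.01%
Oligohymenophorea	Tetrahymenida	Glaucomidae	3	6	3.02%
Oligohymenophorea	Tetrahymenida	Tetrahymenidae	1	1	0.50%
Oligohymenophorea	Tetrahymenida	Turaniellidae	1	2	1.01%
Oligohymenophorea	Peniculida	Lembadionidae	1	1	0.50%
Oligohymenophorea	Peniculida	Frontoniidae	1	2	1.01%
Oligohymenophorea	Peniculida	Parameciidae	1	1	0.50%
Karyorelictea	Loxodida	Loxodidae	1	2	1.01%
Karyorelictea	Protostomatida	Trachelocercidea	1	1	0.50%
Nassophorea	Synhymeniida	Scaphidiodontidae	1	2	1.01%
Nassophorea	Nassulida	Nassulidae	1	3	1.51%
Nassophorea	Nassulida	Furgasoniidae	1	2	1.01%
Nassophorea	Microthoracida	Leptopharyngidae	1	2	1.01%
Litostomatea	Pleurostomatida	Amphileptidae	1	1	0.50%
Litostomatea	Pleurostomatida	Litonotidae	2	7	3.52%
Litostomatea	Haptorida	Spathidiidae	2	16	8.04%
Litostomatea	Haptorida	Trachelophyllidae	2	5	2.51%
Litostomatea	Haptorida	Actinobolinidae	1	1	0.50%
Litostomatea	Haptorida	Enchelyidae	2	2	1.01%
Litostomatea	Haptorida	Tracheliidae	3	7	3.52%
Litostomatea	Haptorida	Lacrymariidae	1	2	1.01%
Litostomatea	Haptorida	Didiniidae	1	1	0.50%
Litostomatea	Haptorida	Acropisthiidae	1	1	0.50%
Litostomatea	Entodiniomorphida	Ophryoscolecidae	1	2	1.01%
Litostomatea	Cyclotrichiida	Mesodiniidae	1	1	0.50%
Armophorea	Armophorida	Metopidae	1	2	1.01%
Prostomatea	Prorodontida	Colepidae	1	1	0.50%
Prostomatea	Prorodontida	Holophryidae	1	4	2.01%
Prostomatea	Prorodontida	Prorodontidae	2	5	2.51%
Prostomatea	Prorodontida	Urotrichidae	1	4	2.01%
Prostomatea	Prorodontida	Plagiocampidae	1	3	1.51%
Prostomatea	Prorodontida	Placidae	1	1	0.50%
Colpodea	Cyrtolophosidida	Cyrtolophosididae	1	4	2.01%
Colpodea	Cyrtolophosidida	Platyophryidae	1	2	1.01%
Colpodea	Colpodida	Colpodidae	2	6	3.02%
Colpodea	Colpodida	Grossglockneriidae	1	1	0.50%
Colpodea	Bryophryida	Bryophyidea	1	1	0.50%
Plagiopylea	Plagiopylida	Plagiopylidae	1	1	0.50%
Plagiopylea	Odontostomatida	Epalxellidae	1	1	0.50%
Spirotrichea	Strombidiida	Strombidiidae	1	1	0.50%
Spirotrichea	Stichotrichida	Spirofilidae	1	2	1.01%
Spirotrichea	Stichotrichida	Keronidae	1	1	0.50%
Spirotrichea	Sporadotrichida	Halteriidae	1	1	0.50%
Spirotrichea	Sporadotrichida	Trachelostylidae	1	1	0.50%
Spirotrichea	Sporadotrichida	Oxytrichidae	7	15	7.54%
Spirotrichea	Urostylida	Urostylidae	4	8	4.02%
Spirotrichea	Euplotida	Euplotidae	1	4	2.01%
Spirotrichea	Euplotida	Aspidiscidae	1	1	0.50%
Spirotrichea	Choreotrichida	Strobilidiidae	1	2	1.01%
Phyllopharyngea	Endogenida	Acinetidae	1	1	0.50%
Phyllopharyngea	Exogenida	Podophryidae	1	3	1.51%
Phyllopharyngea	Chlamydodontida	Chilodonellidae	1	6	3.02%
Heterotrichea	Heterotrichida	Blepharismidae	1	2	1.01%
Heterotrichea	Heterotrichida	Stentoridae	1	1	0.50%
Heterotrichea	Heterotrichida	Spirostomidae	1	1	0.50%
Heterotrichea	Heterotrichida	Condylostomatidae	1	1	0.50%
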