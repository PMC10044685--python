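species	genus	subfamily	family	order	infraclass	class
Heterodontus zebra	Heterodontus		Heterodontidae	Heterodontiformes	Selachii	Elasmobranchii
Chiloscyllium hasseltii	Chiloscyllium		Hemiscylliidae	Orectolobiformes	Selachii	Elasmobranchii
Chiloscyllium indicum	Chiloscyllium		Hemiscylliidae	Orectolobiformes	Selachii	Elasmobranchii
Chiloscyllium plagiosum	Chiloscyllium		Hemiscylliidae	Orectolobiformes	Selachii	Elasmobranchii
Chiloscyllium punctatum	Chiloscyllium		Hemiscylliidae	Orectolobiformes	Selachii	Elasmobranchii
Chiloscyllium griseum	Chiloscyllium		Hemiscylliidae	Orectolobiformes	Selachii	Elasmobranchii
Alopias pelagicus	Alopias		Alopiidae	Lamniformes	Selachii	Elasmobranchii
Alopias superciliosus	Alopias		Alopiidae	Lamniformes	Selachii	Elasmobranchii
Atelomycterus marmoratus	Atelomycterus		Scyliorhinidae	Carcharhiniformes	Selachii	Elasmobranchii
Cephaloscyllium sarawakense	Cephaloscyllium		Scyliorhinidae	Carcharhiniformes	Selachii	Elasmobranchii
Cephaloscyllium umbratile	Cephaloscyllium		Scyliorhinidae	Carcharhiniformes	Selachii	Elasmobranchii
Halaelurus buergeri	Halaelurus		Scyliorhinidae	Carcharhiniformes	Selachii	Elasmobranchii
Hemigaleus microstoma	Hemigaleus		Hemigaleidae	Carcharhiniformes	Selachii	Elasmobranchii
Hemipristis elongata	Hemipristis		Hemigaleidae	Carcharhiniformes	Selachii	Elasmobranchii
Carcharhinus amblyrhynchoides	Carcharhinus		Carcharhinidae	Carcharhiniformes	Selachii	Elasmobranchii
Carcharhinus amboinensis	Carcharhinus		Carcharhinidae	Carcharhiniformes	Selachii	Elasmobranchii
Carcharhinus brevipinna	Carcharhinus		Carcharhinidae	Carcharhiniformes	Selachii	Elasmobranchii
Carcharhinus leucas	Carcharhinus		Carcharhinidae	Carcharhiniformes	Selachii	Elasmobranchii
Carcharhinus limbatus	Carcharhinus		Carcharhinidae	Carcharhiniformes	Selachii	Elasmobranchii
Carcharhinus melanopterus	Carcharhinus		Carcharhinidae	Carcharhiniformes	Selachii	Elasmobranchii
Carcharhinus sealei	Carcharhinus		Carcharhinidae	Carcharhiniformes	Selachii	Elasmobranchii
Carcharhinus sorrah	Carcharhinus		Carcharhinidae	Carcharhiniformes	Selachii	Elasmobranchii
Lamiopsis tephrodes	Lamiopsis		Carcharhinidae	Carcharhiniformes	Selachii	Elasmobranchii
Loxodon macrorhinus	Loxodon		Carcharhinidae	Carcharhiniformes	Selachii	Elasmobranchii
Rhizoprionodon acutus	Rhizoprionodon		Carcharhinidae	Carcharhiniformes	Selachii	Elasmobranchii
Rhizoprionodon oligolinx	Rhizoprionodon		Carcharhinidae	Carcharhiniformes	Selachii	Elasmobranchii
Scoliodon macrorhynchos	Scoliodon		Carcharhinidae	Carcharhiniformes	Selachii	Elasmobranchii
Triaenodon obesus	Triaenodon		Carcharhinidae	Carcharhiniformes	Selachii	Elasmobranchii
Galeocerdo cuvier	Galeocerdo		Carcharhinidae	Carcharhiniformes	Selachii	Elasmobranchii
Sphyrna lewini	Sphyrna		Sphyrnidae	Carcharhiniformes	Selachii	Elasmobranchii
Squalus altipinnis	Squalus		Squalidae	Squaliformes	Selachii	Elasmobranchii
Squalus brevirostris	Squalus		Squalidae	Squaliformes	Selachii	Elasmobranchii
Squalus edmundsi	Squalus		Squalidae	Squaliformes	Selachii	Elasmobranchii
Squatina tergocellatoides	Squatina		Squatinidae	Squatiniformes	Selachii	Elasmobranchii
Narcine brevilabiata	Narcine		Narcinidae	Torpediniformes	Batoidea	Elasmobranchii
Narcine maculata	Narcine		Narcinidae	Torpediniformes	Batoidea	Elasmobranchii
Narcine oculifera	Narcine		Narcinidae	Torpediniformes	Batoidea	Elasmobranchii
Rhina ancylostomus	Rhina		Rhinidae	Rhinopristiformes	Batoidea	Elasmobranchii
Rhynchobatus australiae	Rhynchobatus		Rhinidae	Rhinopristiformes	Batoidea	Elasmobranchii
Rhinobatos borneensis	Rhinobatos		Rhinobatidae	Rhinopristiformes	Batoidea	Elasmobranchii
Rhinobatos formosensis	Rhinobatos		Rhinobatidae	Rhinopristiformes	Batoidea	Elasmobranchii
Rhinobatos jimbaranensis	Rhinobatos		Rhinobatidae	Rhinopristiformes	Batoidea	Elasmobranchii
Rhinobatos schlegelii	Rhinobatos		Rhinobatidae	Rhinopristiformes	Batoidea	Elasmobranchii
Okamejei boesemani	Okamejei		Rajidae	Rajiformes	Batoidea	Elasmobranchii
Okamejei cairae	Okamejei		Rajidae	Rajiformes	Batoidea	Elasmobranchii
Okamejei hollandi	Okamejei		Rajidae	Rajiformes	Batoidea	Elasmobranchii
Bathytoshia lata	Bathytoshia	Dasyatinae	Dasyatidae	Myliobatiformes	Batoidea	Elasmobranchii
Hemitrygon bennettii	Hemitrygon	Dasyatinae	Dasyatidae	Myliobatiformes	Batoidea	Elasmobranchii
Hemitrygon parvonigra	Hemitrygon	Dasyatinae	Dasyatidae	Myliobatiformes	Batoidea	Elasmobranchii
Taeniurops meyeni	Taeniurops	Dasyatinae	Dasyatidae	Myliobatiformes	Batoidea	Elasmobranchii
Telatrygon biasa	Telatrygon	Dasyatinae	Dasyatidae	Myliobatiformes	Batoidea	Elasmobranchii
Telatrygon zugei	Telatrygon	Dasyatinae	Dasyatidae	Myliobatiformes	Batoidea	Elasmobranchii
Neotrygon kuhlii	Neotrygon	Neotrygoninae	Dasyatidae	Myliobatiformes	Batoidea	Elasmobranchii
Neotrygon malaccensis	Neotrygon	Neotrygoninae	Dasyatidae	Myliobatiformes	Batoidea	Elasmobranchii
Neotrygon orientalis	Neotrygon	Neotrygoninae	Dasyatidae	Myliobatiformes	Batoidea	Elasmobranchii
Neotrygon varidens	Neotrygon	Neotrygoninae	Dasyatidae	Myliobatiformes	Batoidea	Elasmobranchii
Taeniura lymma	Taeniura	Neotrygoninae	Dasyatidae	Myliobatiformes	Batoidea	Elasmobranchii
Brevitrygon heterura	Brevitrygon	Urogymninae	Dasyatidae	Myliobatiformes	Batoidea	Elasmobranchii
Himantura chaophraya	Himantura	Urogymninae	Dasyatidae	Myliobatiformes	Batoidea	Elasmobranchii
Himantura gerrardi	Himantura	Urogymninae	Dasyatidae	Myliobatiformes	Batoidea	Elasmobranchii
Himantura leoparda	Himantura	Urogymninae	Dasyatidae	Myliobatiformes	Batoidea	Elasmobranchii
Himantura uarnak	Himantura	Urogymninae	Dasyatidae	Myliobatiformes	Batoidea	Elasmobranchii
Himantura undulata	Himantura	Urogymninae	Dasyatidae	Myliobatiformes	Batoidea	Elasmobranchii
Maculabatis gerrardi	Maculabatis	Urogymninae	Dasyatidae	Myliobatiformes	Batoidea	Elasmobranchii
Maculabatis macrura	Maculabatis	Urogymninae	Dasyatidae	Myliobatiformes	Batoidea	Elasmobranchii
Pateobatis uarnacoides	Pateobatis	Urogymninae	Dasyatidae	Myliobatiformes	Batoidea	Elasmobranchii
Urogymnus asperrimus	Urogymnus	Urogymninae	Dasyatidae	Myliobatiformes	Batoidea	Elasmobranchii
Urogymnus lobistoma	Urogymnus	Urogymninae	Dasyatidae	Myliobatiformes	Batoidea	Elasmobranchii
Pastinachus gracilicaudus	Pastinachus	Hypolophinae	Dasyatidae	Myliobatiformes	Batoidea	Elasmobranchii
Pastinachus solocirostris	Pastinachus	Hypolophinae	Dasyatidae	Myliobatiformes	Batoidea	Elasmobranchii
Gymnura poecilura	Gymnura		Gymnuridae	Myliobatiformes	Batoidea	Elasmobranchii
Gymnura zonura	Gymnura		Gymnuridae	Myliobatiformes	Batoidea	Elasmobranchii
Plesiobatis daviesi	Plesiobatis		Plesiobatidae	Myliobatiformes	Batoidea	Elasmobranchii
Urolophus aurantiacus	Urolophus		Urolophidae	Myliobatiformes	Batoidea	Elasmobranchii
Urolophus expansus	Urolophus		Urolophidae	Myliobatiformes	Batoidea	Elasmobranchii
Aetobatus ocellatus	Aetobatus		Myliobatidae	Myliobatiformes	Batoidea	Elasmobranchii
Aetomylaeus vespertilio	Aetomylaeus		Myliobatidae	Myliobatiformes	Batoidea	Elasmobranchii
Myliobatis hamlyni	Myliobatis		Myliobatidae	Myliobatiformes	Batoidea	Elasmobranchii
Myliobatis tobijei	Myliobatis		Myliobatidae	Myliobatiformes	Batoidea	Elasmobranchii
Rhinoptera jayakari	Rhinoptera		Rhinopteridae	Myliobatiformes	Batoidea	Elasmobranchii
Mobula kuhlii	Mobula		Mobulidae	Myliobatiformes	Batoidea	Elasmobranchii
Mobula thurstoni	Mobula		Mobulidae	Myliobatiformes	Batoidea	Elasmobranchii
Chimaera phantasma	Chimaera		Chimaeridae	Chimaeriformes		Holocephali
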