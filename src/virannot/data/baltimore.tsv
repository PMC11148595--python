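family	baltimore_group	nucleic_acid
Adenoviridae	I	dsDNA
Alloherpesviridae	I	dsDNA
Ackermannviridae	I	dsDNA
Ascoviridae	I	dsDNA
Asfarviridae	I	dsDNA
Autographiviridae	I	dsDNA
Baculoviridae	I	dsDNA
Corticoviridae	I	dsDNA
Demerecviridae	I	dsDNA
Drexlerviridae	I	dsDNA
Fuselloviridae	I	dsDNA
Herelleviridae	I	dsDNA
Herpesviridae	I	dsDNA
Iridoviridae	I	dsDNA
Marseilleviridae	I	dsDNA
Mimiviridae	I	dsDNA
Myoviridae	I	dsDNA
Nudiviridae	I	dsDNA
Pandoraviridae	I	dsDNA
Papillomaviridae	I	dsDNA
Phycodnaviridae	I	dsDNA
Pithoviridae	I	dsDNA
Podoviridae	I	dsDNA
Polyomaviridae	I	dsDNA
Poxviridae	I	dsDNA
Siphoviridae	I	dsDNA
Straboviridae	I	dsDNA
Tectiviridae	I	dsDNA
Anelloviridae	II	ssDNA
Bacilladnaviridae	II	ssDNA
Circoviridae	II	ssDNA
Geminiviridae	II	ssDNA
Genomoviridae	II	ssDNA
Inoviridae	II	ssDNA
Microviridae	II	ssDNA
Nanoviridae	II	ssDNA
Parvoviridae	II	ssDNA
Redondoviridae	II	ssDNA
Smacoviridae	II	ssDNA
Amalgaviridae	III	dsRNA
Birnaviridae	III	dsRNA
Chrysoviridae	III	dsRNA
Cystoviridae	III	dsRNA
Hypoviridae	III	dsRNA
Partitiviridae	III	dsRNA
Picobirnaviridae	III	dsRNA
Quadriviridae	III	dsRNA
Reoviridae	III	dsRNA
Sedoreoviridae	III	dsRNA
Spinareoviridae	III	dsRNA
Totiviridae	III	dsRNA
Alphaflexiviridae	IV	ssRNA(+)
Arteriviridae	IV	ssRNA(+)
Astroviridae	IV	ssRNA(+)
Betaflexiviridae	IV	ssRNA(+)
Bromoviridae	IV	ssRNA(+)
Caliciviridae	IV	ssRNA(+)
Closteroviridae	IV	ssRNA(+)
Coronaviridae	IV	ssRNA(+)
Dicistroviridae	IV	ssRNA(+)
Fiersviridae	IV	ssRNA(+)
Flaviviridae	IV	ssRNA(+)
Hepeviridae	IV	ssRNA(+)
Iflaviridae	IV	ssRNA(+)
Leviviridae	IV	ssRNA(+)
Luteoviridae	IV	ssRNA(+)
Marnaviridae	IV	ssRNA(+)
Matonaviridae	IV	ssRNA(+)
Nodaviridae	IV	ssRNA(+)
Picornaviridae	IV	ssRNA(+)
Potyviridae	IV	ssRNA(+)
Secoviridae	IV	ssRNA(+)
Solemoviridae	IV	ssRNA(+)
Togaviridae	IV	ssRNA(+)
Tombusviridae	IV	ssRNA(+)
Tymoviridae	IV	ssRNA(+)
Virgaviridae	IV	ssRNA(+)
Arenaviridae	V	ssRNA(-)
Bornaviridae	V	ssRNA(-)
Filoviridae	V	ssRNA(-)
Hantaviridae	V	ssRNA(-)
Nairoviridae	V	ssRNA(-)
Orthomyxoviridae	V	ssRNA(-)
Paramyxoviridae	V	ssRNA(-)
Peribunyaviridae	V	ssRNA(-)
Phasmaviridae	V	ssRNA(-)
Phenuiviridae	V	ssRNA(-)
Pneumoviridae	V	ssRNA(-)
Rhabdoviridae	V	ssRNA(-)
Belpaoviridae	VI	ssRNA-RT
Metaviridae	VI	ssRNA-RT
Pseudoviridae	VI	ssRNA-RT
Retroviridae	VI	ssRNA-RT
Caulimoviridae	VII	dsDNA-RT
Hepadnaviridae	VII	dsDNA-RT
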