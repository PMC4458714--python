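protein_description	biological_process	msl2kd_effect	rnase_effect
CG30122	Splicing	Decrease	Decrease
IGF-II mRNA-binding protein	Splicing		Decrease
No on or off transient A	Splicing		Decrease
polyA-binding protein	Splicing		Decrease
Srp54	Splicing		Decrease
SF2	Splicing		Decrease
Rm62	Splicing		
Quaking related 58E-1	Splicing		Decrease
Zinc-finger protein at 72D	Splicing	Decrease	Decrease
CG5641	Splicing		Decrease
CG9684	Splicing		Decrease
Lark	Splicing		Decrease
Rasputin	Splicing	Decrease	Decrease
CG11266	Splicing		Decrease
Lethal (3) 72Ab	Splicing		
Aly	Splicing		Decrease
CG7185	Alternative splicing		
Heterogeneous nuclear ribonucleoprotein at 87F	Alternative splicing	Decrease	Decrease
Heterogeneous nuclear ribonucleoprotein at 98DE	Alternative splicing		Decrease
Argonaute 2	RNAi		Decrease
CG8414	rRNA processing		
nop5	rRNA processing		Decrease
Fibrillarin	rRNA processing		Decrease
Sister-of-Sex-lethal	RNA binding		Decrease
CG1316	RNA binding		
CG13472	RNA binding		Decrease
Protein on ecdysone puffs	RNA binding		Decrease
Heterogeneous nuclear ribonucleoprotein at 27C	mRNA localization		Decrease
Glorund	mRNA localization	Decrease	Decrease
Belle	RNA helicase		Decrease
CG10777	RNA helicase	Increase	Decrease
CG5800	RNA helicase	Decrease	Decrease
CG7878	RNA helicase		
Upf1	mRNA-decay		Decrease
eIF-5A	Translation		
eIF3-S9	Translation		
Eukaryotic initiation factor 2beta	Translation		
Eukaryotic initiation factor 3 p66 subunit	Translation	Decrease	Decrease
Eukaryotic translation initiation factor 4G	Translation		
CG8636	Translation		
CG10990	Translation	Decrease	Decrease
CG6094	Translation		Decrease
Mi-2	Chromatin remodeling		
Nucleosome assembly protein 1	Chromatin remodeling		
Nucleoplasmin	Chromatin remodeling		
Minichromosome maintenance 7	DNA replication		
Minichromosome maintenance 5	DNA replication		
Replication factor C subunit 3	DNA replication		
Rat1	DNA catabolic process		
SMC2	Chromosome condensation		
Translationally controlled tumor protein	DNA repair		
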