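genus	traits
Bacillus	PGP;biocontrol
Pseudomonas	PGP;biocontrol;stress_resistance
Rhizobium	PGP
Bradyrhizobium	PGP
Azotobacter	PGP
Azospirillum	PGP;stress_resistance
Streptomyces	biocontrol
Burkholderia	PGP;biocontrol
Paenibacillus	PGP;biocontrol
Enterobacter	PGP
Serratia	biocontrol
Arthrobacter	stress_resistance
Mesorhizobium	PGP
Sinorhizobium	PGP
Variovorax	stress_resistance
Herbaspirillum	PGP
Flavobacterium	biocontrol
Achromobacter	stress_resistance
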