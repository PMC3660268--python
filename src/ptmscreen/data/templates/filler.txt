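# Neutral filler sentences (must contain no PTM filtering token)
The protein was purified to homogeneity by size exclusion chromatography.
Expression levels were quantified by densitometry in three biological replicates.
Cells were cultured under standard conditions prior to downstream analysis.
Binding partners were identified using a targeted two-hybrid approach.
The crystal structure revealed a compact globular fold with two domains.
Knockdown experiments produced a modest reduction in colony formation.
Subcellular localization was examined by confocal microscopy.
The recombinant protein retained full enzymatic activity after storage.
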