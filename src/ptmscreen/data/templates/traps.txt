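# Trap templates (labelled negative): trap_class|ptm|text
chemical_name|acetylation|Biosynthesis of cysteine requires O-acetylserine as a key intermediate.
chemical_name|acetylation|Acetylcholine release at the synapse was quantified after stimulation.
chemical_name|sulfation|Sepharose 4B-tyrosine-sulfanilamide resin was used for affinity chromatography.
chemical_name|methylation|The methyl ester derivative was synthesized for pharmacological testing.
dna_methylation|methylation|DNA methylation of CpG islands was profiled across tumor genomes.
dna_methylation|methylation|Promoter methylation of CpG dinucleotides silences transcription in these lines.
enzyme_description|phosphorylation|The kinase domain of {gene} phosphorylates numerous cellular substrates.
enzyme_description|acetylation|Histone acetyltransferase activity of {gene} was measured in nuclear extracts.
enzyme_description|glycosylation|The transferase {gene} catalyzes glycosylation of nascent polypeptides.
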