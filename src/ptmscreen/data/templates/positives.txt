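# Positive statement templates: ptm|style|residue(or -)|text
# Placeholders: {gene} {residue} full name, {Residue3} three-letter code,
# {R1} one-letter code, {pos}/{pos2} single positions, {poslist} enumeration.
phosphorylation|spelled|-|Kinase assays showed that {gene} is phosphorylated at {residue} {pos}.
phosphorylation|enumeration|-|Mass spectrometry of {gene} identified phosphorylated {residue} positions {poslist}.
phosphorylation|compact3|-|Western blotting confirmed that {gene} is phosphorylated on {Residue3}-{pos}.
phosphorylation|compact1|-|Mutation of {R1}{pos} abolished phosphorylation of {gene} in transfected cells.
phosphorylation|leftward|-|Modification at position {pos} of the {residue} residue promotes phosphorylation of {gene}.
acetylation|spelled|lysine|Chromatin-bound {gene} was acetylated at {residue} {pos} under stress conditions.
acetylation|terminus|methionine|The N-terminal {residue} of {gene} is acetylated in vivo.
acetylation|none|lysine|Proteomic analysis revealed that {gene} undergoes acetylation on {residue} residues.
amidation|terminus|glycine|The C-terminal {residue} of {gene} is amidated during peptide maturation.
amidation|none|glycine|Mature {gene} peptide requires amidation of its {residue} residue for full activity.
disulfide_bond|pair|cysteine|A disulfide bond links {residue} {pos} and {residue} {pos2} in {gene}.
disulfide_bond|none|cysteine|An intramolecular disulfide bridge stabilizes the {residue}-rich domain of {gene}.
glycosylation|spelled|asparagine|N-glycosylation of {gene} occurs at {residue} {pos} within the conserved sequon.
glycosylation|none|asparagine|Lectin blotting indicated that {gene} is glycosylated on {residue} residues.
methylation|spelled|-|Purified {gene} is methylated at {residue} {pos} by a dedicated transferase.
methylation|none|-|Dimethylation of a conserved {residue} residue regulates {gene} turnover.
sulfation|spelled|tyrosine|Tyrosine sulfation of {gene} was mapped to {residue} {pos} in the mature chain.
sulfation|generic|tyrosine|Sulfation of {gene} occurs at the site at position {pos}.
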