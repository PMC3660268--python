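# Homolog-species trap templates (true statement, wrong species): text
In murine cells, {gene} was phosphorylated at {residue} {pos} following growth factor treatment.
Studies of the murine ortholog showed that {gene} is phosphorylated at {residue} {pos}.
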