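human	Homo sapiens
human	humans
mouse	murine
mouse	Mus musculus
mouse	mice
rat	Rattus norvegicus
yeast	Saccharomyces cerevisiae
yeast	budding yeast
bovine	Bos taurus
chicken	Gallus gallus
zebrafish	Danio rerio
fruit fly	Drosophila melanogaster
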