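# Positive-without-abstract-site templates (exemption cases): ptm|text
phosphorylation|Phosphorylation of {gene} regulates its catalytic activity during mitosis.
acetylation|Reversible acetylation modulates the nuclear functions of {gene}.
glycosylation|Altered glycosylation of {gene} correlates with disease progression.
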