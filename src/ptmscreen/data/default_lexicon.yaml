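# Default PTM vocabulary: the seven modification classes most frequently
# annotated in UniProtKB, each with its document-level filtering token(s),
# sentence-level trigger patterns, stop terms, and modifiable residues.
# Filtering tokens are unanchored lowercase substrings; trigger patterns are
# word-boundary-aware regular expressions compiled case-insensitively.
# Curators may extend this file; load_lexicon validates it on load.
linking_terms:
  - position
  - positions
  - residue
  - residues
  - site
  - sites
  - at
  - 'on'
  - in
  - of
  - the
  - and
  - or
generic_site_terms:
  - site
  - sites
  - residue
  - residues
global_exclusions:
  - name: dna_methylation
    ptm: methylation
    cues:
      - DNA
      - CpG
      - cytosine
      - promoter methylation
      - histone-free
classes:
  acetylation:
    filtering_tokens: [acet]
    trigger_patterns:
      - '\b(?:de|hyper|hypo|un)?acetylat(?:e[sd]?|ing|ion|ions)\b'
      - '\b(?:[no][\-\s]?)?acetyl[\-\s]?(?:lysine|serine|threonine|methionine|alanine|glycine|choline)s?\b'
    stop_terms:
      - o-acetylserine
      - acetylcholine
      - acetyl-coa
      - acetyltransferase
      - acetate
    allowed_residues:
      - lysine
      - serine
      - threonine
      - alanine
      - glycine
      - methionine
      - cysteine
    terminus_allowed: {n: true, c: false}
    position_required_in_abstract_screen: false
  amidation:
    filtering_tokens: [amid]
    trigger_patterns:
      - '\b(?:alpha[\-\s]?)?amidat(?:e[sd]?|ing|ion|ions)\b'
    stop_terms:
      - deamidation
      - deamidated
      - sulfanilamide
      - niacinamide
      - acrylamide
    allowed_residues:
      - glycine
      - valine
      - phenylalanine
      - leucine
      - methionine
    terminus_allowed: {n: false, c: true}
    position_required_in_abstract_screen: false
  disulfide_bond:
    filtering_tokens: [disulf, disulph]
    trigger_patterns:
      - '\bdisul(?:f|ph)ides?(?:[\-\s](?:bond(?:s|ed|ing)?|bridge[sd]?|link(?:s|ed|age|ages)?))?\b'
    stop_terms: []
    allowed_residues:
      - cysteine
    terminus_allowed: {n: false, c: false}
    position_required_in_abstract_screen: false
  glycosylation:
    filtering_tokens: [glyco]
    trigger_patterns:
      - '\b(?:[no][\-\s]?)?(?:de|hyper|hypo)?glycosylat(?:e[sd]?|ing|ion|ions)\b'
    stop_terms:
      - glycosylphosphatidyl
    allowed_residues:
      - asparagine
      - serine
      - threonine
      - tryptophan
    terminus_allowed: {n: false, c: false}
    position_required_in_abstract_screen: false
  methylation:
    filtering_tokens: [methyl]
    trigger_patterns:
      - '\b(?:de|hyper|hypo|mono|di|tri|un)?methylat(?:e[sd]?|ing|ion|ions)\b'
    stop_terms:
      - '-methyl-'
      - methyl ester
      - methylene
    allowed_residues:
      - lysine
      - arginine
      - histidine
      - glutamine
      - glutamate
    terminus_allowed: {n: true, c: false}
    position_required_in_abstract_screen: false
  phosphorylation:
    filtering_tokens: [phospho]
    trigger_patterns:
      - '\b(?:auto|hyper|hypo|de|trans|un)?phosphorylat(?:e[sd]?|ing|ion|ions)\b'
      - '\bphospho[\-\s]?(?:serine|threonine|tyrosine|histidine|ser|thr|tyr|his)\b'
      - '\bphosphosites?\b'
    stop_terms: []
    allowed_residues:
      - serine
      - threonine
      - tyrosine
      - histidine
    terminus_allowed: {n: false, c: false}
    position_required_in_abstract_screen: true
  sulfation:
    filtering_tokens: [sulf, sulph]
    trigger_patterns:
      - '\b(?:tyrosine[\-\s]?)?sul(?:f|ph)at(?:ed|ing|ion|ions)\b'
      - '\bsul(?:f|ph)o[\-\s]?tyrosine\b'
    stop_terms:
      - sulfanilamide
      - sepharose
      - heparan
      - chondroitin
      - dodecyl
    allowed_residues:
      - tyrosine
    terminus_allowed: {n: false, c: false}
    position_required_in_abstract_screen: false
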