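"""PTM vocabulary: loading, validation and compilation.

A lexicon bundles, per modification class, the document-level *filtering
token* (a bare lowercase substring such as ``phospho`` whose presence anywhere
in a document triggers fine-grained processing), the sentence-level *trigger
patterns* (word-boundary-aware regular expressions with morphological suffix
alternation), *stop terms* that veto a trigger match in chemical-name
contexts, the set of residues at which the modification can occur, and
terminus/position flags.  Document-wide context rules (e.g. the DNA/CpG
methylation exclusion) live at the lexicon level.

The packaged default lexicon covers the seven PTM classes most frequently
annotated in UniProtKB (acetylation, amidation, disulfide bond formation,
glycosylation, methylation, phosphorylation, sulfation).  It is a plain YAML
file so curators can extend it to further modification classes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from .residues import AMINO_ACIDS

KNOWN_PTM_CLASSES = frozenset({
    "acetylation", "amidation", "disulfide_bond", "glycosylation",
    "methylation", "phosphorylation", "sulfation",
})

#: window (characters) around a trigger span within which a stop term vetoes
#: the match — an appositive-scale neighbourhood, no syntactic parsing.
STOP_TERM_WINDOW = 15


class LexiconError(ValueError):
    """Raised when a lexicon config fails validation."""


def _literal_core(pattern: str) -> str:
    """Lowercased alphabetic skeleton of a regex, used to check that a trigger
    pattern embeds its class's filtering token."""
    return re.sub(r"[^a-z]", "", pattern.lower())


@dataclass
class ContextRule:
    """Document/sentence context exclusion, e.g. DNA methylation.

    A trigger of ``ptm`` is vetoed when one of the ``cues`` occurs in the same
    sentence and no mention of a modifiable protein residue lies closer to the
    trigger than the nearest cue.
    """
    name: str
    ptm: str
    cues: List[str]


@dataclass
class PTMClass:
    name: str
    filtering_tokens: List[str]
    trigger_patterns: List[str]
    stop_terms: List[str] = field(default_factory=list)
    allowed_residues: List[str] = field(default_factory=list)
    terminus_allowed: Dict[str, bool] = field(
        default_factory=lambda: {"n": False, "c": False})
    position_required_in_abstract_screen: bool = False
    _compiled: Optional[List[re.Pattern]] = field(
        default=None, repr=False, compare=False)

    def compiled_triggers(self) -> List[re.Pattern]:
        if self._compiled is None:
            self._compiled = [re.compile(p, re.IGNORECASE)
                              for p in self.trigger_patterns]
        return self._compiled

    def validate(self) -> None:
        if self.name not in KNOWN_PTM_CLASSES:
            raise LexiconError(f"unknown PTM class name: {self.name!r}")
        if not self.filtering_tokens:
            raise LexiconError(f"{self.name}: empty filtering token set")
        for tok in self.filtering_tokens:
            if tok != tok.lower():
                raise LexiconError(
                    f"{self.name}: filtering token {tok!r} must be lowercase")
        for pat in self.trigger_patterns:
            try:
                re.compile(pat, re.IGNORECASE)
            except re.error as exc:
                raise LexiconError(
                    f"{self.name}: pattern {pat!r} does not compile: {exc}"
                ) from exc
            core = _literal_core(pat)
            if not any(tok in core for tok in self.filtering_tokens):
                raise LexiconError(
                    f"{self.name}: pattern {pat!r} lacks a filtering token")
        for res in self.allowed_residues:
            if res not in AMINO_ACIDS:
                raise LexiconError(
                    f"{self.name}: unknown residue {res!r}")


@dataclass
class PTMLexicon:
    classes: Dict[str, PTMClass]
    linking_terms: List[str]
    generic_site_terms: List[str]
    global_exclusions: List[ContextRule] = field(default_factory=list)

    def validate(self) -> None:
        for cls in self.classes.values():
            cls.validate()
        for rule in self.global_exclusions:
            if rule.ptm not in self.classes:
                raise LexiconError(
                    f"exclusion {rule.name!r} targets unknown class {rule.ptm!r}")

    def to_dict(self) -> dict:
        """Canonical (sorted-key) plain-dict form for serialization."""
        return {
            "classes": {
                name: {
                    "filtering_tokens": sorted(c.filtering_tokens),
                    "trigger_patterns": list(c.trigger_patterns),
                    "stop_terms": sorted(c.stop_terms),
                    "allowed_residues": sorted(c.allowed_residues),
                    "terminus_allowed": {"n": c.terminus_allowed.get("n", False),
                                         "c": c.terminus_allowed.get("c", False)},
                    "position_required_in_abstract_screen":
                        c.position_required_in_abstract_screen,
                }
                for name, c in sorted(self.classes.items())
            },
            "linking_terms": list(self.linking_terms),
            "generic_site_terms": list(self.generic_site_terms),
            "global_exclusions": [
                {"name": r.name, "ptm": r.ptm, "cues": list(r.cues)}
                for r in self.global_exclusions
            ],
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True,
                           allow_unicode=True)


def _lexicon_from_dict(data: dict) -> PTMLexicon:
    if not isinstance(data, dict) or "classes" not in data:
        raise LexiconError("lexicon config must be a mapping with a "
                           "'classes' key")
    classes: Dict[str, PTMClass] = {}
    for name, spec in data["classes"].items():
        term = spec.get("terminus_allowed", {}) or {}
        classes[name] = PTMClass(
            name=name,
            filtering_tokens=list(spec.get("filtering_tokens", [])),
            trigger_patterns=list(spec.get("trigger_patterns", [])),
            stop_terms=[s.lower() for s in spec.get("stop_terms", [])],
            allowed_residues=list(spec.get("allowed_residues", [])),
            terminus_allowed={"n": bool(term.get("n", False)),
                              "c": bool(term.get("c", False))},
            position_required_in_abstract_screen=bool(
                spec.get("position_required_in_abstract_screen", False)),
        )
    lex = PTMLexicon(
        classes=classes,
        linking_terms=list(data.get("linking_terms", [])),
        generic_site_terms=list(data.get("generic_site_terms", [])),
        global_exclusions=[
            ContextRule(name=r["name"], ptm=r["ptm"], cues=list(r["cues"]))
            for r in data.get("global_exclusions", [])
        ],
    )
    lex.validate()
    return lex


def load_lexicon(path: str | Path) -> PTMLexicon:
    """Load and validate a lexicon config (YAML or JSON — YAML is a superset).

    Raises LexiconError naming the offending entry on any validation failure.
    """
    with open(path, encoding="utf-8") as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise LexiconError(f"cannot parse {path}: {exc}") from exc
    return _lexicon_from_dict(data)


def default_lexicon() -> PTMLexicon:
    """The packaged seven-class default lexicon."""
    text = (resources.files("ptmscreen") / "data" /
            "default_lexicon.yaml").read_text(encoding="utf-8")
    return _lexicon_from_dict(yaml.safe_load(text))
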