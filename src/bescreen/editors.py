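"""Registry of base-editor constructs and degenerate-IUPAC PAM matching.

Each construct couples a Cas targeting module (PAM pattern, PAM side,
spacer length) with a deaminase (base conversion) and the protospacer
interval inside which that deaminase edits efficiently (the editing
window).  Protospacer positions are numbered 1-based from the 5' end of
the protospacer on the targeted strand for every construct, including
5'-PAM ones; construct-specific windows absorb any geometric offset.

Windows are configuration, not constants: the defaults below are chosen
for internal consistency with worked nSpCas9/nSaCas9/KKH examples and can
be overridden from a YAML/JSON registry file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

from Bio.Data.IUPACData import ambiguous_dna_values

from .errors import DomainError, ParseError, UnknownConstructError, ValidationError

#: IUPAC letter -> set of concrete bases it allows.
IUPAC_SETS: dict[str, frozenset[str]] = {
    letter: frozenset(expansion) for letter, expansion in ambiguous_dna_values.items()
}

#: conversion (substrate, product) on the targeted strand -> editor class
CONVERSION_CLASSES: dict[tuple[str, str], str] = {
    ("A", "G"): "ABE",
    ("C", "T"): "CBE",
    ("C", "G"): "CGBE",
}


def iupac_match(pattern: str, seq: str) -> bool:
    """True iff ``seq`` matches the degenerate IUPAC ``pattern`` base-by-base.

    Case-insensitive; requires equal lengths.
    """
    if len(pattern) != len(seq):
        raise DomainError(
            f"pattern/sequence length mismatch: {len(pattern)} vs {len(seq)}"
        )
    for p, b in zip(pattern.upper(), seq.upper()):
        allowed = IUPAC_SETS.get(p)
        if allowed is None:
            raise ParseError(f"invalid IUPAC letter {p!r} in pattern {pattern!r}")
        if b not in allowed:
            if b not in "ACGT":
                raise ParseError(f"invalid base {b!r} in sequence {seq!r}")
            return False
    return True


@dataclass(frozen=True)
class EditorConstruct:
    """Targeting rules of one base-editor construct."""

    name: str
    pam_pattern: str
    pam_side: str  # "3prime" | "5prime", relative to the protospacer
    spacer_length: int
    window: tuple[int, int]  # inclusive protospacer positions, 1-based from 5'
    conversion: tuple[str, str]  # (substrate, product) on the targeted strand
    confidence_note: str = ""

    def __post_init__(self) -> None:
        if not self.pam_pattern:
            raise ValidationError("empty PAM pattern")
        bad = set(self.pam_pattern.upper()) - set(IUPAC_SETS)
        if bad:
            raise ValidationError(f"invalid IUPAC letters in PAM pattern: {sorted(bad)}")
        if self.pam_side not in ("3prime", "5prime"):
            raise ValidationError(f"pam_side must be 3prime or 5prime, got {self.pam_side!r}")
        lo, hi = self.window
        if not (1 <= lo <= hi <= self.spacer_length):
            raise ValidationError(
                f"editing window {self.window} must satisfy "
                f"1 <= start <= end <= spacer_length ({self.spacer_length})"
            )
        conv = (self.conversion[0].upper(), self.conversion[1].upper())
        if conv not in CONVERSION_CLASSES:
            raise ValidationError(f"unsupported base conversion {conv}")
        object.__setattr__(self, "conversion", conv)
        object.__setattr__(self, "pam_pattern", self.pam_pattern.upper())

    @property
    def editor_class(self) -> str:
        """ABE, CBE, or CGBE, derived from the conversion."""
        return CONVERSION_CLASSES[self.conversion]

    @property
    def pam_length(self) -> int:
        return len(self.pam_pattern)


#: Default ABE8e constructs.  PAM geometry follows the published Cas
#: modules; editing windows reproduce the worked bystander sets of the
#: three reference guides and are configurable.
DEFAULT_CONSTRUCTS: tuple[EditorConstruct, ...] = (
    EditorConstruct("nSpCas9-ABE8e", "NGG", "3prime", 20, (4, 8), ("A", "G")),
    EditorConstruct("nSaCas9-ABE8e", "NNGRRT", "3prime", 21, (3, 13), ("A", "G")),
    EditorConstruct("KKH-nSaCas9-ABE8e", "NNNRRT", "3prime", 21, (3, 13), ("A", "G")),
    EditorConstruct(
        "CasMINI-ABE8e",
        "TTTR",
        "5prime",
        20,
        (3, 8),
        ("A", "G"),
        confidence_note=(
            "no worked example in source; defaults from construct literature, configurable"
        ),
    ),
)


class Registry(dict):
    """Ordered name -> EditorConstruct mapping."""

    def __init__(self, constructs: Iterable[EditorConstruct] = ()):
        super().__init__((c.name, c) for c in constructs)

    def get_construct(self, name: str) -> EditorConstruct:
        try:
            return self[name]
        except KeyError:
            raise UnknownConstructError(
                f"unknown construct {name!r}; known: {', '.join(self)}"
            ) from None

    def add(self, construct: EditorConstruct) -> None:
        self[construct.name] = construct


def default_registry() -> Registry:
    return Registry(DEFAULT_CONSTRUCTS)


def get_construct(name: str) -> EditorConstruct:
    """Look up a construct in the default registry."""
    return default_registry().get_construct(name)


def _construct_from_config(name: str, cfg: Mapping) -> EditorConstruct:
    conv = cfg["conversion"]
    if isinstance(conv, str):
        if ">" not in conv:
            raise ValidationError(f"conversion must look like 'A>G', got {conv!r}")
        conv = tuple(conv.split(">", 1))
    return EditorConstruct(
        name=name,
        pam_pattern=cfg["pam_pattern"],
        pam_side=cfg.get("pam_side", "3prime"),
        spacer_length=int(cfg["spacer_length"]),
        window=(int(cfg["window"][0]), int(cfg["window"][1])),
        conversion=(conv[0], conv[1]),
        confidence_note=cfg.get("confidence_note", ""),
    )


def load_registry(config: Optional[Mapping | str] = None) -> Registry:
    """Build a registry: package defaults overlaid with user overrides.

    ``config`` may be a mapping ``{name: {pam_pattern, pam_side,
    spacer_length, window, conversion, ...}}`` or a path to a YAML/JSON
    file holding one.  Entries replace same-named defaults; new names are
    appended.
    """
    reg = default_registry()
    if config is None:
        return reg
    if isinstance(config, str):
        import json

        import yaml

        with open(config) as fh:
            text = fh.read()
        config = json.loads(text) if config.endswith(".json") else yaml.safe_load(text)
    if not isinstance(config, Mapping):
        raise ValidationError("registry config must be a mapping of name -> settings")
    for name, cfg in config.items():
        try:
            reg.add(_construct_from_config(name, cfg))
        except (KeyError, TypeError, IndexError) as exc:
            raise ValidationError(f"malformed registry entry {name!r}: {exc}") from exc
    return reg
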