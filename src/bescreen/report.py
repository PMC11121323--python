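"""Screening reports: display convention, TSV/JSON writers, pipeline driver.

Display convention for a guide: the protospacer is uppercase with the
target base replaced by ``[WT>MUT]`` rendered on the targeted strand, and
the PAM is appended lowercase on its side of the protospacer, e.g.
``TTAG[G>A]TATTGCAAATGCTGTTtttaat``.  The editing window cannot be
underlined in plain text, so it travels as explicit (start, end) metadata.
Reports are byte-stable: no timestamps, fixed ordering, sorted JSON keys.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from typing import Optional, Sequence

import pandas as pd

from .amenability import EditStrategy
from .bystanders import BystanderReport, bystander_report
from .editors import EditorConstruct, Registry
from .errors import ValidationError
from .guides import GuideCandidate, ScreenMatrix, screen_matrix
from .transcript import MiniTranscript, Variant

TSV_COLUMNS = [
    "variant",
    "construct",
    "n_guides",
    "strand",
    "protospacer",
    "pam",
    "target_pos",
    "display_string",
    "n_bystanders",
    "bystander_labels",
    "codon_outcome_labels",
]


def _package_version() -> str:
    try:
        return _pkg_version("bescreen")
    except PackageNotFoundError:  # pragma: no cover - editable corner case
        return "unknown"


def registry_hash(registry: Registry | Sequence[EditorConstruct]) -> str:
    """Stable digest of the construct settings used for a run."""
    constructs = list(registry.values()) if hasattr(registry, "values") else list(registry)
    blob = json.dumps([asdict(c) for c in constructs], sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def format_guide_display(
    guide: GuideCandidate,
    variant: Variant,
    strategy: EditStrategy,
    pam_side: str = "3prime",
) -> str:
    """Published display convention for one guide.

    The bracket shows wild-type > mutant alleles on the *targeted* strand
    (for a reverse-strand guide these are the complements of the coding
    change, which is reported separately).
    """
    proto = guide.protospacer.upper()
    p = guide.target_window_position
    bracket = (
        f"[{strategy.corrected_base_on_target_strand}>"
        f"{strategy.mutant_base_on_target_strand}]"
    )
    body = proto[:p - 1] + bracket + proto[p:]
    pam = guide.pam.lower()
    # 3' PAM trails the protospacer; 5' PAM leads it
    return body + pam if pam_side == "3prime" else pam + body


@dataclass(frozen=True)
class VariantScreen:
    """Everything the pipeline derives for one variant."""

    variant: Variant
    matrix: ScreenMatrix
    displays: dict[str, str]  # construct -> display string (chosen guide)
    bystanders: dict[str, BystanderReport]  # construct -> report (chosen guide)


def screen_variant(
    t: MiniTranscript, variant: Variant, registry: Registry
) -> VariantScreen:
    """Run the full pipeline (classify, enumerate, annotate) for one SNV."""
    matrix = screen_matrix(t, variant, registry)
    displays: dict[str, str] = {}
    bys: dict[str, BystanderReport] = {}
    for name, guide in matrix.best.items():
        if guide is None:
            continue
        construct = registry.get_construct(name)
        strategy = next(
            s for s in matrix.strategies if s.editor_class == construct.editor_class
        )
        displays[name] = format_guide_display(guide, variant, strategy, construct.pam_side)
        bys[name] = bystander_report(t, guide, construct, variant)
    return VariantScreen(variant, matrix, displays, bys)


@dataclass(frozen=True)
class ScreenReport:
    """Machine-readable per-variant x per-construct screening table."""

    rows: tuple[dict, ...]
    meta: dict

    def to_dict(self) -> dict:
        return {"meta": dict(self.meta), "rows": [dict(r) for r in self.rows]}

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenReport":
        return cls(tuple(dict(r) for r in d["rows"]), dict(d["meta"]))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "ScreenReport":
        return cls.from_dict(json.loads(text))

    def to_tsv(self) -> str:
        df = pd.DataFrame(list(self.rows), columns=TSV_COLUMNS)
        return df.to_csv(sep="\t", index=False, lineterminator="\n")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.rows), columns=TSV_COLUMNS)


def build_report(
    t: MiniTranscript,
    variants: Sequence[Variant],
    registry: Registry,
    seed: Optional[int] = None,
) -> ScreenReport:
    """Screen every variant against every registry construct.

    One row per (variant, construct); rows for constructs without a
    candidate carry empty guide fields.  Output is deterministic for a
    given transcript/variant/registry triple.
    """
    if not variants:
        raise ValidationError("no variants")
    rows: list[dict] = []
    for variant in variants:
        vs = screen_variant(t, variant, registry)
        strands = {
            s.editor_class: s.target_strand for s in vs.matrix.strategies
        }
        for name in registry:
            guide = vs.matrix.best[name]
            rep = vs.bystanders.get(name)
            construct = registry.get_construct(name)
            rows.append(
                {
                    "variant": variant.label,
                    "construct": name,
                    "n_guides": vs.matrix.counts[name],
                    "strand": (
                        guide.strand if guide else strands.get(construct.editor_class, "")
                    ),
                    "protospacer": guide.protospacer if guide else "",
                    "pam": guide.pam if guide else "",
                    "target_pos": guide.target_window_position if guide else "",
                    "display_string": vs.displays.get(name, ""),
                    "n_bystanders": len(rep.edits) if rep else "",
                    "bystander_labels": (
                        ";".join(e.label for e in rep.edits) if rep else ""
                    ),
                    "codon_outcome_labels": (
                        ";".join(o.label for o in rep.codon_outcomes) if rep else ""
                    ),
                }
            )
    meta = {
        "package_version": _package_version(),
        "registry_hash": registry_hash(registry),
        "transcript": t.name,
        "seed": seed,
    }
    return ScreenReport(tuple(rows), meta)


def write_report(report: ScreenReport, path: str, fmt: str = "tsv") -> None:
    """Write a report as TSV or JSON (UTF-8, LF)."""
    if fmt not in ("tsv", "json"):
        raise ValidationError(f"unknown report format {fmt!r}")
    text = report.to_tsv() if fmt == "tsv" else report.to_json()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(text)
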