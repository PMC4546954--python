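"""Corpus readers and writers.

The native dialect is UTF-8 TSV, one ``label<TAB>sentence`` record per line.
Labels are mapped through a shipped, editable alias table onto the closed
eight-class set (Cure, Prevent, SideEffect, DisOnly, TreatOnly, Vague,
NoCure, Nonrelevant). A best-effort ``biotext`` dialect additionally strips
inline entity markup (``<DIS>...</DIS>``-style tags) from the sentence text
before processing.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from ._resources import tsv_rows
from .exceptions import DataFormatError

CANONICAL_LABELS = (
    "Cure",
    "Prevent",
    "SideEffect",
    "DisOnly",
    "TreatOnly",
    "Vague",
    "NoCure",
    "Nonrelevant",
)


@dataclass(frozen=True)
class CorpusRecord:
    label: str
    text: str
    id: str

    def __post_init__(self) -> None:
        if self.label not in CANONICAL_LABELS:
            raise ValueError(f"label {self.label!r} is not one of {CANONICAL_LABELS}")
        if not self.text:
            raise ValueError("record text must be non-empty")


@lru_cache(maxsize=None)
def default_label_aliases() -> dict[str, str]:
    aliases = {row[0].lower(): row[1] for row in tsv_rows("label_aliases.tsv")}
    for label in CANONICAL_LABELS:
        aliases.setdefault(label.lower(), label)
    return aliases


_MARKUP_RE = re.compile(r"</?[A-Za-z][^<>]*>")


def _strip_markup(text: str) -> str:
    return re.sub(r"\s{2,}", " ", _MARKUP_RE.sub("", text)).strip()


def read_corpus(
    path: Union[str, Path],
    dialect: str = "tsv",
    aliases: Optional[Mapping[str, str]] = None,
) -> list[CorpusRecord]:
    """Read a labeled sentence corpus; malformed lines are reported by number."""
    if dialect not in ("tsv", "biotext"):
        raise DataFormatError(f"unknown corpus dialect {dialect!r}")
    if aliases is None:
        aliases = default_label_aliases()
    path = Path(path)
    records: list[CorpusRecord] = []
    for lineno, line in enumerate(
        path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        if "\t" not in line:
            raise DataFormatError(f"{path.name} line {lineno}: missing tab separator")
        raw_label, text = line.split("\t", 1)
        label = aliases.get(raw_label.strip().lower())
        if label is None:
            raise DataFormatError(
                f"{path.name} line {lineno}: unknown label {raw_label.strip()!r}"
            )
        if dialect == "biotext":
            text = _strip_markup(text)
        text = text.strip()
        if not text:
            raise DataFormatError(f"{path.name} line {lineno}: empty sentence text")
        records.append(CorpusRecord(label=label, text=text, id=f"{path.stem}:{lineno}"))
    if not records:
        raise DataFormatError(f"{path.name}: corpus contains no records")
    return records


def write_corpus(records: Iterable[CorpusRecord], path: Union[str, Path]) -> None:
    lines = [f"{rec.label}\t{rec.text}" for rec in records]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def corpus_stats(records: Sequence[CorpusRecord]) -> dict[str, int]:
    """Per-label sentence counts (all canonical labels) plus the total."""
    stats = {label: 0 for label in CANONICAL_LABELS}
    for rec in records:
        stats[rec.label] += 1
    stats["total"] = len(records)
    return stats


def format_stats(stats: Mapping[str, int]) -> str:
    width = max(len(k) for k in stats)
    lines = [f"{k:<{width}}  {stats[k]:>6}" for k in stats if k != "total"]
    lines.append(f"{'total':<{width}}  {stats['total']:>6}")
    return "\n".join(lines)
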