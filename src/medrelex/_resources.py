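"""Access to the data files shipped with the package."""
from __future__ import annotations

from functools import lru_cache
from importlib import resources


def data_text(name: str) -> str:
    return resources.files("medrelex.data").joinpath(name).read_text(encoding="utf-8")


@lru_cache(maxsize=None)
def word_set(name: str) -> frozenset[str]:
    """A data file with one lowercase entry per line, '#' comments allowed."""
    out = set()
    for line in data_text(name).splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line.lower())
    return frozenset(out)


@lru_cache(maxsize=None)
def tsv_rows(name: str) -> tuple[tuple[str, ...], ...]:
    rows = []
    for line in data_text(name).splitlines():
        if line and not line.startswith("#"):
            rows.append(tuple(line.split("\t")))
    return tuple(rows)
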