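"""Chemical–disease knowledge tables and the binary pair-feature vector.

Four resources are supported, mirroring the ones commonly used for
adverse-drug-reaction extraction: CTD (curated chemical–disease associations
with relation-type tags such as ``marker/mechanism`` or ``therapeutic``),
MEDI (drug indications), SIDER (drug side effects) and a precomputed MeSH
ancestor/descendant table.  Each is a TSV of ``chem_id  dis_id  tag`` rows.

A candidate pair is featurised as a fixed-order binary vector with one slot
per (table, tag) combination: the slot is 1 iff that table lists the pair
with that tag.  The layout is derived once from the loaded tables, so the
vector is identical in meaning across all candidates of a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

KNOWN_TABLES = ("CTD", "MEDI", "SIDER", "MESH_HIER")
_FILE_NAMES = {name.lower(): name for name in KNOWN_TABLES}
PRESENT = "present"


class KnowledgeFormatError(ValueError):
    pass


@dataclass
class KnowledgeTable:
    """One resource: (chem_id, dis_id) -> set of relation-type tags."""

    name: str
    entries: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    def add(self, chem_id: str, dis_id: str, tag: str) -> None:
        if not tag:
            raise ValueError("empty tag")
        self.entries.setdefault((chem_id, dis_id), set()).add(tag)

    def tags(self, chem_id: str, dis_id: str) -> set[str]:
        return self.entries.get((chem_id, dis_id), set())

    @property
    def tag_inventory(self) -> list[str]:
        return sorted({t for tags in self.entries.values() for t in tags})


@dataclass
class FeatureLayout:
    """Ordered (table, tag) slots defining each bit of the feature vector."""

    slots: list[tuple[str, str]]

    @property
    def width(self) -> int:
        return len(self.slots)


@dataclass
class KnowledgeFeatures:
    bits: np.ndarray
    layout: FeatureLayout


def load_knowledge(directory) -> list[KnowledgeTable]:
    """Load every ``<name>.tsv`` found under ``directory``.

    Lines starting with ``#`` are comments; duplicate rows collapse by set
    semantics.  Missing files are simply absent tables (their bits are zero
    downstream).  Malformed rows raise with file and line number.
    """
    directory = Path(directory)
    tables: list[KnowledgeTable] = []
    for stem, name in _FILE_NAMES.items():
        path = directory / f"{stem}.tsv"
        if not path.exists():
            continue
        table = KnowledgeTable(name)
        with open(path, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 3 or not all(f.strip() for f in fields):
                    raise KnowledgeFormatError(
                        f"{path}:{lineno}: expected 3 tab-separated columns "
                        f"(chem_id, dis_id, tag), got {line!r}"
                    )
                chem, dis, tag = (f.strip() for f in fields)
                table.add(chem, dis, tag)
        tables.append(table)
    return tables


def write_knowledge(tables: list[KnowledgeTable], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for table in tables:
        with open(directory / f"{table.name.lower()}.tsv", "w", encoding="utf-8") as fh:
            fh.write("# chem_id\tdis_id\ttag\n")
            for (chem, dis), tags in sorted(table.entries.items()):
                for tag in sorted(tags):
                    fh.write(f"{chem}\t{dis}\t{tag}\n")


def build_layout(tables: list[KnowledgeTable]) -> FeatureLayout:
    """Fixed slot order: tables in canonical order, tags sorted within."""
    slots: list[tuple[str, str]] = []
    by_name = {t.name: t for t in tables}
    for name in KNOWN_TABLES:
        if name in by_name:
            for tag in by_name[name].tag_inventory:
                slots.append((name, tag))
    return FeatureLayout(slots)


def featurize_pair(
    chem_id: str,
    dis_id: str,
    tables: list[KnowledgeTable],
    layout: FeatureLayout | None = None,
) -> KnowledgeFeatures:
    """Binary membership indicator of a pair over every (table, tag) slot.

    Pure function of (pair, tables): unknown pairs give the all-zero vector.
    """
    if layout is None:
        layout = build_layout(tables)
    by_name = {t.name: t for t in tables}
    bits = np.zeros(layout.width, dtype=np.float64)
    for i, (name, tag) in enumerate(layout.slots):
        table = by_name.get(name)
        if table is not None and tag in table.tags(chem_id, dis_id):
            bits[i] = 1.0
    return KnowledgeFeatures(bits=bits, layout=layout)
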