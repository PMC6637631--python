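"""Reading, validation and harmonization of association edge lists.

The pipeline consumes three two-column association tables — miRNA–disease,
miRNA–lncRNA and lncRNA–disease — plus an optional two-column name-alias map.
Labels are matched case-insensitively after whitespace trimming but stored in
their original (first-seen) spelling, because public ncRNA/disease tables mix
capitalisation conventions.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

KINDS = ("miRNA-disease", "miRNA-lncRNA", "lncRNA-disease")


def _key(label: str) -> str:
    return label.strip().casefold()


@dataclass(frozen=True)
class AssociationTable:
    """A deduplicated list of (source, target) association records.

    ``kind`` fixes the semantics of the two columns:

    - ``miRNA-disease``: (miRNA, disease)
    - ``miRNA-lncRNA``:  (miRNA, lncRNA)
    - ``lncRNA-disease``: (lncRNA, disease)
    """

    kind: str
    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown table kind {self.kind!r}; expected one of {KINDS}")
        seen = set()
        for s, t in self.records:
            if not s.strip() or not t.strip():
                raise ValueError(f"empty label in record {(s, t)!r}")
            k = (_key(s), _key(t))
            if k in seen:
                raise ValueError(f"duplicate record {(s, t)!r}")
            seen.add(k)

    @classmethod
    def from_records(cls, kind: str, records: Iterable[Sequence[str]]) -> "AssociationTable":
        """Build a table, trimming whitespace and collapsing duplicates (first wins)."""
        out: list[tuple[str, str]] = []
        seen: set[tuple[str, str]] = set()
        for rec in records:
            s, t = str(rec[0]).strip(), str(rec[1]).strip()
            k = (_key(s), _key(t))
            if k in seen:
                continue
            seen.add(k)
            out.append((s, t))
        return cls(kind=kind, records=tuple(out))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sources(self) -> tuple[str, ...]:
        """Unique source labels, order of first appearance."""
        return _unique([s for s, _ in self.records])

    @property
    def targets(self) -> tuple[str, ...]:
        return _unique([t for _, t in self.records])

    def source_keys(self) -> set[str]:
        return {_key(s) for s, _ in self.records}

    def target_keys(self) -> set[str]:
        return {_key(t) for _, t in self.records}

    def filter(self, predicate) -> "AssociationTable":
        return AssociationTable(
            kind=self.kind,
            records=tuple(r for r in self.records if predicate(*r)),
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "miRNA-disease": ("miRNA", "disease"),
            "miRNA-lncRNA": ("miRNA", "lncRNA"),
            "lncRNA-disease": ("lncRNA", "disease"),
        }[self.kind]
        return pd.DataFrame(list(self.records), columns=list(cols))


def _unique(labels: Iterable[str]) -> tuple[str, ...]:
    seen: set[str] = set()
    out: list[str] = []
    for lab in labels:
        k = _key(lab)
        if k not in seen:
            seen.add(k)
            out.append(lab)
    return tuple(out)


@dataclass(frozen=True)
class EntityIndex:
    """Deterministic bijection between entity labels and dense matrix positions.

    Positions are assigned by lexicographic order of the casefolded label so the
    same label set always yields the same matrix layout.
    """

    role: str
    labels: tuple[str, ...] = field(default=())

    @classmethod
    def from_labels(cls, role: str, labels: Iterable[str]) -> "EntityIndex":
        uniq = _unique(labels)
        ordered = tuple(sorted(uniq, key=lambda s: (_key(s), s)))
        return cls(role=role, labels=ordered)

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return _key(label) in self._positions()

    def _positions(self) -> dict[str, int]:
        # rebuilt on demand; frozen dataclass keeps no mutable cache
        return {_key(lab): i for i, lab in enumerate(self.labels)}

    def position(self, label: str) -> int:
        try:
            return self._positions()[_key(label)]
        except KeyError:
            raise KeyError(f"unknown {self.role} label {label!r}") from None

    def label(self, position: int) -> str:
        return self.labels[position]


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_association_table(path: str | Path, kind: str) -> AssociationTable:
    """Read a two-column TSV/CSV edge list.

    The delimiter is sniffed; a header row is detected heuristically (first line
    whose cells reappear nowhere else as labels and which matches common header
    words, or any first line when the caller's file declares one — in practice a
    line like ``miRNA<tab>disease`` is skipped).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"empty table: {path}")
    delim = _sniff_delimiter(text[:4096])
    rows: list[list[str]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = [p.strip() for p in line.split(delim)]
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected >=2 columns, got {len(parts)}")
        rows.append(parts[:2])
    if rows and _looks_like_header(rows[0], kind):
        rows = rows[1:]
    if not rows:
        raise ValueError(f"empty table: {path}")
    table = AssociationTable.from_records(kind, rows)
    logger.info("read %d %s records from %s", len(table), kind, path)
    return table


_HEADER_WORDS = {
    "mirna", "lncrna", "disease", "source", "target", "mir", "lnc",
    "mirna_name", "lncrna_name", "disease_name", "name1", "name2",
}


def _looks_like_header(row: Sequence[str], kind: str) -> bool:
    return all(_key(c) in _HEADER_WORDS for c in row[:2])


def write_association_table(table: AssociationTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (name, alias) TSV; returns a casefolded lookup."""
    path = Path(path)
    text = path.read_text()
    delim = _sniff_delimiter(text[:4096])
    mapping: dict[str, str] = {}
    for line in text.splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = [p.strip() for p in line.split(delim)]
        if len(parts) < 2:
            raise ValueError(f"alias map line needs 2 columns: {line!r}")
        mapping[_key(parts[0])] = parts[1]
    return mapping


def apply_aliases(table: AssociationTable, aliases: Mapping[str, str]) -> AssociationTable:
    """Exact-string alias substitution on both columns (case-insensitive keys)."""
    if not aliases:
        return table
    recs = [
        (aliases.get(_key(s), s), aliases.get(_key(t), t))
        for s, t in table.records
    ]
    return AssociationTable.from_records(table.kind, recs)


def harmonize(
    md: AssociationTable,
    ml: AssociationTable,
    ld: AssociationTable | None,
    aliases: Mapping[str, str] | None = None,
) -> tuple[AssociationTable, AssociationTable, AssociationTable | None]:
    """Restrict the three tables to a mutually consistent entity universe.

    Keeps only miRNAs present in *both* the miRNA–disease and miRNA–lncRNA
    tables (with their associations), then keeps lncRNA–disease pairs whose
    lncRNA survives in the miRNA–lncRNA table and whose disease survives in the
    miRNA–disease table. Alias substitution is applied first. Idempotent.
    """
    if aliases:
        md = apply_aliases(md, aliases)
        ml = apply_aliases(ml, aliases)
        if ld is not None:
            ld = apply_aliases(ld, aliases)
    if md.kind != "miRNA-disease" or ml.kind != "miRNA-lncRNA":
        raise ValueError("harmonize expects (md, ml, ld) table kinds in that order")

    common_mirnas = md.source_keys() & ml.source_keys()
    if not common_mirnas:
        raise ValueError("no miRNA occurs in both the miRNA-disease and miRNA-lncRNA tables")
    md_h = md.filter(lambda m, d: _key(m) in common_mirnas)
    ml_h = ml.filter(lambda m, l: _key(m) in common_mirnas)

    ld_h: AssociationTable | None = None
    if ld is not None:
        if ld.kind != "lncRNA-disease":
            raise ValueError("third table must be lncRNA-disease")
        lnc_keys = ml_h.target_keys()
        dis_keys = md_h.target_keys()
        ld_h = ld.filter(lambda l, d: _key(l) in lnc_keys and _key(d) in dis_keys)
        if len(ld_h) == 0:
            logger.warning("harmonization left no lncRNA-disease associations")
    logger.info(
        "harmonized: %d md, %d ml, %s ld records",
        len(md_h), len(ml_h), "no" if ld_h is None else len(ld_h),
    )
    return md_h, ml_h, ld_h


def build_indices(
    md: AssociationTable,
    ml: AssociationTable,
) -> tuple[EntityIndex, EntityIndex, EntityIndex]:
    """Entity indices (miRNA, lncRNA, disease) from harmonized md/ml tables."""
    mirnas = EntityIndex.from_labels("miRNA", md.sources + ml.sources)
    lncs = EntityIndex.from_labels("lncRNA", ml.targets)
    diseases = EntityIndex.from_labels("disease", md.targets)
    return mirnas, lncs, diseases


def summary(
    md: AssociationTable,
    ml: AssociationTable,
    ld: AssociationTable | None,
) -> dict:
    """Entity/edge counts, JSON-serialisable."""
    out = {
        "n_mirna": len(_unique(md.sources + ml.sources)),
        "n_lncrna": len(ml.targets),
        "n_disease": len(md.targets),
        "edges": {"miRNA-disease": len(md), "miRNA-lncRNA": len(ml)},
    }
    if ld is not None:
        out["edges"]["lncRNA-disease"] = len(ld)
        out["n_lncrna_ld"] = len(ld.sources)
        out["n_disease_ld"] = len(ld.targets)
    return out
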