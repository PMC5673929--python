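"""Reading, validation and writing of study compound tables.

The input of an enrichment run is one row per identified metabolite:
compound name, isomeric SMILES, optional PubChem CID, a raw per-metabolite
significance p-value (e.g. from a two-group Student t-test) and a fold
change defined as the ratio of group medians (case over control).  Rows
that violate the record invariants are dropped and itemized in a parse
report rather than aborting the run.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fingerprints import SmilesParseError, parse_smiles

__all__ = [
    "CompoundRecord",
    "StudyTable",
    "DEFAULT_COLUMN_MAP",
    "StudyTableError",
    "read_study_table",
    "write_study_table",
    "two_group_stats",
]

DEFAULT_COLUMN_MAP: dict[str, str] = {
    "name": "compound_name",
    "smiles": "smiles",
    "pubchem_cid": "pubchem_id",
    "effect_p": "pvalue",
    "fold_change": "foldchange",
}


class StudyTableError(ValueError):
    """Validation failure of a study compound table."""


@dataclass
class CompoundRecord:
    """One identified metabolite with its effect statistics.

    ``effect_p`` is the raw per-metabolite significance in [0, 1];
    ``fold_change`` is the positive ratio of group medians (case /
    control), so values > 1 mean increased in the case group.
    """

    compound_id: str
    name: str
    smiles: str
    effect_p: float
    fold_change: float
    pubchem_cid: int | None = None

    def validate(self) -> None:
        if not (0.0 <= self.effect_p <= 1.0) or math.isnan(self.effect_p):
            raise StudyTableError(f"{self.compound_id}: p-value outside [0,1]")
        if not (self.fold_change > 0) or math.isnan(self.fold_change):
            raise StudyTableError(f"{self.compound_id}: non-positive fold change")
        parse_smiles(self.smiles)
        if self.pubchem_cid is not None and self.pubchem_cid <= 0:
            raise StudyTableError(f"{self.compound_id}: non-positive PubChem CID")


@dataclass
class StudyTable:
    """Ordered collection of validated compound records plus provenance."""

    records: list[CompoundRecord]
    source: str = "<memory>"
    dropped: list[tuple[int, str, str]] = field(default_factory=list)
    # dropped rows: (1-based data row number, compound name or id, reason)

    def __post_init__(self):
        ids = [r.compound_id for r in self.records]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise StudyTableError(f"duplicate compound_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, compound_id: str) -> CompoundRecord:
        for rec in self.records:
            if rec.compound_id == compound_id:
                return rec
        raise KeyError(compound_id)

    def parse_report(self) -> str:
        lines = [
            f"source: {self.source}",
            f"accepted records: {len(self.records)}",
            f"dropped rows: {len(self.dropped)}",
        ]
        for row, name, reason in self.dropped:
            lines.append(f"  row {row} ({name}): {reason}")
        return "\n".join(lines) + "\n"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": [r.compound_id for r in self.records],
                "compound_name": [r.name for r in self.records],
                "smiles": [r.smiles for r in self.records],
                "pubchem_id": [
                    "" if r.pubchem_cid is None else r.pubchem_cid
                    for r in self.records
                ],
                "pvalue": [r.effect_p for r in self.records],
                "foldchange": [r.fold_change for r in self.records],
            }
        )


def _sniff_delimiter(path: Path, override: str | None) -> str:
    if override:
        return override
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_study_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    min_records: int = 3,
) -> StudyTable:
    """Read and validate a study compound table from CSV/TSV.

    ``column_map`` maps the record fields (name, smiles, pubchem_cid,
    effect_p, fold_change) to header names; unmapped optional columns may
    be absent.  Invalid rows (unparseable SMILES, missing or out-of-range
    p-value, non-positive fold change) are dropped and itemized; duplicate
    compound identifiers abort with an error naming the duplicates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    delim = _sniff_delimiter(path, delimiter)

    with open(path, encoding="utf-8-sig", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None:
            raise StudyTableError(f"{path}: empty file")
        header = set(reader.fieldnames)
        for fieldname in ("name", "smiles", "effect_p", "fold_change"):
            if cmap[fieldname] not in header:
                raise StudyTableError(
                    f"{path}: required column {cmap[fieldname]!r} missing "
                    f"(have {sorted(header)})"
                )
        has_cid = cmap["pubchem_cid"] in header
        has_id = "compound_id" in header

        records: list[CompoundRecord] = []
        dropped: list[tuple[int, str, str]] = []
        for i, row in enumerate(reader, start=1):
            name = (row.get(cmap["name"]) or "").strip()
            cid_raw = (row.get(cmap["pubchem_cid"]) or "").strip() if has_cid else ""
            compound_id = (row.get("compound_id") or "").strip() if has_id else ""
            if not compound_id:
                compound_id = name
            try:
                effect_p = float(row.get(cmap["effect_p"]) or "nan")
                fold_change = float(row.get(cmap["fold_change"]) or "nan")
            except ValueError:
                dropped.append((i, name or f"row{i}", "non-numeric statistics"))
                continue
            rec = CompoundRecord(
                compound_id=compound_id,
                name=name,
                smiles=(row.get(cmap["smiles"]) or "").strip(),
                effect_p=effect_p,
                fold_change=fold_change,
                pubchem_cid=int(cid_raw) if cid_raw else None,
            )
            try:
                rec.validate()
            except SmilesParseError:
                dropped.append((i, name or f"row{i}", "SMILES parse failure"))
                continue
            except StudyTableError as exc:
                reason = str(exc).split(": ", 1)[-1]
                if math.isnan(fold_change) or fold_change <= 0:
                    reason = "non-positive fold change"
                elif math.isnan(effect_p) or not (0 <= effect_p <= 1):
                    reason = "missing or out-of-range p-value"
                dropped.append((i, name or f"row{i}", reason))
                continue
            records.append(rec)

    if not records:
        raise StudyTableError(f"{path}: no valid rows")
    if len(records) < min_records:
        raise StudyTableError(
            f"{path}: only {len(records)} valid rows; at least "
            f"{min_records} required to form any set"
        )
    return StudyTable(records=records, source=str(path), dropped=dropped)


def write_study_table(table: StudyTable, path: str | Path) -> None:
    """Write a study table back to CSV/TSV (lossless round trip)."""
    path = Path(path)
    delim = _sniff_delimiter(path, None)
    df = table.to_frame()
    df.to_csv(path, sep=delim, index=False)


def two_group_stats(
    abundance: pd.DataFrame,
    group_labels: Sequence[str],
    case_group: str | None = None,
) -> pd.DataFrame:
    """Per-compound two-group Student t-test p-value and fold change.

    ``abundance`` is compounds x samples (positive reals); ``group_labels``
    assigns each sample column to one of exactly two groups.  The fold
    change is median(case) / median(control), with the case group taken as
    ``case_group`` (default: first label encountered).  A compound with
    zero variance in both groups gets p-value 1.0 and ``flat=True``.
    """
    labels = pd.Series(list(group_labels), index=abundance.columns)
    groups = list(dict.fromkeys(labels))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    case = case_group if case_group is not None else groups[0]
    control = [g for g in groups if g != case][0]
    a = abundance.loc[:, labels == case].to_numpy(dtype=float)
    b = abundance.loc[:, labels == control].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("abundances must be finite")

    flat = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=True)
        pvals = np.asarray(res.pvalue, dtype=float)
    pvals[flat] = 1.0
    med_a = np.median(a, axis=1)
    med_b = np.median(b, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = med_a / med_b
    return pd.DataFrame(
        {"effect_p": pvals, "fold_change": fc, "flat": flat},
        index=abundance.index,
    )
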