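"""The machine-readable annotation library of cassaine-type diterpenoids.

Each record carries the molecular formula, observed [M+H]+ m/z, retention
time, arm class, substituent loss multiset plus generic H2O/CO losses, the
printed mass deviation, literature status (NEW vs known) and the four-way
relative abundance profile across the sample subgroups (Ouesso-Sua, Sua *,
ivo-Libr 1, ivo-Libr 2).

Records whose printed formula/m-z/delta triple cannot be reproduced by
exact-mass arithmetic are flagged ``unverifiable-as-printed`` and excluded
from reproduction checks (the values are retained as annotations).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

from .annotation import SubstituentMultiset
from .formula import MolecularFormula, parse_formula

__all__ = ["LibraryRecord", "Table2Library", "load_library", "GROUP_ORDER"]

#: Canonical subgroup order used throughout (matches the profile strings).
GROUP_ORDER = ("Ouesso-Sua", "Sua *", "ivo-Libr 1", "ivo-Libr 2")


def _parse_multiset(text: str) -> SubstituentMultiset:
    text = (text or "").strip()
    if not text or text == "-":
        return SubstituentMultiset()
    counts: dict[str, int] = {}
    for part in text.split(";"):
        name, _, n = part.partition(":")
        counts[name.strip()] = int(n) if n else 1
    return SubstituentMultiset(counts)


@dataclass(frozen=True)
class LibraryRecord:
    id: str
    formula: MolecularFormula
    observed_mz: float
    rt_min: float
    printed_delta_ppm: float
    arm: str
    substituents: SubstituentMultiset
    generic_losses: SubstituentMultiset
    ref_status: str  # "NEW" | "known"
    flag: Optional[str]  # e.g. "unverifiable-as-printed"
    dominant_group: str
    abundance_profile: tuple[int, ...]

    @property
    def total_losses(self) -> SubstituentMultiset:
        """Substituent plus generic losses; what the fragment cascade shows."""
        merged = self.substituents.as_dict()
        for k, n in self.generic_losses.counts:
            merged[k] = merged.get(k, 0) + n
        return SubstituentMultiset(merged)

    @property
    def is_new(self) -> bool:
        return self.ref_status == "NEW"

    @property
    def verifiable(self) -> bool:
        return self.flag is None


class Table2Library:
    """Ordered collection of :class:`LibraryRecord` with id lookup."""

    def __init__(self, records: list[LibraryRecord]):
        self.records = list(records)
        self._by_id = {r.id: r for r in self.records}

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    def __getitem__(self, record_id: str) -> LibraryRecord:
        return self._by_id[record_id]

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._by_id

    @property
    def new_records(self) -> list[LibraryRecord]:
        return [r for r in self.records if r.is_new]


def load_library(path: str | Path | None = None) -> Table2Library:
    """Load the bundled annotation library (or a user TSV of same schema)."""
    if path is None:
        source = resources.files("cassanet.data") / "cassane_library.tsv"
        text = source.read_text()
    else:
        text = Path(path).read_text()
    records = []
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        profile = tuple(int(x) for x in row["abundance_profile"].split("/"))
        if len(profile) != len(GROUP_ORDER):
            raise ValueError(
                f"record {row['id']}: profile must have {len(GROUP_ORDER)} entries"
            )
        flag = row.get("flag", "").strip()
        records.append(
            LibraryRecord(
                id=row["id"],
                formula=parse_formula(row["formula"]),
                observed_mz=float(row["observed_mz"]),
                rt_min=float(row["rt_min"]),
                printed_delta_ppm=float(row["printed_delta_ppm"]),
                arm=row["arm"],
                substituents=_parse_multiset(row["substituents"]),
                generic_losses=_parse_multiset(row["generic_losses"]),
                ref_status=row["ref_status"],
                flag=None if flag in ("", "-") else flag,
                dominant_group=row["dominant_group"],
                abundance_profile=profile,
            )
        )
    return Table2Library(records)
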