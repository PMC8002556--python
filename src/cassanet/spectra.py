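"""MS/MS spectra, MGF input/output and feature quantification tables.

The MGF dialect follows the MZmine GNPS-export conventions the rest of the
pipeline expects: one ``BEGIN IONS``/``END IONS`` block per feature, the
feature id in ``TITLE``, ``PEPMASS`` mandatory, retention time in
``RTINSECONDS`` (stored internally in minutes) and ``CHARGE=1+``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from pyteomics import mgf as _pyteomics_mgf

__all__ = [
    "Peak",
    "Spectrum",
    "FeatureTable",
    "MGFError",
    "read_mgf",
    "write_mgf",
    "clean_spectrum",
    "read_quant_table",
]


class MGFError(ValueError):
    """Raised for malformed MGF blocks (the message names the block index)."""


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class Spectrum:
    """A single MS/MS spectrum: precursor, retention time and peak list.

    Peaks are kept sorted by m/z.  Fragments above the precursor m/z are
    allowed (near-precursor ions occur in real QTOF spectra).
    """

    id: str
    precursor_mz: float
    rt: float  # minutes
    peaks: tuple[Peak, ...]
    charge: int = 1
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(
            self, "peaks", tuple(sorted(self.peaks, key=lambda p: p.mz))
        )

    @property
    def mzs(self) -> list[float]:
        return [p.mz for p in self.peaks]

    @property
    def intensities(self) -> list[float]:
        return [p.intensity for p in self.peaks]


@dataclass(frozen=True)
class FeatureTable:
    """Feature x sample intensity matrix with a sample-to-group mapping."""

    intensities: pd.DataFrame  # rows: feature ids, columns: sample ids
    groups: dict[str, str]  # sample id -> group label

    def __post_init__(self):
        missing = [s for s in self.intensities.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group assignment: {missing}")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.sample_ids:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file into a list of :class:`Spectrum`.

    ``RTINSECONDS`` is converted to minutes; a missing charge defaults to
    +1.  A block without ``PEPMASS`` or with an unparseable peak line
    raises :class:`MGFError` naming the 1-based block index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: list[Spectrum] = []
    with _pyteomics_mgf.read(str(path), use_index=False, convert_arrays=1) as reader:
        for i, block in enumerate(reader, start=1):
            try:
                params = block["params"]
                if "pepmass" not in params or params["pepmass"][0] is None:
                    raise MGFError(f"MGF block {i}: missing PEPMASS")
                precursor = float(params["pepmass"][0])
                title = str(params.get("title", f"spectrum_{i}"))
                rt_s = params.get("rtinseconds")
                rt = float(rt_s) / 60.0 if rt_s is not None else 0.0
                charge = int(params["charge"][0]) if "charge" in params else 1
                peaks = tuple(
                    Peak(float(mz), float(inten))
                    for mz, inten in zip(block["m/z array"], block["intensity array"])
                )
            except MGFError:
                raise
            except Exception as exc:  # malformed numbers, bad peak lines ...
                raise MGFError(f"MGF block {i}: {exc}") from exc
            spectra.append(Spectrum(title, precursor, rt, peaks, charge))
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF (TITLE=id, PEPMASS, RTINSECONDS, CHARGE=1+).

    m/z values are printed to 4 decimals, intensities to 2.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.4f}\n")
            fh.write(f"RTINSECONDS={s.rt * 60.0:.2f}\n")
            fh.write(f"CHARGE={s.charge}+\n")
            for p in s.peaks:
                fh.write(f"{p.mz:.4f} {p.intensity:.2f}\n")
            fh.write("END IONS\n")


def clean_spectrum(
    s: Spectrum, noise_floor: float = 0.0, merge_tol: float = 0.005
) -> Spectrum:
    """Drop sub-threshold peaks and merge peaks closer than ``merge_tol``.

    Peaks within ``merge_tol`` Da of each other collapse to their
    intensity-weighted mean m/z with summed intensity.  A spectrum whose
    peaks all fall below the floor is retained with an empty peak list and
    flagged ``"empty-after-clean"``.  The operation is idempotent.
    """
    if merge_tol < 0:
        raise ValueError("merge_tol must be >= 0")
    kept = [p for p in s.peaks if p.intensity >= noise_floor]
    merged: list[Peak] = []
    if merge_tol > 0:
        cluster: list[Peak] = []
        for p in kept:
            if cluster and p.mz - cluster[-1].mz <= merge_tol:
                cluster.append(p)
            else:
                if cluster:
                    merged.append(_merge_cluster(cluster))
                cluster = [p]
        if cluster:
            merged.append(_merge_cluster(cluster))
    else:
        merged = kept
    flags = s.flags
    if not merged and s.peaks:
        flags = tuple(set(flags) | {"empty-after-clean"})
    return replace(s, peaks=tuple(merged), flags=flags)


def _merge_cluster(cluster: list[Peak]) -> Peak:
    total = sum(p.intensity for p in cluster)
    if total == 0:
        mz = sum(p.mz for p in cluster) / len(cluster)
    else:
        mz = sum(p.mz * p.intensity for p in cluster) / total
    return Peak(mz, total)


def read_quant_table(
    path: str | Path, group_map_path: str | Path
) -> FeatureTable:
    """Read a feature quantification CSV/TSV and a sample->group TSV.

    The quantification table has sample ids in the header and feature ids
    in the first column.  Every sample must appear in the group map; any
    non-numeric intensity cell raises with its row/column location.
    """
    path, group_map_path = Path(path), Path(group_map_path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    try:
        values = raw.astype(float)
    except ValueError:
        for feature in raw.index:
            for sample in raw.columns:
                cell = raw.loc[feature, sample]
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric intensity at feature {feature!r}, "
                        f"sample {sample!r}: {cell!r}"
                    ) from None
        raise
    gm = pd.read_csv(group_map_path, sep="\t", header=None, names=["sample", "group"], dtype=str)
    groups = dict(zip(gm["sample"], gm["group"]))
    return FeatureTable(values, groups)


def write_quant_table(
    table: FeatureTable, path: str | Path, group_map_path: str | Path
) -> None:
    """Write a FeatureTable back to CSV + two-column group-map TSV."""
    table.intensities.to_csv(path)
    with open(group_map_path, "w") as fh:
        for sample in table.sample_ids:
            fh.write(f"{sample}\t{table.groups[sample]}\n")
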