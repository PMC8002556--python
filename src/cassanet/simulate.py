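"""In-silico fragmentation and ground-truthed dataset emission.

The simulator turns a structural specification (total formula, arm class,
substituent loss multiset, extra generic H2O/CO losses) into the MS/MS
spectrum its fragmentation cascade predicts: the [M+H]+ precursor, the
arm-diagnostic ions, the full-arm-loss anchor, and one fragment for every
non-empty sub-multiset of the losses below the anchor.  Fragment m/z are
theoretical (exact-mass arithmetic); observed instrument values deviate
from these by a few mDa, which the noise model emulates with ppm-scale
jitter.

The intensity model is deliberately simple and fixed: precursor 100, arm
ions 80, cascade ions 60 x 0.8^(number of losses); no physical
fragmentation energetics are modelled.
"""

from __future__ import annotations

import itertools
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotation import ARM_FULL_LOSS, LOSS_ALPHABET, SubstituentMultiset
from .formula import MolecularFormula, parse_formula, protonated_mz
from .library import GROUP_ORDER, LibraryRecord, Table2Library
from .spectra import Peak, Spectrum, write_mgf

__all__ = [
    "CompoundSpec",
    "NoiseModel",
    "simulate_fragments",
    "apply_noise",
    "emit_dataset",
    "spec_from_record",
    "library_specs",
    "homologous_family",
]

_ARM_IONS = {
    "NME": (31.0422, 75.0684),
    "PAE": (17.0265, 61.0528),
    "DME": (45.0578, 89.0841),
    "AMD": (18.0106, 32.0262, 75.0684),
}

#: Minimum mass the bare scaffold ion must retain after all losses (Da).
SCAFFOLD_FLOOR = 150.0


@dataclass(frozen=True)
class CompoundSpec:
    """Ground-truth structural specification driving the simulator."""

    id: str
    formula: MolecularFormula
    arm_class: str
    substituents: SubstituentMultiset = field(default_factory=SubstituentMultiset)
    generic_losses: SubstituentMultiset = field(default_factory=SubstituentMultiset)
    family_id: str = ""
    rt_min: float = 10.0

    def __post_init__(self):
        if self.arm_class not in _ARM_IONS:
            raise ValueError(f"unknown arm class {self.arm_class!r}")

    @property
    def total_losses(self) -> SubstituentMultiset:
        merged = self.substituents.as_dict()
        for k, n in self.generic_losses.counts:
            merged[k] = merged.get(k, 0) + n
        return SubstituentMultiset(merged)

    @property
    def precursor_mz(self) -> float:
        return protonated_mz(self.formula)


@dataclass(frozen=True)
class NoiseModel:
    """Instrument noise emulation; identical seed -> identical dataset."""

    mz_jitter_ppm: float = 0.0
    intensity_cv: float = 0.0
    spurious_mean: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.mz_jitter_ppm, self.intensity_cv, self.spurious_mean) < 0:
            raise ValueError("noise parameters must be non-negative")


def _submultisets(counts: Mapping[str, int]):
    names = sorted(counts)
    axes = [range(counts[n] + 1) for n in names]
    for combo in itertools.product(*axes):
        if any(combo):
            yield {n: k for n, k in zip(names, combo) if k}


def simulate_fragments(spec: CompoundSpec) -> Spectrum:
    """Noiseless theoretical MS/MS spectrum of a compound spec.

    Raises if the losses would eat into the tricyclic scaffold (total loss
    mass within ``SCAFFOLD_FLOOR`` Da of the precursor).
    """
    p = spec.precursor_mz
    arm_masses = _ARM_IONS[spec.arm_class]
    full_arm = ARM_FULL_LOSS[spec.arm_class][1]
    anchor = p - full_arm
    total = spec.total_losses
    if anchor - total.mass < SCAFFOLD_FLOOR:
        raise ValueError(
            f"{spec.id}: losses leave less than {SCAFFOLD_FLOOR} Da of scaffold"
        )
    peaks: dict[float, float] = {round(p, 6): 100.0}

    def put(mz: float, intensity: float):
        key = round(mz, 6)
        peaks[key] = max(peaks.get(key, 0.0), intensity)

    for loss in arm_masses:
        put(p - loss, 80.0)
    put(anchor, 80.0)
    for sub in _submultisets(total.as_dict()):
        mass = sum(LOSS_ALPHABET[k][0] * n for k, n in sub.items())
        depth = sum(sub.values())
        put(anchor - mass, 60.0 * 0.8**depth)
    return Spectrum(
        id=spec.id,
        precursor_mz=p,
        rt=spec.rt_min,
        peaks=tuple(Peak(mz, i) for mz, i in peaks.items()),
    )


def apply_noise(s: Spectrum, nm: NoiseModel) -> Spectrum:
    """Perturb a spectrum: ppm-scale Gaussian m/z jitter, mean-preserving
    lognormal intensity noise, and Poisson-distributed spurious peaks
    uniform in [100, precursor].  Deterministic under the model's seed
    (keyed additionally by the spectrum id so every spectrum of a dataset
    gets an independent stream)."""
    rng = np.random.default_rng(
        np.random.SeedSequence([nm.seed, zlib.crc32(s.id.encode()) % 2**31])
    )
    sigma = float(np.sqrt(np.log1p(nm.intensity_cv**2)))
    peaks = []
    for p in s.peaks:
        mz = p.mz * (1.0 + rng.normal(0.0, nm.mz_jitter_ppm) * 1e-6)
        if sigma > 0:
            inten = p.intensity * float(np.exp(rng.normal(-sigma**2 / 2, sigma)))
        else:
            inten = p.intensity
        peaks.append(Peak(mz, inten))
    n_spurious = int(rng.poisson(nm.spurious_mean)) if nm.spurious_mean > 0 else 0
    for _ in range(n_spurious):
        mz = float(rng.uniform(100.0, s.precursor_mz))
        peaks.append(Peak(mz, float(rng.uniform(0.5, 10.0))))
    precursor = s.precursor_mz * (
        1.0 + (rng.normal(0.0, nm.mz_jitter_ppm) * 1e-6 if nm.mz_jitter_ppm > 0 else 0.0)
    )
    return Spectrum(s.id, precursor, s.rt, tuple(peaks), s.charge, s.flags)


# --------------------------------------------------------------------------
# dataset emission


def spec_from_record(rec: LibraryRecord, family_id: str | None = None) -> CompoundSpec:
    """Build the simulator spec encoded by an annotation-library record."""
    return CompoundSpec(
        id=rec.id,
        formula=rec.formula,
        arm_class=rec.arm,
        substituents=rec.substituents,
        generic_losses=rec.generic_losses,
        family_id=family_id if family_id is not None else rec.id[0],
        rt_min=rec.rt_min,
    )


def library_specs(lib: Table2Library) -> list[CompoundSpec]:
    """Simulator specs for every library record (family = sub-cluster letter)."""
    return [spec_from_record(r) for r in lib]


def homologous_family(
    family_id: str,
    base_formula: str,
    n_members: int,
    arm_class: str = "NME",
    substituents: Mapping[str, int] | None = None,
    generic_losses: Mapping[str, int] | None = None,
    rt_min: float = 10.0,
) -> list[CompoundSpec]:
    """A CH2-homologue series sharing arm and substituents.

    Members share the whole loss cascade, so every peak of one member
    matches a peak of another under the precursor-shifted rule and the
    family forms a single network component.
    """
    base = parse_formula(base_formula)
    specs = []
    for k in range(n_members):
        counts = base.as_dict()
        counts["C"] = counts.get("C", 0) + k
        counts["H"] = counts.get("H", 0) + 2 * k
        specs.append(
            CompoundSpec(
                id=f"{family_id}_{k}",
                formula=MolecularFormula(counts),
                arm_class=arm_class,
                substituents=SubstituentMultiset(substituents or {}),
                generic_losses=SubstituentMultiset(generic_losses or {}),
                family_id=family_id,
                rt_min=rt_min + 0.5 * k,
            )
        )
    return specs


def emit_dataset(
    specs: Sequence[CompoundSpec],
    profiles: Sequence[Sequence[float]],
    nm: NoiseModel,
    out_dir: str | Path,
    groups: Sequence[str] = GROUP_ORDER,
    samples_per_group: int = 3,
    base_intensity: float = 1e6,
) -> dict:
    """Emit MGF + quantification CSV + group map TSV + ground-truth JSON.

    ``profiles`` has one row per spec and one column per group; row values
    are relative weights whose scaled values (``base_intensity`` x weight /
    100) become the group means.  Per-sample intensities are lognormal
    around the group mean with the noise model's CV.  Returns the ground
    truth as a dict (also written to ``ground_truth.json``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    profiles = [list(row) for row in profiles]
    if len(profiles) != len(specs):
        raise ValueError("one profile row per compound spec required")
    for row in profiles:
        if len(row) != len(groups):
            raise ValueError("profile row length must equal number of groups")
        if any(v < 0 for v in row):
            raise ValueError("profile weights must be non-negative")
    if samples_per_group < 1:
        raise ValueError("need at least one sample per group")

    spectra = [apply_noise(simulate_fragments(sp), nm) for sp in specs]
    write_mgf(spectra, out_dir / "features.mgf")

    samples = [
        f"{g.replace(' ', '').replace('*', 'star')}_s{i + 1}"
        for g in groups
        for i in range(samples_per_group)
    ]
    rng = np.random.default_rng(np.random.SeedSequence([nm.seed, 982451653]))
    sigma = float(np.sqrt(np.log1p(nm.intensity_cv**2)))
    rows = []
    truth: dict = {"groups": list(groups), "features": {}}
    for sp, row in zip(specs, profiles):
        means = [base_intensity * v / 100.0 for v in row]
        values = []
        for g_idx in range(len(groups)):
            for _ in range(samples_per_group):
                mean = means[g_idx]
                if mean == 0:
                    values.append(0.0)
                elif sigma > 0:
                    values.append(mean * float(np.exp(rng.normal(-sigma**2 / 2, sigma))))
                else:
                    values.append(mean)
        rows.append(values)
        truth["features"][sp.id] = {
            "compound": sp.id,
            "family": sp.family_id,
            "formula": sp.formula.hill(),
            "arm_class": sp.arm_class,
            "substituents": sp.substituents.as_dict(),
            "generic_losses": sp.generic_losses.as_dict(),
            "group_means": means,
        }

    with open(out_dir / "quant.csv", "w") as fh:
        fh.write("feature," + ",".join(samples) + "\n")
        for sp, values in zip(specs, rows):
            fh.write(sp.id + "," + ",".join(f"{v:.4f}" for v in values) + "\n")
    with open(out_dir / "groups.tsv", "w") as fh:
        for g_idx, g in enumerate(groups):
            for i in range(samples_per_group):
                fh.write(f"{samples[g_idx * samples_per_group + i]}\t{g}\n")
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth
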