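"""Diagnostic neutral-loss annotation of cassaine-type diterpenoids.

Cassaine-type diterpenoids carry a nitrogen-containing side chain ("arm")
at C-13 of the cassane scaffold.  In positive-mode MS/MS the linkage type
of that arm leaves a characteristic fingerprint of neutral losses from the
[M+H]+ precursor:

* ester of N-methylethanolamine (NME): loss of methylamine CH3NH2
  (31.0422 Da) and of the whole arm C3H9NO (75.0684 Da);
* ester of N,N-dimethylethanolamine (DME): loss of dimethylamine C2H7N
  (45.0578 Da) and of the whole arm C4H11NO (89.0841 Da);
* ester of ethanolamine / primary amine, indistinguishable from an
  amide-alcohol (PAE): loss of NH3 (17.0265 Da) and of C2H7NO (61.0528 Da);
* N-methyl amide with a terminal alcohol (AMD): losses of H2O (18.0106 Da)
  and CH3OH (32.0262 Da); the common arm cut C3H9NO is observed for both
  ester and amide compounds, so it alone does not separate NME from AMD.

Below the arm-loss "anchor" ion, successive losses of the scaffold
substituents (acetate/methyl-ester 60.0211, CO, H2O, tigloyl and its
hydrated/reduced forms, glucosyl) form a ladder; decomposing the ladder
mass differences over that loss alphabet recovers the substituent multiset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .formula import (
    FormulaCandidate,
    MolecularFormula,
    assign_formula,
    neutral_mass,
    parse_formula,
    ppm_error,
)
from .networking import MolecularNetwork
from .spectra import Spectrum

__all__ = [
    "ARM_CLASSES",
    "ARM_FULL_LOSS",
    "LOSS_ALPHABET",
    "ArmCall",
    "SubstituentMultiset",
    "CassaneAnnotation",
    "AnnotationConfig",
    "detect_arm_type",
    "infer_substituents",
    "annotate_node",
    "propagate_family",
    "write_annotation_report",
]

# --------------------------------------------------------------------------
# loss alphabets

#: Substituent loss alphabet: name -> (mass Da, default max count per compound).
LOSS_ALPHABET: dict[str, tuple[float, int]] = {
    "ester60": (60.0211, 3),  # CH3COOH, isobaric with CH3OH+CO
    "oxo": (27.9949, 4),  # CO (includes generic carbonyl losses)
    "hydroxy": (18.0106, 4),  # H2O (includes generic dehydrations)
    "tigloyl": (100.0524, 1),  # C5H8O2, tigloyl or 3-methylcrotonyl
    "dihydrotigloyl": (102.0681, 1),  # C5H10O2, reduced tigloyl
    "hydroxytigloyl": (118.0630, 1),  # C5H10O3, hydrated tigloyl
    "glucosyl": (162.0528, 1),  # C6H10O5
}

#: Alternative observed mass for glucosyl cleavage (C6H9O5-like radical cut).
GLUCOSYL_ALT_MASS = 161.0450

#: Named substituents compared exactly during library matching; hydroxy/oxo
#: counts absorb generic dehydrations/decarbonylations and are compared with
#: slack instead.
STRICT_SUBSTITUENTS = ("ester60", "tigloyl", "dihydrotigloyl", "hydroxytigloyl", "glucosyl")

ARM_CLASSES = ("NME", "PAE", "DME", "AMD", "NONE")

# partial (amine-side) diagnostic losses per ester arm class
_ARM_PARTIAL = {
    "NME": ("CH3NH2", 31.0422),
    "DME": ("C2H7N", 45.0578),
    "PAE": ("NH3", 17.0265),
}

#: Full-arm loss mass per arm class (defines the cascade anchor ion).
ARM_FULL_LOSS: dict[str, tuple[str, float]] = {
    "NME": ("C3H9NO", 75.0684),
    "DME": ("C4H11NO", 89.0841),
    "PAE": ("C2H7NO", 61.0528),
    "AMD": ("C3H9NO", 75.0684),
}

_AMD_SIGNATURE = (("H2O", 18.0106), ("CH3OH", 32.0262))


@dataclass(frozen=True)
class ArmCall:
    """Classification of the C-13 arm with the supporting neutral losses.

    ``evidence`` holds (loss name, observed delta Da, deviation in ppm of
    the observed delta from the diagnostic loss mass).
    """

    arm_class: str
    evidence: tuple[tuple[str, float, float], ...] = ()

    def __post_init__(self):
        if self.arm_class not in ARM_CLASSES:
            raise ValueError(f"unknown arm class {self.arm_class!r}")
        if self.arm_class != "NONE" and not self.evidence:
            raise ValueError("non-NONE arm call requires evidence")

    @property
    def full_arm_mass(self) -> float:
        return ARM_FULL_LOSS[self.arm_class][1]


@dataclass(frozen=True)
class SubstituentMultiset:
    """Counts over the substituent loss alphabet (order-free)."""

    counts: tuple[tuple[str, int], ...] = ()

    def __init__(self, counts: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        items = dict(counts)
        for name, n in items.items():
            if name not in LOSS_ALPHABET:
                raise ValueError(f"unknown loss symbol {name!r}")
            if n < 0:
                raise ValueError(f"negative count for {name}")
        object.__setattr__(
            self,
            "counts",
            tuple((k, items[k]) for k in LOSS_ALPHABET if items.get(k, 0) > 0),
        )

    def __getitem__(self, name: str) -> int:
        return dict(self.counts).get(name, 0)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    @property
    def total(self) -> int:
        return sum(n for _, n in self.counts)

    @property
    def mass(self) -> float:
        return sum(LOSS_ALPHABET[k][0] * n for k, n in self.counts)

    def __str__(self) -> str:
        return ";".join(f"{k}:{n}" for k, n in self.counts) or "-"


@dataclass(frozen=True)
class CassaneAnnotation:
    """Per-node structural call produced by :func:`annotate_node`."""

    node_id: str
    arm: ArmCall
    substituents: SubstituentMultiset
    formula_candidates: tuple[FormulaCandidate, ...]
    library_match: Optional[str]
    confidence: str  # "high" | "medium" | "flagged"

    @property
    def best_formula(self) -> Optional[FormulaCandidate]:
        return self.formula_candidates[0] if self.formula_candidates else None


@dataclass
class AnnotationConfig:
    delta_tol_da: float = 0.01
    formula_tol_ppm: float = 10.0
    max_generic_h2o: int = 2
    max_generic_co: int = 2
    loss_max_counts: dict[str, int] = field(
        default_factory=lambda: {k: m for k, (_, m) in LOSS_ALPHABET.items()}
    )


# --------------------------------------------------------------------------
# arm classification


def detect_arm_type(s: Spectrum, tol: float = 0.01) -> ArmCall:
    """Classify the C-13 arm from precursor-to-fragment neutral losses.

    All fragment deltas (precursor - fragment m/z) are matched against the
    diagnostic losses within ``tol`` Da.  Ester arms are recognised by
    their amine-containing losses with precedence NME > DME > PAE; the
    amide class (AMD) requires both the H2O and CH3OH losses and the
    absence of any amine-containing ester diagnostic.  The arm cut C3H9NO
    is shared by NME and AMD and is used as NME evidence only when no
    amide signature is present.
    """
    deltas = [s.precursor_mz - p.mz for p in s.peaks if p.mz < s.precursor_mz]

    def find(mass: float):
        best = None
        for d in deltas:
            if abs(d - mass) <= tol and (best is None or abs(d - mass) < abs(best - mass)):
                best = d
        return best

    hits: dict[str, float] = {}
    for name, mass in [
        _ARM_PARTIAL["NME"],
        _ARM_PARTIAL["DME"],
        _ARM_PARTIAL["PAE"],
        ARM_FULL_LOSS["NME"],
        ARM_FULL_LOSS["DME"],
        ARM_FULL_LOSS["PAE"],
        *_AMD_SIGNATURE,
    ]:
        d = find(mass)
        if d is not None:
            hits[name] = d

    def ev(*names: str) -> tuple[tuple[str, float, float], ...]:
        out = []
        masses = dict(
            [_ARM_PARTIAL["NME"], _ARM_PARTIAL["DME"], _ARM_PARTIAL["PAE"]]
            + list(ARM_FULL_LOSS.values())
            + list(_AMD_SIGNATURE)
        )
        for n in names:
            if n in hits:
                out.append((n, hits[n], ppm_error(hits[n], masses[n])))
        return tuple(out)

    amide_signature = "H2O" in hits and "CH3OH" in hits
    if "CH3NH2" in hits:
        return ArmCall("NME", ev("CH3NH2", "C3H9NO"))
    if "C2H7N" in hits or "C4H11NO" in hits:
        return ArmCall("DME", ev("C2H7N", "C4H11NO"))
    if "NH3" in hits or "C2H7NO" in hits:
        return ArmCall("PAE", ev("NH3", "C2H7NO"))
    if amide_signature:
        return ArmCall("AMD", ev("H2O", "CH3OH", "C3H9NO"))
    if "C3H9NO" in hits:
        return ArmCall("NME", ev("C3H9NO"))
    return ArmCall("NONE")


# --------------------------------------------------------------------------
# substituent inference


def _decompose(
    delta: float,
    tol: float,
    max_counts: Mapping[str, int],
) -> list[dict[str, int]]:
    """All multisets over the loss alphabet whose mass explains ``delta``.

    A multiset of n losses is accepted when |delta - mass| <= tol * n
    (the tolerance accumulates along the cascade).  The glucosyl symbol is
    matched at either of its two observed cleavage masses.
    """
    symbols: list[tuple[str, float, int]] = []
    for name, (mass, default_max) in LOSS_ALPHABET.items():
        symbols.append((name, mass, max_counts.get(name, default_max)))
    symbols.append(("glucosyl", GLUCOSYL_ALT_MASS, max_counts.get("glucosyl", 1)))
    # heaviest first prunes the DFS fastest
    symbols.sort(key=lambda t: -t[1])

    out: list[dict[str, int]] = []
    max_losses = sum(m for _, _, m in symbols)

    def dfs(idx: int, remaining: float, n_losses: int, acc: dict[str, int]):
        if n_losses > 0 and abs(remaining) <= tol * n_losses:
            out.append(dict(acc))
            # keep searching: a longer decomposition may also be valid
        if idx == len(symbols) or n_losses >= max_losses:
            return
        name, mass, cap = symbols[idx]
        already = acc.get(name, 0)
        dfs(idx + 1, remaining, n_losses, acc)
        for k in range(1, cap - already + 1):
            rem = remaining - k * mass
            if rem < -tol * (n_losses + k):
                break
            acc[name] = already + k
            dfs(idx + 1, rem, n_losses + k, acc)
        acc[name] = already
        if acc[name] == 0:
            acc.pop(name, None)

    dfs(0, delta, 0, {})
    # deduplicate (glucosyl alt mass can produce the same multiset twice)
    seen, unique = set(), []
    for d in out:
        key = tuple(sorted(d.items()))
        if key not in seen:
            seen.add(key)
            unique.append(d)
    return unique


def _is_submultiset(small: Mapping[str, int], big: Mapping[str, int]) -> bool:
    return all(big.get(k, 0) >= n for k, n in small.items())


def infer_substituents(
    s: Spectrum,
    arm: ArmCall,
    tol: float = 0.01,
    max_counts: Mapping[str, int] | None = None,
) -> SubstituentMultiset:
    """Recover the substituent loss multiset from the cascade below the anchor.

    The anchor A is the full-arm-loss ion (located within ``tol`` of
    precursor - arm mass, or synthesised at that theoretical position).
    Every fragment below A defines a mass difference that is decomposed
    over the loss alphabet; the overall explanation is the decomposition
    of the deepest explainable fragment that accounts for the largest
    number of intermediate fragments (ties: fewest losses, then alphabet
    order), united with the minimal decompositions of any fragment it does
    not cover.  The result is invariant to intensity scaling and to peak
    order.
    """
    if arm.arm_class == "NONE":
        raise ValueError("cannot infer substituents without an arm call")
    max_counts = dict(max_counts or {})
    anchor = s.precursor_mz - arm.full_arm_mass
    observed = [p.mz for p in s.peaks if abs(p.mz - anchor) <= tol]
    if observed:
        anchor = min(observed, key=lambda m: abs(m - anchor))

    deltas = sorted(
        {round(anchor - p.mz, 6) for p in s.peaks if p.mz < anchor - tol},
        reverse=True,
    )
    if not deltas:
        return SubstituentMultiset()

    decomps = {d: _decompose(d, tol, max_counts) for d in deltas}
    explainable = [d for d in deltas if decomps[d]]
    if not explainable:
        return SubstituentMultiset()

    deepest = explainable[0]
    rest = explainable[1:]

    def candidate_key(D: dict[str, int]):
        covered = sum(
            1 for d in rest if any(_is_submultiset(m, D) for m in decomps[d])
        )
        n_losses = sum(D.values())
        return (-covered, n_losses, tuple(sorted(D.items())))

    best = min(decomps[deepest], key=candidate_key)

    result = dict(best)
    for d in rest:
        if any(_is_submultiset(m, result) for m in decomps[d]):
            continue
        minimal = min(decomps[d], key=lambda m: (sum(m.values()), tuple(sorted(m.items()))))
        for k, n in minimal.items():
            result[k] = max(result.get(k, 0), n)
    return SubstituentMultiset(result)


# --------------------------------------------------------------------------
# node annotation and family propagation


def _confidence(candidates: Sequence[FormulaCandidate]) -> str:
    if not candidates:
        return "flagged"
    best = abs(candidates[0].delta_ppm)
    if best <= 5:
        return "high"
    if best <= 15:
        return "medium"
    return "flagged"


def _match_library(
    arm: ArmCall,
    subs: SubstituentMultiset,
    candidates: Sequence[FormulaCandidate],
    rt: float,
    lib,
    config: AnnotationConfig,
) -> Optional[str]:
    formulas = {c.formula for c in candidates}
    scored = []
    for rec in lib:
        if rec.formula not in formulas:
            continue
        if rec.arm != arm.arm_class:
            continue
        total = rec.total_losses
        if any(subs[k] != total[k] for k in STRICT_SUBSTITUENTS):
            continue
        sub = rec.substituents
        if not (sub["hydroxy"] <= subs["hydroxy"] <= sub["hydroxy"] + config.max_generic_h2o):
            continue
        if not (sub["oxo"] <= subs["oxo"] <= sub["oxo"] + config.max_generic_co):
            continue
        dist = abs(subs["hydroxy"] - total["hydroxy"]) + abs(subs["oxo"] - total["oxo"])
        scored.append((dist, abs(rt - rec.rt_min), rec.id))
    if not scored:
        return None
    return min(scored)[2]


def annotate_node(
    s: Spectrum,
    lib=None,
    config: AnnotationConfig | None = None,
) -> CassaneAnnotation:
    """Full structural call for one cleaned spectrum.

    Runs arm classification, substituent inference (only when an arm was
    found), exact-mass formula assignment on the precursor, and matching
    against the annotation library.  A library match requires formula
    equality with the record, an identical arm class, exact agreement on
    the acyl/glucosyl substituents and hydroxy/oxo counts within the
    generic-loss slack; ambiguity is resolved by the closest hydroxy/oxo
    totals, then retention time, then record id.
    """
    config = config or AnnotationConfig()
    arm = detect_arm_type(s, config.delta_tol_da)
    if arm.arm_class != "NONE":
        subs = infer_substituents(s, arm, config.delta_tol_da, config.loss_max_counts)
    else:
        subs = SubstituentMultiset()
    candidates = tuple(assign_formula(s.precursor_mz, config.formula_tol_ppm))
    match = None
    if lib is not None and arm.arm_class != "NONE":
        match = _match_library(arm, subs, candidates, s.rt, lib, config)
    return CassaneAnnotation(
        node_id=s.id,
        arm=arm,
        substituents=subs,
        formula_candidates=candidates,
        library_match=match,
        confidence=_confidence(candidates),
    )


def propagate_family(
    net: MolecularNetwork,
    annotations: Mapping[str, CassaneAnnotation],
) -> dict[str, str]:
    """Flood family labels through network components.

    Every node in a component containing at least one arm-positive
    annotation is labelled ``"cassane-type candidate"``; annotated nodes
    keep their specific label (library id, else arm class).
    """
    labels: dict[str, str] = {}
    for comp in net.components:
        seeds = [
            n for n in comp
            if n in annotations and annotations[n].arm.arm_class != "NONE"
        ]
        if not seeds:
            continue
        for n in comp:
            ann = annotations.get(n)
            if ann is not None and ann.arm.arm_class != "NONE":
                labels[n] = ann.library_match or ann.arm.arm_class
            else:
                labels[n] = "cassane-type candidate"
    return labels


def write_annotation_report(
    annotations: Mapping[str, CassaneAnnotation],
    path: str | Path,
    heavy_mass_threshold: float = 488.0,
) -> None:
    """Write the annotation report TSV (one row per node).

    The ``heavy`` column flags neutral masses >= ``heavy_mass_threshold``
    Da, the operational cut-off under which the larger 3-beta-acyl
    compounds of E. ivorense fall; it is a report convenience, not a
    structural claim.
    """
    with open(path, "w") as fh:
        fh.write(
            "node\tarm\tsubstituents\tbest_formula\tdelta_ppm\t"
            "library_match\tconfidence\theavy\n"
        )
        for node in sorted(annotations):
            a = annotations[node]
            best = a.best_formula
            formula = best.formula.hill() if best else "-"
            delta = f"{abs(best.delta_ppm):.2f}" if best else "-"
            heavy = (
                "yes"
                if best and neutral_mass(best.theoretical_mz) >= heavy_mass_threshold
                else "no"
            )
            fh.write(
                f"{node}\t{a.arm.arm_class}\t{a.substituents}\t{formula}\t"
                f"{delta}\t{a.library_match or '-'}\t{a.confidence}\t{heavy}\n"
            )
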