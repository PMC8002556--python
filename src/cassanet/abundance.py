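"""Per-subgroup abundance profiles of features.

A feature's profile is the vector of its arithmetic mean intensities over
the samples of each subgroup, expressed as integer percentages that sum to
exactly 100 (largest-remainder rounding).  Profiles feed the pie-chart
node attributes of the molecular network export.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .spectra import FeatureTable

__all__ = ["GroupProfile", "group_means", "proportion_profile", "profile_table"]


@dataclass(frozen=True)
class GroupProfile:
    feature_id: str
    group_order: tuple[str, ...]
    means: tuple[float, ...]
    proportions: tuple[int, ...]  # sum to exactly 100; empty if undefined
    dominant: str | None

    @property
    def defined(self) -> bool:
        return bool(self.proportions)

    @property
    def profile_string(self) -> str:
        return "/".join(str(p) for p in self.proportions) if self.defined else "-"


def group_means(table: FeatureTable) -> pd.DataFrame:
    """Arithmetic mean intensity per feature (rows) and group (columns).

    Groups follow first-appearance order of the samples; every group must
    contain at least one sample.
    """
    order = table.group_labels
    empty = sorted(set(table.groups.values()) - set(order))
    if empty:
        raise ValueError(f"group {empty[0]!r} has no samples")
    cols = {}
    for g in order:
        samples = [s for s in table.sample_ids if table.groups[s] == g]
        cols[g] = table.intensities[samples].mean(axis=1)
    return pd.DataFrame(cols)[order]


def largest_remainder(fractions: Sequence[float], total: int = 100) -> list[int]:
    """Round non-negative fractions (summing to 1) to integers summing to
    ``total`` by the largest-remainder (Hamilton) method.

    Ties in remainder are broken by position order: earlier entries
    receive the extra unit first.
    """
    raw = [f * total for f in fractions]
    floors = [int(r) for r in raw]
    shortfall = total - sum(floors)
    remainders = sorted(
        range(len(raw)), key=lambda i: (-(raw[i] - floors[i]), i)
    )
    for i in remainders[:shortfall]:
        floors[i] += 1
    return floors


def proportion_profile(
    feature_id: str,
    means: Sequence[float],
    group_order: Sequence[str],
) -> GroupProfile:
    """Integer percentage profile of one feature's group means.

    All-zero features yield an undefined (flagged) profile; the dominant
    group is the argmax of the means, ties resolved by group order.
    """
    means = [float(m) for m in means]
    if any(m < 0 for m in means):
        raise ValueError("group means must be non-negative")
    total = sum(means)
    if total == 0:
        return GroupProfile(feature_id, tuple(group_order), tuple(means), (), None)
    props = largest_remainder([m / total for m in means])
    dominant = group_order[max(range(len(means)), key=lambda i: (means[i], -i))]
    return GroupProfile(
        feature_id, tuple(group_order), tuple(means), tuple(props), dominant
    )


def profile_table(table: FeatureTable) -> list[GroupProfile]:
    """Profiles for every feature of a quantification table."""
    means = group_means(table)
    order = list(means.columns)
    return [
        proportion_profile(f, means.loc[f].tolist(), order) for f in means.index
    ]


def write_profile_table(profiles: Sequence[GroupProfile], path: str | Path) -> None:
    """Profile TSV: feature, per-group means, a/b/c/d string, dominant."""
    with open(path, "w") as fh:
        if profiles:
            groups = "\t".join(f"mean_{g}" for g in profiles[0].group_order)
            fh.write(f"feature\t{groups}\tprofile\tdominant\n")
        for p in profiles:
            means = "\t".join(f"{m:.2f}" for m in p.means)
            fh.write(f"{p.feature_id}\t{means}\t{p.profile_string}\t{p.dominant or '-'}\n")
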