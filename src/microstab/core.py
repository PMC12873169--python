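"""Prevalence-threshold core microbiota and cross-group core partition.

Presence is abundance strictly above the detection threshold; core
membership is prevalence *at least* the prevalence threshold. Prevalence
is computed over samples pooled per age group, so individuals with more
samples carry more weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .data import AbundanceTable, AgeGroup, DetectionThreshold, GROUP_ORDER

#: default prevalence thresholds: 100%, 80%, 50%
DEFAULT_THRESHOLDS = (1.0, 0.8, 0.5)

#: the seven membership regions of three overlapping cores
PARTITION_REGIONS = ("I", "A", "E", "IA", "IE", "AE", "IAE")


@dataclass(frozen=True)
class PrevalenceProfile:
    """Per-taxon fraction of one group's samples where the taxon is present."""

    age_group: AgeGroup
    prevalence: pd.Series
    n_samples: int
    detection: DetectionThreshold


@dataclass(frozen=True)
class CoreSet:
    """Taxa whose prevalence in one group meets a threshold."""

    age_group: AgeGroup
    prevalence_threshold: float
    detection: DetectionThreshold
    members: pd.Series  # taxon id -> prevalence, members only

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self.members.index)

    def __len__(self) -> int:
        return len(self.members)


def compute_prevalence(
    table: AbundanceTable, group: AgeGroup, detection: DetectionThreshold
) -> PrevalenceProfile:
    """Fraction of the group's samples with abundance > detection, per taxon."""
    sample_ids = [s.sample_id for s in table.samples_of_group(group)]
    if not sample_ids:
        raise ValueError(f"age group {group.value} has no samples")
    present = table.values[sample_ids] > detection.value
    prevalence = present.sum(axis=1) / len(sample_ids)
    return PrevalenceProfile(
        age_group=group,
        prevalence=prevalence,
        n_samples=len(sample_ids),
        detection=detection,
    )


def extract_core(profile: PrevalenceProfile, threshold: float) -> CoreSet:
    """Taxa with prevalence >= threshold ("present in at least" that share)."""
    if not (0 < threshold <= 1):
        raise ValueError(f"prevalence threshold must be in (0, 1], got {threshold}")
    members = profile.prevalence[profile.prevalence >= threshold]
    return CoreSet(
        age_group=profile.age_group,
        prevalence_threshold=threshold,
        detection=profile.detection,
        members=members.sort_index(),
    )


def core_partition(cores: dict[AgeGroup, CoreSet]) -> dict[str, frozenset[str]]:
    """Split three group cores into the 7 exclusive membership regions.

    Region keys are "I", "A", "E" (exclusive to one group), "IA", "IE",
    "AE" (exactly two groups) and "IAE" (all three).
    """
    if set(cores) != set(GROUP_ORDER):
        raise ValueError("core_partition needs exactly one CoreSet per age group")
    thresholds = {c.prevalence_threshold for c in cores.values()}
    detections = {c.detection for c in cores.values()}
    if len(thresholds) != 1:
        raise ValueError(f"mismatched prevalence thresholds: {sorted(thresholds)}")
    if len(detections) != 1:
        raise ValueError("mismatched detection thresholds")
    sets = {g.value: cores[g].taxa for g in GROUP_ORDER}
    regions: dict[str, frozenset[str]] = {}
    for region in PARTITION_REGIONS:
        inside = frozenset.intersection(*(sets[g] for g in region))
        outside = frozenset().union(
            *(sets[g] for g in "IAE" if g not in region)
        )
        regions[region] = inside - outside
    return regions


def core_analysis(
    table: AbundanceTable,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    detection: DetectionThreshold = DetectionThreshold(),
) -> tuple[dict[tuple[AgeGroup, float], CoreSet], dict[float, dict[str, frozenset[str]]]]:
    """All cores (group x threshold) plus the partition at each threshold."""
    profiles = {g: compute_prevalence(table, g, detection) for g in GROUP_ORDER}
    cores = {
        (g, th): extract_core(profiles[g], th)
        for g in GROUP_ORDER
        for th in thresholds
    }
    partitions = {
        th: core_partition({g: cores[(g, th)] for g in GROUP_ORDER})
        for th in thresholds
    }
    return cores, partitions


def core_table(core: CoreSet) -> pd.DataFrame:
    return pd.DataFrame(
        {"taxon_id": core.members.index, "prevalence": core.members.values}
    )


def partition_table(partition: dict[str, frozenset[str]]) -> pd.DataFrame:
    rows = [
        {"region": region, "n_taxa": len(taxa), "taxa": ",".join(sorted(taxa))}
        for region, taxa in partition.items()
    ]
    return pd.DataFrame(rows)
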