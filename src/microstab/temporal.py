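"""Within-individual Jaccard decay and the Jaccard core index.

Jaccard similarity is computed on presence sets (abundance strictly above
the detection threshold) between samples of the *same* individual only,
binned by time gap in 60-day windows. The Jaccard core index compares one
sample's presence set against a fixed 50%-prevalence reference core:

    JCI = |C n S| / (|C| + |S| - |C n S|)

which is the plain Jaccard index of the two sets.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import AbundanceTable, AgeGroup, DetectionThreshold, GROUP_ORDER
from .core import CoreSet

logger = logging.getLogger("microstab")

DEFAULT_BIN_WIDTH = 60


@dataclass(frozen=True)
class JaccardPair:
    """Jaccard similarity between two samples of one individual."""

    individual_id: str
    sample_a: str
    sample_b: str
    day_gap: int
    J: float


@dataclass(frozen=True)
class JaccardCoreIndex:
    """One sample's similarity to a fixed reference core."""

    sample_id: str
    reference_group: AgeGroup
    JCI: float
    subject_age_years: float
    sample_group: AgeGroup


def _presence_set(column: pd.Series, detection: DetectionThreshold) -> frozenset[str]:
    return frozenset(column.index[column > detection.value])


def jaccard_presence(
    sample_a: pd.Series, sample_b: pd.Series, detection: DetectionThreshold
) -> float:
    """|A n B| / |A u B| on presence sets; 1.0 (with a warning) if both empty."""
    a = _presence_set(sample_a, detection)
    b = _presence_set(sample_b, detection)
    union = a | b
    if not union:
        logger.warning("Jaccard of two empty presence sets defined as 1.0")
        return 1.0
    return len(a & b) / len(union)


def pairwise_within_individual(
    table: AbundanceTable, detection: DetectionThreshold
) -> list[JaccardPair]:
    """All unordered within-individual sample pairs; no cross-individual pairs."""
    pairs: list[JaccardPair] = []
    for ind in table.individuals():
        samples = table.samples_of_individual(ind)
        for sa, sb in itertools.combinations(samples, 2):
            pairs.append(
                JaccardPair(
                    individual_id=ind,
                    sample_a=sa.sample_id,
                    sample_b=sb.sample_id,
                    day_gap=abs(sb.collection_day - sa.collection_day),
                    J=jaccard_presence(
                        table.column(sa.sample_id), table.column(sb.sample_id), detection
                    ),
                )
            )
    return pairs


def bin_series(pairs: list[JaccardPair], width: int = DEFAULT_BIN_WIDTH) -> pd.DataFrame:
    """Mean/sd of J per half-open gap bin [k*width, (k+1)*width).

    The representative gap is the bin midpoint; the sd is the n-1 sample
    standard deviation, missing (NaN) for single-pair bins.
    """
    if width < 1:
        raise ValueError(f"bin width must be >= 1, got {width}")
    if not pairs:
        return pd.DataFrame(
            columns=["bin", "gap_days", "mean_J", "sd_J", "n_pairs"]
        ).astype({"bin": int, "n_pairs": int})
    df = pd.DataFrame({"gap": [p.day_gap for p in pairs], "J": [p.J for p in pairs]})
    df["bin"] = df["gap"] // width
    grouped = df.groupby("bin")["J"]
    out = pd.DataFrame(
        {
            "bin": grouped.mean().index,
            "gap_days": grouped.mean().index * width + width / 2,
            "mean_J": grouped.mean().values,
            "sd_J": grouped.std(ddof=1).values,
            "n_pairs": grouped.size().values,
        }
    ).reset_index(drop=True)
    return out


def jaccard_core_index(
    sample: pd.Series,
    core: CoreSet,
    detection: DetectionThreshold,
) -> float:
    """(common taxa) / (core taxa + sample taxa - common taxa) against a fixed core."""
    if len(core) == 0:
        raise ValueError("reference core is empty; JCI undefined")
    c = core.taxa
    s = _presence_set(sample, detection)
    common = len(c & s)
    return common / (len(c) + len(s) - common)


def jci_age_trajectory(
    table: AbundanceTable,
    cores: dict[AgeGroup, CoreSet],
    detection: DetectionThreshold,
) -> list[JaccardCoreIndex]:
    """One JCI per (sample, reference group), paired with subject age."""
    missing = [
        s.sample_id for s in table.samples if not np.isfinite(s.subject_age_years)
    ]
    if missing:
        raise ValueError(f"samples missing subject age: {missing}")
    if not cores:
        raise ValueError("at least one reference core is required")
    records: list[JaccardCoreIndex] = []
    for ref_group in (g for g in GROUP_ORDER if g in cores):
        core = cores[ref_group]
        for s in table.samples:
            records.append(
                JaccardCoreIndex(
                    sample_id=s.sample_id,
                    reference_group=ref_group,
                    JCI=jaccard_core_index(table.column(s.sample_id), core, detection),
                    subject_age_years=s.subject_age_years,
                    sample_group=s.age_group,
                )
            )
    return records


def pairs_table(pairs: list[JaccardPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": [p.individual_id for p in pairs],
            "sample_a": [p.sample_a for p in pairs],
            "sample_b": [p.sample_b for p in pairs],
            "day_gap": [p.day_gap for p in pairs],
            "jaccard": [p.J for p in pairs],
        }
    )


def jci_table(records: list[JaccardCoreIndex]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "sample_group": [r.sample_group.value for r in records],
            "reference_group": [r.reference_group.value for r in records],
            "subject_age_years": [r.subject_age_years for r in records],
            "jci": [r.JCI for r in records],
        }
    )
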