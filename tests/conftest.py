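import numpy as np
import pandas as pd
import pytest

from microstab.data import (
    AbundanceTable,
    AgeGroup,
    DetectionThreshold,
    PathwayMap,
    SampleRecord,
)
from microstab.robustness import GenomeContent


def make_table(values: dict[str, list[float]], taxa: list[str], meta=None) -> AbundanceTable:
    """Tiny AbundanceTable from explicit columns; default metadata is one
    individual per group with sequential days."""
    df = pd.DataFrame(values, index=pd.Index(taxa, name="taxon_id"))
    if meta is None:
        meta = []
        for i, sid in enumerate(df.columns):
            meta.append(
                SampleRecord(
                    sample_id=sid,
                    individual_id=f"X{i:02d}",
                    age_group=AgeGroup.A,
                    collection_day=0,
                    subject_age_years=30.0,
                )
            )
    return AbundanceTable(df, meta)


@pytest.fixture
def detection() -> DetectionThreshold:
    return DetectionThreshold(1e-4)


@pytest.fixture
def small_cohort():
    from microstab.simulate import CohortConfig, generate_cohort

    return generate_cohort(
        CohortConfig(n_individuals_per_group=3, n_taxa=25, n_timepoints=5, seed=11)
    )


@pytest.fixture
def identity_content() -> GenomeContent:
    n = 10
    taxa = [f"g{i}" for i in range(n)]
    fns = [f"K{i}" for i in range(n)]
    cn = pd.DataFrame(np.eye(n), index=pd.Index(taxa, name="taxon_id"), columns=fns)
    pmap = PathwayMap(
        pd.DataFrame(
            {
                "function_id": fns,
                "pathway_id": ["P1"] * 5 + ["P2"] * 5,
                "superpathway_id": ["SP1"] * 5 + ["SP2"] * 5,
            }
        )
    )
    return GenomeContent(cn, pd.Series(1, index=cn.index), pmap)


@pytest.fixture
def uniform_abundance(identity_content) -> pd.Series:
    n = len(identity_content.taxa)
    return pd.Series(np.full(n, 1.0 / n), index=identity_content.copy_numbers.index)
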