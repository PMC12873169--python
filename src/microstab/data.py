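"""Shared data types and tabular I/O.

All tables are tab-separated UTF-8 with "." decimal; numbers are written
with 10 significant digits so that a written table re-reads bit-exactly.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("microstab")

#: significant digits used for every serialized float
FLOAT_FMT = "%.10g"

COLUMN_SUM_TOL = 1e-9
RENORM_TOL = 1e-6


class AgeGroup(str, enum.Enum):
    """Cohort age group: Infant, Adult, Elder."""

    I = "I"
    A = "A"
    E = "E"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: canonical group order used everywhere (Infant, Adult, Elder)
GROUP_ORDER: tuple[AgeGroup, ...] = (AgeGroup.I, AgeGroup.A, AgeGroup.E)


@dataclass(frozen=True)
class SampleRecord:
    """One longitudinal sample of one individual.

    ``collection_day`` is days since that individual's first sample
    (re-based to 0 on ingest); ``subject_age_years`` is the subject's age
    at collection.
    """

    sample_id: str
    individual_id: str
    age_group: AgeGroup
    collection_day: int
    subject_age_years: float

    def __post_init__(self) -> None:
        if self.collection_day < 0:
            raise ValueError(
                f"sample {self.sample_id}: collection_day must be >= 0, "
                f"got {self.collection_day}"
            )


@dataclass(frozen=True)
class DetectionThreshold:
    """Relative-abundance cutoff; a taxon is present iff abundance > value."""

    value: float = 1e-4

    def __post_init__(self) -> None:
        if not (0 <= self.value < 1):
            raise ValueError(f"detection threshold must be in [0, 1), got {self.value}")


class PathwayMap:
    """Two-level grouping of functions: function -> pathway -> superpathway."""

    def __init__(self, entries: pd.DataFrame) -> None:
        required = ["function_id", "pathway_id", "superpathway_id"]
        missing = [c for c in required if c not in entries.columns]
        if missing:
            raise ValueError(f"pathway map missing columns: {missing}")
        entries = entries[required].astype(str).reset_index(drop=True)
        if entries["function_id"].duplicated().any():
            dup = entries.loc[entries["function_id"].duplicated(), "function_id"].iloc[0]
            raise ValueError(f"function {dup!r} mapped to more than one pathway")
        sp_per_pw = entries.groupby("pathway_id")["superpathway_id"].nunique()
        bad = sp_per_pw[sp_per_pw > 1]
        if len(bad):
            raise ValueError(
                f"pathway {bad.index[0]!r} mapped to more than one superpathway"
            )
        self.entries = entries
        self.function_to_pathway: dict[str, str] = dict(
            zip(entries["function_id"], entries["pathway_id"])
        )
        self.pathway_to_superpathway: dict[str, str] = dict(
            zip(entries["pathway_id"], entries["superpathway_id"])
        )

    @property
    def functions(self) -> list[str]:
        return list(self.entries["function_id"])

    @property
    def pathways(self) -> list[str]:
        return list(dict.fromkeys(self.entries["pathway_id"]))

    @property
    def superpathways(self) -> list[str]:
        return list(dict.fromkeys(self.entries["superpathway_id"]))

    def functions_in(self, level: str, scope_id: str) -> list[str]:
        """Function ids belonging to one pathway or superpathway."""
        if level == "pathway":
            mask = self.entries["pathway_id"] == scope_id
        elif level == "superpathway":
            mask = self.entries["superpathway_id"] == scope_id
        else:
            raise ValueError(f"unknown level {level!r}")
        return list(self.entries.loc[mask, "function_id"])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PathwayMap) and self.entries.equals(other.entries)


class AbundanceTable:
    """Relative-abundance matrix (taxa x samples) joined to sample metadata.

    ``values`` is a DataFrame indexed by taxon id with one column per
    sample id; every entry is in [0, 1] and each column sums to 1 (unless
    constructed with ``normalize=False``, used only by the noiseless
    simulator mode for exact-moment oracles).
    """

    def __init__(
        self,
        values: pd.DataFrame,
        samples: Sequence[SampleRecord],
        *,
        normalize: bool = True,
    ) -> None:
        values = values.astype(float)
        if values.index.duplicated().any():
            raise ValueError("duplicate taxon ids")
        if values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        sample_ids = [s.sample_id for s in samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids in metadata")
        missing = [c for c in values.columns if c not in set(sample_ids)]
        if missing:
            raise ValueError(f"no metadata for sample(s): {missing}")
        # order metadata to match the value columns
        by_id = {s.sample_id: s for s in samples}
        samples = [by_id[c] for c in values.columns]
        if (values.values < 0).any():
            taxon, sample = np.argwhere(values.values < 0)[0]
            raise ValueError(
                f"negative abundance for taxon {values.index[taxon]!r} "
                f"in sample {values.columns[sample]!r}"
            )
        groups_per_ind = pd.Series(
            [s.age_group for s in samples], index=[s.individual_id for s in samples]
        )
        n_groups = groups_per_ind.groupby(level=0).nunique()
        if (n_groups > 1).any():
            bad = n_groups[n_groups > 1].index[0]
            raise ValueError(f"individual {bad!r} appears in more than one age group")
        if normalize:
            sums = values.sum(axis=0)
            if (sums <= 0).any():
                bad = sums.index[sums <= 0][0]
                raise ValueError(f"sample {bad!r} has zero total abundance")
            off = sums[(sums - 1.0).abs() > RENORM_TOL]
            if len(off):
                logger.warning(
                    "renormalizing %d sample column(s) not summing to 1: %s",
                    len(off),
                    list(off.index[:5]),
                )
            values = values / sums
        self.values = values
        self.samples: list[SampleRecord] = list(samples)
        self._by_id = {s.sample_id: s for s in self.samples}

    # -- accessors ---------------------------------------------------------

    @property
    def taxa(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def metadata(self) -> pd.DataFrame:
        """Sample metadata as a DataFrame indexed by sample id."""
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "individual_id": [s.individual_id for s in self.samples],
                "age_group": [s.age_group.value for s in self.samples],
                "collection_day": [s.collection_day for s in self.samples],
                "subject_age_years": [s.subject_age_years for s in self.samples],
            }
        ).set_index("sample_id", drop=False)

    def sample(self, sample_id: str) -> SampleRecord:
        return self._by_id[sample_id]

    def column(self, sample_id: str) -> pd.Series:
        return self.values[sample_id]

    def individuals(self) -> list[str]:
        return list(dict.fromkeys(s.individual_id for s in self.samples))

    def samples_of_group(self, group: AgeGroup) -> list[SampleRecord]:
        return [s for s in self.samples if s.age_group == group]

    def samples_of_individual(self, individual_id: str) -> list[SampleRecord]:
        recs = [s for s in self.samples if s.individual_id == individual_id]
        return sorted(recs, key=lambda s: s.collection_day)

    def presence(self, detection: DetectionThreshold) -> pd.DataFrame:
        """Boolean taxa x samples matrix: abundance strictly above detection."""
        return self.values > detection.value

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, AbundanceTable)
            and self.values.equals(other.values)
            and self.samples == other.samples
        )


# ---------------------------------------------------------------------------
# readers / writers


def read_metadata(path: str | os.PathLike) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = [
        "sample_id",
        "individual_id",
        "age_group",
        "collection_day",
        "subject_age_years",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    # re-base collection days to first sample = 0 per individual
    day = df["collection_day"].astype(float)
    base = day.groupby(df["individual_id"]).transform("min")
    rebased = (day - base).round().astype(int)
    records = [
        SampleRecord(
            sample_id=row.sample_id,
            individual_id=row.individual_id,
            age_group=AgeGroup(row.age_group),
            collection_day=int(d),
            subject_age_years=float(row.subject_age_years),
        )
        for row, d in zip(df.itertuples(index=False), rebased)
    ]
    return records


def read_abundance_table(
    path: str | os.PathLike, metadata_path: str | os.PathLike
) -> AbundanceTable:
    """Read a taxa-rows x sample-columns TSV plus its sample metadata TSV.

    Columns whose sum deviates from 1 by more than 1e-6 are renormalized
    with a logged warning; a sample column without a metadata row, or any
    negative abundance, is a hard error.
    """
    df = pd.read_csv(path, sep="\t", index_col="taxon_id")
    records = read_metadata(metadata_path)
    known = {r.sample_id for r in records}
    orphans = [c for c in df.columns if c not in known]
    if orphans:
        raise ValueError(f"no metadata for sample(s): {orphans}")
    records = [r for r in records if r.sample_id in set(df.columns)]
    return AbundanceTable(df, records)


def _format_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Render every float with FLOAT_FMT so round-trips are bit-exact."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: FLOAT_FMT % v if pd.notna(v) else "")
    return out


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, *, index: bool = False) -> None:
    if index:
        df = df.reset_index()
    _format_frame(df).to_csv(path, sep="\t", index=False)


def write_abundance_table(
    table: AbundanceTable, abundance_path: str | os.PathLike, metadata_path: str | os.PathLike
) -> None:
    values = table.values.copy()
    values.index.name = "taxon_id"
    write_tsv(values, abundance_path, index=True)
    write_tsv(table.metadata.reset_index(drop=True), metadata_path)


def read_genome_content(
    content_path: str | os.PathLike,
    rrn_path: str | os.PathLike,
    pathway_path: str | os.PathLike,
):
    """Read copy-number matrix, 16S copy numbers, and the pathway map.

    Returns a :class:`microstab.robustness.GenomeContent`. Declared here so
    the CLI has a single I/O entry point; the type lives with its algorithms.
    """
    from .robustness import GenomeContent

    copy_numbers = pd.read_csv(content_path, sep="\t", index_col="taxon_id")
    rrn_df = pd.read_csv(rrn_path, sep="\t", index_col="taxon_id")
    if "rrn_copies" not in rrn_df.columns:
        raise ValueError("rrn table must have a 'rrn_copies' column")
    pmap = PathwayMap(pd.read_csv(pathway_path, sep="\t", dtype=str))
    return GenomeContent(copy_numbers, rrn_df["rrn_copies"].astype(int), pmap)


# ---------------------------------------------------------------------------
# result serialization + manifest


def _versions() -> dict[str, str]:
    import importlib.metadata as im
    import scipy

    return {
        "microstab": im.version("microstab"),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }


def write_result_tables(
    results: Mapping[str, pd.DataFrame],
    out_dir: str | os.PathLike,
    *,
    config: Mapping | None = None,
    seed: int | None = None,
) -> list[str]:
    """Write one TSV per named result plus a JSON run manifest.

    ``results`` maps a file stem (e.g. ``"core_I_p100"``) to a DataFrame.
    Returns the written paths (manifest last). Re-reading a written table
    reproduces it bit-exactly thanks to the fixed float format.
    """
    out_dir = os.fspath(out_dir)
    try:
        os.makedirs(out_dir, exist_ok=True)
        probe = os.path.join(out_dir, ".write_probe")
        with open(probe, "w"):
            pass
        os.remove(probe)
    except OSError as exc:
        raise OSError(f"output directory {out_dir!r} is not writable: {exc}") from exc
    paths: list[str] = []
    for stem, df in results.items():
        path = os.path.join(out_dir, f"{stem}.tsv")
        write_tsv(df, path)
        paths.append(path)
    manifest = {
        "tables": sorted(os.path.basename(p) for p in paths),
        "config": _jsonable(config) if config is not None else None,
        "seed": seed,
        "versions": _versions(),
    }
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths.append(manifest_path)
    return paths


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
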