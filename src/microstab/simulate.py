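"""Synthetic longitudinal cohorts and genome-content tables.

The cohort generator produces genus-level relative-abundance time series
whose per-taxon temporal fluctuations follow the power law
``sigma^2 = V * mu^(2*beta)``, with a core/transient prevalence structure
and irregular per-individual sampling days. A noiseless mode emits series
whose sample moments satisfy the law exactly, for estimator oracles.

Fluctuations are drawn from a gamma distribution with mean ``mu`` and
variance ``V * mu^(2*beta)``: unlike a zero-truncated normal, a gamma can
realize sd/mean ratios above 1, which the law demands at low abundances.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    AbundanceTable,
    AgeGroup,
    DetectionThreshold,
    GROUP_ORDER,
    PathwayMap,
    SampleRecord,
)

#: subject age ranges (years) at enrolment per group
AGE_RANGES: dict[AgeGroup, tuple[float, float]] = {
    AgeGroup.I: (2.0, 5.0),
    AgeGroup.A: (27.0, 44.0),
    AgeGroup.E: (69.0, 81.0),
}


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the longitudinal cohort generator."""

    n_individuals_per_group: int = 10
    n_timepoints: int = 8
    interval_days_mean: float = 75.0
    interval_days_sd: float = 25.0
    n_taxa: int = 60
    core_fraction: float = 0.5
    taylor_V: float = 0.3
    taylor_beta: float = 0.75
    group_prevalence_trend: float = 0.1
    detection: DetectionThreshold = field(default_factory=DetectionThreshold)
    seed: int = 0
    # secondary knobs
    mu_log_sigma: float = 1.0
    core_detection_prob: float = 0.98
    transient_detection_prob: float = 0.45
    min_timepoints: int | None = None
    noiseless: bool = False

    def __post_init__(self) -> None:
        if not (0.5 <= self.taylor_beta <= 1.0):
            raise ValueError(f"taylor_beta must be in [0.5, 1], got {self.taylor_beta}")
        if self.taylor_V <= 0:
            raise ValueError(f"taylor_V must be > 0, got {self.taylor_V}")
        if not (0 <= self.core_fraction <= 1):
            raise ValueError(f"core_fraction must be in [0, 1], got {self.core_fraction}")
        if self.interval_days_mean <= 0 or self.interval_days_sd <= 0:
            raise ValueError("interval day parameters must be positive")
        if self.n_individuals_per_group < 1 or self.n_timepoints < 2 or self.n_taxa < 1:
            raise ValueError("cohort dimensions out of range")


@dataclass(frozen=True)
class GenomeContentConfig:
    """Knobs of the genome-content generator."""

    n_taxa: int = 60
    n_functions: int = 200
    redundancy: float = 0.5
    rrn_min: int = 1
    rrn_max: int = 15
    n_pathways: int = 20
    n_superpathways: int = 5
    copy_number_max: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.redundancy <= 1):
            raise ValueError(f"redundancy must be in [0, 1], got {self.redundancy}")
        if self.rrn_min < 1 or self.rrn_max < self.rrn_min:
            raise ValueError("rrn bounds out of range")
        if self.n_functions < self.n_pathways:
            raise ValueError("n_functions must be >= n_pathways")
        if self.n_pathways < self.n_superpathways:
            raise ValueError("n_pathways must be >= n_superpathways")


def _taxon_ids(n: int) -> list[str]:
    return [f"g{i + 1:04d}" for i in range(n)]


def _sampling_days(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    intervals = np.maximum(1, np.rint(rng.normal(mean, sd, size=n - 1))).astype(int)
    return np.concatenate([[0], np.cumsum(intervals)])


def _noiseless_series(mu: np.ndarray, sigma: np.ndarray, n_t: int) -> np.ndarray:
    """Deterministic taxa x time matrix whose sample moments are exact.

    Each taxon takes a high value at one (staggered) time point and a low
    value elsewhere, chosen so the temporal mean is exactly mu and the
    n-1 sample standard deviation exactly sigma. Unlike an alternating
    +/-sigma pattern this stays non-negative for sd/mean ratios up to
    sqrt(n_t), which the power law demands at low abundances; it needs
    mu >= sigma / sqrt(n_t) (see :func:`_floor_means`).
    """
    low = mu - sigma / np.sqrt(n_t)
    high = mu + sigma * (n_t - 1) / np.sqrt(n_t)
    if (low < 0).any():
        raise ValueError(
            "noiseless series infeasible: sd/mean exceeds sqrt(n_timepoints)"
        )
    series = np.tile(low[:, None], (1, n_t))
    spike_t = np.arange(mu.size) % n_t
    series[np.arange(mu.size), spike_t] = high
    return series


def _floor_means(
    mu: np.ndarray, v: float, beta: float, n_t: int
) -> np.ndarray:
    """Raise tiny means to the noiseless-feasibility floor, keeping sum 1.

    Feasibility requires mu >= sqrt(V) * mu^beta / sqrt(n_t), i.e.
    mu >= (V / n_t)^(1 / (2 - 2 beta)) for beta < 1. Floored taxa take the
    floor; the rest are scaled down to preserve the unit sum (iterated, as
    the rescaling can push new taxa under the floor).
    """
    if beta >= 1.0:
        if v > n_t:
            raise ValueError("noiseless mode with beta = 1 requires V <= n_timepoints")
        return mu
    mu_min = (v / n_t) ** (1.0 / (2.0 - 2.0 * beta)) * 1.000001
    if mu_min * mu.size >= 1.0:
        raise ValueError(
            "noiseless mode infeasible: too many taxa for this V and beta"
        )
    mu = mu.copy()
    for _ in range(mu.size + 1):
        low = mu < mu_min
        if not low.any():
            return mu
        mu[low] = mu_min
        free = ~low
        budget = 1.0 - mu_min * low.sum()
        mu[free] *= budget / mu[free].sum()
    return mu  # pragma: no cover - loop always terminates earlier


#: standardize-clip sweeps in the stochastic sampler (see _stochastic_series)
_MOMENT_ITERS = 8


def _stochastic_series(
    mu: np.ndarray,
    sigma: np.ndarray,
    n_t: int,
    rng: np.random.Generator,
    floor: float = 0.0,
) -> np.ndarray:
    """Random taxa x time fluctuations honoring sigma^2 = V * mu^(2*beta).

    Draws come from a gamma with the designed mean and sd (a gamma, unlike
    a zero-truncated normal, realizes sd/mean > 1, which the law forces at
    low abundances), stratified over time (one draw per quantile slice, in
    random order) so short series sample the whole distribution. Each row
    is then affinely re-standardized to the designed (mu, sigma) and
    clipped at zero, iterated a few times: with 8 time points the naive
    log-moment regression is otherwise dominated by small-sample bias of
    the sample sd, not by the designed law.
    """
    from scipy import stats as sps

    shape = (mu / sigma) ** 2
    scale = sigma**2 / mu
    n_taxa = mu.size
    strata = rng.permuted(np.tile(np.arange(n_t), (n_taxa, 1)), axis=1)
    u = (strata + rng.random((n_taxa, n_t))) / n_t
    x = sps.gamma.ppf(u, shape[:, None], scale=scale[:, None])
    for _ in range(_MOMENT_ITERS):
        m = x.mean(axis=1, keepdims=True)
        s = x.std(axis=1, ddof=1, keepdims=True)
        live = s[:, 0] > 0
        x[live] = mu[live, None] + (x[live] - m[live]) * (
            sigma[live, None] / s[live]
        )
        np.clip(x, floor, None, out=x)
    return x


def generate_cohort(config: CohortConfig) -> AbundanceTable:
    """Simulate a three-age-group longitudinal cohort.

    Per individual: sampling days start at 0 and advance by positive
    jittered intervals; subject-level mean abundances are drawn
    log-normally and closed to sum 1; each time point draws every taxon
    with sd ``sqrt(V) * mu^beta`` around its mean, applies the
    core/transient detection structure, and renormalizes the column.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_core = int(round(config.core_fraction * config.n_taxa))
    taxa = _taxon_ids(config.n_taxa)
    lo_t = config.min_timepoints or config.n_timepoints

    columns: dict[str, np.ndarray] = {}
    records: list[SampleRecord] = []
    for g_index, group in enumerate(GROUP_ORDER):
        p_core = config.core_detection_prob
        p_trans = float(
            np.clip(
                config.transient_detection_prob
                + config.group_prevalence_trend * g_index,
                0.0,
                1.0,
            )
        )
        detect_prob = np.where(np.arange(config.n_taxa) < n_core, p_core, p_trans)
        for i in range(config.n_individuals_per_group):
            ind_id = f"{group.value}{i + 1:02d}"
            n_t = int(rng.integers(lo_t, config.n_timepoints + 1))
            days = _sampling_days(
                rng, n_t, config.interval_days_mean, config.interval_days_sd
            )
            age0 = rng.uniform(*AGE_RANGES[group])
            mu = rng.lognormal(0.0, config.mu_log_sigma, size=config.n_taxa)
            mu /= mu.sum()
            if config.noiseless:
                mu = _floor_means(mu, config.taylor_V, config.taylor_beta, n_t)
            sigma = np.sqrt(config.taylor_V) * mu**config.taylor_beta

            if config.noiseless:
                series = _noiseless_series(mu, sigma, n_t)
            else:
                floor = 2.0 * config.detection.value
                series = _stochastic_series(mu, sigma, n_t, rng, floor=floor)
                detected = (
                    rng.random(size=(config.n_taxa, n_t)) < detect_prob[:, None]
                )
                series = np.where(detected, series, 0.0)
                sums = series.sum(axis=0)
                if (sums <= 0).any():  # pragma: no cover - wholly empty column
                    empty = sums <= 0
                    series[:, empty] = mu[:, None]
                    sums = series.sum(axis=0)
                series = series / sums

            for t, day in enumerate(days):
                sample_id = f"{ind_id}T{t + 1}"
                columns[sample_id] = series[:, t]
                records.append(
                    SampleRecord(
                        sample_id=sample_id,
                        individual_id=ind_id,
                        age_group=group,
                        collection_day=int(day),
                        subject_age_years=round(age0 + day / 365.25, 4),
                    )
                )

    values = pd.DataFrame(columns, index=pd.Index(taxa, name="taxon_id"))
    return AbundanceTable(values, records, normalize=not config.noiseless)


def generate_genome_content(config: GenomeContentConfig):
    """Simulate a PICRUSt2-style genome-content bundle.

    Each function is either *shared* (same copy number in every taxon) or
    *private* (carried by exactly one owner taxon); the shared fraction is
    the ``redundancy`` knob, so redundancy 1 gives identical genome rows
    and redundancy 0 gives pairwise-disjoint function sets (when
    ``n_taxa <= n_functions``). Functions are partitioned into pathways,
    pathways into superpathways.
    """
    from .robustness import GenomeContent

    rng = np.random.default_rng(config.seed)
    taxa = _taxon_ids(config.n_taxa)
    functions = [f"K{j + 1:05d}" for j in range(config.n_functions)]

    n_shared = int(round(config.redundancy * config.n_functions))
    order = rng.permutation(config.n_functions)
    shared = np.zeros(config.n_functions, dtype=bool)
    shared[order[:n_shared]] = True
    owners = np.arange(config.n_functions) % config.n_taxa
    copies = rng.integers(1, config.copy_number_max + 1, size=config.n_functions)

    matrix = np.zeros((config.n_taxa, config.n_functions), dtype=int)
    matrix[:, shared] = copies[shared][None, :]
    private = np.flatnonzero(~shared)
    matrix[owners[private], private] = copies[private]

    rrn = rng.integers(config.rrn_min, config.rrn_max + 1, size=config.n_taxa)

    pw_of_fn = np.arange(config.n_functions) * config.n_pathways // config.n_functions
    sp_of_pw = (
        np.arange(config.n_pathways) * config.n_superpathways // config.n_pathways
    )
    entries = pd.DataFrame(
        {
            "function_id": functions,
            "pathway_id": [f"P{p + 1:03d}" for p in pw_of_fn],
            "superpathway_id": [f"SP{sp_of_pw[p] + 1:02d}" for p in pw_of_fn],
        }
    )
    copy_numbers = pd.DataFrame(
        matrix, index=pd.Index(taxa, name="taxon_id"), columns=functions
    )
    return GenomeContent(
        copy_numbers,
        pd.Series(rrn, index=copy_numbers.index, name="rrn_copies"),
        PathwayMap(entries),
    )


def config_to_dict(config) -> dict:
    d = dataclasses.asdict(config)
    if isinstance(d.get("detection"), dict):
        d["detection"] = d["detection"]["value"]
    return d


def cohort_config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    if "detection" in d and not isinstance(d["detection"], DetectionThreshold):
        d["detection"] = DetectionThreshold(float(d["detection"]))
    return CohortConfig(**d)
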