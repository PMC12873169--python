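"""Per-individual Taylor's-power-law stability parameters.

For each individual, the mean ``mu`` and n-1 standard deviation ``sigma``
of every taxon's relative abundance over that individual's time points
are regressed as ``log10 sigma = beta * log10 mu + intercept`` (OLS), so
the power-law index ``beta`` is the slope and the fluctuation amplitude
``V = 10^(2 * intercept)`` satisfies ``sigma^2 = V * mu^(2*beta)``: a
hypothetical dominant taxon at mu = 1 has variance V. beta = 1/2 is the
Poisson-like limit, beta = 1 the exponential-like limit.

Fits are compared across age groups after standardizing (log10 V, beta)
to the reference (Adult) group; the "healthy window" is the circle
holding probability p of a standard bivariate normal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import AbundanceTable, AgeGroup

logger = logging.getLogger("microstab")

MIN_TAXA_FIT = 3


@dataclass(frozen=True)
class TaxonMoments:
    """Per-taxon temporal mean/sd for one individual (zeroes included)."""

    individual_id: str
    age_group: AgeGroup
    mu: pd.Series
    sigma: pd.Series
    n_timepoints: int


@dataclass(frozen=True)
class TaylorFit:
    individual_id: str
    age_group: AgeGroup
    V: float
    beta: float
    se_logV: float
    se_beta: float
    r2: float
    n_taxa_fit: int
    n_timepoints: int

    @property
    def log10_V(self) -> float:
        return math.log10(self.V)

    @property
    def low_confidence(self) -> bool:
        """Flagged when fitted from only two time points."""
        return self.n_timepoints < 3


@dataclass(frozen=True)
class StandardizedTaylorSpace:
    """Per-individual (log10 V, beta) in reference-group sd units."""

    reference_group: AgeGroup
    ref_mean_logV: float
    ref_sd_logV: float
    ref_mean_beta: float
    ref_sd_beta: float
    coords: pd.DataFrame  # individual_id, age_group, z_V, z_beta, se_z_V, se_z_beta


def taxon_moments(table: AbundanceTable, individual_id: str) -> TaxonMoments:
    """Temporal mean and n-1 sd per taxon over one individual's samples.

    Zero observations count for taxa seen at least once; taxa never
    observed in this individual are dropped.
    """
    samples = table.samples_of_individual(individual_id)
    if len(samples) < 2:
        raise ValueError(
            f"individual {individual_id!r} has {len(samples)} sample(s); need >= 2"
        )
    sub = table.values[[s.sample_id for s in samples]]
    seen = (sub > 0).any(axis=1)
    sub = sub.loc[seen]
    return TaxonMoments(
        individual_id=individual_id,
        age_group=samples[0].age_group,
        mu=sub.mean(axis=1),
        sigma=sub.std(axis=1, ddof=1),
        n_timepoints=len(samples),
    )


def fit_taylor(moments: TaxonMoments, *, regress_variance: bool = False) -> TaylorFit:
    """OLS of log10 sigma on log10 mu; beta = slope, V = 10^(2*intercept).

    With ``regress_variance=True`` the regression runs on log10 sigma^2
    instead (slope = 2*beta, intercept = log10 V); both parameterizations
    give identical estimates, the sd form is the reference because it puts
    beta directly on the 1/2 (Poisson-like) to 1 (exponential-like) scale.
    """
    usable = (moments.mu > 0) & (moments.sigma > 0)
    n_constant = int((moments.sigma == 0).sum())
    if n_constant:
        logger.info(
            "individual %s: %d constant taxa excluded from Taylor regression",
            moments.individual_id,
            n_constant,
        )
    mu = moments.mu[usable]
    sigma = moments.sigma[usable]
    if len(mu) < MIN_TAXA_FIT:
        raise ValueError(
            f"individual {moments.individual_id!r}: {len(mu)} usable taxa; "
            f"need >= {MIN_TAXA_FIT} for the Taylor fit"
        )
    x = np.log10(mu.values)
    if regress_variance:
        res = stats.linregress(x, 2 * np.log10(sigma.values))
        beta, v = res.slope / 2, 10**res.intercept
        se_beta, se_logv = res.stderr / 2, res.intercept_stderr
    else:
        res = stats.linregress(x, np.log10(sigma.values))
        beta, v = res.slope, 10 ** (2 * res.intercept)
        se_beta, se_logv = res.stderr, 2 * res.intercept_stderr
    fit = TaylorFit(
        individual_id=moments.individual_id,
        age_group=moments.age_group,
        V=v,
        beta=beta,
        se_logV=se_logv,
        se_beta=se_beta,
        r2=res.rvalue**2,
        n_taxa_fit=len(mu),
        n_timepoints=moments.n_timepoints,
    )
    if fit.low_confidence:
        logger.warning(
            "individual %s fitted from only %d time points (low confidence)",
            fit.individual_id,
            fit.n_timepoints,
        )
    return fit


def fit_all(table: AbundanceTable) -> list[TaylorFit]:
    """Taylor fit for every individual with at least two samples."""
    fits = []
    for ind in table.individuals():
        if len(table.samples_of_individual(ind)) < 2:
            logger.warning("individual %s skipped: fewer than 2 samples", ind)
            continue
        fits.append(fit_taylor(taxon_moments(table, ind)))
    return fits


def standardize_fits(
    fits: list[TaylorFit], reference: AgeGroup = AgeGroup.A
) -> StandardizedTaylorSpace:
    """Z-score (log10 V, beta) per axis against the reference group.

    Standard errors are scaled by the same per-axis reference sd; the
    reference individuals' standardized coordinates have mean 0, sd 1.
    """
    ref = [f for f in fits if f.age_group == reference]
    if len(ref) < 2:
        raise ValueError(
            f"reference group {reference.value} has {len(ref)} fit(s); need >= 2"
        )
    ref_logV = np.array([f.log10_V for f in ref])
    ref_beta = np.array([f.beta for f in ref])
    sd_logV = ref_logV.std(ddof=1)
    sd_beta = ref_beta.std(ddof=1)
    if sd_logV == 0 or sd_beta == 0:
        raise ValueError("reference group has zero spread on an axis")
    coords = pd.DataFrame(
        {
            "individual_id": [f.individual_id for f in fits],
            "age_group": [f.age_group.value for f in fits],
            "z_V": [(f.log10_V - ref_logV.mean()) / sd_logV for f in fits],
            "z_beta": [(f.beta - ref_beta.mean()) / sd_beta for f in fits],
            "se_z_V": [f.se_logV / sd_logV for f in fits],
            "se_z_beta": [f.se_beta / sd_beta for f in fits],
        }
    )
    return StandardizedTaylorSpace(
        reference_group=reference,
        ref_mean_logV=ref_logV.mean(),
        ref_sd_logV=sd_logV,
        ref_mean_beta=ref_beta.mean(),
        ref_sd_beta=sd_beta,
        coords=coords,
    )


def confidence_radius(p: float) -> float:
    """Radius enclosing probability p of a standard bivariate normal."""
    if not (0 < p < 1):
        raise ValueError(f"confidence level must be in (0, 1), got {p}")
    return math.sqrt(-2.0 * math.log1p(-p))


def classify_window(space: StandardizedTaylorSpace, p: float) -> pd.DataFrame:
    """Inside/outside flag per individual for the radius-p window (boundary inside)."""
    r = confidence_radius(p)
    out = space.coords.copy()
    out["distance"] = np.hypot(out["z_V"], out["z_beta"])
    out["confidence_level"] = p
    out["inside"] = out["distance"] <= r
    return out


def fits_table(fits: list[TaylorFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": [f.individual_id for f in fits],
            "age_group": [f.age_group.value for f in fits],
            "V": [f.V for f in fits],
            "beta": [f.beta for f in fits],
            "se_logV": [f.se_logV for f in fits],
            "se_beta": [f.se_beta for f in fits],
            "r2": [f.r2 for f in fits],
            "n_taxa_fit": [f.n_taxa_fit for f in fits],
            "n_timepoints": [f.n_timepoints for f in fits],
            "low_confidence": [f.low_confidence for f in fits],
        }
    )
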