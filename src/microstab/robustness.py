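"""Taxa-function robustness: attenuation and buffering against null genomes.

A sample's taxonomic profile is projected into function space through a
genome-content table (16S-copy-number corrected). Communities are
perturbed by removing taxa in random order until a target relative
abundance is knocked out; each perturbation yields a taxonomic shift
``d_T`` and a functional shift ``d_F`` (Bray-Curtis on the original vs
perturbed profiles). The response cloud is summarized by a hinge model

    d_F = s * max(0, d_T - b)

whose slope ``s`` (how fast function shifts once perturbation bites) and
offset ``b`` (how much perturbation is tolerated first) are standardized
against a null ensemble in which whole genome rows (with their 16S copy
numbers) are reassigned to taxa at random:

    attenuation A = (mean s_null - s_obs) / sd s_null
    buffering   B = (b_obs - mean b_null) / sd b_null

Positive A: the observed functional response is flatter than random
genome assignment predicts; positive B: a larger perturbation is
tolerated. The hinge-plus-row-shuffle construction is a declared,
fully-specified stand-in for external robustness pipelines, not a
re-implementation of any of them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DetectionThreshold, PathwayMap

logger = logging.getLogger("microstab")

GLOBAL_SCOPE = "global"
DEFAULT_MAGNITUDES: tuple[float, ...] = tuple(np.round(np.arange(1, 16) * 0.05, 2))
DEFAULT_REPS = 20
DEFAULT_NULLS = 100
HINGE_GRID_STEP = 0.005
MAX_MAGNITUDE = 0.95


class GenomeContent:
    """Taxa x gene-family copy numbers, 16S copy numbers, and pathway map."""

    def __init__(
        self, copy_numbers: pd.DataFrame, rrn: pd.Series, pathway_map: PathwayMap
    ) -> None:
        if (copy_numbers.values < 0).any():
            raise ValueError("copy numbers must be non-negative")
        rrn = rrn.reindex(copy_numbers.index)
        if rrn.isna().any():
            missing = list(rrn.index[rrn.isna()][:5])
            raise ValueError(f"missing 16S copy number for taxa: {missing}")
        if (rrn < 1).any():
            raise ValueError("16S copy numbers must be >= 1")
        unknown = [f for f in copy_numbers.columns if f not in pathway_map.function_to_pathway]
        if unknown:
            raise ValueError(f"functions absent from pathway map: {unknown[:5]}")
        self.copy_numbers = copy_numbers.astype(float)
        self.rrn = rrn.astype(float)
        self.pathway_map = pathway_map

    @property
    def taxa(self) -> list[str]:
        return list(self.copy_numbers.index)

    @property
    def functions(self) -> list[str]:
        return list(self.copy_numbers.columns)

    def scope_indices(self, scope: str) -> np.ndarray:
        """Column indices of the functions belonging to a scope."""
        if scope == GLOBAL_SCOPE:
            return np.arange(len(self.functions))
        level, _, scope_id = scope.partition(":")
        if level not in ("pathway", "superpathway") or not scope_id:
            raise ValueError(f"bad scope {scope!r}")
        wanted = set(self.pathway_map.functions_in(level, scope_id))
        idx = np.array(
            [j for j, f in enumerate(self.functions) if f in wanted], dtype=int
        )
        if idx.size == 0:
            raise ValueError(f"scope {scope!r} contains no functions")
        return idx


@dataclass(frozen=True)
class PerturbationCurve:
    sample_id: str
    scope: str
    d_T: np.ndarray
    d_F: np.ndarray
    magnitudes: tuple[float, ...]
    reps: int

    @property
    def points(self) -> pd.DataFrame:
        return pd.DataFrame({"d_T": self.d_T, "d_F": self.d_F})


@dataclass(frozen=True)
class HingeFit:
    """Least-squares d_F = slope * max(0, d_T - offset)."""

    slope: float
    offset: float
    rss: float
    n_points: int


@dataclass(frozen=True)
class RobustnessScore:
    sample_id: str
    scope: str
    attenuation: float
    buffering: float
    attenuation_defined: bool
    buffering_defined: bool
    s_obs: float
    b_obs: float
    s_null_mean: float
    s_null_sd: float
    b_null_mean: float
    b_null_sd: float
    n_null: int


# ---------------------------------------------------------------------------
# elementary operations


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """1 - sum(min(x, y)) for two non-negative composition vectors (sum 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("Bray-Curtis inputs must be non-negative")
    return float(1.0 - np.minimum(x, y).sum())


def functional_profile(abundance: pd.Series, content: GenomeContent) -> pd.Series:
    """Project a taxonomic composition into function space.

    Abundances are divided by 16S copy numbers, renormalized, pushed
    through the copy-number matrix, and the resulting function vector is
    renormalized to sum 1.
    """
    extra = [t for t in abundance.index if t not in set(content.taxa)]
    if extra:
        raise ValueError(f"taxa absent from genome content: {extra[:5]}")
    vec = abundance.reindex(content.taxa).fillna(0.0).to_numpy(dtype=float)
    profile = _functional_rows(
        vec[None, :], content.copy_numbers.to_numpy(), content.rrn.to_numpy()
    )[0]
    if profile.sum() <= 0:
        raise ValueError("no taxon in the sample carries any function")
    return pd.Series(profile, index=content.functions, name=abundance.name)


def _functional_rows(
    rows: np.ndarray, copy_matrix: np.ndarray, rrn: np.ndarray
) -> np.ndarray:
    """rrn-correct, renormalize, project, renormalize; zero rows stay zero."""
    w = rows / rrn[None, :]
    sums = w.sum(axis=1, keepdims=True)
    np.divide(w, sums, out=w, where=sums > 0)
    f = w @ copy_matrix
    fsums = f.sum(axis=1, keepdims=True)
    np.divide(f, fsums, out=f, where=fsums > 0)
    return f


def perturb(
    abundance: pd.Series | np.ndarray, magnitude: float, rng: np.random.Generator
) -> pd.Series | np.ndarray:
    """Knock out taxa in random order until >= magnitude abundance is removed.

    The last removed taxon may overshoot the target; survivors are
    renormalized. magnitude 0 returns the input unchanged. If a draw
    empties the community it is resampled once, then raises.
    """
    if not (0 <= magnitude <= MAX_MAGNITUDE):
        raise ValueError(f"magnitude must be in [0, {MAX_MAGNITUDE}], got {magnitude}")
    index = abundance.index if isinstance(abundance, pd.Series) else None
    vec = np.asarray(abundance, dtype=float)
    if magnitude == 0:
        out = vec.copy()
    else:
        out = _perturb_vector(vec, magnitude, rng)
        if out is None:
            out = _perturb_vector(vec, magnitude, rng)
        if out is None:
            raise ValueError(
                f"perturbation at magnitude {magnitude} empties the community"
            )
    return pd.Series(out, index=index) if index is not None else out


def _perturb_vector(
    vec: np.ndarray, magnitude: float, rng: np.random.Generator
) -> np.ndarray | None:
    present = np.flatnonzero(vec > 0)
    order = present[rng.permutation(present.size)]
    removed_mass = np.cumsum(vec[order])
    k = int(np.searchsorted(removed_mass, magnitude * vec.sum() - 1e-12) + 1)
    if k >= present.size:
        return None
    out = vec.copy()
    out[order[:k]] = 0.0
    return out / out.sum()


_PERTURB_RETRIES = 100


def _perturbation_set(
    vec: np.ndarray,
    magnitudes: tuple[float, ...],
    reps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack of perturbed compositions plus their taxonomic shifts d_T.

    Magnitudes no removal order can satisfy without emptying the community
    (those above 1 minus the smallest present share) are skipped with a
    warning so one dominant taxon cannot abort a whole sample; unlucky
    removal orders at feasible magnitudes are simply redrawn.
    """
    total = vec.sum()
    min_share = vec[vec > 0].min() / total
    rows = []
    skipped = []
    for m in magnitudes:
        if m > 1.0 - min_share + 1e-12:
            skipped.append(m)
            continue
        for _ in range(reps):
            if m == 0:
                rows.append(vec.copy())
                continue
            for _attempt in range(_PERTURB_RETRIES):
                out = _perturb_vector(vec, m, rng)
                if out is not None:
                    break
            else:  # pragma: no cover - feasibility was checked above
                raise ValueError(
                    f"no valid removal order found at magnitude {m}"
                )
            rows.append(out)
    if skipped:
        logger.warning(
            "skipped infeasible perturbation magnitudes %s "
            "(community would be emptied)",
            skipped,
        )
    if not rows:
        raise ValueError("no feasible perturbation magnitudes for this sample")
    mat = np.vstack(rows)
    d_t = 1.0 - np.minimum(mat, vec[None, :]).sum(axis=1)
    return mat, d_t


def _scope_shifts(f_rows: np.ndarray, f0: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Bray-Curtis between scope-restricted renormalized profiles.

    Both sides are cut down to the scope's functions and renormalized
    within it. A zero-sum side is treated as an empty profile: shift 0 if
    both are empty, 1 otherwise.
    """
    sub = f_rows[:, idx]
    ref = f0[idx]
    ref_sum = ref.sum()
    sums = sub.sum(axis=1, keepdims=True)
    if ref_sum > 0:
        ref = ref / ref_sum
    norm = np.divide(sub, sums, out=np.zeros_like(sub), where=sums > 0)
    d = 1.0 - np.minimum(norm, ref[None, :]).sum(axis=1)
    empty_rows = sums[:, 0] <= 0
    if ref_sum > 0:
        d[empty_rows] = 1.0
    else:
        d = np.where(empty_rows, 0.0, 1.0)
    d = np.clip(d, 0.0, 1.0)
    d[d < 1e-12] = 0.0  # snap float dust so identical profiles give exactly 0
    return d


def perturbation_curve(
    abundance: pd.Series,
    content: GenomeContent,
    scope: str = GLOBAL_SCOPE,
    magnitudes: tuple[float, ...] = DEFAULT_MAGNITUDES,
    reps: int = DEFAULT_REPS,
    rng: np.random.Generator | None = None,
    sample_id: str = "",
) -> PerturbationCurve:
    """(d_T, d_F) cloud over a magnitude grid, reps draws per magnitude."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = rng or np.random.default_rng()
    idx = content.scope_indices(scope)
    vec = abundance.reindex(content.taxa).fillna(0.0).to_numpy(dtype=float)
    copy_matrix = content.copy_numbers.to_numpy()
    rrn = content.rrn.to_numpy()
    f0 = _functional_rows(vec[None, :], copy_matrix, rrn)[0]
    mat, d_t = _perturbation_set(vec, magnitudes, reps, rng)
    f_rows = _functional_rows(mat, copy_matrix, rrn)
    d_f = _scope_shifts(f_rows, f0, idx)
    return PerturbationCurve(
        sample_id=sample_id or str(abundance.name or ""),
        scope=scope,
        d_T=d_t,
        d_F=d_f,
        magnitudes=tuple(magnitudes),
        reps=reps,
    )


def fit_hinge(curve: PerturbationCurve) -> HingeFit:
    """Grid search on the offset with closed-form slope per grid point."""
    return _fit_hinge_arrays(curve.d_T, curve.d_F)


def _fit_hinge_arrays(d_t: np.ndarray, d_f: np.ndarray) -> HingeFit:
    if d_t.size < 10:
        raise ValueError(f"hinge fit needs >= 10 points, got {d_t.size}")
    max_dt = float(d_t.max())
    if max_dt == 0:
        raise ValueError("all taxonomic shifts are zero; hinge fit undefined")
    grid = np.arange(0.0, max_dt + HINGE_GRID_STEP / 2, HINGE_GRID_STEP)
    h = np.clip(d_t[:, None] - grid[None, :], 0.0, None)
    denom = (h * h).sum(axis=0)
    num = d_f @ h
    slope = np.divide(num, denom, out=np.zeros_like(denom), where=denom > 0)
    np.clip(slope, 0.0, None, out=slope)
    rss = (d_f * d_f).sum() - 2 * slope * num + slope * slope * denom
    best = int(np.argmin(rss))  # argmin takes the first minimum: smallest b wins ties
    return HingeFit(
        slope=float(slope[best]),
        offset=float(grid[best]),
        rss=float(max(rss[best], 0.0)),
        n_points=int(d_t.size),
    )


# ---------------------------------------------------------------------------
# null standardization


def _null_permutations(
    n_taxa: int, n_null: int, rng: np.random.Generator
) -> list[np.ndarray]:
    return [rng.permutation(n_taxa) for _ in range(n_null)]


def _score_from_fits(
    sample_id: str,
    scope: str,
    obs: HingeFit,
    s_null: np.ndarray,
    b_null: np.ndarray,
) -> RobustnessScore:
    s_sd = float(s_null.std(ddof=1))
    b_sd = float(b_null.std(ddof=1))
    s_ok = s_sd > 0
    b_ok = b_sd > 0
    if not (s_ok and b_ok):
        logger.warning(
            "sample %s scope %s: degenerate null distribution "
            "(attenuation defined=%s, buffering defined=%s)",
            sample_id,
            scope,
            s_ok,
            b_ok,
        )
    return RobustnessScore(
        sample_id=sample_id,
        scope=scope,
        attenuation=(float(s_null.mean()) - obs.slope) / s_sd if s_ok else float("nan"),
        buffering=(obs.offset - float(b_null.mean())) / b_sd if b_ok else float("nan"),
        attenuation_defined=s_ok,
        buffering_defined=b_ok,
        s_obs=obs.slope,
        b_obs=obs.offset,
        s_null_mean=float(s_null.mean()),
        s_null_sd=s_sd,
        b_null_mean=float(b_null.mean()),
        b_null_sd=b_sd,
        n_null=int(s_null.size),
    )


def robustness_scores(
    observed: HingeFit,
    content: GenomeContent,
    abundance: pd.Series,
    scope: str = GLOBAL_SCOPE,
    n_null: int = DEFAULT_NULLS,
    rng: np.random.Generator | None = None,
    magnitudes: tuple[float, ...] = DEFAULT_MAGNITUDES,
    reps: int = DEFAULT_REPS,
    sample_id: str = "",
) -> RobustnessScore:
    """Standardize an observed hinge fit against row-shuffled null genomes.

    Each null reassigns whole genome rows (jointly with 16S copy numbers)
    to taxa by one permutation, then refits the hinge on a fresh
    perturbation set shared by all nulls.
    """
    if n_null < 20:
        raise ValueError(f"n_null must be >= 20, got {n_null}")
    rng = rng or np.random.default_rng()
    idx = content.scope_indices(scope)
    vec = abundance.reindex(content.taxa).fillna(0.0).to_numpy(dtype=float)
    mat, d_t = _perturbation_set(vec, magnitudes, reps, rng)
    copy_matrix = content.copy_numbers.to_numpy()
    rrn = content.rrn.to_numpy()
    s_null = np.empty(n_null)
    b_null = np.empty(n_null)
    for i, perm in enumerate(_null_permutations(len(content.taxa), n_null, rng)):
        cm = copy_matrix[perm]
        rr = rrn[perm]
        f0 = _functional_rows(vec[None, :], cm, rr)[0]
        d_f = _scope_shifts(_functional_rows(mat, cm, rr), f0, idx)
        fit = _fit_hinge_arrays(d_t, d_f)
        s_null[i] = fit.slope
        b_null[i] = fit.offset
    return _score_from_fits(
        sample_id or str(abundance.name or ""), scope, observed, s_null, b_null
    )


def sample_robustness(
    abundance: pd.Series,
    content: GenomeContent,
    scope: str = GLOBAL_SCOPE,
    magnitudes: tuple[float, ...] = DEFAULT_MAGNITUDES,
    reps: int = DEFAULT_REPS,
    n_null: int = DEFAULT_NULLS,
    rng: np.random.Generator | None = None,
    sample_id: str = "",
) -> tuple[PerturbationCurve, HingeFit, RobustnessScore]:
    """Observed curve + hinge fit + null-standardized score for one sample."""
    rng = rng or np.random.default_rng()
    curve = perturbation_curve(
        abundance, content, scope, magnitudes, reps, rng, sample_id=sample_id
    )
    obs = fit_hinge(curve)
    score = robustness_scores(
        obs, content, abundance, scope, n_null, rng, magnitudes, reps, sample_id
    )
    return curve, obs, score


def pathway_robustness(
    abundance: pd.Series,
    content: GenomeContent,
    level: str = "superpathway",
    magnitudes: tuple[float, ...] = DEFAULT_MAGNITUDES,
    reps: int = DEFAULT_REPS,
    n_null: int = DEFAULT_NULLS,
    rng: np.random.Generator | None = None,
    sample_id: str = "",
) -> list[RobustnessScore]:
    """One null-standardized score per pathway (or superpathway) for a sample.

    One perturbation set and one null ensemble are shared across scopes so
    per-scope scores are comparable; scopes whose observed shifts are all
    zero alongside zero taxonomic shift cannot occur, but scopes where the
    hinge is undefined are skipped with a warning.
    """
    if level == "pathway":
        scope_ids = content.pathway_map.pathways
    elif level == "superpathway":
        scope_ids = content.pathway_map.superpathways
    else:
        raise ValueError(f"level must be 'pathway' or 'superpathway', got {level!r}")
    rng = rng or np.random.default_rng()
    sid = sample_id or str(abundance.name or "")
    vec = abundance.reindex(content.taxa).fillna(0.0).to_numpy(dtype=float)
    mat, d_t = _perturbation_set(vec, magnitudes, reps, rng)
    copy_matrix = content.copy_numbers.to_numpy()
    rrn = content.rrn.to_numpy()
    perms = _null_permutations(len(content.taxa), n_null, rng)

    scopes: list[str] = []
    scope_idx: list[np.ndarray] = []
    for scope_id in scope_ids:
        scope = f"{level}:{scope_id}"
        try:
            scope_idx.append(content.scope_indices(scope))
            scopes.append(scope)
        except ValueError:
            logger.warning("scope %s skipped: no functions", scope)

    f0 = _functional_rows(vec[None, :], copy_matrix, rrn)[0]
    f_rows = _functional_rows(mat, copy_matrix, rrn)
    obs_fits = [
        _fit_hinge_arrays(d_t, _scope_shifts(f_rows, f0, idx)) for idx in scope_idx
    ]
    s_null = np.empty((len(scopes), n_null))
    b_null = np.empty((len(scopes), n_null))
    for i, perm in enumerate(perms):
        cm = copy_matrix[perm]
        rr = rrn[perm]
        f0_n = _functional_rows(vec[None, :], cm, rr)[0]
        f_n = _functional_rows(mat, cm, rr)
        for k, idx in enumerate(scope_idx):
            fit = _fit_hinge_arrays(d_t, _scope_shifts(f_n, f0_n, idx))
            s_null[k, i] = fit.slope
            b_null[k, i] = fit.offset
    return [
        _score_from_fits(sid, scope, obs_fits[k], s_null[k], b_null[k])
        for k, scope in enumerate(scopes)
    ]


def scores_table(scores: list[RobustnessScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in scores],
            "scope": [s.scope for s in scores],
            "attenuation": [s.attenuation for s in scores],
            "buffering": [s.buffering for s in scores],
            "attenuation_defined": [s.attenuation_defined for s in scores],
            "buffering_defined": [s.buffering_defined for s in scores],
            "s_obs": [s.s_obs for s in scores],
            "b_obs": [s.b_obs for s in scores],
            "s_null_mean": [s.s_null_mean for s in scores],
            "s_null_sd": [s.s_null_sd for s in scores],
            "b_null_mean": [s.b_null_mean for s in scores],
            "b_null_sd": [s.b_null_sd for s in scores],
            "n_null": [s.n_null for s in scores],
        }
    )
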