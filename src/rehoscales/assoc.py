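"""Case-control difference maps and eigengene-difference-map association.

Difference statistics are the t of the group term in a linear model
y ~ intercept + group + age + sex, per voxel or region. Regional values
are first screened for normality with a seeded Monte-Carlo
Kolmogorov-Smirnov test (Lilliefors-style, parameters estimated from the
sample). Bonferroni thresholds are alpha/m.

Module eigengenes are correlated with the difference map spatially:
at the voxel level, the t value at each tissue sample is the mean t inside
a 6 mm sphere around the sample (world mm); at regional levels the
regional t is used directly. Correlations run separately for cortical and
subcortical units because expression profiles differ sharply between the
compartments; Benjamini-Hochberg q values are computed within compartment
across modules (raw p is reported alongside).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_ks_null_cache: dict[tuple[int, int, int], np.ndarray] = {}


def _ks_statistic(values: np.ndarray) -> float:
    """KS distance of a sample from a normal with its own mean/SD."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    z = (x - x.mean()) / x.std(ddof=1)
    cdf = stats.norm.cdf(z)
    upper = np.arange(1, n + 1) / n - cdf
    lower = cdf - np.arange(0, n) / n
    return float(max(upper.max(), lower.max()))


def ks_normality(values: np.ndarray, n_draws: int = 2000, seed: int = 0) -> float:
    """Composite-normality KS test with a seeded Monte-Carlo null.

    Because mean and SD are estimated from the sample, the standard KS
    distribution is invalid (Lilliefors' problem); the null is therefore
    simulated: ``n_draws`` normal samples of the same size, each tested the
    same way. The Monte-Carlo null for a given (n, n_draws, seed) is cached,
    so the returned p is deterministic.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 8:
        raise ValueError("normality test requires n >= 8")
    if np.ptp(values) == 0:
        logger.warning("constant input to ks_normality; returning p = 0")
        return 0.0
    d_obs = _ks_statistic(values)
    key = (n, n_draws, seed)
    if key not in _ks_null_cache:
        rng = np.random.default_rng(seed)
        draws = rng.standard_normal((n_draws, n))
        draws.sort(axis=1)
        z = (draws - draws.mean(axis=1, keepdims=True)) / draws.std(axis=1, ddof=1, keepdims=True)
        cdf = stats.norm.cdf(z)
        grid_hi = np.arange(1, n + 1) / n
        grid_lo = np.arange(0, n) / n
        d_null = np.maximum((grid_hi - cdf).max(axis=1), (cdf - grid_lo).max(axis=1))
        _ks_null_cache[key] = d_null
    d_null = _ks_null_cache[key]
    return float((1 + (d_null >= d_obs).sum()) / (n_draws + 1))


def adjusted_ttest(
    y: np.ndarray, group: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """t and two-sided p of the group term in y ~ 1 + group + covariates.

    ``y`` may be (n,) or (n, m) for m units tested at once (vectorised over
    columns). Collinear covariate columns are dropped with a warning.
    """
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    if single:
        y = y[:, None]
    group = np.asarray(group, dtype=float)
    n = len(group)
    cols = [np.ones(n), group]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.extend(cov.T)
    X = np.column_stack(cols)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        # never drop the intercept or the group column
        keep = sorted(set(piv[:rank]) | {0, 1})[: rank]
        if 1 not in keep:
            raise ValueError("group column is collinear with covariates")
        logger.warning("dropping %d collinear covariate columns", X.shape[1] - len(keep))
        X = X[:, keep]

    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[1] / se
    p = 2 * stats.t.sf(np.abs(t), df)
    if single:
        return float(t[0]), float(p[0])
    return t, p


@dataclass
class DifferenceMap:
    """Per-unit case-control t statistics at one scale."""

    scale: int
    t: np.ndarray
    p: np.ndarray
    unit_ids: np.ndarray
    normality_p: np.ndarray | None = None
    covariates: tuple[str, ...] = ("age", "sex")


def difference_map(
    features: np.ndarray,
    group: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    scale: int = 0,
    unit_ids: np.ndarray | None = None,
    normality_seed: int = 0,
) -> DifferenceMap:
    """Covariate-adjusted case-control t per unit, plus normality screening.

    ``features`` is subjects x units (regional profiles or masked voxels);
    group is 1 for patients. Normality p (per unit, KS Monte-Carlo) is
    reported for regional scales (<= 500 units) where the check is the
    study procedure; voxel-level maps skip it.
    """
    features = np.asarray(features, dtype=float)
    cov = np.column_stack([np.asarray(age, float), np.asarray(sex, float)])
    t, p = adjusted_ttest(features, group, cov)
    if unit_ids is None:
        unit_ids = np.arange(features.shape[1])
    normality = None
    if features.shape[1] <= 500:
        normality = np.array(
            [ks_normality(features[:, j], seed=normality_seed) for j in range(features.shape[1])]
        )
    return DifferenceMap(
        scale=scale, t=t, p=p, unit_ids=np.asarray(unit_ids), normality_p=normality
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise error threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def sphere_sample_t(
    tmap_volume: np.ndarray,
    affine: np.ndarray,
    mask: np.ndarray,
    sample_coords: np.ndarray,
    radius: float = 6.0,
) -> np.ndarray:
    """Mean t inside a sphere (world mm) around each tissue sample.

    A voxel contributes iff its centre lies within ``radius`` of the sample
    (no partial-volume weighting). Samples covering zero in-mask voxels get
    NaN and are logged.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    mask = np.asarray(mask, dtype=bool)
    ijk = np.argwhere(mask)
    centres = (np.asarray(affine)[:3, :3] @ ijk.T).T + np.asarray(affine)[:3, 3]
    tvals = np.asarray(tmap_volume, dtype=float)[mask]
    out = np.empty(len(sample_coords))
    for i, pt in enumerate(np.asarray(sample_coords, dtype=float)):
        inside = np.linalg.norm(centres - pt, axis=1) <= radius
        if not inside.any():
            logger.warning("sample %d covers no in-mask voxel within %.1f mm", i, radius)
            out[i] = np.nan
        else:
            out[i] = tvals[inside].mean()
    return out


def me_t_correlation(
    eigengenes: pd.DataFrame,
    t_values: np.ndarray,
    compartment_labels: np.ndarray,
) -> pd.DataFrame:
    """Module-eigengene vs difference-map spatial correlation, per compartment.

    ``eigengenes`` is module x unit; ``t_values`` and ``compartment_labels``
    align with its columns. Returns rows (module, compartment, r, p, q,
    n_units) with BH-FDR q within each compartment across modules.
    Compartments with fewer than 3 usable units are omitted (logged).
    """
    t_values = np.asarray(t_values, dtype=float)
    compartment_labels = np.asarray(compartment_labels)
    if eigengenes.shape[1] != len(t_values) or len(t_values) != len(compartment_labels):
        raise ValueError("eigengene units, t values and compartments must align")
    rows = []
    for compartment in pd.unique(compartment_labels):
        sel = (compartment_labels == compartment) & ~np.isnan(t_values)
        if sel.sum() < 3:
            logger.warning("compartment %r has <3 units; omitted", compartment)
            continue
        sub_t = t_values[sel]
        block = []
        for module in eigengenes.index:
            me = eigengenes.loc[module].to_numpy(float)[sel]
            if me.std() == 0 or sub_t.std() == 0:
                logger.warning("zero-variance vector for module %s in %s", module, compartment)
                continue
            r, p = stats.pearsonr(me, sub_t)
            block.append({
                "module": module,
                "compartment": compartment,
                "r": r,
                "p": p,
                "n_units": int(sel.sum()),
            })
        if block:
            q = multipletests([b["p"] for b in block], method="fdr_bh")[1]
            for b, qv in zip(block, q):
                b["q"] = qv
            rows.extend(block)
    return pd.DataFrame(rows, columns=["module", "compartment", "r", "p", "q", "n_units"])


def compare_demographics(table: pd.DataFrame) -> pd.DataFrame:
    """Group comparisons of age (pooled two-sample t) and sex (chi-square).

    ``table`` needs columns group (1 = patient), age, sex (0/1 coded).
    The sex test is a Pearson chi-square on the 2x2 count table, df = 1,
    without continuity correction.
    """
    for col in ("group", "age", "sex"):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    g1 = table[table["group"] == 1]
    g0 = table[table["group"] != 1]
    t, p_age = stats.ttest_ind(g1["age"], g0["age"], equal_var=True)

    counts = pd.crosstab(table["group"], table["sex"]).to_numpy()
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("a demographic cell has expected count 0")
    chi2, p_sex, dof, _ = stats.chi2_contingency(counts, correction=False)
    return pd.DataFrame(
        [
            {"variable": "age", "statistic": float(t), "test": "t", "p": float(p_age)},
            {"variable": "sex", "statistic": float(chi2), "test": "chi2", "p": float(p_sex)},
        ]
    )


def chi_square_counts(counts: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a contingency table."""
    counts = np.asarray(counts, dtype=float)
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("a margin of the contingency table is zero")
    chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)
    return float(chi2), float(p)
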