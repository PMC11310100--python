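"""Regional homogeneity (ReHo) via Kendall's coefficient of concordance.

For each in-mask voxel, the time series of the voxel and its neighbours
(6/18/26-connectivity) are rank-transformed over time and their rank
concordance W is computed:

    W = 12 * sum_t (R_t - mean R)^2 / (K^2 (n^3 - n))

with K series ("raters"), n timepoints ("items") and R_t the rank sum at
timepoint t. W is 1 for identical rank orderings, and has expectation 1/K
for independent series. Maps can be z-standardised over the mask
(population SD) and averaged within parcellation regions.

Ties are resolved by average ranks; no tie-correction term is applied to
the denominator (BOLD series are continuous, ties arise only in degenerate
synthetic inputs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .imaging import BoldRun, HierarchicalParcellation

logger = logging.getLogger(__name__)

_CONNECTIVITY_OFFSETS: dict[int, np.ndarray] = {}


def _offsets(connectivity: int) -> np.ndarray:
    """Neighbour index offsets for 6/18/26 connectivity (voxel excluded)."""
    if connectivity not in (6, 18, 26):
        raise ValueError("connectivity must be 6, 18 or 26")
    if connectivity not in _CONNECTIVITY_OFFSETS:
        grid = np.array(
            [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
        )
        dist = np.abs(grid).sum(axis=1)
        maxdist = {6: 1, 18: 2, 26: 3}[connectivity]
        _CONNECTIVITY_OFFSETS[connectivity] = grid[(dist > 0) & (dist <= maxdist)]
    return _CONNECTIVITY_OFFSETS[connectivity]


@dataclass
class ReHoMap:
    """Per-voxel Kendall's W values on a masked grid.

    ``neighbourhood_size`` records K (voxel + in-mask neighbours) per voxel;
    ``valid`` flags voxels with enough neighbours for a meaningful W.
    """

    values: np.ndarray
    mask: np.ndarray
    z_standardised: bool = False
    neighbourhood_size: np.ndarray | None = None
    valid: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.z_standardised:
            in_mask = self.values[self.mask]
            if in_mask.size and (in_mask.min() < -1e-9 or in_mask.max() > 1 + 1e-9):
                raise ValueError("raw W values must lie in [0, 1]")


def kendall_w(series_matrix: np.ndarray) -> float:
    """Kendall's coefficient of concordance of K time series over n timepoints.

    series_matrix is (K, n). Returns W in [0, 1]; an all-constant input
    (every rank tied everywhere) yields 0 by convention.
    """
    x = np.asarray(series_matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("series_matrix must be 2D (K series x n timepoints)")
    k, n = x.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 series and 2 timepoints")
    ranks = rankdata(x, axis=1)
    rank_sums = ranks.sum(axis=0)
    ss = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    denom = k**2 * (n**3 - n) / 12.0
    if ss == 0.0 and np.ptp(ranks, axis=1).max() == 0:
        logger.info("all-constant input to kendall_w; returning W=0 by convention")
        return 0.0
    return min(ss / denom, 1.0)


def reho_map(
    run: BoldRun,
    mask: np.ndarray,
    connectivity: int = 26,
    min_neighbors: int = 7,
) -> ReHoMap:
    """Whole-brain ReHo map: Kendall's W of each voxel with its neighbours.

    Edge voxels use whatever in-mask neighbours exist (variable K); voxels
    with fewer than ``min_neighbors`` in-mask neighbours get W = 0 and are
    flagged invalid.

    Implementation ranks every voxel's series once, then accumulates
    neighbourhood rank sums by shifting the rank volume, which gives
    bit-identical results to per-voxel evaluation.
    """
    offsets = _offsets(connectivity)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    data = run.data
    n = data.shape[3]

    ranks = np.zeros_like(data)
    ranks[mask] = rankdata(data[mask], axis=1)

    rank_sum = np.array(ranks, copy=True)  # starts with the voxel itself
    k_count = mask.astype(np.int64).copy()
    maskf = mask.astype(float)
    for off in offsets:
        shifted = _shift3d(ranks, off)
        shifted_mask = _shift3d(maskf[..., None], off)[..., 0]
        rank_sum += shifted
        k_count += shifted_mask.astype(np.int64)

    k = k_count.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_rank_sum = k * (n + 1) / 2.0
        ss = ((rank_sum - mean_rank_sum[..., None]) ** 2).sum(axis=-1)
        w = 12.0 * ss / (k**2 * (n**3 - n))
    w = np.where(mask, np.clip(w, 0.0, 1.0), 0.0)

    valid = mask & (k_count - 1 >= min_neighbors)
    n_invalid = int((mask & ~valid).sum())
    if n_invalid:
        logger.info("%d in-mask voxels below min_neighbors=%d set to 0", n_invalid, min_neighbors)
    w[mask & ~valid] = 0.0
    return ReHoMap(
        values=w,
        mask=mask,
        neighbourhood_size=k_count,
        valid=valid,
        affine=run.affine,
    )


def _shift3d(arr: np.ndarray, offset: np.ndarray) -> np.ndarray:
    """Shift a (x,y,z,...) array by an integer 3-vector, zero-filling edges."""
    out = np.zeros_like(arr)
    src = [slice(None)] * arr.ndim
    dst = [slice(None)] * arr.ndim
    for ax, d in enumerate(offset):
        size = arr.shape[ax]
        if d == 0:
            continue
        if d > 0:
            dst[ax] = slice(d, size)
            src[ax] = slice(0, size - d)
        else:
            dst[ax] = slice(0, size + d)
            src[ax] = slice(-d, size)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def zscore_map(reho: ReHoMap) -> ReHoMap:
    """Z-standardise a ReHo map over the mask (population SD).

    Subtracts the in-mask mean and divides by the in-mask SD; out-of-mask
    voxels stay zero.
    """
    in_mask = reho.values[reho.mask]
    sd = in_mask.std()  # population convention (divide by N)
    if sd <= 0:
        raise ValueError("constant ReHo map cannot be z-standardised")
    z = np.zeros_like(reho.values)
    z[reho.mask] = (in_mask - in_mask.mean()) / sd
    return ReHoMap(
        values=z,
        mask=reho.mask,
        z_standardised=True,
        neighbourhood_size=reho.neighbourhood_size,
        valid=reho.valid,
        affine=reho.affine,
    )


@dataclass
class RegionalProfile:
    """Per-region mean ReHo at one parcellation scale."""

    scale: int
    region_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.region_ids) != len(self.values):
            raise ValueError("region_ids and values must align")


def regional_means(
    reho: ReHoMap, parcellation: HierarchicalParcellation, scale: int
) -> RegionalProfile:
    """Mean ReHo over in-mask voxels of each region at the given scale.

    Regions with no in-mask voxels get NaN (logged).
    """
    if scale not in parcellation.labels:
        raise KeyError(f"unknown scale {scale}")
    labels = parcellation.labels[scale]
    region_ids = parcellation.region_ids(scale)
    lab = labels[reho.mask]
    val = reho.values[reho.mask]
    sums = np.bincount(lab, weights=val, minlength=int(region_ids.max()) + 1)
    counts = np.bincount(lab, minlength=int(region_ids.max()) + 1)
    out = np.full(len(region_ids), np.nan)
    for i, rid in enumerate(region_ids):
        if counts[rid] > 0:
            out[i] = sums[rid] / counts[rid]
        else:
            logger.warning("region %d at scale %d has no in-mask voxels", rid, scale)
    return RegionalProfile(scale=scale, region_ids=region_ids, values=out)
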