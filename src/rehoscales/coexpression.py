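"""Signed weighted co-expression networks and module eigengenes (WGCNA-lite).

From a gene x unit expression matrix (units are tissue samples or brain
regions): Pearson gene-gene correlation, signed soft-threshold adjacency
A_ij = ((1 + r_ij)/2)^beta, topological overlap (TOM), average-linkage
hierarchical clustering of 1 - TOM with a static cut, and per-module
first-principal-component eigengenes.

The soft power is the smallest candidate whose scale-free topology fit
(signed R^2 of the log-log degree-distribution regression) reaches the
target; when no candidate reaches it, beta = 12 is used with a warning.
Analyses on fewer than 15 units are refused outright — co-expression
estimated from fewer units is too unstable to cluster.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

MIN_UNITS = 15
DEFAULT_POWER = 12
GREY = 0


class TooFewUnitsError(ValueError):
    """Raised when a co-expression analysis is requested on <15 units."""


@dataclass
class CoexpressionNetwork:
    correlation: np.ndarray
    beta: float
    adjacency: np.ndarray
    tom: np.ndarray
    fit_r2: float | None = None


@dataclass
class ModulePartition:
    """Per-gene module labels; 0 is the grey (unassigned) module."""

    labels: np.ndarray
    min_module_size: int

    def sizes(self) -> dict[int, int]:
        uniq, counts = np.unique(self.labels, return_counts=True)
        return {int(u): int(c) for u, c in zip(uniq, counts)}

    @property
    def n_modules(self) -> int:
        return len([m for m in self.sizes() if m != GREY])


@dataclass
class EigengeneMatrix:
    """Module x unit eigengene values with per-module variance explained."""

    values: pd.DataFrame  # index = module label, columns = units
    variance_explained: pd.Series


def _standardise_rows(expr: np.ndarray) -> np.ndarray:
    x = np.asarray(expr, dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("constant gene rows cannot be standardised")
    return (x - mu) / sd


def gene_correlation(expr: np.ndarray) -> np.ndarray:
    """Pearson correlation between gene rows."""
    z = _standardise_rows(expr)
    r = z @ z.T / z.shape[1]
    return np.clip(r, -1.0, 1.0)


def signed_adjacency(cor_matrix: np.ndarray, beta: float) -> np.ndarray:
    """Signed soft-threshold adjacency ((1 + r)/2)^beta with unit diagonal."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    cor = np.asarray(cor_matrix, dtype=float)
    if cor.min() < -1 - 1e-9 or cor.max() > 1 + 1e-9:
        raise ValueError("correlations must lie in [-1, 1]")
    a = ((1.0 + cor) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the scale-free topology fit of the degree distribution.

    Connectivities k_i (row sums minus the diagonal) are binned; log10 of
    bin frequency is regressed on log10 of mean bin connectivity, and the
    R^2 is sign-corrected (negative slope -> positive fit index).
    """
    k = adjacency.sum(axis=1) - 1.0
    k = k[k > 0]
    if len(k) < 3:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if members.size == 0:
            continue
        xs.append(members.mean())
        ys.append(members.size / len(k))
    if len(xs) < 3:
        return 0.0
    lx, ly = np.log10(xs), np.log10(ys)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = ((ly - pred) ** 2).sum()
    ss_tot = ((ly - ly.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2)


def pick_power(
    expr: np.ndarray,
    candidate_powers: tuple[int, ...] = tuple(range(1, 21)),
    target_r2: float = 0.8,
) -> tuple[int, float]:
    """Smallest soft power whose scale-free fit reaches ``target_r2``.

    ``expr`` is gene x unit. Refuses fewer than 15 units (the guard that
    makes very coarse parcellations ineligible for module detection).
    Returns (beta, fit R^2); falls back to beta=12 with a warning when no
    candidate reaches the target.
    """
    expr = np.asarray(expr, dtype=float)
    n_units = expr.shape[1]
    if n_units < MIN_UNITS:
        raise TooFewUnitsError(
            f"co-expression analysis requires at least {MIN_UNITS} units, got {n_units}"
        )
    cor = gene_correlation(expr)
    for beta in candidate_powers:
        r2 = scale_free_fit(signed_adjacency(cor, beta))
        if r2 >= target_r2:
            return int(beta), r2
    warnings.warn(
        f"no candidate power reached scale-free fit {target_r2}; using default "
        f"beta={DEFAULT_POWER}",
        stacklevel=2,
    )
    return DEFAULT_POWER, scale_free_fit(signed_adjacency(cor, DEFAULT_POWER))


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_{u != i,j} A_iu A_uj + A_ij) / (min(k_i, k_j) + 1 - A_ij)
    with k = row sums excluding the diagonal; TOM_ii = 1.
    """
    a = np.asarray(adjacency, dtype=float)
    k = a.sum(axis=1) - 1.0
    # sum over u != i, j of A_iu * A_uj: full product minus the u=i and u=j terms
    shared = a @ a - np.diag(a)[:, None] * a - a * np.diag(a)[None, :]
    numer = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = numer / denom
    tom = np.clip(np.nan_to_num(tom), 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    tom: np.ndarray,
    min_module_size: int = 30,
    cut_height: float = 0.99,
) -> ModulePartition:
    """Average-linkage clustering of 1 - TOM with a static tree cut.

    Clusters smaller than ``min_module_size`` become grey (label 0); the
    rest are renumbered 1, 2, ... by decreasing size.
    """
    diss = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(diss, 0.0)
    condensed = squareform(diss, checks=False)
    tree = linkage(condensed, method="average")
    raw = fcluster(tree, t=cut_height, criterion="distance")

    labels = np.zeros(len(raw), dtype=int)
    uniq, counts = np.unique(raw, return_counts=True)
    keep = [(c, u) for u, c in zip(uniq, counts) if c >= min_module_size]
    keep.sort(key=lambda t: (-t[0], t[1]))
    for new_label, (_, old) in enumerate(keep, start=1):
        labels[raw == old] = new_label
    if not keep:
        warnings.warn("all genes assigned to the grey module", stacklevel=2)
    return ModulePartition(labels=labels, min_module_size=min_module_size)


def module_eigengenes(
    expr: np.ndarray,
    partition: ModulePartition,
    unit_names: list | None = None,
    include_grey: bool = False,
) -> EigengeneMatrix:
    """First-principal-component eigengene per module.

    ``expr`` is gene x unit; each gene row is standardised, the module
    submatrix is decomposed by SVD, and the first right singular vector is
    scaled to unit variance. The sign is fixed so that the mean correlation
    between the eigengene and the module's genes is non-negative.
    """
    z = _standardise_rows(expr)
    n_units = z.shape[1]
    if unit_names is None:
        unit_names = list(range(n_units))
    modules = [m for m in sorted(partition.sizes()) if include_grey or m != GREY]
    rows, varexp = {}, {}
    for m in modules:
        idx = np.flatnonzero(partition.labels == m)
        if len(idx) < 2:
            raise ValueError(f"module {m} has fewer than 2 genes")
        sub = z[idx]
        u, s, vt = np.linalg.svd(sub, full_matrices=False)
        me = vt[0]
        me = (me - me.mean()) / me.std()
        corr_sign = np.sign((sub @ me).mean())
        if corr_sign < 0:
            me = -me
        rows[m] = me
        varexp[m] = float(s[0] ** 2 / (s**2).sum())
    values = pd.DataFrame(rows, index=unit_names).T
    return EigengeneMatrix(values=values, variance_explained=pd.Series(varexp))


def build_network(expr: np.ndarray, beta: int | None = None, target_r2: float = 0.8) -> CoexpressionNetwork:
    """Correlation -> (picked) power -> signed adjacency -> TOM, bundled."""
    expr = np.asarray(expr, dtype=float)
    if expr.shape[1] < MIN_UNITS:
        raise TooFewUnitsError(
            f"co-expression analysis requires at least {MIN_UNITS} units, got {expr.shape[1]}"
        )
    cor = gene_correlation(expr)
    r2 = None
    if beta is None:
        beta, r2 = pick_power(expr, target_r2=target_r2)
    adj = signed_adjacency(cor, beta)
    tom = topological_overlap(adj)
    return CoexpressionNetwork(correlation=cor, beta=beta, adjacency=adj, tom=tom, fit_r2=r2)
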