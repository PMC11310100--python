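"""Residual BOLD preprocessing and hierarchical parcellation handling.

The steps here pick up *after* spatial preprocessing (slice timing,
realignment, normalisation are assumed done upstream): head-motion
summarisation (framewise displacement), construction of the nuisance
design (drift, Friston-24 motion expansion, tissue signals, motion-spike
regressors), nuisance regression, temporal band-pass filtering, and
merging of hierarchical parcellation labels across spatial scales.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Rotation-to-millimetre conversion radius (mm) for framewise displacement.
FD_ROTATION_RADIUS_MM = 50.0

MOTION_COLUMNS = ("tx", "ty", "tz", "rx", "ry", "rz")


@dataclass
class BoldRun:
    """A single subject's 4D BOLD acquisition.

    data is (x, y, z, t); translations of the world transform are carried in
    ``affine`` (voxel indices -> world mm, NIfTI convention).
    """

    subject_id: str
    data: np.ndarray
    tr_seconds: float
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4 or self.data.shape[3] < 2:
            raise ValueError("BOLD data must be 4D with at least 2 volumes")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class MotionTrace:
    """Per-volume rigid-body motion parameters.

    ``params`` is (t, 6): three translations in mm then three rotations in
    radians, columns ``tx ty tz rx ry rz``.
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(
                f"motion parameters must have 6 columns ({' '.join(MOTION_COLUMNS)}), "
                f"got shape {self.params.shape}"
            )

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @property
    def fd(self) -> np.ndarray:
        return compute_fd(self)


def compute_fd(motion: MotionTrace) -> np.ndarray:
    """Framewise displacement (Power formulation), in mm.

    FD_t = sum |d translations| + 50 mm * sum |d rotations|; FD_0 = 0.
    Rotations are converted to arc length on a 50 mm sphere.
    """
    params = motion.params
    if params.shape[0] < 2:
        raise ValueError("need at least 2 volumes to compute FD")
    diffs = np.abs(np.diff(params, axis=0))
    fd = diffs[:, :3].sum(axis=1) + FD_ROTATION_RADIUS_MM * diffs[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def friston24(params: np.ndarray) -> np.ndarray:
    """Friston 24-parameter motion expansion: [p, p^2, p(t-1), p(t-1)^2].

    The backshifted terms are zero-padded at the first volume.
    """
    lagged = np.vstack([np.zeros((1, 6)), params[:-1]])
    return np.hstack([params, params**2, lagged, lagged**2])


def build_nuisance(
    motion: MotionTrace,
    tissue_signals: dict[str, np.ndarray],
    fd: np.ndarray | None = None,
    fd_threshold: float = 0.5,
    include_global: bool = True,
) -> np.ndarray:
    """Assemble the nuisance regressor matrix.

    Columns, in order: intercept, linear trend, Friston-24 motion expansion,
    white matter signal, CSF signal, global signal (iff ``include_global``),
    then one 0/1 spike column per volume with FD > ``fd_threshold``
    (scrubbing as spike regression, preserving the temporal grid).

    tissue_signals must provide keys ``"wm"`` and ``"csf"``; ``"global"`` is
    required when ``include_global`` is set.
    """
    t = motion.n_volumes
    if fd is None:
        fd = compute_fd(motion)
    fd = np.asarray(fd, dtype=float)
    if fd.shape[0] != t:
        raise ValueError("FD length must equal number of volumes")

    columns = [np.ones(t), np.linspace(-1.0, 1.0, t), friston24(motion.params)]
    for key in ("wm", "csf"):
        sig = np.asarray(tissue_signals[key], dtype=float)
        if sig.shape[0] != t:
            raise ValueError(f"tissue signal {key!r} length mismatch")
        columns.append(sig)
    if include_global:
        sig = np.asarray(tissue_signals["global"], dtype=float)
        if sig.shape[0] != t:
            raise ValueError("global signal length mismatch")
        columns.append(sig)

    flagged = np.flatnonzero(fd > fd_threshold)
    if flagged.size >= t - 1:  # FD[0] is 0 by definition, so t-1 means everything moved
        raise ValueError("every volume exceeds the FD threshold; no data left")
    for idx in flagged:
        spike = np.zeros(t)
        spike[idx] = 1.0
        columns.append(spike)

    return np.column_stack(columns)


def regress_nuisance(ts_matrix: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """Residualise time series against nuisance regressors (OLS).

    ts_matrix is (t, n_series). Constant-zero and linearly dependent
    regressor columns are dropped with a warning; residuals are orthogonal
    to every retained column.
    """
    y = np.asarray(ts_matrix, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    X = np.asarray(regressors, dtype=float)
    if y.shape[0] != X.shape[0]:
        raise ValueError("time series and regressors must have the same length")

    keep = ~np.all(X == 0.0, axis=0)
    if not keep.all():
        logger.warning("dropping %d constant-zero regressor columns", (~keep).sum())
    X = X[:, keep]

    # Drop linearly dependent columns (QR with column pivoting).
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        keep_idx = np.sort(piv[:rank])
        logger.warning(
            "rank-deficient nuisance design: keeping %d of %d columns",
            rank,
            X.shape[1],
        )
        X = X[:, keep_idx]

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return resid if np.asarray(ts_matrix).ndim > 1 else resid[:, 0]


def bandpass(
    ts_matrix: np.ndarray,
    tr_seconds: float,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
) -> np.ndarray:
    """Ideal (frequency-domain) band-pass filter along the time axis.

    Retains Fourier components with low_hz <= f <= high_hz; everything else
    (including the DC term) is zeroed. ts_matrix is (t, n_series) or (t,).
    """
    if not 0 <= low_hz < high_hz:
        raise ValueError("require 0 <= low_hz < high_hz")
    nyquist = 1.0 / (2.0 * tr_seconds)
    if high_hz >= nyquist:
        raise ValueError(f"high_hz={high_hz} must be below Nyquist={nyquist:.4f} Hz")

    y = np.asarray(ts_matrix, dtype=float)
    t = y.shape[0]
    freqs = np.fft.rfftfreq(t, d=tr_seconds)
    spectrum = np.fft.rfft(y, axis=0)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spectrum[~keep] = 0.0
    return np.fft.irfft(spectrum, n=t, axis=0)


@dataclass
class HierarchicalParcellation:
    """Label volumes at several spatial scales plus fine->coarse merge maps.

    ``labels`` maps scale id -> 3D integer volume (0 = background);
    ``merge_maps`` maps (scale_from, scale_to) -> {fine label: coarse label};
    ``regions`` is a table with columns scale, region_id, name, hemisphere
    ('L'/'R') and compartment ('cortical'/'subcortical'). ``mask`` is the
    analysis mask shared by all scales, ``affine`` the voxel->world
    transform.
    """

    labels: dict[int, np.ndarray]
    merge_maps: dict[tuple[int, int], dict[int, int]]
    regions: pd.DataFrame
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def scales(self) -> list[int]:
        return sorted(self.labels)

    def region_ids(self, scale: int) -> np.ndarray:
        sub = self.regions[self.regions["scale"] == scale]
        return np.asarray(sorted(sub["region_id"]))

    def n_regions(self, scale: int) -> int:
        return len(self.region_ids(scale))

    def region_table(self, scale: int) -> pd.DataFrame:
        sub = self.regions[self.regions["scale"] == scale]
        return sub.sort_values("region_id").reset_index(drop=True)

    def validate(self) -> None:
        for (sf, st), mapping in self.merge_maps.items():
            merged = merge_parcellation(self, sf, st)
            if not np.array_equal(merged, self.labels[st]):
                raise ValueError(f"merge map {sf}->{st} inconsistent with stored labels")


def merge_parcellation(
    parcellation: HierarchicalParcellation, scale_from: int, scale_to: int
) -> np.ndarray:
    """Relabel a fine-scale volume at a coarser scale via the merge map.

    Chains adjacent merge maps if the pair is not stored directly.
    Background (0) is preserved.
    """
    mapping = _resolve_merge_map(parcellation, scale_from, scale_to)
    fine = parcellation.labels[scale_from]
    out = np.zeros_like(fine)
    present = np.unique(fine)
    for lab in present:
        if lab == 0:
            continue
        if lab not in mapping:
            raise KeyError(f"fine label {lab} missing from merge map {scale_from}->{scale_to}")
        out[fine == lab] = mapping[lab]
    return out


def _resolve_merge_map(
    parcellation: HierarchicalParcellation, scale_from: int, scale_to: int
) -> dict[int, int]:
    if scale_from == scale_to:
        labs = np.unique(parcellation.labels[scale_from])
        return {int(l): int(l) for l in labs if l != 0}
    if (scale_from, scale_to) in parcellation.merge_maps:
        return parcellation.merge_maps[(scale_from, scale_to)]
    # chain through intermediate scales (e.g. 2->4 via 3)
    for (sf, st), first in parcellation.merge_maps.items():
        if sf == scale_from:
            try:
                rest = _resolve_merge_map(parcellation, st, scale_to)
            except KeyError:
                continue
            return {fine: rest[coarse] for fine, coarse in first.items()}
    raise KeyError(f"no merge map from scale {scale_from} to {scale_to}")


def clean_run(
    run: BoldRun,
    mask: np.ndarray,
    motion: MotionTrace,
    fd_threshold: float = 0.5,
    include_global: bool = True,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    wm_mask: np.ndarray | None = None,
    csf_mask: np.ndarray | None = None,
) -> BoldRun:
    """Nuisance-regress then band-pass a run; returns a cleaned copy.

    Tissue signals are mean series over the supplied masks; when a tissue
    mask is absent the analysis mask mean stands in (synthetic data carries
    no tissue segmentation). The regression-then-filter order is fixed.
    """
    mask = np.asarray(mask, dtype=bool)
    data = run.data
    t = data.shape[3]
    in_mask = data[mask]  # (n_vox, t)
    global_sig = in_mask.mean(axis=0)
    wm_sig = data[np.asarray(wm_mask, bool)].mean(axis=0) if wm_mask is not None else global_sig
    csf_sig = data[np.asarray(csf_mask, bool)].mean(axis=0) if csf_mask is not None else global_sig
    design = build_nuisance(
        motion,
        {"wm": wm_sig, "csf": csf_sig, "global": global_sig},
        fd_threshold=fd_threshold,
        include_global=include_global,
    )
    resid = regress_nuisance(in_mask.T, design)
    filtered = bandpass(resid, run.tr_seconds, low_hz, high_hz)
    out = np.zeros_like(data)
    out[mask] = filtered.T
    return BoldRun(run.subject_id, out, run.tr_seconds, run.affine)
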