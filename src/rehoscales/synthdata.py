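"""Seeded synthetic cohorts and expression bundles with planted structure.

The generator emulates every input of the analysis: a hierarchical
block parcellation on a voxel grid, a two-group resting-state cohort in
which patients carry extra *local synchrony* (a region-shared latent
series mixed into the voxel noise, which is exactly what Kendall's-W
regional homogeneity responds to), symptom scores correlated with the
per-subject effect strength, head-motion traces with scrub-worthy spikes,
and an AHBA-style probe bundle whose planted co-expression module tracks
a supplied effect map so that the module eigengene correlates spatially
with the case-control difference map at a configured target.

Everything is a pure function of :class:`SimulationConfig`; all random
streams are spawned from the single seed, so identical configs give
bit-identical outputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import BoldRun, HierarchicalParcellation, MotionTrace

logger = logging.getLogger(__name__)

VOXEL_SCALE = 1  # scale id of the voxel level; labelled scales start at 2

# Symptom-scale summary statistics used for the synthetic patient scores
# (mean, SD, scale minimum).
PANSS_DISTRIBUTIONS = {
    "panss_total": (71.1, 22.3, 30),
    "panss_positive": (16.8, 7.7, 7),
    "panss_negative": (20.0, 8.9, 7),
    "panss_general": (34.3, 10.5, 16),
}
AGE_DISTRIBUTIONS = {"patient": (33.9, 9.6), "control": (33.7, 11.0)}
MALE_FRACTIONS = {"patient": 54 / 103, "control": 45 / 110}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with desk-scale defaults."""

    seed: int = 0
    grid_dims: tuple[int, int, int] = (16, 16, 16)
    n_timepoints: int = 150
    tr_seconds: float = 2.0
    n_per_group: tuple[int, int] = (30, 30)  # (patients, controls)
    n_regions: tuple[int, ...] = (16, 4, 2)  # labelled scales 2, 3, 4
    effect_regions: tuple[int, ...] = (1, 6, 11)  # fine-scale region ids
    synchrony_effect: float = 0.8
    synchrony_spread: float = 0.15  # relative per-subject variation of the effect
    clinical_link: tuple[tuple[int, float], ...] = ((1, 0.32),)
    subcortical_fraction: float = 0.3  # innermost fraction of regions per scale
    n_genes: int = 300
    n_modules: int = 3
    module_sizes: tuple[int, ...] = (80, 80, 80)
    planted_module: int = 1  # module label whose latent tracks the effect map
    planted_me_t_corr: float = 0.7
    n_expression_samples: int = 200
    n_donors: int = 4
    probes_per_gene: int = 2
    absent_probe_fraction: float = 0.25
    noise_sd: float = 0.5
    voxel_size_mm: float = 3.0

    def __post_init__(self) -> None:
        # accept plain lists (e.g. parsed YAML) for the sequence fields
        for name in ("grid_dims", "n_per_group", "n_regions", "effect_regions", "module_sizes"):
            setattr(self, name, tuple(getattr(self, name)))
        self.clinical_link = tuple(tuple(pair) for pair in self.clinical_link)
        if any(d < 8 for d in self.grid_dims):
            raise ValueError("grid dimensions must each be >= 8")
        if self.n_timepoints < 60:
            raise ValueError("need at least 60 timepoints")
        if not 0.0 <= self.synchrony_effect <= 1.0:
            raise ValueError("synchrony_effect must lie in [0, 1]")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes must sum to at most n_genes")
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes must have n_modules entries")
        if self.n_regions[0] > int(np.prod(self.grid_dims)):
            raise ValueError("more regions requested than voxels")

    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        # centre the grid on the world origin so hemispheres split at x = 0
        aff[:3, 3] = -self.voxel_size_mm * (np.array(self.grid_dims) - 1) / 2.0
        return aff


@dataclass
class GroundTruth:
    """Planted-parameter record for recovery tests."""

    effect_region_ids: tuple[int, ...]
    latent_driver: pd.Series | None = None  # per-patient clinical driver z
    subject_strength: pd.Series | None = None  # per-subject synchrony weight
    gene_module: pd.Series | None = None  # gene -> module label
    planted_me_t_corr: float | None = None
    clinical_targets: tuple[tuple[int, float], ...] = ()


def _factor3(n: int, prefer_even_x: bool = True) -> tuple[int, int, int]:
    """Factor n into three near-equal integers (x-factor even when possible)."""
    best = None
    for a in range(1, n + 1):
        if n % a:
            continue
        for b in range(1, n // a + 1):
            if (n // a) % b:
                continue
            c = n // (a * b)
            dims = (a, b, c)
            spread = max(dims) - min(dims)
            even_penalty = 0 if (a % 2 == 0 or not prefer_even_x) else 1
            key = (even_penalty, spread, -a)
            if best is None or key < best[0]:
                best = (key, dims)
    return best[1]


def _dividing_factors(n: int, parent: tuple[int, int, int]) -> tuple[int, int, int]:
    """Factor n into three integers dividing ``parent`` elementwise."""
    best = None
    for a in range(1, parent[0] + 1):
        if n % a or parent[0] % a:
            continue
        for b in range(1, parent[1] + 1):
            if (n // a) % b or parent[1] % b:
                continue
            c = n // (a * b)
            if c > parent[2] or parent[2] % c:
                continue
            dims = (a, b, c)
            even_penalty = 0 if a % 2 == 0 else 1
            key = (even_penalty, max(dims) - min(dims), -a)
            if best is None or key < best[0]:
                best = (key, dims)
    if best is None:
        raise ValueError(f"cannot nest {n} regions inside block grid {parent}")
    return best[1]


def _block_labels(grid_dims, factors) -> np.ndarray:
    nx, ny, nz = grid_dims
    bx, by, bz = factors
    ix = np.minimum((np.arange(nx) * bx) // nx, bx - 1)
    iy = np.minimum((np.arange(ny) * by) // ny, by - 1)
    iz = np.minimum((np.arange(nz) * bz) // nz, bz - 1)
    lab = (
        ix[:, None, None] * (by * bz)
        + iy[None, :, None] * bz
        + iz[None, None, :]
        + 1
    )
    return np.broadcast_to(lab, grid_dims).copy()


def make_atlas(config: SimulationConfig) -> HierarchicalParcellation:
    """Hierarchical block parcellation of the full grid.

    Labelled scales 2, 3, ... partition the mask into contiguous axis-aligned
    blocks; each coarser scale is an exact union of finer blocks, recorded in
    the merge maps. Region metadata marks hemisphere by the sign of the
    region centre's x world coordinate and compartment by a distance shell:
    the innermost ``subcortical_fraction`` of regions (by centroid distance
    from the grid centre) are subcortical, the rest cortical.
    """
    dims = config.grid_dims
    scale_sizes = config.n_regions
    if list(scale_sizes) != sorted(scale_sizes, reverse=True):
        raise ValueError("region counts must decrease with scale")
    if scale_sizes[0] > int(np.prod(dims)):
        raise ValueError("more regions requested than voxels")

    factors = [_factor3(scale_sizes[0])]
    for n in scale_sizes[1:]:
        factors.append(_dividing_factors(n, factors[-1]))

    labels: dict[int, np.ndarray] = {}
    merge_maps: dict[tuple[int, int], dict[int, int]] = {}
    for level, (n, fac) in enumerate(zip(scale_sizes, factors)):
        scale = level + 2
        labels[scale] = _block_labels(dims, fac)
    for level in range(1, len(scale_sizes)):
        fine_scale, coarse_scale = level + 1, level + 2
        ff, cf = factors[level - 1], factors[level]
        mapping = {}
        for ix in range(ff[0]):
            for iy in range(ff[1]):
                for iz in range(ff[2]):
                    fine_label = ix * ff[1] * ff[2] + iy * ff[2] + iz + 1
                    cx = ix // (ff[0] // cf[0])
                    cy = iy // (ff[1] // cf[1])
                    cz = iz // (ff[2] // cf[2])
                    mapping[fine_label] = cx * cf[1] * cf[2] + cy * cf[2] + cz + 1
        merge_maps[(fine_scale, coarse_scale)] = mapping

    mask = np.ones(dims, dtype=bool)
    affine = config.affine()
    centre = (np.array(dims) - 1) / 2.0

    rows = []
    for level, n in enumerate(scale_sizes):
        scale = level + 2
        lab = labels[scale]
        centroids = {}
        for rid in range(1, n + 1):
            vox = np.argwhere(lab == rid)
            centroids[rid] = vox.mean(axis=0)
        dist = {rid: float(np.linalg.norm(c - centre)) for rid, c in centroids.items()}
        order = sorted(dist, key=lambda r: (dist[r], r))
        n_sub = min(max(int(np.floor(config.subcortical_fraction * n)), 1), n - 1)
        subcortical = set(order[:n_sub])
        for rid in range(1, n + 1):
            world_x = (affine[:3, :3] @ centroids[rid])[0] + affine[0, 3]
            rows.append(
                {
                    "scale": scale,
                    "region_id": rid,
                    "name": f"s{scale}_r{rid:03d}",
                    "hemisphere": "L" if world_x < 0 else "R",
                    "compartment": "subcortical" if rid in subcortical else "cortical",
                }
            )
    regions = pd.DataFrame(rows)
    return HierarchicalParcellation(
        labels=labels, merge_maps=merge_maps, regions=regions, mask=mask, affine=affine
    )


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def make_cohort(
    config: SimulationConfig, atlas: HierarchicalParcellation
) -> tuple[list[BoldRun], list[MotionTrace], pd.DataFrame, GroundTruth]:
    """Two-group BOLD cohort with planted local synchrony in patients.

    Each subject's voxel time series is unit-variance white noise; within
    the effect regions, patient voxels are mixed with a region-shared latent
    series, x <- (1 - s) * noise + s * latent, re-standardised, where s is
    the subject's effect strength (the configured synchrony weight with
    mild per-subject spread). Symptom scores are linear transforms of the
    per-subject latent driver with closed-form attenuation to the target
    correlation. Motion traces are smooth random walks with occasional
    displacement spikes exceeding the 0.5 mm scrub threshold.
    """
    n_pat, n_con = config.n_per_group
    if min(n_pat, n_con) < 3:
        raise ValueError("need at least 3 subjects per group")
    rng_subj, rng_bold, rng_motion, rng_clin = _streams(config.seed, 4)

    subjects = [f"P{i + 1:03d}" for i in range(n_pat)] + [f"C{i + 1:03d}" for i in range(n_con)]
    groups = ["patient"] * n_pat + ["control"] * n_con

    ages, sexes = [], []
    for grp in groups:
        mu, sd = AGE_DISTRIBUTIONS[grp]
        ages.append(float(np.clip(np.round(rng_subj.normal(mu, sd), 1), 18.0, 70.0)))
        sexes.append("M" if rng_subj.random() < MALE_FRACTIONS[grp] else "F")

    # Per-patient latent clinical driver and effect strength.
    z = rng_clin.standard_normal(n_pat)
    w = config.synchrony_effect
    strength_pat = np.clip(w * (1.0 + config.synchrony_spread * z), 0.0, 1.0)
    strength = np.concatenate([strength_pat, np.zeros(n_con)])

    target_rho = config.clinical_link[0][1] if config.clinical_link else 0.0
    scores = {}
    for name, (mu, sd, floor_val) in PANSS_DISTRIBUTIONS.items():
        eps = rng_clin.standard_normal(n_pat)
        latent = target_rho * z + np.sqrt(max(0.0, 1 - target_rho**2)) * eps
        vals = np.round(mu + sd * latent).clip(min=floor_val)
        scores[name] = np.concatenate([vals, np.full(n_con, np.nan)])

    fine_scale = 2
    labels = atlas.labels[fine_scale]
    effect_masks = {rid: labels == rid for rid in config.effect_regions}
    t_len = config.n_timepoints
    affine = config.affine()

    runs, motions = [], []
    for j, sid in enumerate(subjects):
        data = rng_bold.standard_normal(config.grid_dims + (t_len,))
        s = strength[j]
        if s > 0:
            for rid, region_mask in effect_masks.items():
                latent = rng_bold.standard_normal(t_len)
                mixed = (1.0 - s) * data[region_mask] + s * latent
                data[region_mask] = mixed / np.sqrt((1.0 - s) ** 2 + s**2)
        else:
            # consume the same number of draws so patient/control streams stay aligned
            for _ in effect_masks:
                rng_bold.standard_normal(t_len)
        runs.append(BoldRun(sid, data, config.tr_seconds, affine))

        steps = np.column_stack(
            [rng_motion.normal(0.0, 0.01, (t_len, 3)), rng_motion.normal(0.0, 2e-4, (t_len, 3))]
        )
        params = np.cumsum(steps, axis=0)
        n_spikes = rng_motion.integers(1, 4)
        for v in rng_motion.choice(np.arange(5, t_len - 1), size=n_spikes, replace=False):
            params[v, rng_motion.integers(0, 3)] += 0.65  # FD spike > 0.5 mm
        motions.append(MotionTrace(params))

    participants = pd.DataFrame(
        {
            "subject_id": subjects,
            "group": groups,
            "age": ages,
            "sex": sexes,
            **scores,
        }
    )
    truth = GroundTruth(
        effect_region_ids=tuple(config.effect_regions),
        latent_driver=pd.Series(z, index=subjects[:n_pat]),
        subject_strength=pd.Series(strength, index=subjects),
        planted_me_t_corr=config.planted_me_t_corr,
        clinical_targets=tuple(config.clinical_link),
    )
    return runs, motions, participants, truth


def synthetic_effect_map(
    atlas: HierarchicalParcellation, effect_regions, seed: int = 0, effect_size: float = 3.0
) -> np.ndarray:
    """Piecewise-constant pseudo t-map: regional baseline + boost in effect regions."""
    rng = np.random.default_rng(seed)
    labels = atlas.labels[2]
    out = np.zeros(labels.shape, dtype=float)
    for rid in np.unique(labels):
        if rid == 0:
            continue
        val = rng.standard_normal()
        if rid in set(effect_regions):
            val += effect_size
        out[labels == rid] = val
    return out


def make_expression_bundle(
    config: SimulationConfig,
    atlas: HierarchicalParcellation,
    effect_tmap: np.ndarray,
):
    """AHBA-style probe bundle with a planted effect-tracking module.

    Samples are placed at jittered in-mask voxel centres in the left
    hemisphere across ``n_donors`` pseudo-donors. Gene expression is module
    latent x loading + noise; the planted module's latent is an affine
    function of the local effect-map value at each sample (target spatial
    correlation ``planted_me_t_corr`` in expectation). Each gene carries
    ``probes_per_gene`` probes; a configurable fraction of the redundant
    (non-primary) probes is marked below background, and the RNA-seq twin
    is a monotone transform of the primary probe plus noise.
    """
    from .transcript import ProbeBundle, SampleAnnotation

    if effect_tmap.shape != atlas.mask.shape:
        raise ValueError("effect map must live on the atlas grid")
    n_samples = config.n_expression_samples
    if n_samples < 15:
        warnings.warn(
            "fewer than 15 expression samples requested; module detection "
            "downstream will refuse this dataset",
            stacklevel=2,
        )
    rng_pos, rng_expr, rng_probe = _streams(config.seed + 1, 3)

    fine_scale = 2
    region_table = atlas.region_table(fine_scale).set_index("region_id")
    left_ids = set(region_table.index[region_table["hemisphere"] == "L"])
    labels = atlas.labels[fine_scale]
    left_vox = np.argwhere(np.isin(labels, list(left_ids)) & atlas.mask)
    if len(left_vox) == 0:
        raise ValueError("no left-hemisphere voxels in the atlas")

    pick = rng_pos.integers(0, len(left_vox), size=n_samples)
    ijk = left_vox[pick]
    jitter = rng_pos.uniform(-0.4, 0.4, size=(n_samples, 3))
    world = (atlas.affine[:3, :3] @ (ijk + jitter).T).T + atlas.affine[:3, 3]
    donors = np.array([f"D{1 + (i % config.n_donors)}" for i in rng_pos.permutation(n_samples)])
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    compartments = region_table.loc[labels[tuple(ijk.T)], "compartment"].to_numpy()

    annotations = SampleAnnotation(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "donor": donors,
                "x": world[:, 0],
                "y": world[:, 1],
                "z": world[:, 2],
                "hemisphere": "L",
                "compartment": compartments,
            }
        )
    )

    t_at_sample = effect_tmap[tuple(ijk.T)]
    rho = config.planted_me_t_corr
    latents = {}
    for m in range(1, config.n_modules + 1):
        if m == config.planted_module:
            zt = (t_at_sample - t_at_sample.mean()) / t_at_sample.std()
            latents[m] = rho * zt + np.sqrt(max(0.0, 1 - rho**2)) * rng_expr.standard_normal(n_samples)
        else:
            latents[m] = rng_expr.standard_normal(n_samples)

    gene_names = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    gene_module = np.zeros(config.n_genes, dtype=int)
    start = 0
    for m, size in enumerate(config.module_sizes, start=1):
        gene_module[start : start + size] = m
        start += size

    expr = np.empty((config.n_genes, n_samples))
    for g in range(config.n_genes):
        m = gene_module[g]
        if m == 0:
            expr[g] = rng_expr.standard_normal(n_samples)
        else:
            loading = rng_expr.uniform(0.6, 1.0)
            expr[g] = loading * latents[m] + config.noise_sd * rng_expr.standard_normal(n_samples)

    # Probe layer: primary probe (p0) is the cleanest; extras get more noise.
    probe_ids, probe_gene, probe_rows = [], [], []
    for g, gene in enumerate(gene_names):
        for p in range(config.probes_per_gene):
            probe_ids.append(f"{gene}_p{p}")
            probe_gene.append(gene)
            extra_sd = config.noise_sd * (0.1 + 0.3 * p)
            probe_rows.append(expr[g] + extra_sd * rng_probe.standard_normal(n_samples))
    expression = pd.DataFrame(probe_rows, index=probe_ids, columns=sample_ids)
    probe2gene = pd.Series(probe_gene, index=probe_ids)

    secondary = [pid for pid in probe_ids if not pid.endswith("_p0")]
    n_absent = int(round(config.absent_probe_fraction * len(secondary)))
    absent = set(rng_probe.choice(secondary, size=n_absent, replace=False)) if n_absent else set()
    call_rows = []
    for pid in probe_ids:
        frac = 0.3 if pid in absent else 0.9
        call_rows.append((rng_probe.random(n_samples) < frac).astype(int))
    pacalls = pd.DataFrame(call_rows, index=probe_ids, columns=sample_ids)

    primary = expression.loc[[f"{g}_p0" for g in gene_names]].to_numpy()
    rnaseq_vals = np.exp(0.5 * primary) + 0.2 * config.noise_sd * rng_probe.standard_normal(primary.shape)
    rnaseq = pd.DataFrame(rnaseq_vals, index=gene_names, columns=sample_ids)

    bundle = ProbeBundle(
        expression=expression,
        probe2gene=probe2gene,
        pacalls=pacalls,
        rnaseq=rnaseq,
        donors=pd.Series(donors, index=sample_ids),
    )
    truth = GroundTruth(
        effect_region_ids=(),
        gene_module=pd.Series(gene_module, index=gene_names),
        planted_me_t_corr=rho,
    )
    return bundle, annotations, truth
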