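"""Microarray expression processing in the AHBA style.

A probe-level expression bundle (probe x sample intensities, probe->gene
map, present/absent detection calls, an RNA-seq twin of the same tissue,
donor and stereotaxic annotation per sample) is reduced to a gene x sample
matrix and then to gene x region matrices through a fixed sequence:

1. probe -> gene reassignment (table-driven; the mapping is an input),
2. background filter: drop probes expressed above background in <= 50%
   of samples ("over 50%" is strict),
3. drop genes with no RNA-seq measurement,
4. drop probes with Spearman rho < 0.2 against their gene's RNA-seq profile,
5. keep one representative probe per gene (highest rho, ties -> lowest
   probe id),
6. differential stability (DS): mean inter-donor correlation of regional
   expression profiles; keep the top half of genes by DS.

Sample-to-region assignment is nearest labelled voxel centre in world mm,
with a distance cap; regional expression is the mean over assigned samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .imaging import HierarchicalParcellation

logger = logging.getLogger(__name__)

RHO_THRESHOLD = 0.2
MIN_SHARED_SAMPLES = 4  # Spearman rho on fewer shared samples is refused


@dataclass
class ProbeBundle:
    """Probe-level expression with annotations.

    expression: probe x sample DataFrame; probe2gene: Series probe -> gene
    symbol; pacalls: 0/1 DataFrame, same shape as expression (1 = above
    background); rnaseq: gene x sample DataFrame (the RNA-seq twin);
    donors: Series sample -> donor id.
    """

    expression: pd.DataFrame
    probe2gene: pd.Series
    pacalls: pd.DataFrame
    rnaseq: pd.DataFrame
    donors: pd.Series

    def __post_init__(self) -> None:
        if self.pacalls.shape != self.expression.shape:
            raise ValueError("pacalls must have the same shape as expression")
        if not self.expression.index.equals(self.pacalls.index):
            raise ValueError("pacalls index must match expression probes")
        if self.probe2gene.index.duplicated().any():
            raise ValueError("a probe may map to at most one gene")


@dataclass
class SampleAnnotation:
    """Tissue-sample annotation table.

    Columns: sample_id, donor, x, y, z (world mm), hemisphere ('L'/'R'),
    compartment ('cortical'/'subcortical').
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "donor", "x", "y", "z", "hemisphere", "compartment")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"sample annotation missing columns: {sorted(missing)}")

    def left_hemisphere(self) -> "SampleAnnotation":
        return SampleAnnotation(self.table[self.table["hemisphere"] == "L"].reset_index(drop=True))


@dataclass
class DSResult:
    scores: pd.Series  # per-gene differential stability
    retained: pd.Index  # top half by DS

    def __post_init__(self) -> None:
        s = self.scores.dropna()
        if len(s) and (s.min() < -1 - 1e-9 or s.max() > 1 + 1e-9):
            raise ValueError("DS scores must lie in [-1, 1]")


def filter_probes_background(bundle: ProbeBundle) -> pd.Index:
    """Probes detected above background in strictly more than 50% of samples."""
    frac_present = bundle.pacalls.mean(axis=1)
    return bundle.expression.index[frac_present > 0.5]


def select_representative_probes(
    bundle: ProbeBundle,
    probes: pd.Index | None = None,
    rho_threshold: float = RHO_THRESHOLD,
) -> pd.DataFrame:
    """Collapse probes to one representative per gene via RNA-seq concordance.

    Restricted to ``probes`` when given (e.g. the background-filtered set).
    Genes without RNA-seq coverage are removed first. Each remaining probe is
    scored by Spearman rho against its gene's RNA-seq profile on shared
    samples; probes with rho < ``rho_threshold`` are dropped, and the
    highest-rho probe represents each gene (ties -> lowest probe id).
    Returns the gene x sample expression matrix.
    """
    expr = bundle.expression if probes is None else bundle.expression.loc[probes]
    shared_samples = expr.columns.intersection(bundle.rnaseq.columns)
    if len(shared_samples) < MIN_SHARED_SAMPLES:
        raise ValueError(
            f"need at least {MIN_SHARED_SAMPLES} samples shared with RNA-seq, "
            f"got {len(shared_samples)}"
        )

    best: dict[str, tuple[float, object]] = {}
    for probe in expr.index:
        gene = bundle.probe2gene.get(probe)
        if gene is None or gene not in bundle.rnaseq.index:
            continue  # no RNA-seq measure for this gene
        x = expr.loc[probe, shared_samples].to_numpy(float)
        y = bundle.rnaseq.loc[gene, shared_samples].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("constant profile for probe %s; dropped (rho undefined)", probe)
            continue
        rho = stats.spearmanr(x, y).statistic
        if np.isnan(rho) or rho < rho_threshold:
            continue
        incumbent = best.get(gene)
        # strict > keeps the lowest probe id on ties (probes iterate in index order
        # for equal rho; enforce explicitly for robustness)
        if incumbent is None or rho > incumbent[0] or (rho == incumbent[0] and probe < incumbent[1]):
            best[gene] = (rho, probe)

    genes = sorted(best)
    rows = expr.loc[[best[g][1] for g in genes]]
    rows.index = pd.Index(genes, name="gene")
    return rows


def differential_stability(
    gene_sample: pd.DataFrame,
    sample_donors: pd.Series,
    sample_regions: pd.Series,
    min_common_regions: int = 3,
) -> DSResult:
    """Differential stability: mean inter-donor correlation of regional profiles.

    For every donor, per-gene regional-mean expression profiles are formed;
    for every donor pair with >= ``min_common_regions`` shared regions, the
    Pearson correlation between their profiles (common regions only) is
    computed per gene, and DS is the mean over pairs. Retains the top
    ceil(G/2) genes by DS.
    """
    donors = sorted(sample_donors.unique())
    if len(donors) < 2:
        raise ValueError("differential stability needs at least 2 donors")

    profiles: dict[object, pd.DataFrame] = {}
    for donor in donors:
        cols = sample_donors.index[sample_donors == donor]
        cols = gene_sample.columns.intersection(cols)
        regions = sample_regions.loc[cols]
        prof = gene_sample[cols].T.groupby(regions).mean().T  # gene x region
        profiles[donor] = prof

    pair_corrs = []
    for i, d1 in enumerate(donors):
        for d2 in donors[i + 1 :]:
            common = profiles[d1].columns.intersection(profiles[d2].columns)
            if len(common) < min_common_regions:
                logger.warning(
                    "donor pair (%s, %s) has %d common regions (<%d); skipped",
                    d1, d2, len(common), min_common_regions,
                )
                continue
            a = profiles[d1][common].to_numpy(float)
            b = profiles[d2][common].to_numpy(float)
            a = a - a.mean(axis=1, keepdims=True)
            b = b - b.mean(axis=1, keepdims=True)
            denom = np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (a * b).sum(axis=1) / denom
            pair_corrs.append(pd.Series(r, index=gene_sample.index))
    if not pair_corrs:
        raise ValueError("no donor pair had enough common regions")

    ds = pd.concat(pair_corrs, axis=1).mean(axis=1)
    n_keep = int(np.ceil(len(ds) / 2))
    order = ds.sort_values(ascending=False, kind="stable")
    retained = order.index[:n_keep]
    return DSResult(scores=ds, retained=retained)


def assign_samples(
    annotations: SampleAnnotation,
    parcellation: HierarchicalParcellation,
    scale: int,
    max_distance: float | None = None,
) -> pd.Series:
    """Assign each sample to the region of its nearest labelled voxel centre.

    Distances are Euclidean in world mm via the parcellation affine.
    Samples farther than ``max_distance`` (default 2x the voxel size) from
    any labelled voxel stay unassigned (NaN, logged). Exact distance ties go
    to the lowest region id.
    """
    labels = parcellation.labels[scale]
    ijk = np.argwhere(labels > 0)
    if ijk.size == 0:
        raise ValueError(f"no labelled voxels at scale {scale}")
    affine = parcellation.affine
    voxel_size = float(np.cbrt(abs(np.linalg.det(affine[:3, :3]))))
    if max_distance is None:
        max_distance = 2.0 * voxel_size
    centres = (affine[:3, :3] @ ijk.T).T + affine[:3, 3]
    voxel_regions = labels[tuple(ijk.T)]

    out = {}
    for _, row in annotations.table.iterrows():
        pt = np.array([row["x"], row["y"], row["z"]], dtype=float)
        d = np.linalg.norm(centres - pt, axis=1)
        dmin = d.min()
        if dmin > max_distance:
            logger.warning(
                "sample %s is %.2f mm from the nearest labelled voxel (cap %.2f); unassigned",
                row["sample_id"], dmin, max_distance,
            )
            out[row["sample_id"]] = np.nan
            continue
        candidates = voxel_regions[d <= dmin + 1e-9]
        out[row["sample_id"]] = int(candidates.min())
    return pd.Series(out, name="region")


def regional_expression(
    gene_sample: pd.DataFrame, assignments: pd.Series
) -> pd.DataFrame:
    """Average expression of all assigned samples within each region.

    Unassigned samples are ignored; regions with no samples simply do not
    appear in the output (logged by the caller against the parcellation).
    """
    assigned = assignments.dropna()
    cols = gene_sample.columns.intersection(assigned.index)
    grouped = gene_sample[cols].T.groupby(assigned.loc[cols].astype(int)).mean().T
    grouped.columns.name = "region"
    return grouped


@dataclass
class ProcessedExpression:
    """Output of the probe-to-gene pipeline plus provenance counts."""

    gene_sample: pd.DataFrame
    ds: DSResult
    log: dict = field(default_factory=dict)


def process_bundle(
    bundle: ProbeBundle,
    annotations: SampleAnnotation,
    parcellation: HierarchicalParcellation,
    ds_scale: int,
    rho_threshold: float = RHO_THRESHOLD,
    left_only: bool = True,
) -> ProcessedExpression:
    """Run the fixed probe pipeline and DS filter; returns gene x sample data.

    The stage order (background filter -> RNA-seq gene filter -> rho filter
    -> representative probe -> DS) is fixed; ``ds_scale`` names the
    parcellation scale whose regions anchor the DS regional profiles.
    """
    ann = annotations.left_hemisphere() if left_only else annotations
    sample_ids = ann.table["sample_id"]
    bundle = ProbeBundle(
        expression=bundle.expression[sample_ids],
        probe2gene=bundle.probe2gene,
        pacalls=bundle.pacalls[sample_ids],
        rnaseq=bundle.rnaseq[bundle.rnaseq.columns.intersection(sample_ids)],
        donors=bundle.donors.loc[sample_ids],
    )
    kept_probes = filter_probes_background(bundle)
    gene_sample = select_representative_probes(bundle, kept_probes, rho_threshold)

    assignments = assign_samples(ann, parcellation, ds_scale)
    assignments.index.name = "sample_id"
    ds = differential_stability(
        gene_sample,
        bundle.donors,
        assignments,
    )
    retained = gene_sample.loc[ds.retained.sort_values()]
    log = {
        "n_probes_in": int(len(bundle.expression)),
        "n_probes_background": int(len(kept_probes)),
        "n_genes_representative": int(len(gene_sample)),
        "n_genes_retained_ds": int(len(retained)),
        "n_samples": int(len(sample_ids)),
    }
    return ProcessedExpression(gene_sample=retained, ds=ds, log=log)
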