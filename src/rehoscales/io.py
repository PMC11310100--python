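"""On-disk formats: NIfTI volumes, TSV tables, YAML configs.

Voxel coordinates are 0-based; world coordinates go through the NIfTI
affine. Motion files are TSV with header ``tx ty tz rx ry rz``
(translations in mm, rotations in radians). Merge maps are TSV with
columns ``scale_from_id``/``scale_to_id``.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .imaging import BoldRun, HierarchicalParcellation, MotionTrace
from .transcript import ProbeBundle, SampleAnnotation


def save_nifti(data: np.ndarray, affine: np.ndarray, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.asarray(affine))
    nib.save(img, str(path))
    return path


def load_bold(path, subject_id: str, tr_seconds: float) -> BoldRun:
    img = nib.load(str(path))
    return BoldRun(subject_id, np.asarray(img.dataobj, dtype=float), tr_seconds, img.affine)


def save_motion(motion: MotionTrace, path) -> Path:
    path = Path(path)
    pd.DataFrame(motion.params, columns=["tx", "ty", "tz", "rx", "ry", "rz"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def load_motion(path) -> MotionTrace:
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    expected = ["tx", "ty", "tz", "rx", "ry", "rz"]
    if list(table.columns) != expected:
        raise ValueError(f"motion file must have columns {expected}, got {list(table.columns)}")
    return MotionTrace(table.to_numpy(float))


def save_parcellation(parcellation: HierarchicalParcellation, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_nifti(parcellation.mask.astype(np.int16), parcellation.affine, out_dir / "mask.nii.gz")
    for scale, labels in parcellation.labels.items():
        save_nifti(labels.astype(np.int16), parcellation.affine, out_dir / f"labels_scale{scale}.nii.gz")
    for (sf, st), mapping in parcellation.merge_maps.items():
        pd.DataFrame(
            sorted(mapping.items()), columns=["scale_from_id", "scale_to_id"]
        ).to_csv(out_dir / f"merge_{sf}_to_{st}.tsv", sep="\t", index=False)
    parcellation.regions.to_csv(out_dir / "regions.tsv", sep="\t", index=False)
    return out_dir


def save_bundle(bundle: ProbeBundle, annotations: SampleAnnotation, out_dir) -> Path:
    """Write the expression bundle in its five-file TSV layout."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"probe_id": bundle.probe2gene.index, "gene_symbol": bundle.probe2gene.values}
    ).to_csv(out_dir / "probes.tsv", sep="\t", index=False)
    bundle.expression.to_csv(out_dir / "expression.tsv", sep="\t")
    bundle.pacalls.to_csv(out_dir / "pacalls.tsv", sep="\t")
    bundle.rnaseq.to_csv(out_dir / "rnaseq.tsv", sep="\t")
    annotations.table.to_csv(out_dir / "samples.tsv", sep="\t", index=False)
    return out_dir


def load_bundle(bundle_dir) -> tuple[ProbeBundle, SampleAnnotation]:
    bundle_dir = Path(bundle_dir)
    probes = pd.read_csv(bundle_dir / "probes.tsv", sep="\t", float_precision="round_trip")
    expression = pd.read_csv(bundle_dir / "expression.tsv", sep="\t", index_col=0, float_precision="round_trip")
    pacalls = pd.read_csv(bundle_dir / "pacalls.tsv", sep="\t", index_col=0, float_precision="round_trip")
    rnaseq = pd.read_csv(bundle_dir / "rnaseq.tsv", sep="\t", index_col=0, float_precision="round_trip")
    samples = pd.read_csv(bundle_dir / "samples.tsv", sep="\t", float_precision="round_trip")
    donors = pd.Series(samples["donor"].values, index=samples["sample_id"].values)
    bundle = ProbeBundle(
        expression=expression,
        probe2gene=pd.Series(probes["gene_symbol"].values, index=probes["probe_id"].values),
        pacalls=pacalls,
        rnaseq=rnaseq,
        donors=donors,
    )
    return bundle, SampleAnnotation(samples)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg
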