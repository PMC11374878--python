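"""File formats: NIfTI volumes, FSL bval/bvec, TCK/TRK streamlines, TSV.

All volumes are written as NIfTI-1 with an RAS affine in mm; streamlines
are stored in world (mm) coordinates (TCK native; TRK through nibabel's
voxel-convention handling).  Every pipeline run can write a JSON manifest
recording the configuration, the seed and input hashes, so outputs are
reproducible byte for byte from the manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .gradients import GradientTable, detect_shells
from .tracking import Tractogram

__all__ = [
    "read_dwi",
    "write_dwi",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
    "read_mask",
    "write_mask",
    "write_scalar_map",
    "read_streamlines",
    "write_streamlines",
    "write_manifest",
]


def read_bvals_bvecs(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    """FSL convention: bvals one row; bvecs three rows (x, y, z)."""
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.ndim == 1:
        bvecs = bvecs.reshape(-1, 3)
    return bvals, bvecs


def write_bvals_bvecs(bval_path, bvec_path, gtab: GradientTable) -> None:
    np.savetxt(bval_path, gtab.bvals[None, :], fmt="%.1f")
    np.savetxt(bvec_path, gtab.bvecs.T, fmt="%.8f")


def read_dwi(nifti_path, bval_path, bvec_path):
    """Load a 4D DWI and its gradient table.

    Shells are auto-detected by b-value clustering (+-50 s/mm^2); non-unit
    direction vectors are normalized with a warning.  Returns
    (data, affine, GradientTable).
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.get_fdata())
    bvals, bvecs = read_bvals_bvecs(bval_path, bvec_path)
    if data.ndim != 4 or data.shape[3] != bvals.shape[0]:
        raise ValueError(
            f"volume count mismatch: image has {data.shape[3] if data.ndim == 4 else 'no'} "
            f"volumes, gradient table has {bvals.shape[0]}"
        )
    dw = bvals > 50.0
    norms = np.linalg.norm(bvecs[dw], axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        import warnings

        warnings.warn("non-unit gradient directions found; normalizing")
        bvecs = bvecs.copy()
        bvecs[dw] = bvecs[dw] / norms[:, None]
    gtab = GradientTable(bvals, bvecs, detect_shells(bvals))
    return data, img.affine, gtab


def write_dwi(nifti_path, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(nifti_path))


def read_mask(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()) > 0.5, img.affine


def write_mask(path, mask: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def write_scalar_map(path, scalar_map, affine: np.ndarray, sidecar: dict | None = None) -> None:
    """Write a quantitative map as float32 NIfTI plus a JSON sidecar."""
    nib.save(nib.Nifti1Image(scalar_map.data.astype(np.float32), affine), str(path))
    meta = {"metric": scalar_map.name, "units": scalar_map.units}
    if sidecar:
        meta.update(sidecar)
    Path(str(path)).with_suffix("").with_suffix(".json").write_text(
        json.dumps(meta, indent=2, sort_keys=True)
    )


def write_streamlines(path, tractogram: Tractogram, affine: np.ndarray | None = None) -> None:
    """Write TCK or TRK (by extension); coordinates are world mm."""
    path = str(path)
    sl = [np.asarray(s, dtype=np.float32) for s in tractogram.streamlines]
    nt = nib.streamlines.Tractogram(sl, affine_to_rasmm=np.eye(4))
    if path.endswith(".tck"):
        nib.streamlines.save(nt, path)
    elif path.endswith(".trk"):
        header = {}
        if affine is not None:
            header[nib.streamlines.trk.Field.VOXEL_TO_RASMM] = affine.astype(np.float32)
            header[nib.streamlines.trk.Field.VOXEL_SIZES] = tuple(
                np.linalg.norm(affine[:3, :3], axis=0)
            )
        nib.streamlines.save(nt, path, header=header)
    else:
        raise ValueError(f"unknown streamline format for {path!r} (use .tck or .trk)")


def read_streamlines(path) -> Tractogram:
    path = str(path)
    if not (path.endswith(".tck") or path.endswith(".trk")):
        raise ValueError(f"unknown streamline format for {path!r} (use .tck or .trk)")
    tf = nib.streamlines.load(path)
    return Tractogram([np.asarray(s) for s in tf.tractogram.streamlines])


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(path, config: dict, seed: int, inputs: list | None = None) -> dict:
    """JSON run manifest: version, config, seed, input hashes."""
    from . import __version__

    manifest = {
        "version": __version__,
        "seed": int(seed),
        "config": config,
        "inputs": {str(p): _hash_file(p) for p in (inputs or []) if Path(str(p)).exists()},
    }
    Path(str(path)).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def write_atlas(tck_path, tsv_path, atlas) -> None:
    """Centroid TCK plus a TSV of (label, category, hemisphere, threshold_mm)."""
    write_streamlines(tck_path, Tractogram([e.centroid for e in atlas.entries]))
    pd.DataFrame(
        {
            "label": [e.name for e in atlas.entries],
            "category": [e.category for e in atlas.entries],
            "hemisphere": [e.hemisphere for e in atlas.entries],
            "threshold_mm": [e.threshold_mm for e in atlas.entries],
        }
    ).to_csv(tsv_path, sep="\t", index=False)


def read_atlas(tck_path, tsv_path):
    from .bundles import BundleAtlas, BundleEntry

    cent = read_streamlines(tck_path)
    meta = pd.read_csv(tsv_path, sep="\t")
    entries = [
        BundleEntry(
            row.label,
            cent.streamlines[i],
            float(row.threshold_mm),
            str(getattr(row, "category", "other")),
            "" if pd.isna(getattr(row, "hemisphere", "")) else str(getattr(row, "hemisphere", "")),
        )
        for i, row in enumerate(meta.itertuples())
    ]
    return BundleAtlas(entries)


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
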