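"""Readers and writers: NIfTI volumes, gradient tables, TrackVis .trk, CSV.

All internal geometry is in millimeters with an axis-aligned affine scaled
by the voxel size and the origin at the volume corner; voxel (i, j, k)
spans ``[i, i+1) * voxel_size`` along each axis.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .connectome import ConnectionMatrix, DistanceMatrix
from .phantom import DWIDataset
from .schemes import read_bvals_bvecs, scheme_from_tables, write_bvals_bvecs
from .tracking import StreamlineSet

__all__ = [
    "save_dwi",
    "load_dwi",
    "save_volume",
    "load_volume",
    "save_streamlines",
    "load_streamlines",
    "save_matrix_csv",
    "load_matrix_csv",
    "save_matrix_sparse",
]


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(voxel_size)
    return aff


def save_volume(data: np.ndarray, voxel_size, path) -> None:
    img = nib.Nifti1Image(np.asarray(data), _affine(voxel_size))
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), np.asarray(img.header.get_zooms()[:3])


def save_dwi(dwi: DWIDataset, stem) -> dict:
    """Write signal as 4-D NIfTI plus bvals/bvecs and mask/label volumes.

    ``stem`` is a path prefix; returns the paths written.
    """
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "dwi": stem.with_suffix(".nii.gz"),
        "bvals": stem.parent / (stem.name + ".bval"),
        "bvecs": stem.parent / (stem.name + ".bvec"),
        "wm_mask": stem.parent / (stem.name + "_wm.nii.gz"),
        "roi_labels": stem.parent / (stem.name + "_roi.nii.gz"),
    }
    save_volume(dwi.signal.astype(np.float32), dwi.voxel_size, paths["dwi"])
    write_bvals_bvecs(dwi.scheme, paths["bvals"], paths["bvecs"])
    save_volume(dwi.wm_mask.astype(np.uint8), dwi.voxel_size, paths["wm_mask"])
    save_volume(dwi.roi_labels.astype(np.int16), dwi.voxel_size, paths["roi_labels"])
    return paths


def load_dwi(
    nifti_path, bvals_path, bvecs_path, wm_mask_path=None, roi_labels_path=None,
    kind: str = "shell",
) -> DWIDataset:
    """Rebuild a DWIDataset from disk; the scheme comes from the gradient
    table (b0 rows detected by b = 0)."""
    signal, voxel_size = load_volume(nifti_path)
    signal = np.asarray(signal, dtype=float)
    bvals, bvecs = read_bvals_bvecs(bvals_path, bvecs_path)
    if signal.shape[-1] != len(bvals):
        raise ValueError(
            f"NIfTI has {signal.shape[-1]} volumes but gradient table has "
            f"{len(bvals)} entries"
        )
    scheme = scheme_from_tables(bvals, bvecs, kind=kind)
    shape = signal.shape[:3]
    if wm_mask_path is not None:
        wm = np.asarray(load_volume(wm_mask_path)[0]).astype(bool)
    else:
        wm = np.ones(shape, dtype=bool)
    if roi_labels_path is not None:
        roi = np.asarray(load_volume(roi_labels_path)[0]).astype(int)
    else:
        roi = np.zeros(shape, dtype=int)
    return DWIDataset(signal, scheme, voxel_size, wm, roi,
                      provenance={"source": str(nifti_path)})


def save_streamlines(sset: StreamlineSet, path, voxel_size, dimensions) -> None:
    """TrackVis .trk with voxel_size and dim header fields populated."""
    from nibabel.streamlines import Tractogram
    from nibabel.streamlines.trk import TrkFile

    vs = np.asarray(voxel_size, dtype=np.float32)
    tract = Tractogram(
        [np.asarray(s, dtype=np.float32) for s in sset.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    header = {
        "voxel_sizes": vs,
        "dimensions": np.asarray(dimensions, dtype=np.int16),
        "voxel_to_rasmm": _affine(vs),
        "voxel_order": "RAS",
    }
    TrkFile(tract, header=header).save(str(path))


def load_streamlines(path) -> tuple[StreamlineSet, dict]:
    from nibabel.streamlines.trk import TrkFile

    trk = TrkFile.load(str(path))
    lines = [np.asarray(s, dtype=np.float32) for s in trk.tractogram.streamlines]
    return StreamlineSet(lines, provenance={"source": str(path)}), dict(trk.header)


def save_matrix_csv(matrix, path) -> None:
    """Headered CSV, ROI ids as both header row and index column."""
    data = matrix.counts if isinstance(matrix, ConnectionMatrix) else matrix.distances
    pd.DataFrame(data, index=matrix.roi_ids, columns=matrix.roi_ids).to_csv(path)


def load_matrix_csv(path, kind: str = "connection"):
    df = pd.read_csv(path, index_col=0)
    roi_ids = [int(c) for c in df.columns]
    if kind == "connection":
        return ConnectionMatrix(df.to_numpy(dtype=int), roi_ids)
    return DistanceMatrix(df.to_numpy(dtype=float), roi_ids)


def save_matrix_sparse(matrix: ConnectionMatrix, path) -> None:
    """Coordinate-list text: one `i j count` line per nonzero upper-triangle cell."""
    with open(path, "w") as fh:
        fh.write("# roi_i roi_j count\n")
        n = len(matrix.roi_ids)
        for a in range(n):
            for b in range(a + 1, n):
                if matrix.counts[a, b]:
                    fh.write(
                        f"{matrix.roi_ids[a]} {matrix.roi_ids[b]} "
                        f"{matrix.counts[a, b]}\n"
                    )
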