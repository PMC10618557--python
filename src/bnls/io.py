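"""File formats and run manifests.

Images move as NIfTI volumes (4D, subject axis last) via nibabel, or as ``.npz``
array containers for 2D grids; genotypes/covariates as TSV with a header row
of variant ids; chains as HDF5; configurations as YAML; manifests as JSON.
Voxel order is always the C-order scan of the (masked) grid.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .forward_model import Dataset
from .gp_basis import Grid
from .selection import InclusionMap

__all__ = [
    "read_images",
    "write_images",
    "read_genotypes",
    "write_genotypes",
    "write_inclusion_map",
    "RunManifest",
]


@dataclasses.dataclass
class RunManifest:
    """Everything needed to reproduce a run byte-for-byte (except timestamps)."""

    command: str
    config: dict
    seed: int
    input_hashes: dict
    software_version: str
    timestamp: str

    @staticmethod
    def create(command: str, config: dict, seed: int, inputs: dict) -> "RunManifest":
        from . import __version__

        hashes = {}
        for name, path in inputs.items():
            h = hashlib.sha256()
            h.update(Path(path).read_bytes())
            hashes[name] = h.hexdigest()
        return RunManifest(command=command, config=config, seed=seed,
                           input_hashes=hashes, software_version=__version__,
                           timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _mask_indices(mask: np.ndarray):
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("mask must be binary")
    return mask.astype(bool).ravel(order="C")


def read_images(source, mask=None) -> tuple[np.ndarray, tuple[int, ...]]:
    """Load subject images into an n x p matrix (C-order voxel scan).

    ``source`` is either a list of per-subject NIfTI paths (order preserved) or
    one 4D NIfTI with the subject axis last.  ``mask`` (optional binary array
    of the spatial shape) selects the voxels.
    Returns (Y, spatial_shape).
    """
    if isinstance(source, (str, Path)):
        vol = np.asarray(nib.load(str(source)).dataobj, dtype=float)
        if vol.ndim != 4:
            raise ValueError("single-file input must be a 4D volume")
        spatial = vol.shape[:3]
        flat = vol.reshape(-1, vol.shape[3], order="C").T
    else:
        vols = [np.asarray(nib.load(str(pth)).dataobj, dtype=float)
                for pth in source]
        spatial = vols[0].shape
        for v in vols[1:]:
            if v.shape != spatial:
                raise ValueError("subjects have inconsistent image shapes")
        flat = np.stack([v.ravel(order="C") for v in vols])
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != spatial:
            raise ValueError("mask shape does not match images")
        flat = flat[:, _mask_indices(mask)]
    return np.ascontiguousarray(flat), tuple(spatial)


def write_images(path, Y: np.ndarray, spatial_shape) -> None:
    """Write an n x p matrix as a 4D NIfTI (subject axis last, identity affine)."""
    n = Y.shape[0]
    vol = Y.T.reshape(*spatial_shape, n, order="C")
    nib.save(nib.Nifti1Image(vol.astype(np.float64), np.eye(4)), str(path))


def read_genotypes(path, standardize: bool = True,
                   impute_mean: bool = True) -> tuple[np.ndarray, list[str]]:
    """Read a TSV genotype/covariate table (header = variant ids).

    Missing entries are mean-imputed per column, then each column is
    standardized to mean 0, variance 1 (both optional).
    Returns (S, variant_ids).
    """
    df = pd.read_csv(path, sep="\t")
    ids = list(df.columns)
    S = df.to_numpy(dtype=float)
    if impute_mean:
        for k in range(S.shape[1]):
            col = S[:, k]
            obs = np.isfinite(col)
            if not obs.any():
                raise ValueError(f"column {ids[k]!r} is entirely missing")
            col[~obs] = col[obs].mean()
    elif not np.all(np.isfinite(S)):
        raise ValueError("missing values present and imputation disabled")
    if standardize:
        sd = S.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("constant column cannot be standardized")
        S = (S - S.mean(axis=0)) / sd
    return S, ids


def write_genotypes(path, S: np.ndarray, variant_ids=None) -> None:
    ids = variant_ids or [f"var{k}" for k in range(S.shape[1])]
    pd.DataFrame(S, columns=ids).to_csv(path, sep="\t", index=False)


def write_inclusion_map(path, inc_map: InclusionMap, spatial_shape) -> None:
    """Write a voxel inclusion-probability map as a NIfTI volume."""
    vol = np.asarray(inc_map.probs).reshape(spatial_shape, order="C")
    nib.save(nib.Nifti1Image(vol.astype(np.float64), np.eye(4)), str(path))
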