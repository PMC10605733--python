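"""Blob labeling, filtering, volume and inertia-eigenvalue eccentricity.

Blobbing is two-dimensional on the stitched mosaic: voxels are grouped
into 8-connected components, and components are never allowed to bridge
the seams between stitched slice tiles (each tile is labeled
independently).  Blobs smaller than 5 voxels (~1e-2 mL) are filtered
out by default.

Eccentricity of a blob comes from the 2x2 matrix of second central
moments of its member coordinates: with eigenvalues l >= s,

    E = (l - s) / (l + s)

ranging from 0 (round) to 1 (line).  The classical axis-ratio form
``sqrt(1 - s/l)`` is available via ``definition="classical"``.  For a
dense ellipse with semi-axes a >= b the moment eigenvalues are
proportional to a^2 and b^2, so E approaches (a^2-b^2)/(a^2+b^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

MIN_BLOB_VOXELS = 5
_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass(eq=False)
class Blob:
    """One labeled 8-connected component on the stitched mosaic."""

    label: int
    slice_index: int
    coords: np.ndarray            # (n, 2) mosaic (row, col)
    voxel_count: int = 0
    volume_ml: float = float("nan")
    inertia: np.ndarray | None = None
    eigenvalues: tuple[float, float] | None = None  # (l, s), l >= s
    eccentricity: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=int))
        self.voxel_count = len(self.coords)


def label_blobs(mask_mosaic: np.ndarray,
                slice_index_map: np.ndarray) -> list[Blob]:
    """8-connected components per stitched tile, labels in raster order.

    ``slice_index_map`` assigns a slice index to every mosaic column;
    components are computed tile by tile so they can never merge across
    a stitch seam.
    """
    mask_mosaic = np.asarray(mask_mosaic).astype(bool)
    slice_index_map = np.asarray(slice_index_map)
    if mask_mosaic.ndim != 2:
        raise ValueError("mask must be a 2-D mosaic")
    if slice_index_map.shape != (mask_mosaic.shape[1],):
        raise ValueError("slice_index_map length must equal mosaic width")
    if np.any(np.diff(slice_index_map) < 0):
        raise ValueError("slice_index_map must be non-decreasing")

    blobs: list[Blob] = []
    next_label = 1
    for s in np.unique(slice_index_map):
        cols = np.flatnonzero(slice_index_map == s)
        c0, c1 = cols[0], cols[-1] + 1
        tile = mask_mosaic[:, c0:c1]
        labeled, n = ndimage.label(tile, structure=_EIGHT_CONNECTED)
        for k in range(1, n + 1):
            rr, cc = np.nonzero(labeled == k)
            blobs.append(
                Blob(
                    label=next_label,
                    slice_index=int(s),
                    coords=np.column_stack([rr, cc + c0]),
                )
            )
            next_label += 1
    return blobs


def filter_blobs(blobs: list[Blob], min_voxels: int = MIN_BLOB_VOXELS) -> list[Blob]:
    """Drop blobs with fewer than ``min_voxels`` member voxels."""
    return [b for b in blobs if b.voxel_count >= min_voxels]


def blob_volume(blob: Blob, voxel_volume_ml: float) -> float:
    """Volume in mL: voxel count times the voxel volume."""
    if voxel_volume_ml <= 0:
        raise ValueError("voxel volume must be positive")
    blob.volume_ml = blob.voxel_count * voxel_volume_ml
    return blob.volume_ml


def blob_eccentricity(blob: Blob, definition: str = "normalized-difference") -> float:
    """Eccentricity from the inertia (second-central-moment) eigenvalues.

    Rotation-, translation- and scale-invariant.  A single-voxel blob
    (l + s = 0) is defined to have eccentricity 0.
    """
    coords = blob.coords.astype(float)
    centered = coords - coords.mean(axis=0)
    inertia = centered.T @ centered / len(coords)
    eigvals = np.linalg.eigvalsh(inertia)       # ascending
    s_k, l_k = float(max(eigvals[0], 0.0)), float(eigvals[1])
    blob.inertia = inertia
    blob.eigenvalues = (l_k, s_k)
    if l_k + s_k == 0.0:
        blob.eccentricity = 0.0
        return 0.0
    if definition == "normalized-difference":
        ecc = (l_k - s_k) / (l_k + s_k)
    elif definition == "classical":
        ecc = float(np.sqrt(1.0 - s_k / l_k)) if l_k > 0 else 0.0
    else:
        raise ValueError(f"unknown eccentricity definition: {definition}")
    blob.eccentricity = float(np.clip(ecc, 0.0, 1.0))
    return blob.eccentricity


def measure_blobs(blobs: list[Blob], voxel_volume_ml: float,
                  definition: str = "normalized-difference") -> list[Blob]:
    for b in blobs:
        blob_volume(b, voxel_volume_ml)
        blob_eccentricity(b, definition=definition)
    return blobs


def extract_features(blobs: list[Blob]) -> dict[str, float | bool]:
    """Per-threshold summary features of a measured blob list.

    Returns max blob volume, average blob volume and the eccentricity of
    the largest (maximum-volume) blob; volume ties resolve to the lowest
    label.  An empty list yields zero features and ``empty=True``.
    """
    if not blobs:
        return {
            "max_blob_vol_ml": 0.0,
            "ave_blob_vol_ml": 0.0,
            "max_blob_ecc": 0.0,
            "n_blobs": 0,
            "empty": True,
        }
    for b in blobs:
        if not np.isfinite(b.volume_ml) or b.eccentricity is None:
            raise ValueError("blobs must be measured before feature extraction")
    volumes = np.array([b.volume_ml for b in blobs])
    order = sorted(range(len(blobs)), key=lambda i: (-volumes[i], blobs[i].label))
    largest = blobs[order[0]]
    return {
        "max_blob_vol_ml": float(largest.volume_ml),
        "ave_blob_vol_ml": float(volumes.mean()),
        "max_blob_ecc": float(largest.eccentricity),
        "n_blobs": len(blobs),
        "empty": False,
    }


def blob_table(blobs: list[Blob]) -> pd.DataFrame:
    """CSV-ready per-blob table (label, slice, count, volume, l, s, E)."""
    rows = []
    for b in blobs:
        l_k, s_k = b.eigenvalues if b.eigenvalues is not None else (np.nan, np.nan)
        rows.append(
            {
                "label": b.label,
                "slice_index": b.slice_index,
                "voxel_count": b.voxel_count,
                "volume_ml": b.volume_ml,
                "eig_large": l_k,
                "eig_small": s_k,
                "eccentricity": b.eccentricity,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["label", "slice_index", "voxel_count", "volume_ml",
                 "eig_large", "eig_small", "eccentricity"],
    )
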