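"""Assemble the registered, stitched three-channel hypercube.

Pipeline: resample every sequence onto the coarsest in-plane grid,
translate the moving sequences onto the reference lattice using header
origins (plus an optional manual tweak), crop everything to the common
field of view, then abut the slices horizontally into a narrow mosaic.

The in-plane target grid is the sequence with the *largest* voxel size
(ties broken in favour of ADC, the reference sequence).  Slice grids
are assumed shared across sequences; a mismatch raises rather than
silently resampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import SEQUENCE_LABELS, SequenceVolume

log = logging.getLogger(__name__)


class RegistrationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def _in_plane_area(vol: SequenceVolume) -> float:
    return vol.spacing[1] * vol.spacing[2]

def target_label(sequences: dict[str, SequenceVolume]) -> str:
    """Label of the lowest-resolution (largest in-plane voxel) sequence."""
    best = max(_in_plane_area(v) for v in sequences.values())
    for lab in ("ADC", "HBV", "T2"):
        if lab in sequences and np.isclose(_in_plane_area(sequences[lab]), best):
            return lab
    return max(sequences, key=lambda k: _in_plane_area(sequences[k]))


def _resample_in_plane(
    vol: SequenceVolume, new_spacing: tuple[float, float], order: int = 1
) -> SequenceVolume:
    """Resample in-plane to ``new_spacing`` keeping origin and slice grid."""
    sy_old, sx_old = vol.in_plane_spacing
    sy_new, sx_new = new_spacing
    if np.isclose(sy_old, sy_new) and np.isclose(sx_old, sx_new):
        return vol
    ns, nr, nc = vol.shape
    nr_new = max(1, int(round(nr * sy_old / sy_new)))
    nc_new = max(1, int(round(nc * sx_old / sx_new)))
    rr = np.arange(nr_new) * sy_new / sy_old
    cc = np.arange(nc_new) * sx_new / sx_old
    grid_r, grid_c = np.meshgrid(rr, cc, indexing="ij")
    out = np.empty((ns, nr_new, nc_new), dtype=float)
    for s in range(ns):
        out[s] = ndimage.map_coordinates(
            np.asarray(vol.data[s], dtype=float),
            [grid_r, grid_c],
            order=order,
            mode="constant",
            cval=0.0,
        )
    return vol.with_data(
        out, spacing=(vol.spacing[0], sy_new, sx_new)
    )


def resample_to_lowest_resolution(
    sequences: dict[str, SequenceVolume], mask_labels: tuple[str, ...] = ()
) -> tuple[dict[str, SequenceVolume], str]:
    """Resample all sequences onto the coarsest in-plane grid.

    Masks (labels listed in ``mask_labels``) use nearest-neighbour
    interpolation; intensities use linear.  Returns the resampled dict
    and the target label.  Slice counts must agree.
    """
    if len(sequences) < 2:
        raise RegistrationError("need at least two sequences to co-register")
    tlabel = target_label(sequences)
    target = sequences[tlabel]
    counts = {lab: v.shape[0] for lab, v in sequences.items()}
    if len(set(counts.values())) != 1:
        raise RegistrationError(
            "inconsistent slice counts across sequences: "
            + ", ".join(f"{k}={v}" for k, v in counts.items())
        )
    out = {}
    for lab, vol in sequences.items():
        order = 0 if lab in mask_labels else 1
        out[lab] = _resample_in_plane(vol, target.in_plane_spacing, order=order)
    return out, tlabel


# ---------------------------------------------------------------------------
# translation and cropping
# ---------------------------------------------------------------------------

def translate_align(
    moving: SequenceVolume,
    reference: SequenceVolume,
    extra_shift: tuple[int, int] = (0, 0),
) -> SequenceVolume:
    """Shift ``moving`` onto the reference in-plane lattice.

    The shift is the header-origin difference converted to voxels
    (rounded to the nearest integer; the residual is logged) plus the
    manual ``extra_shift``.  Out-of-field voxels are zero-filled and the
    surviving extent recorded in ``valid_box``.
    """
    if not np.allclose(moving.in_plane_spacing, reference.in_plane_spacing):
        raise RegistrationError(
            "translate_align requires a common in-plane grid "
            f"({moving.label}: {moving.in_plane_spacing} vs "
            f"{reference.label}: {reference.in_plane_spacing})"
        )
    sy, sx = reference.in_plane_spacing
    exact_r = (reference.origin[1] - moving.origin[1]) / sy
    exact_c = (reference.origin[2] - moving.origin[2]) / sx
    kr, kc = int(round(exact_r)), int(round(exact_c))
    if abs(exact_r - kr) > 1e-6 or abs(exact_c - kc) > 1e-6:
        log.info(
            "%s: rounding sub-voxel header shift, residual (%.3f, %.3f) voxels",
            moving.label, exact_r - kr, exact_c - kc,
        )
    kr += int(extra_shift[0])
    kc += int(extra_shift[1])

    ns, nr, nc = moving.shape
    out = np.zeros_like(np.asarray(moving.data, dtype=float))
    # out[r, c] = moving[r + kr, c + kc]
    r0_dst, r1_dst = max(0, -kr), min(nr, nr - kr)
    c0_dst, c1_dst = max(0, -kc), min(nc, nc - kc)
    if r1_dst <= r0_dst or c1_dst <= c0_dst:
        raise RegistrationError(
            f"{moving.label}: translation ({kr}, {kc}) leaves no overlap"
        )
    out[:, r0_dst:r1_dst, c0_dst:c1_dst] = moving.data[
        :, r0_dst + kr : r1_dst + kr, c0_dst + kc : c1_dst + kc
    ]
    return moving.with_data(
        out,
        origin=(moving.origin[0], reference.origin[1], reference.origin[2]),
        valid_box=(r0_dst, r1_dst, c0_dst, c1_dst),
    )


def crop_to_common_fov(
    sequences: dict[str, SequenceVolume],
    masks: dict[str, SequenceVolume] | None = None,
) -> tuple[dict[str, SequenceVolume], dict[str, SequenceVolume]]:
    """Crop all sequences (and masks) to the intersection of valid extents."""
    shapes = {v.data.shape for v in sequences.values()}
    nr = min(s[1] for s in shapes)
    nc = min(s[2] for s in shapes)
    r0, r1, c0, c1 = 0, nr, 0, nc
    for vol in sequences.values():
        if vol.valid_box is not None:
            br0, br1, bc0, bc1 = vol.valid_box
            r0, r1 = max(r0, br0), min(r1, br1)
            c0, c1 = max(c0, bc0), min(c1, bc1)
    if r1 <= r0 or c1 <= c0:
        raise RegistrationError("empty field-of-view intersection")

    def _crop(vol: SequenceVolume) -> SequenceVolume:
        new_origin = (
            vol.origin[0],
            vol.origin[1] + r0 * vol.spacing[1],
            vol.origin[2] + c0 * vol.spacing[2],
        )
        return vol.with_data(
            vol.data[:, r0:r1, c0:c1], origin=new_origin, valid_box=None
        )

    out_seqs = {lab: _crop(v) for lab, v in sequences.items()}
    out_masks = {lab: _crop(v) for lab, v in (masks or {}).items()}
    return out_seqs, out_masks


# ---------------------------------------------------------------------------
# stitching
# ---------------------------------------------------------------------------

def stitch_volume(arr: np.ndarray) -> np.ndarray:
    """(slices, rows, cols) -> (rows, slices*cols) mosaic, slices abutted."""
    ns, nr, nc = arr.shape
    return np.transpose(arr, (1, 0, 2)).reshape(nr, ns * nc)


def unstitch_volume(mosaic: np.ndarray, n_slices: int) -> np.ndarray:
    nr, width = mosaic.shape
    if width % n_slices:
        raise ValueError("mosaic width not divisible by slice count")
    nc = width // n_slices
    return np.transpose(mosaic.reshape(nr, n_slices, nc), (1, 0, 2))


@dataclass
class Hypercube:
    """Registered 3-channel cube plus its stitched mosaic view.

    ``data`` has shape (3, slices, rows, cols) with channel order
    (ADC, HBV, T2); ``mosaic`` is (3, rows, slices*cols);
    ``slice_index_map`` gives, for every mosaic column, the slice it
    came from (constant within each stitched tile).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[0] != 3:
            raise ValueError("hypercube data must be (3, slices, rows, cols)")

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def mosaic(self) -> np.ndarray:
        return np.stack([stitch_volume(ch) for ch in self.data])

    @property
    def slice_index_map(self) -> np.ndarray:
        ns, nc = self.data.shape[1], self.data.shape[3]
        return np.repeat(np.arange(ns), nc)

    def stitch_like(self, arr: np.ndarray) -> np.ndarray:
        """Mosaic view of any (slices, rows, cols) array on this grid."""
        if arr.shape != self.data.shape[1:]:
            raise ValueError("array is not on the hypercube grid")
        return stitch_volume(arr)

    def unstitch_like(self, mosaic: np.ndarray) -> np.ndarray:
        return unstitch_volume(mosaic, self.n_slices)


def stitch(channels: dict[str, SequenceVolume]) -> Hypercube:
    """Stack registered (ADC, HBV, T2) sequences into a Hypercube."""
    missing = [lab for lab in SEQUENCE_LABELS if lab not in channels]
    if missing:
        raise RegistrationError(f"missing sequences: {missing}")
    shapes = {channels[lab].data.shape for lab in SEQUENCE_LABELS}
    if len(shapes) != 1:
        raise RegistrationError(f"channels not on a common grid: {shapes}")
    ref = channels["ADC"]
    data = np.stack(
        [np.asarray(channels[lab].data, dtype=float) for lab in SEQUENCE_LABELS]
    )
    return Hypercube(data=data, spacing=ref.spacing, origin=ref.origin)


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

def register_study(
    sequences: dict[str, SequenceVolume],
    masks: dict[str, SequenceVolume] | None = None,
    extra_shifts: dict[str, tuple[int, int]] | None = None,
) -> tuple[Hypercube, dict[str, np.ndarray]]:
    """Resample, translate, crop and stitch one patient study.

    ``masks`` must live on the target (reference) grid; they are cropped
    identically to the image channels and returned as plain arrays on
    the hypercube grid.
    """
    extra_shifts = extra_shifts or {}
    resampled, tlabel = resample_to_lowest_resolution(sequences)
    reference = resampled[tlabel]
    aligned = {}
    for lab, vol in resampled.items():
        if lab == tlabel:
            aligned[lab] = vol
        else:
            aligned[lab] = translate_align(
                vol, reference, extra_shift=extra_shifts.get(lab, (0, 0))
            )
    mask_vols = dict(masks or {})
    for lab, m in mask_vols.items():
        if m.data.shape != reference.data.shape:
            raise RegistrationError(
                f"mask {lab!r} is not on the reference grid "
                f"({m.data.shape} vs {reference.data.shape})"
            )
    cropped, cropped_masks = crop_to_common_fov(aligned, mask_vols)
    cube = stitch(cropped)
    return cube, {lab: np.asarray(m.data) for lab, m in cropped_masks.items()}
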