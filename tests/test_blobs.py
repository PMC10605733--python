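import numpy as np
import pytest

from bpspect.blobs import (
    Blob,
    blob_eccentricity,
    blob_table,
    blob_volume,
    extract_features,
    filter_blobs,
    label_blobs,
    measure_blobs,
)


# ---------------------------------------------------------------------------
# oracle: brute-force BFS flood fill, 8-connected
# ---------------------------------------------------------------------------

def bfs_components(mask):
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    comps = []
    for r0, c0 in zip(*np.nonzero(mask)):
        if seen[r0, c0]:
            continue
        stack, members = [(r0, c0)], []
        seen[r0, c0] = True
        while stack:
            r, c = stack.pop()
            members.append((r, c))
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]
                            and mask[rr, cc] and not seen[rr, cc]):
                        seen[rr, cc] = True
                        stack.append((rr, cc))
        comps.append(frozenset(members))
    return set(comps)


def _coord_sets(blobs):
    return {frozenset(map(tuple, b.coords)) for b in blobs}


def _single_tile_map(width):
    return np.zeros(width, dtype=int)


# ---------------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------------

def test_diagonal_voxels_one_blob():
    mask = np.zeros((4, 4), bool)
    mask[1, 1] = mask[2, 2] = True
    blobs = label_blobs(mask, _single_tile_map(4))
    assert len(blobs) == 1
    assert blobs[0].voxel_count == 2


def test_separated_voxels_two_blobs():
    mask = np.zeros((1, 5), bool)
    mask[0, 0] = mask[0, 2] = True
    assert len(label_blobs(mask, _single_tile_map(5))) == 2


def test_labels_match_bfs_oracle(rng):
    for _ in range(25):
        mask = rng.random((64, 64)) < 0.3
        blobs = label_blobs(mask, _single_tile_map(64))
        assert _coord_sets(blobs) == bfs_components(mask)


def test_labels_raster_order(rng):
    mask = rng.random((32, 32)) < 0.2
    blobs = label_blobs(mask, _single_tile_map(32))
    assert [b.label for b in blobs] == list(range(1, len(blobs) + 1))


def test_seam_never_bridged():
    # two tiles of width 4; a solid bar crossing the seam must split
    mask = np.zeros((3, 8), bool)
    mask[1, 2:6] = True
    smap = np.repeat([0, 1], 4)
    blobs = label_blobs(mask, smap)
    assert len(blobs) == 2
    assert sorted(b.slice_index for b in blobs) == [0, 1]
    # oracle per tile agrees
    per_tile = bfs_components(mask[:, :4]) | {
        frozenset((r, c + 4) for r, c in comp)
        for comp in bfs_components(mask[:, 4:])
    }
    assert _coord_sets(blobs) == per_tile


def test_empty_mask():
    assert label_blobs(np.zeros((4, 4), bool), _single_tile_map(4)) == []


def test_bad_slice_map():
    with pytest.raises(ValueError, match="non-decreasing"):
        label_blobs(np.zeros((2, 4), bool), np.array([0, 1, 0, 1]))


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _blob_of(n, label=1):
    return Blob(label=label, slice_index=0, coords=[(0, i) for i in range(n)])


def test_filter_boundary():
    kept = filter_blobs([_blob_of(4, 1), _blob_of(5, 2)])
    assert [b.label for b in kept] == [2]  # 4 removed, 5 kept


def test_filter_identity_when_all_large():
    blobs = [_blob_of(6, 1), _blob_of(9, 2)]
    assert filter_blobs(blobs) == blobs


def test_filter_constructed_components():
    # components of sizes 3, 5 and 12 -> two survivors
    mask = np.zeros((12, 20), bool)
    mask[0, 0:3] = True
    mask[4, 5:10] = True
    mask[8:11, 12:16] = True
    blobs = label_blobs(mask, _single_tile_map(20))
    assert sorted(b.voxel_count for b in blobs) == [3, 5, 12]
    assert len(filter_blobs(blobs)) == 2


# ---------------------------------------------------------------------------
# volume
# ---------------------------------------------------------------------------

def test_single_voxel_volume():
    blob = _blob_of(1)
    assert blob_volume(blob, 2 * 2 * 3 / 1000.0) == pytest.approx(0.012)


def test_sphere_volume_close_to_analytic():
    # digital sphere, radius 9 mm on a 2 mm isotropic grid
    r_mm, sp = 9.0, 2.0
    n = 12
    z, y, x = np.meshgrid(*[sp * (np.arange(n) - n / 2)] * 3, indexing="ij")
    inside = z**2 + y**2 + x**2 <= r_mm**2
    volume = inside.sum() * sp**3 / 1000.0
    analytic = 4 / 3 * np.pi * (r_mm / 10) ** 3
    assert volume == pytest.approx(analytic, rel=0.15)


def test_invalid_voxel_volume():
    with pytest.raises(ValueError, match="positive"):
        blob_volume(_blob_of(3), 0.0)


# ---------------------------------------------------------------------------
# eccentricity
# ---------------------------------------------------------------------------

def moment_ecc_oracle(coords):
    """Brute-force second-central-moment eccentricity."""
    coords = np.asarray(coords, float)
    mu = coords.mean(axis=0)
    mrr = np.mean((coords[:, 0] - mu[0]) ** 2)
    mcc = np.mean((coords[:, 1] - mu[1]) ** 2)
    mrc = np.mean((coords[:, 0] - mu[0]) * (coords[:, 1] - mu[1]))
    tr = mrr + mcc
    disc = np.sqrt((mrr - mcc) ** 2 + 4 * mrc**2)
    l, s = (tr + disc) / 2, (tr - disc) / 2
    return (l - s) / (l + s) if tr > 0 else 0.0


def _ellipse_coords(a, b, step=1.0, angle=0.0):
    lim = int(np.ceil(max(a, b))) + 1
    g = np.arange(-lim, lim + step, step)
    yy, xx = np.meshgrid(g, g, indexing="ij")
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * xx + sa * yy
    v = -sa * xx + ca * yy
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return np.column_stack(np.nonzero(inside))


def test_line_eccentricity_one():
    for n in (2, 5, 20):
        blob = Blob(label=1, slice_index=0, coords=[(0, i) for i in range(n)])
        assert blob_eccentricity(blob) == pytest.approx(1.0, abs=1e-12)


def test_square_and_disk_eccentricity_zero():
    square = Blob(
        label=1, slice_index=0,
        coords=[(r, c) for r in range(6) for c in range(6)],
    )
    assert blob_eccentricity(square) == pytest.approx(0.0, abs=1e-12)
    disk = Blob(label=2, slice_index=0, coords=_ellipse_coords(10, 10))
    assert blob_eccentricity(disk) == pytest.approx(0.0, abs=1e-12)


def test_two_to_one_ellipse_limit():
    # closed form (a^2 - b^2)/(a^2 + b^2) = 0.6 for a = 2b
    blob = Blob(label=1, slice_index=0, coords=_ellipse_coords(40, 20))
    assert blob_eccentricity(blob) == pytest.approx(0.6, abs=0.02)


def test_matches_moment_oracle(rng):
    for _ in range(50):
        pts = rng.integers(0, 30, size=(rng.integers(2, 40), 2))
        blob = Blob(label=1, slice_index=0, coords=pts)
        assert blob_eccentricity(blob) == pytest.approx(
            moment_ecc_oracle(pts), abs=1e-12
        )


def test_rotation_and_reflection_invariance():
    coords = _ellipse_coords(12, 5)
    base = blob_eccentricity(Blob(label=1, slice_index=0, coords=coords))
    rot90 = coords[:, ::-1].copy()
    refl = np.column_stack([coords[:, 0], -coords[:, 1]])
    for variant in (rot90, refl):
        e = blob_eccentricity(Blob(label=1, slice_index=0, coords=variant))
        assert e == pytest.approx(base, abs=1e-12)


def test_arbitrary_rotation_stability():
    base = blob_eccentricity(
        Blob(label=1, slice_index=0, coords=_ellipse_coords(30, 15, step=0.5))
    )
    for angle in (0.3, 0.7, 1.1):
        rotated = blob_eccentricity(
            Blob(label=1, slice_index=0,
                 coords=_ellipse_coords(30, 15, step=0.5, angle=angle))
        )
        assert abs(rotated - base) < 0.02


def test_translation_and_scale_invariance():
    coords = _ellipse_coords(10, 4)
    base = blob_eccentricity(Blob(label=1, slice_index=0, coords=coords))
    shifted = blob_eccentricity(
        Blob(label=1, slice_index=0, coords=coords + [100, 200])
    )
    scaled = blob_eccentricity(Blob(label=1, slice_index=0, coords=coords * 3))
    assert shifted == pytest.approx(base, abs=1e-12)
    assert scaled == pytest.approx(base, abs=1e-12)


def test_single_voxel_eccentricity_zero():
    assert blob_eccentricity(_blob_of(1)) == 0.0


def test_classical_definition_option():
    line = Blob(label=1, slice_index=0, coords=[(0, 0), (0, 1), (0, 2)])
    assert blob_eccentricity(line, definition="classical") == pytest.approx(1.0)
    with pytest.raises(ValueError, match="unknown"):
        blob_eccentricity(line, definition="nope")


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def _measured(sizes, voxel_ml=0.01):
    blobs = [_blob_of(n, label=i + 1) for i, n in enumerate(sizes)]
    return measure_blobs(blobs, voxel_ml)


def test_single_blob_features():
    blobs = _measured([7])
    feats = extract_features(blobs)
    assert feats["max_blob_vol_ml"] == feats["ave_blob_vol_ml"] == pytest.approx(0.07)
    assert feats["max_blob_ecc"] == pytest.approx(blobs[0].eccentricity)
    assert not feats["empty"]


def test_feature_arithmetic():
    feats = extract_features(_measured([10, 30]))
    assert feats["max_blob_vol_ml"] == pytest.approx(0.3)
    assert feats["ave_blob_vol_ml"] == pytest.approx(0.2)


def test_volume_tie_lowest_label_wins():
    blobs = [
        Blob(label=1, slice_index=0, coords=[(5, c) for c in range(6)]),
        Blob(label=2, slice_index=0, coords=[(r, 0) for r in range(3)]
             + [(r, 1) for r in range(3)]),
    ]
    measure_blobs(blobs, 0.01)
    feats = extract_features(blobs)
    assert feats["max_blob_ecc"] == pytest.approx(blobs[0].eccentricity)
    # permuting the list leaves the choice unchanged (label breaks the tie)
    feats_perm = extract_features(blobs[::-1])
    assert feats_perm["max_blob_ecc"] == feats["max_blob_ecc"]


def test_empty_feature_flag():
    feats = extract_features([])
    assert feats["empty"]
    assert feats["max_blob_vol_ml"] == 0.0


def test_unmeasured_blobs_rejected():
    with pytest.raises(ValueError, match="measured"):
        extract_features([_blob_of(5)])


def test_blob_table_columns():
    table = blob_table(_measured([6, 8]))
    assert list(table.columns) == [
        "label", "slice_index", "voxel_count", "volume_ml",
        "eig_large", "eig_small", "eccentricity",
    ]
    assert len(table) == 2
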