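"""Adaptive cosine estimator (ACE) target detection on the hypercube.

Background (normal prostate) voxels define second-order statistics: a
mean vector ``m`` and covariance ``CM``.  The tumor signature ``S`` is
derived in-scene from a seed region.  With ``d = x - m`` and
``t = S - m`` the per-voxel score is the squared cosine between the
background-whitened vectors,

    ACE(x) = (t' CM^-1 d)^2 / [(t' CM^-1 t) (d' CM^-1 d)]

which lies in [0, 1], is invariant to positive rescaling of ``d`` and
``t`` and to any invertible affine recoloring applied consistently to
data, mean, covariance and signature.  The decision surface is a cone
around the signature: voxels whose score exceeds a threshold are called
tumor.  A signed (unsquared) cosine variant is available via
``squared=False``.

Covariance regularisation / principal-component removal is deliberately
not applied; a singular covariance is an error asking for more mask
voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .registration import Hypercube

MIN_BACKGROUND_VOXELS = 30


class AceError(ValueError):
    pass


@dataclass
class BackgroundStats:
    """Sample mean and covariance of the masked normal-prostate voxels."""

    mean: np.ndarray
    covariance: np.ndarray
    n_voxels: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.mean.shape != (3,) or self.covariance.shape != (3, 3):
            raise AceError("background stats must be 3-channel")
        if not np.allclose(self.covariance, self.covariance.T):
            raise AceError("covariance must be symmetric")

    @property
    def cholesky(self) -> np.ndarray:
        try:
            return np.linalg.cholesky(self.covariance)
        except np.linalg.LinAlgError as exc:
            raise AceError(
                "background covariance is singular; enlarge the normal-prostate "
                "mask (regularisation is deliberately not applied)"
            ) from exc


@dataclass
class Signature:
    """Three-channel tumor signature with provenance."""

    vector: np.ndarray
    provenance: str = "explicit"

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.vector.shape != (3,):
            raise AceError("signature must be a 3-vector")


@dataclass
class DetectionMap:
    """Per-voxel ACE scores on the hypercube grid (range [0, 1])."""

    scores: np.ndarray
    threshold_convention: str = "squared-cosine"


def _masked_vectors(cube: Hypercube, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    if mask.shape != cube.data.shape[1:]:
        raise AceError(
            f"mask shape {mask.shape} does not match hypercube grid "
            f"{cube.data.shape[1:]}"
        )
    return cube.data[:, mask].T  # (n, 3)


def compute_background_stats(cube: Hypercube, prostate_mask: np.ndarray,
                             min_voxels: int = MIN_BACKGROUND_VOXELS) -> BackgroundStats:
    """Sample mean / covariance (denominator n-1) over masked voxels."""
    vectors = _masked_vectors(cube, prostate_mask)
    n = vectors.shape[0]
    if n < min_voxels:
        raise AceError(f"only {n} background voxels in mask; need >= {min_voxels}")
    mean = vectors.mean(axis=0)
    cov = np.cov(vectors, rowvar=False, ddof=1)
    stats = BackgroundStats(mean=mean, covariance=cov, n_voxels=n)
    stats.cholesky  # fail fast on singular covariance
    return stats


def derive_signature(cube: Hypercube, seed_region: np.ndarray,
                     stats: BackgroundStats | None = None,
                     rtol: float = 1e-8) -> Signature:
    """In-scene signature: the mean vector over the seed-region voxels."""
    vectors = _masked_vectors(cube, seed_region)
    if vectors.shape[0] == 0:
        raise AceError("signature seed region is empty")
    vec = vectors.mean(axis=0)
    if stats is not None:
        scale = max(np.linalg.norm(stats.mean), 1.0)
        if np.linalg.norm(vec - stats.mean) <= rtol * scale:
            raise AceError("degenerate signature: seed mean equals background mean")
    return Signature(vector=vec, provenance=f"seed-region({vectors.shape[0]} voxels)")


def ace_score(cube: Hypercube, stats: BackgroundStats, signature: Signature,
              squared: bool = True) -> DetectionMap:
    """Score every hypercube voxel against the signature.

    Voxels equal to the background mean (``d = 0``) score 0 by
    convention.  Scores are clipped to [0, 1] ([-1, 1] for the signed
    variant) to absorb floating-point round-off.
    """
    L = stats.cholesky
    t = signature.vector - stats.mean
    wt = linalg.solve_triangular(L, t, lower=True)
    tt = float(wt @ wt)
    if tt <= 0 or not np.isfinite(tt):
        raise AceError("degenerate signature: S equals the background mean")

    grid_shape = cube.data.shape[1:]
    d = cube.data.reshape(3, -1) - stats.mean[:, None]          # (3, N)
    wd = linalg.solve_triangular(L, d, lower=True)              # whitened
    num = wt @ wd                                               # (N,)
    dd = np.einsum("ij,ij->j", wd, wd)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos = num / np.sqrt(tt * dd)
    cos[dd == 0] = 0.0  # mean-equal voxels
    if squared:
        scores = np.clip(cos ** 2, 0.0, 1.0)
        convention = "squared-cosine"
    else:
        scores = np.clip(cos, -1.0, 1.0)
        convention = "signed-cosine"
    return DetectionMap(scores=scores.reshape(grid_shape),
                        threshold_convention=convention)


def threshold_map(det: DetectionMap, threshold: float,
                  scene_mask: np.ndarray | None = None) -> np.ndarray:
    """Binary tumor mask: score strictly above ``threshold``.

    ``scene_mask`` (optional) restricts detections to the prostate-scene
    extent; thresholds are nested: mask(t2) is a subset of mask(t1) for
    t2 > t1.
    """
    if not 0.0 <= threshold <= 1.0:
        raise AceError(f"threshold must be in [0, 1], got {threshold}")
    mask = det.scores > threshold
    if scene_mask is not None:
        mask &= np.asarray(scene_mask).astype(bool)
    return mask
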