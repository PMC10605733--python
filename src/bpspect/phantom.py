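"""Synthetic bi-parametric MRI phantoms and cohorts with known ground truth.

A phantom study consists of three co-localised sequences (ADC, HBV, T2)
on different in-plane grids, a prostate ellipsoid filled with correlated
multivariate-Gaussian background, and one or more elliptic-cylinder
tumors whose channel means contrast against the background with sign
pattern (-, +, -) for (ADC, HBV, T2).

Tumors are defined geometrically in physical millimetres and rasterised
onto each sequence grid, so registration tests have sub-voxel truth.
Channel values are drawn once per cell of the *common* (coarsest) grid
and shared by every sequence voxel falling into that cell; this keeps
the cross-channel covariance of the registered hypercube equal to the
requested background covariance.

A cohort attaches to each phantom a latent ordinal grade

    grade = clamp(round(b0 + bV * V + bE * E + noise), 0, 5)

where ``V`` is the true volume (mL) and ``E`` the true in-plane
eccentricity of the patient's largest tumor, so the statistics layer
can be validated by parameter recovery (positive volume effect,
negative eccentricity effect).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .volumes import SEQUENCE_LABELS, SequenceVolume, write_sequence

ISUP_MIN, ISUP_MAX = 0, 5
CSPCA_GRADE = 2  # clinically significant disease: grade >= 2


class PhantomSpecError(ValueError):
    """Raised when a phantom or cohort specification is inconsistent."""


@dataclass
class TumorSpec:
    """Elliptic-cylinder tumor in physical mm.

    ``center`` is (slice, row, col) position in mm; ``a >= b`` are the
    in-plane semi-axes; ``angle`` rotates the major axis in the plane;
    ``height`` is the full extent along the slice direction.  True
    volume is ``pi * a * b * height`` and true in-plane eccentricity is
    ``(a^2 - b^2) / (a^2 + b^2)``.
    """

    center: tuple[float, float, float]
    a: float
    b: float
    height: float
    angle: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise PhantomSpecError(
                f"tumor semi-axes must satisfy a >= b > 0, got a={self.a}, b={self.b}"
            )
        if self.height <= 0:
            raise PhantomSpecError("tumor height must be positive")

    @property
    def volume_ml(self) -> float:
        return float(np.pi * self.a * self.b * self.height) / 1000.0

    @property
    def eccentricity(self) -> float:
        a2, b2 = self.a ** 2, self.b ** 2
        return float((a2 - b2) / (a2 + b2))

    def contains(self, z: np.ndarray, y: np.ndarray, x: np.ndarray) -> np.ndarray:
        """Membership of physical points; strict along slices, closed in-plane."""
        cz, cy, cx = self.center
        dz, dy, dx = z - cz, y - cy, x - cx
        ca, sa = np.cos(self.angle), np.sin(self.angle)
        u = ca * dx + sa * dy   # along major axis
        v = -sa * dx + ca * dy  # along minor axis
        return (np.abs(dz) < self.height / 2.0) & (
            (u / self.a) ** 2 + (v / self.b) ** 2 <= 1.0
        )


@dataclass
class PhantomSpec:
    shapes: dict[str, tuple[int, int, int]]
    spacings: dict[str, tuple[float, float, float]]
    prostate_center: tuple[float, float, float]
    prostate_axes: tuple[float, float, float]
    m_bg: np.ndarray
    cov_bg: np.ndarray
    tumors: list[TumorSpec] = field(default_factory=list)
    m_tum: np.ndarray = field(default_factory=lambda: np.array([600.0, 800.0, 500.0]))
    tumor_sigma: float = 25.0
    t2_offset_voxels: tuple[int, int] = (0, 0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.m_bg = np.asarray(self.m_bg, dtype=float)
        self.cov_bg = np.asarray(self.cov_bg, dtype=float)
        self.m_tum = np.asarray(self.m_tum, dtype=float)
        if self.m_bg.shape != (3,) or self.m_tum.shape != (3,):
            raise PhantomSpecError("channel means must be length-3 vectors")
        if self.cov_bg.shape != (3, 3) or not np.allclose(self.cov_bg, self.cov_bg.T):
            raise PhantomSpecError("background covariance must be symmetric 3x3")
        try:
            np.linalg.cholesky(self.cov_bg)
        except np.linalg.LinAlgError as exc:
            raise PhantomSpecError(
                "background covariance must be positive definite"
            ) from exc
        for lab in SEQUENCE_LABELS:
            if lab not in self.shapes or lab not in self.spacings:
                raise PhantomSpecError(f"missing grid definition for sequence {lab}")
        for tum in self.tumors:
            self._check_inside_prostate(tum)

    def _check_inside_prostate(self, tum: TumorSpec) -> None:
        # sample the tumor rim at both end faces; all points must satisfy
        # the prostate ellipsoid inequality
        theta = np.linspace(0.0, 2 * np.pi, 64, endpoint=False)
        ca, sa = np.cos(tum.angle), np.sin(tum.angle)
        ue, ve = tum.a * np.cos(theta), tum.b * np.sin(theta)
        dx = ca * ue - sa * ve
        dy = sa * ue + ca * ve
        cz, cy, cx = tum.center
        pz, py, px = self.prostate_center
        az, ay, ax = self.prostate_axes
        for z_off in (-tum.height / 2.0, tum.height / 2.0):
            q = (
                ((cz + z_off - pz) / az) ** 2
                + ((cy + dy - py) / ay) ** 2
                + ((cx + dx - px) / ax) ** 2
            )
            if np.any(q > 1.0):
                raise PhantomSpecError(
                    f"tumor at {tum.center} extends outside the prostate ellipsoid"
                )


@dataclass
class PhantomStudy:
    """Generated phantom: three sequences, masks on the common grid, truth."""

    patient_id: str
    sequences: dict[str, SequenceVolume]
    prostate_mask: SequenceVolume  # normal prostate (tumors excluded), uint8
    tumor_mask: SequenceVolume     # tumor labels (0 = none, k = tumor k), uint8
    truth: pd.DataFrame
    spec: PhantomSpec

    def write(self, out_dir: str | Path, fmt: str = ".nii") -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for lab, vol in self.sequences.items():
            write_sequence(vol, out_dir / f"{lab.lower()}{fmt}")
        write_sequence(self.prostate_mask, out_dir / f"prostate_mask{fmt}")
        write_sequence(self.tumor_mask, out_dir / f"tumor_mask{fmt}")
        self.truth.to_csv(out_dir / "tumor_truth.csv", index=False)
        return out_dir


def _common_label(spec: PhantomSpec) -> str:
    """Sequence whose grid the scene is sampled on: largest in-plane voxel."""
    areas = {
        lab: spec.spacings[lab][1] * spec.spacings[lab][2] for lab in SEQUENCE_LABELS
    }
    best = max(areas.values())
    for lab in ("ADC", "HBV", "T2"):  # tie -> ADC, the reference sequence
        if np.isclose(areas[lab], best):
            return lab
    raise AssertionError("unreachable")


def _grid_coords(shape, spacing, origin):
    z = origin[0] + spacing[0] * np.arange(shape[0])
    y = origin[1] + spacing[1] * np.arange(shape[1])
    x = origin[2] + spacing[2] * np.arange(shape[2])
    return np.meshgrid(z, y, x, indexing="ij")


def generate_phantom(spec: PhantomSpec, patient_id: str = "phantom") -> PhantomStudy:
    """Rasterise a :class:`PhantomSpec` into three sequences plus truth.

    The T2 sequence is written with a header origin shifted by
    ``t2_offset_voxels`` (row, col) of its own in-plane grid, and its
    voxel contents sampled at the corresponding physical positions —
    i.e. the misalignment is real and recorded in the header, exactly
    what header-driven translation must undo.
    """
    rng = np.random.default_rng(spec.seed)
    common = _common_label(spec)
    cshape = spec.shapes[common]
    cspacing = spec.spacings[common]
    corigin = (0.0, 0.0, 0.0)

    # latent per-cell channel vectors on the common grid
    n_cells = int(np.prod(cshape))
    bg_field = rng.multivariate_normal(spec.m_bg, spec.cov_bg, size=n_cells).reshape(
        *cshape, 3
    )
    tum_field = spec.m_tum + spec.tumor_sigma * rng.standard_normal((*cshape, 3))

    cz, cy, cx = _grid_coords(cshape, cspacing, corigin)
    pz, py, px = spec.prostate_center
    az, ay, ax = spec.prostate_axes
    prostate = ((cz - pz) / az) ** 2 + ((cy - py) / ay) ** 2 + (
        (cx - px) / ax
    ) ** 2 <= 1.0

    tumor_labels = np.zeros(cshape, dtype=np.uint8)
    for k, tum in enumerate(spec.tumors, start=1):
        inside = tum.contains(cz, cy, cx)
        tumor_labels[inside] = k

    scene = np.zeros((*cshape, 3))
    scene[prostate] = bg_field[prostate]
    scene[tumor_labels > 0] = tum_field[tumor_labels > 0]

    sequences: dict[str, SequenceVolume] = {}
    for ch, lab in enumerate(SEQUENCE_LABELS):
        shape = spec.shapes[lab]
        spacing = spec.spacings[lab]
        origin = [0.0, 0.0, 0.0]
        if lab == "T2":
            origin[1] = spec.t2_offset_voxels[0] * spacing[1]
            origin[2] = spec.t2_offset_voxels[1] * spacing[2]
        # nearest common cell for every voxel centre
        idx = []
        for axis in range(3):
            pos = origin[axis] + spacing[axis] * np.arange(shape[axis])
            j = np.rint((pos - corigin[axis]) / cspacing[axis]).astype(int)
            idx.append(np.clip(j, 0, cshape[axis] - 1))
        data = scene[np.ix_(idx[0], idx[1], idx[2]) + (ch,)]
        # voxels physically outside the common-grid extent are off-scene
        for axis in range(3):
            pos = origin[axis] + spacing[axis] * np.arange(shape[axis])
            out = (pos < corigin[axis] - cspacing[axis] / 2) | (
                pos > corigin[axis] + cspacing[axis] * (cshape[axis] - 0.5)
            )
            if out.any():
                sl = [slice(None)] * 3
                sl[axis] = out
                data[tuple(sl)] = 0.0
        sequences[lab] = SequenceVolume(
            data=data, spacing=spacing, origin=tuple(origin), label=lab
        )

    normal = prostate & (tumor_labels == 0)
    prostate_mask = SequenceVolume(
        normal.astype(np.uint8), cspacing, corigin, label="prostate_mask"
    )
    tumor_mask = SequenceVolume(
        tumor_labels, cspacing, corigin, label="tumor_mask"
    )

    rows = []
    for k, tum in enumerate(spec.tumors, start=1):
        rows.append(
            {
                "patient_id": patient_id,
                "tumor_id": k,
                "center_slice_mm": tum.center[0],
                "center_row_mm": tum.center[1],
                "center_col_mm": tum.center[2],
                "semi_axis_a_mm": tum.a,
                "semi_axis_b_mm": tum.b,
                "height_mm": tum.height,
                "angle_rad": tum.angle,
                "true_volume_ml": tum.volume_ml,
                "true_eccentricity": tum.eccentricity,
                "rasterized_voxels": int(np.sum(tumor_labels == k)),
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "patient_id", "tumor_id", "center_slice_mm", "center_row_mm",
            "center_col_mm", "semi_axis_a_mm", "semi_axis_b_mm", "height_mm",
            "angle_rad", "true_volume_ml", "true_eccentricity",
            "rasterized_voxels",
        ],
    )
    return PhantomStudy(
        patient_id=patient_id,
        sequences=sequences,
        prostate_mask=prostate_mask,
        tumor_mask=tumor_mask,
        truth=truth,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# defaults and cohorts
# ---------------------------------------------------------------------------

DEFAULT_M_BG = np.array([1200.0, 300.0, 900.0])     # (ADC, HBV, T2)
DEFAULT_M_TUM = np.array([600.0, 800.0, 500.0])     # contrast signs (-, +, -)
_BG_SD = np.array([120.0, 60.0, 100.0])
_BG_CORR = np.array(
    [[1.0, 0.3, 0.3],
     [0.3, 1.0, 0.3],
     [0.3, 0.3, 1.0]]
)
DEFAULT_COV_BG = _BG_CORR * np.outer(_BG_SD, _BG_SD)


def default_phantom_spec(
    seed: int = 0,
    tumors: list[TumorSpec] | None = None,
    t2_offset_voxels: tuple[int, int] = (0, 0),
    shape_common: tuple[int, int, int] = (6, 48, 48),
    tumor_sigma: float = 25.0,
) -> PhantomSpec:
    """Small default study: ADC/HBV at 2 mm in-plane, T2 at 1 mm."""
    ns, nr, nc = shape_common
    spacing_c = (3.0, 2.0, 2.0)
    spacing_t2 = (3.0, 1.0, 1.0)
    center = (ns * 3.0 / 2, nr * 2.0 / 2, nc * 2.0 / 2)
    axes = (ns * 3.0 / 2 - 1.0, nr * 2.0 / 3, nc * 2.0 / 3)
    if tumors is None:
        # z-centre midway between slice centres so a 6 mm tumor spans
        # exactly two 3 mm slices
        tumors = [
            TumorSpec(center=(center[0] + 1.5, center[1], center[2]), a=9.0,
                      b=6.0, height=6.0, angle=0.4)
        ]
    return PhantomSpec(
        shapes={
            "ADC": (ns, nr, nc),
            "HBV": (ns, nr, nc),
            "T2": (ns, nr * 2, nc * 2),
        },
        spacings={"ADC": spacing_c, "HBV": spacing_c, "T2": spacing_t2},
        prostate_center=center,
        prostate_axes=axes,
        m_bg=DEFAULT_M_BG,
        cov_bg=DEFAULT_COV_BG,
        tumors=tumors,
        m_tum=DEFAULT_M_TUM,
        tumor_sigma=tumor_sigma,
        t2_offset_voxels=t2_offset_voxels,
        seed=seed,
    )


@dataclass
class CohortSpec:
    """Distributional description of a synthetic patient cohort."""

    n_patients: int
    beta0: float = 1.2
    beta_volume: float = 1.2        # > 0: larger tumors -> higher grade
    beta_eccentricity: float = -2.0  # < 0: rounder tumors -> higher grade
    noise_sigma: float = 0.3
    a_range: tuple[float, float] = (5.0, 11.0)
    axis_ratio_range: tuple[float, float] = (0.45, 1.0)
    height_range: tuple[float, float] = (4.5, 7.5)
    age_mean_sd: tuple[float, float] = (65.0, 7.0)
    psa_log_mean_sd: tuple[float, float] = (2.3, 0.7)
    prostate_volume_mean_sd: tuple[float, float] = (60.0, 20.0)
    tumor_sigma: float = 25.0
    shape_common: tuple[int, int, int] = (6, 48, 48)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise PhantomSpecError("a cohort needs at least 2 patients")


def generate_cohort(cspec: CohortSpec) -> tuple[list[PhantomStudy], pd.DataFrame]:
    """Generate phantoms plus a clinical table with latent ISUP grades.

    The same seed reproduces the cohort exactly (per-patient seeds are
    spawned from one :class:`numpy.random.SeedSequence`).
    """
    root = np.random.SeedSequence(cspec.seed)
    patient_seqs = root.spawn(cspec.n_patients)

    studies: list[PhantomStudy] = []
    rows = []
    for i, sseq in enumerate(patient_seqs):
        pid = f"P{i:03d}"
        prng = np.random.default_rng(sseq)
        a = prng.uniform(*cspec.a_range)
        b = a * prng.uniform(*cspec.axis_ratio_range)
        height = prng.uniform(*cspec.height_range)
        angle = prng.uniform(0.0, np.pi)
        ns, nr, nc = cspec.shape_common
        center = (ns * 3.0 / 2, nr * 2.0 / 2, nc * 2.0 / 2)
        # jitter the tumor centre while keeping it well inside the prostate
        jitter = prng.uniform(-1.0, 1.0, size=2) * 4.0
        tumor = TumorSpec(
            center=(center[0] + 1.5, center[1] + jitter[0], center[2] + jitter[1]),
            a=a,
            b=b,
            height=height,
            angle=angle,
        )
        spec = default_phantom_spec(
            seed=int(prng.integers(0, 2**31 - 1)),
            tumors=[tumor],
            shape_common=cspec.shape_common,
            tumor_sigma=cspec.tumor_sigma,
        )
        study = generate_phantom(spec, patient_id=pid)
        studies.append(study)

        volume = tumor.volume_ml
        ecc = tumor.eccentricity
        latent = (
            cspec.beta0
            + cspec.beta_volume * volume
            + cspec.beta_eccentricity * ecc
            + cspec.noise_sigma * prng.standard_normal()
        )
        grade = int(np.clip(np.rint(latent), ISUP_MIN, ISUP_MAX))
        age = float(np.clip(prng.normal(*cspec.age_mean_sd), 45.0, 85.0))
        psa = float(np.exp(prng.normal(*cspec.psa_log_mean_sd)))
        pvol = float(np.clip(prng.normal(*cspec.prostate_volume_mean_sd), 15.0, 200.0))
        rows.append(
            {
                "patient_id": pid,
                "isup_grade": grade,
                "cspca": grade >= CSPCA_GRADE,
                "psa_ng_ml": round(psa, 3),
                "age_years": round(age, 1),
                "prostate_volume_ml": round(pvol, 1),
                "true_volume_ml": round(volume, 6),
                "true_eccentricity": round(ecc, 6),
            }
        )
    cohort = pd.DataFrame(rows)
    return studies, cohort
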