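"""Synthetic MR-neurography phantoms with known ground truth.

This module generates fully synthetic datasets that mimic a sciatic-nerve
MR-neurography (MRN) protocol: a multi-spin-echo (MSE) stack for T2
relaxometry, a magnetization-transfer (MT) image pair, and a high-resolution
reference volume, together with nerve/muscle ROI masks and the generative
ground truth. The statistical structure follows a crossed
subject x scan x reader design so that the downstream reliability analysis
(ICC, SEM, MDD, Bland-Altman) can be validated against known variance
components.

Signal model
------------
Every voxel is either "nerve" or "muscle" (the background of the thigh is
treated as muscle tissue). The noiseless MSE signal is mono-exponential with
a constant offset,

    S(TE) = PSD * exp(-TE / T2) + offset,

and the MT pair satisfies S1 = S0 * (1 - MTR/100). Magnitude images carry
Rician noise: two independent Gaussian channels of width ``noise_sigma`` are
added in quadrature, which produces the familiar positive noise floor at low
signal-to-noise ratio (one physical reason the offset is a fit parameter
downstream).

Reader variability enters exclusively through stochastic perturbation of the
ROI boundary (readers segment independently on identical images); scan
variability enters through per-scan perturbation of the true tissue values
plus fresh noise. No geometric repositioning, B1 inhomogeneity, or k-space
physics is simulated.

Reproducibility: a single master seed is split into per-(purpose, subject,
scan, reader) substreams with counter-based ``numpy.random.SeedSequence``
spawn keys, so enlarging the cohort never changes earlier draws.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DegenerateRoiError, DesignError

logger = logging.getLogger("qmrn.synthetic")

# --------------------------------------------------------------------------
# Protocol constants (defaults of the emulated acquisition)
# --------------------------------------------------------------------------

#: Echo times of the multi-spin-echo protocol [ms]: 10, 20, ..., 120.
DEFAULT_TE_MS: tuple[float, ...] = tuple(float(te) for te in range(10, 130, 10))

#: Number of central slices entering every per-nerve average.
N_ANALYSIS_SLICES = 6

#: Effective echo time used to render the T2-weighted reference volume [ms].
REF_TE_MS = 54.0

#: Muscle tissue defaults (calibration choices; the ratio of nerve to muscle
#: proton spin density is calibrated to ~0.71).
MUSCLE_T2_MS = 30.0
MUSCLE_MTR_PERCENT = 40.0

#: MT-pair signal levels without the saturation pulse [a.u.].
MT_S0_NERVE = 220.0
MT_S0_MUSCLE = 300.0

#: Muscle ROI: a disc of this area placed at a fixed in-plane offset from the
#: nerve (emulating a ROI "medially adjacent" to the nerve).
MUSCLE_ROI_AREA_MM2 = 80.0
MUSCLE_ROI_OFFSET_MM = 25.0

#: Per-subject jitter of the nerve centre around the FOV centre [mm].
NERVE_CENTER_JITTER_MM = 8.0

#: Biomarker column names used throughout the package.
BIOMARKERS: tuple[str, ...] = (
    "mtr_percent",
    "t2_ms",
    "psd",
    "psd_normalized",
    "csa_mm2",
)

_BIOMARKER_CODE = {name: i for i, name in enumerate(BIOMARKERS)}

# Substream namespaces for seed splitting.
_NS_SUBJECT_EFFECT = 0
_NS_SCAN_EFFECT = 1
_NS_CENTER = 2
_NS_READER_SEED = 3
_NS_IMAGE_NOISE = 4
_NS_MASK_PERTURB = 5
_NS_READER_BIAS = 6
_NS_MEASUREMENT = 7

_SEQ_MSE = 0
_SEQ_MT_OFF = 1
_SEQ_MT_ON = 2
_SEQ_REF = 3


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic substream for a master seed and an integer spawn key."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# --------------------------------------------------------------------------
# Geometry
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Grid:
    """In-plane grid + slice stack of one acquired sequence.

    The field of view is square in physical units, so anisotropic matrices
    (e.g. 192 x 169) imply anisotropic pixels: pixel size is
    ``(fov/rows, fov/cols)`` mm.
    """

    rows: int
    cols: int
    n_slices: int
    slice_thickness_mm: float
    fov_mm: float

    def __post_init__(self) -> None:
        if self.fov_mm <= 0:
            raise ValueError("fov_mm must be positive")
        if self.rows < 1 or self.cols < 1 or self.n_slices < 1:
            raise ValueError("grid dimensions must be positive")
        if self.slice_thickness_mm <= 0:
            raise ValueError("slice_thickness_mm must be positive")

    @property
    def pixel_mm(self) -> tuple[float, float]:
        return (self.fov_mm / self.rows, self.fov_mm / self.cols)

    @property
    def pixel_area_mm2(self) -> float:
        pr, pc = self.pixel_mm
        return pr * pc

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return (self.n_slices, self.rows, self.cols)

    def central_slices(self, k: int = N_ANALYSIS_SLICES) -> list[int]:
        """Indices of the ``k`` central slices (the analysis window)."""
        if self.n_slices < k:
            raise ValueError(f"stack has {self.n_slices} slices, need >= {k}")
        start = (self.n_slices - k) // 2
        return list(range(start, start + k))

    def row_centers_mm(self) -> np.ndarray:
        return (np.arange(self.rows) + 0.5) * (self.fov_mm / self.rows)

    def col_centers_mm(self) -> np.ndarray:
        return (np.arange(self.cols) + 0.5) * (self.fov_mm / self.cols)


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Geometry of the three-sequence MRN protocol.

    Defaults reproduce a 3-T sciatic-nerve protocol: 160 x 160 mm FOV;
    reference T2-weighted stack 512 x 333 / 41 slices / 3.5 mm; MSE stack
    192 x 169 / 13 slices / 3.5 mm with TE = 10..120 ms; MT pair
    128 x 128 / 18 slices / 4 mm.
    """

    fov_mm: float = 160.0
    matrix_mse: tuple[int, int] = (192, 169)
    matrix_mt: tuple[int, int] = (128, 128)
    matrix_ref: tuple[int, int] = (512, 333)
    slice_thickness_mse_mm: float = 3.5
    slice_thickness_mt_mm: float = 4.0
    slice_thickness_ref_mm: float = 3.5
    n_slices_mse: int = 13
    n_slices_mt: int = 18
    n_slices_ref: int = 41
    te_list_ms: tuple[float, ...] = DEFAULT_TE_MS

    def __post_init__(self) -> None:
        if self.fov_mm <= 0:
            raise ValueError("fov_mm must be positive")
        for name in ("matrix_mse", "matrix_mt", "matrix_ref"):
            mat = getattr(self, name)
            if len(mat) != 2 or min(mat) < 16:
                raise ValueError(f"{name} must be two dims >= 16, got {mat}")
        te = np.asarray(self.te_list_ms, dtype=float)
        if te.size < 1 or np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError("te_list_ms must be strictly increasing and positive")
        for name in ("n_slices_mse", "n_slices_mt", "n_slices_ref"):
            if getattr(self, name) < N_ANALYSIS_SLICES:
                raise ValueError(
                    f"{name} must be >= {N_ANALYSIS_SLICES} (six central slices)"
                )

    @property
    def mse(self) -> Grid:
        return Grid(*self.matrix_mse, self.n_slices_mse,
                    self.slice_thickness_mse_mm, self.fov_mm)

    @property
    def mt(self) -> Grid:
        return Grid(*self.matrix_mt, self.n_slices_mt,
                    self.slice_thickness_mt_mm, self.fov_mm)

    @property
    def ref(self) -> Grid:
        return Grid(*self.matrix_ref, self.n_slices_ref,
                    self.slice_thickness_ref_mm, self.fov_mm)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["matrix_mse"] = list(d["matrix_mse"])
        d["matrix_mt"] = list(d["matrix_mt"])
        d["matrix_ref"] = list(d["matrix_ref"])
        d["te_list_ms"] = list(d["te_list_ms"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "AcquisitionGeometry":
        d = dict(d)
        for key in ("matrix_mse", "matrix_mt", "matrix_ref", "te_list_ms"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# --------------------------------------------------------------------------
# Variance components and cohort ground truth
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class VarianceComponents:
    """Additive variance decomposition of one biomarker.

    A measurement for subject s, scan t, reader r is modelled as

        y_str = mu + b_s + w_st + c_r + e_str

    with independent zero-mean normal effects of standard deviation
    ``sd_subject``, ``sd_scan``, ``sd_reader`` and ``sd_residual``. All
    values are in the biomarker's own units.
    """

    mu: float
    sd_subject: float
    sd_scan: float = 0.0
    sd_reader: float = 0.0
    sd_residual: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sd_subject", "sd_scan", "sd_reader", "sd_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def theoretical_test_retest_icc(self) -> float:
        """ICC of a subjects x scans table under this model (one reader)."""
        num = self.sd_subject**2
        den = self.sd_subject**2 + self.sd_scan**2 + self.sd_residual**2
        if den == 0:
            return 1.0
        return num / den

    @property
    def sd_total(self) -> float:
        return math.sqrt(
            self.sd_subject**2 + self.sd_scan**2
            + self.sd_reader**2 + self.sd_residual**2
        )

    @classmethod
    def from_totals(cls, mu: float, sd_total: float, sd_residual: float,
                    sd_scan: float = 0.0, sd_reader: float = 0.0
                    ) -> "VarianceComponents":
        """Build components from a total SD by subtracting error terms."""
        var_subject = sd_total**2 - sd_scan**2 - sd_reader**2 - sd_residual**2
        if var_subject < 0:
            raise ValueError("error SDs exceed the total SD")
        return cls(mu=mu, sd_subject=math.sqrt(var_subject), sd_scan=sd_scan,
                   sd_reader=sd_reader, sd_residual=sd_residual)


#: Defaults calibrated to a healthy-volunteer sciatic-nerve cohort
#: (grand mean +/- SD: MTR 26.75 +/- 3.5 %, T2 64.54 +/- 8.2 ms,
#: PSD 340.93 +/- 78.8 a.u., normalized PSD 0.71 +/- 0.09,
#: CSA 18.1 +/- 4.5 mm^2). The residual SD of each biomarker is set to its
#: published test-retest standard error of measurement; the remaining
#: variance is attributed to subjects.
DEFAULT_VARIANCE_COMPONENTS: Mapping[str, VarianceComponents] = {
    "mtr_percent": VarianceComponents.from_totals(26.75, 3.5, 1.7),
    "t2_ms": VarianceComponents.from_totals(64.54, 8.2, 2.66),
    "psd": VarianceComponents.from_totals(340.93, 78.8, 20.1),
    "psd_normalized": VarianceComponents.from_totals(0.71, 0.09, 0.03),
    "csa_mm2": VarianceComponents.from_totals(18.1, 4.5, 1.0),
}

#: Nerve-to-muscle proton-spin-density ratio used for muscle calibration.
DEFAULT_NPSD_RATIO = 0.71


@dataclass
class CohortTruth:
    """Ground-truth biomarker values for a simulated cohort.

    Arrays are indexed ``[subject, scan]``. ``psd_normalized`` carries its
    own generative truth for measurement-level simulation; in the image
    pipeline the normalized PSD instead emerges as the fitted nerve/muscle
    PSD ratio.
    """

    n_subjects: int
    n_scans: int
    n_readers: int
    t2_ms: np.ndarray
    psd: np.ndarray
    offset_au: np.ndarray
    mtr_percent: np.ndarray
    psd_normalized: np.ndarray
    csa_mm2: np.ndarray
    muscle_t2_ms: float
    muscle_psd: float
    nerve_center_mm: np.ndarray          # (n_subjects, 2): (row, col) in mm
    reader_seeds: np.ndarray             # (n_readers,) int
    seed: int
    variance_components: dict[str, VarianceComponents]

    def __post_init__(self) -> None:
        shape = (self.n_subjects, self.n_scans)
        for name in ("t2_ms", "psd", "offset_au", "mtr_percent",
                     "psd_normalized", "csa_mm2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}")
            setattr(self, name, arr)
        if np.any(self.t2_ms <= 0) or np.any(self.psd <= 0):
            raise ValueError("true T2 and PSD must be positive")
        if np.any(self.mtr_percent < 0) or np.any(self.mtr_percent >= 100):
            raise ValueError("true MTR must lie in [0, 100)")
        if np.any(self.csa_mm2 <= 0):
            raise ValueError("true CSA must be positive")

    def biomarker_truth(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "n_subjects": self.n_subjects,
            "n_scans": self.n_scans,
            "n_readers": self.n_readers,
            "t2_ms": self.t2_ms.tolist(),
            "psd": self.psd.tolist(),
            "offset_au": self.offset_au.tolist(),
            "mtr_percent": self.mtr_percent.tolist(),
            "psd_normalized": self.psd_normalized.tolist(),
            "csa_mm2": self.csa_mm2.tolist(),
            "muscle_t2_ms": self.muscle_t2_ms,
            "muscle_psd": self.muscle_psd,
            "nerve_center_mm": self.nerve_center_mm.tolist(),
            "reader_seeds": self.reader_seeds.tolist(),
            "seed": self.seed,
            "variance_components": {
                k: asdict(v) for k, v in self.variance_components.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortTruth":
        d = dict(d)
        d.pop("schema_version", None)
        d["variance_components"] = {
            k: VarianceComponents(**v)
            for k, v in d["variance_components"].items()
        }
        for key in ("t2_ms", "psd", "offset_au", "mtr_percent",
                    "psd_normalized", "csa_mm2", "nerve_center_mm"):
            d[key] = np.asarray(d[key], dtype=float)
        d["reader_seeds"] = np.asarray(d["reader_seeds"], dtype=np.int64)
        return cls(**d)

    def save(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: Path | str) -> "CohortTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _draw_truth(vc: VarianceComponents, n_subjects: int, n_scans: int,
                seed: int, code: int, lo: float | None, hi: float | None
                ) -> np.ndarray:
    """Draw mu + subject + scan effects, redrawing out-of-range values."""
    values = np.empty((n_subjects, n_scans))
    for s in range(n_subjects):
        rng_b = _rng(seed, _NS_SUBJECT_EFFECT, code, s)
        rng_w = _rng(seed, _NS_SCAN_EFFECT, code, s)
        b = rng_b.normal(0.0, vc.sd_subject)
        for t in range(n_scans):
            w = rng_w.normal(0.0, vc.sd_scan)
            v = vc.mu + b + w
            tries = 0
            while (lo is not None and v <= lo) or (hi is not None and v >= hi):
                tries += 1
                logger.warning(
                    "redrawing out-of-range truth (biomarker code %d, "
                    "subject %d, scan %d, value %.4g)", code, s, t, v)
                if tries % 50 == 0 or vc.sd_scan == 0:
                    b = rng_b.normal(0.0, vc.sd_subject)
                w = rng_w.normal(0.0, vc.sd_scan)
                v = vc.mu + b + w
                if tries > 1000:
                    raise DesignError(
                        "cannot draw an in-range truth value; check the "
                        "variance components")
            values[s, t] = v
    return values


def sample_cohort(n_subjects: int = 21, n_scans: int = 3, n_readers: int = 2,
                  vc_t2: VarianceComponents | None = None,
                  vc_psd: VarianceComponents | None = None,
                  vc_mtr: VarianceComponents | None = None,
                  vc_npsd: VarianceComponents | None = None,
                  vc_csa: VarianceComponents | None = None,
                  seed: int = 0,
                  offset_au: float = 12.0,
                  muscle_t2_ms: float = MUSCLE_T2_MS,
                  muscle_psd: float | None = None) -> CohortTruth:
    """Sample ground-truth biomarkers for a subject x scan x reader design.

    True value per (subject, scan) = mu + subject effect + scan effect, with
    effects drawn independently per biomarker. The constant offset of the
    echo-decay model is shared by all subjects by default. Deterministic
    given ``seed``; per-subject substreams make the draw stable under cohort
    enlargement.
    """
    if n_subjects < 2 or n_scans < 2 or n_readers < 2:
        raise DesignError(
            "need >= 2 subjects, scans and readers for reliability use "
            f"(got {n_subjects}, {n_scans}, {n_readers})")
    vcs = {
        "t2_ms": vc_t2 or DEFAULT_VARIANCE_COMPONENTS["t2_ms"],
        "psd": vc_psd or DEFAULT_VARIANCE_COMPONENTS["psd"],
        "mtr_percent": vc_mtr or DEFAULT_VARIANCE_COMPONENTS["mtr_percent"],
        "psd_normalized": vc_npsd or DEFAULT_VARIANCE_COMPONENTS["psd_normalized"],
        "csa_mm2": vc_csa or DEFAULT_VARIANCE_COMPONENTS["csa_mm2"],
    }
    bounds = {
        "t2_ms": (0.0, None),
        "psd": (0.0, None),
        "mtr_percent": (-1e-12, 100.0),   # allow exactly 0
        "psd_normalized": (0.0, None),
        "csa_mm2": (0.0, None),
    }
    truth_arrays = {}
    for name, vc in vcs.items():
        lo, hi = bounds[name]
        truth_arrays[name] = _draw_truth(
            vc, n_subjects, n_scans, seed, _BIOMARKER_CODE[name], lo, hi)

    centers = np.empty((n_subjects, 2))
    for s in range(n_subjects):
        jitter = _rng(seed, _NS_CENTER, s).uniform(
            -NERVE_CENTER_JITTER_MM, NERVE_CENTER_JITTER_MM, size=2)
        centers[s] = jitter          # offset from the FOV centre, in mm

    reader_seeds = np.array(
        [int(_rng(seed, _NS_READER_SEED, r).integers(2**31))
         for r in range(n_readers)], dtype=np.int64)

    if muscle_psd is None:
        muscle_psd = vcs["psd"].mu / DEFAULT_NPSD_RATIO

    return CohortTruth(
        n_subjects=n_subjects, n_scans=n_scans, n_readers=n_readers,
        t2_ms=truth_arrays["t2_ms"], psd=truth_arrays["psd"],
        offset_au=np.full((n_subjects, n_scans), float(offset_au)),
        mtr_percent=truth_arrays["mtr_percent"],
        psd_normalized=truth_arrays["psd_normalized"],
        csa_mm2=truth_arrays["csa_mm2"],
        muscle_t2_ms=muscle_t2_ms, muscle_psd=float(muscle_psd),
        nerve_center_mm=centers, reader_seeds=reader_seeds, seed=int(seed),
        variance_components=vcs)


# --------------------------------------------------------------------------
# Image containers
# --------------------------------------------------------------------------


@dataclass
class RoiMask:
    """Binary ROI mask on a specific grid. ``data`` is (slice, row, col)."""

    data: np.ndarray
    grid: Grid
    label: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != self.grid.shape3d:
            raise ValueError(
                f"mask shape {self.data.shape} != grid {self.grid.shape3d}")

    def slice(self, index: int) -> np.ndarray:
        return self.data[index]

    def count(self, index: int) -> int:
        return int(self.data[index].sum())

    def nonempty_slices(self) -> np.ndarray:
        return np.flatnonzero(self.data.any(axis=(1, 2)))


@dataclass
class MultiEchoStack:
    """Multi-echo magnitude images, indexed (slice, echo, row, col)."""

    data: np.ndarray
    te_ms: tuple[float, ...]
    grid: Grid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.te_ms = tuple(float(t) for t in self.te_ms)
        expect = (self.grid.n_slices, len(self.te_ms),
                  self.grid.rows, self.grid.cols)
        if self.data.shape != expect:
            raise ValueError(f"stack shape {self.data.shape} != {expect}")
        if np.any(self.data < 0):
            raise ValueError("magnitude images must be non-negative")


@dataclass
class MTPair:
    """MT-off (s0) / MT-on (s1) volume pair, each (slice, row, col)."""

    s0: np.ndarray
    s1: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.s0 = np.asarray(self.s0, dtype=float)
        self.s1 = np.asarray(self.s1, dtype=float)
        if self.s0.shape != self.s1.shape:
            raise ValueError("s0 and s1 must have identical shapes")
        if self.s0.shape != self.grid.shape3d:
            raise ValueError(
                f"volume shape {self.s0.shape} != grid {self.grid.shape3d}")
        if np.any(self.s0 < 0) or np.any(self.s1 < 0):
            raise ValueError("magnitude images must be non-negative")


# --------------------------------------------------------------------------
# Mask construction and rendering
# --------------------------------------------------------------------------


def _disc_mask(grid: Grid, center_mm: Sequence[float], area_mm2: float
               ) -> np.ndarray:
    """Filled disc of a given physical area on one slice (2D bool)."""
    radius = math.sqrt(area_mm2 / math.pi)
    y = grid.row_centers_mm() - center_mm[0]
    x = grid.col_centers_mm() - center_mm[1]
    return (y[:, None] ** 2 + x[None, :] ** 2) <= radius**2


def _nerve_center(truth: CohortTruth, subject: int, grid: Grid
                  ) -> tuple[float, float]:
    cy = grid.fov_mm / 2 + truth.nerve_center_mm[subject, 0]
    cx = grid.fov_mm / 2 + truth.nerve_center_mm[subject, 1]
    return (cy, cx)


def nerve_mask(truth: CohortTruth, subject: int, scan: int, grid: Grid
               ) -> RoiMask:
    """Filled-disc nerve footprint matching the true CSA, on every slice."""
    csa = truth.csa_mm2[subject, scan]
    if csa < grid.pixel_area_mm2:
        raise DegenerateRoiError(
            f"nerve CSA {csa:.2f} mm^2 is smaller than one pixel "
            f"({grid.pixel_area_mm2:.2f} mm^2) on a "
            f"{grid.rows}x{grid.cols} grid")
    center = _nerve_center(truth, subject, grid)
    disc = _disc_mask(grid, center, csa)
    if not disc.any():
        # CSA covers >= one pixel area but no pixel centre falls inside the
        # disc; assign the pixel whose centre is nearest
        i = int(np.argmin(np.abs(grid.row_centers_mm() - center[0])))
        j = int(np.argmin(np.abs(grid.col_centers_mm() - center[1])))
        disc[i, j] = True
    return RoiMask(np.broadcast_to(disc, grid.shape3d).copy(), grid, "nerve")


def muscle_mask(truth: CohortTruth, subject: int, scan: int, grid: Grid
                ) -> RoiMask:
    """Muscle ROI disc at a fixed in-plane offset from the nerve."""
    cy, cx = _nerve_center(truth, subject, grid)
    disc = _disc_mask(grid, (cy, cx + MUSCLE_ROI_OFFSET_MM),
                      MUSCLE_ROI_AREA_MM2)
    if not disc.any():
        raise DegenerateRoiError("muscle ROI covers no pixel")
    return RoiMask(np.broadcast_to(disc, grid.shape3d).copy(), grid, "muscle")


def _rician(noiseless: np.ndarray, sigma: float, rng: np.random.Generator
            ) -> np.ndarray:
    """Apply Rician noise; the identity when sigma == 0."""
    if sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if sigma == 0:
        return noiseless.astype(float, copy=True)
    re = noiseless + rng.normal(0.0, sigma, size=noiseless.shape)
    im = rng.normal(0.0, sigma, size=noiseless.shape)
    return np.sqrt(re**2 + im**2)


def _decay(psd: float, t2: float, offset: float, te: np.ndarray) -> np.ndarray:
    return psd * np.exp(-te / t2) + offset


def render_mse_stack(truth: CohortTruth, subject: int, scan: int,
                     geometry: AcquisitionGeometry, noise_sigma: float = 0.0,
                     seed: int | None = None
                     ) -> tuple[MultiEchoStack, RoiMask, RoiMask]:
    """Render the multi-echo stack plus nerve and muscle masks.

    Nerve voxels decay with the subject/scan's true (PSD, T2, offset);
    everything else behaves as muscle. Rician noise is applied per voxel and
    echo. Deterministic given the truth's master seed (or ``seed``).
    """
    grid = geometry.mse
    seed = truth.seed if seed is None else seed
    te = np.asarray(geometry.te_list_ms)
    nerve = nerve_mask(truth, subject, scan, grid)
    muscle = muscle_mask(truth, subject, scan, grid)

    nerve_curve = _decay(truth.psd[subject, scan], truth.t2_ms[subject, scan],
                         truth.offset_au[subject, scan], te)
    muscle_curve = _decay(truth.muscle_psd, truth.muscle_t2_ms,
                          truth.offset_au[subject, scan], te)
    # (slice, echo, row, col): muscle background, nerve disc overlaid
    noiseless = np.where(nerve.data[:, None, :, :],
                         nerve_curve[None, :, None, None],
                         muscle_curve[None, :, None, None])
    rng = _rng(seed, _NS_IMAGE_NOISE, subject, scan, _SEQ_MSE)
    data = _rician(noiseless, noise_sigma, rng)
    return MultiEchoStack(data, geometry.te_list_ms, grid), nerve, muscle


def render_mt_pair(truth: CohortTruth, subject: int, scan: int,
                   geometry: AcquisitionGeometry, noise_sigma: float = 0.0,
                   seed: int | None = None) -> MTPair:
    """Render the MT-off/MT-on pair: S1 = S0 * (1 - MTR/100) per tissue."""
    grid = geometry.mt
    seed = truth.seed if seed is None else seed
    mtr = truth.mtr_percent[subject, scan]
    nerve = nerve_mask(truth, subject, scan, grid)
    s0 = np.where(nerve.data, MT_S0_NERVE, MT_S0_MUSCLE)
    s1 = np.where(nerve.data,
                  MT_S0_NERVE * (1 - mtr / 100.0),
                  MT_S0_MUSCLE * (1 - MUSCLE_MTR_PERCENT / 100.0))
    rng0 = _rng(seed, _NS_IMAGE_NOISE, subject, scan, _SEQ_MT_OFF)
    rng1 = _rng(seed, _NS_IMAGE_NOISE, subject, scan, _SEQ_MT_ON)
    return MTPair(_rician(s0, noise_sigma, rng0),
                  _rician(s1, noise_sigma, rng1), grid)


def render_reference(truth: CohortTruth, subject: int, scan: int,
                     geometry: AcquisitionGeometry, noise_sigma: float = 0.0,
                     seed: int | None = None
                     ) -> tuple[np.ndarray, RoiMask, RoiMask]:
    """High-resolution T2-weighted reference volume (nerve hyperintense)."""
    grid = geometry.ref
    seed = truth.seed if seed is None else seed
    nerve = nerve_mask(truth, subject, scan, grid)
    muscle = muscle_mask(truth, subject, scan, grid)
    te_ref = np.array(REF_TE_MS)
    s_nerve = float(_decay(truth.psd[subject, scan],
                           truth.t2_ms[subject, scan],
                           truth.offset_au[subject, scan], te_ref))
    s_muscle = float(_decay(truth.muscle_psd, truth.muscle_t2_ms,
                            truth.offset_au[subject, scan], te_ref))
    noiseless = np.where(nerve.data, s_nerve, s_muscle)
    rng = _rng(seed, _NS_IMAGE_NOISE, subject, scan, _SEQ_REF)
    return _rician(noiseless, noise_sigma, rng), nerve, muscle


# --------------------------------------------------------------------------
# Reader emulation
# --------------------------------------------------------------------------


def perturb_mask(mask: RoiMask, reader: int, boundary_flip_prob: float,
                 seed: int, max_attempts: int = 10) -> RoiMask:
    """Emulate independent manual segmentation by toggling boundary voxels.

    Each inner-boundary voxel (mask voxel touching background) and each
    outer-boundary voxel (background voxel touching the mask) independently
    flips with probability ``boundary_flip_prob``. Interior voxels never
    change. If a perturbation empties a slice that was non-empty, a fresh
    substream is tried, up to ``max_attempts`` times.
    """
    if not 0 <= boundary_flip_prob <= 0.5:
        raise ValueError("boundary_flip_prob must lie in [0, 0.5]")
    if boundary_flip_prob == 0:
        return RoiMask(mask.data.copy(), mask.grid, mask.label)
    occupied = mask.data.any(axis=(1, 2))
    structure = np.zeros((1, 3, 3), dtype=bool)
    structure[0] = [[0, 1, 0], [1, 1, 1], [0, 1, 0]]   # in-plane 4-connectivity
    for attempt in range(max_attempts):
        rng = _rng(seed, _NS_MASK_PERTURB, reader, attempt)
        inner = mask.data & ~ndimage.binary_erosion(mask.data, structure)
        outer = ndimage.binary_dilation(mask.data, structure) & ~mask.data
        boundary = inner | outer
        flips = boundary & (rng.random(mask.data.shape) < boundary_flip_prob)
        new = mask.data ^ flips
        if np.array_equal(new.any(axis=(1, 2)), occupied):
            return RoiMask(new, mask.grid, mask.label)
        logger.warning("mask perturbation emptied a slice; retrying "
                       "(attempt %d)", attempt + 1)
    raise DegenerateRoiError(
        f"mask perturbation emptied an analysis slice {max_attempts} times")


# --------------------------------------------------------------------------
# Measurement-level simulation (the reliability replica)
# --------------------------------------------------------------------------


def simulate_measurements(truth: CohortTruth, seed: int | None = None
                          ) -> pd.DataFrame:
    """Simulate reader measurements directly from the variance components.

    Each biomarker measurement is its (subject, scan) truth plus a reader
    bias ~ N(0, sd_reader) and a residual ~ N(0, sd_residual). This bypasses
    image rendering and is the fast replica used to validate the reliability
    stage against known components.
    """
    seed = truth.seed if seed is None else seed
    rows = []
    reader_bias = {}
    for name, vc in truth.variance_components.items():
        code = _BIOMARKER_CODE[name]
        reader_bias[name] = [
            _rng(seed, _NS_READER_BIAS, code, r).normal(0.0, vc.sd_reader)
            for r in range(truth.n_readers)]
    for s in range(truth.n_subjects):
        for t in range(truth.n_scans):
            for r in range(truth.n_readers):
                row = {"subject": s, "scan": t, "reader": r}
                for name, vc in truth.variance_components.items():
                    code = _BIOMARKER_CODE[name]
                    e = _rng(seed, _NS_MEASUREMENT, code, s, t, r).normal(
                        0.0, vc.sd_residual)
                    row[name] = (truth.biomarker_truth(name)[s, t]
                                 + reader_bias[name][r] + e)
                rows.append(row)
    return pd.DataFrame(rows)


def simulate_icc_tables(n: int, k: int, sd_subject: float, sd_error: float,
                        reps: int, seed: int, sd_rater: float = 0.0
                        ) -> np.ndarray:
    """Simulate ``reps`` complete n x k measurement tables.

    value[i, j] = subject_i + rater_j + error_ij; the theoretical
    absolute-agreement ICC is sd_subject^2 / (sd_subject^2 + sd_rater^2 +
    sd_error^2). Returns an array of shape (reps, n, k).
    """
    rng = np.random.default_rng(seed)
    subj = rng.normal(0.0, sd_subject, size=(reps, n, 1))
    rater = rng.normal(0.0, sd_rater, size=(reps, 1, k))
    err = rng.normal(0.0, sd_error, size=(reps, n, k))
    return subj + rater + err


# --------------------------------------------------------------------------
# On-disk dataset generation
# --------------------------------------------------------------------------


def generate_dataset(out_dir: Path | str, *, n_subjects: int = 21,
                     n_scans: int = 3, n_readers: int = 2,
                     geometry: AcquisitionGeometry | None = None,
                     noise_sigma: float = 5.0,
                     boundary_flip_prob: float = 0.15,
                     seed: int = 0,
                     truth: CohortTruth | None = None) -> Path:
    """Write a complete synthetic dataset to disk; returns the manifest path.

    Per (subject, scan): MSE stack (NIfTI + TE JSON sidecar), MT-off/MT-on
    volumes, reference volume, and per-reader nerve/muscle masks drawn on
    the reference grid and perturbed per reader. A ground-truth JSON sidecar
    and a manifest CSV (subject, scan, reader, role, path, checksum) index
    the dataset. Re-running with the same seed reproduces identical bytes.
    """
    from . import io_report  # local import; io_report imports this module

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geometry = geometry or AcquisitionGeometry()
    if truth is None:
        truth = sample_cohort(n_subjects, n_scans, n_readers, seed=seed)

    rows: list[dict] = []

    def _add(path: Path, subject, scan, reader, role):
        rows.append({
            "subject": subject, "scan": scan, "reader": reader, "role": role,
            "path": str(path.relative_to(out)),
            "checksum": io_report.sha256_file(path)})

    truth_path = out / "truth.json"
    truth.save(truth_path)
    _add(truth_path, "", "", "", "truth")

    geom_path = out / "geometry.json"
    geom_path.write_text(json.dumps(geometry.to_dict(), indent=1))
    _add(geom_path, "", "", "", "geometry")

    for s in range(truth.n_subjects):
        for t in range(truth.n_scans):
            stem = out / f"sub-{s:02d}_scan-{t}"
            mse, _, _ = render_mse_stack(truth, s, t, geometry, noise_sigma)
            p = stem.with_name(stem.name + "_mse.nii")
            io_report.save_mse_stack(p, mse)
            _add(p, s, t, "", "mse")
            _add(p.with_suffix(".json"), s, t, "", "te_sidecar")

            pair = render_mt_pair(truth, s, t, geometry, noise_sigma)
            p0 = stem.with_name(stem.name + "_mt-off.nii")
            p1 = stem.with_name(stem.name + "_mt-on.nii")
            io_report.save_volume(p0, pair.s0, pair.grid)
            io_report.save_volume(p1, pair.s1, pair.grid)
            _add(p0, s, t, "", "mt_off")
            _add(p1, s, t, "", "mt_on")

            ref, ref_nerve, ref_muscle = render_reference(
                truth, s, t, geometry, noise_sigma)
            pr = stem.with_name(stem.name + "_ref.nii")
            io_report.save_volume(pr, ref, geometry.ref)
            _add(pr, s, t, "", "ref")

            for r in range(truth.n_readers):
                mask_seed = int(_rng(truth.seed, _NS_MASK_PERTURB, s, t)
                                .integers(2**31))
                for base, role in ((ref_nerve, "mask_nerve"),
                                   (ref_muscle, "mask_muscle")):
                    pert = perturb_mask(base, r, boundary_flip_prob,
                                        mask_seed)
                    pm = stem.with_name(
                        stem.name + f"_reader-{r}_{role}.nii")
                    io_report.save_mask(pm, pert)
                    _add(pm, s, t, r, role)

    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
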