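"""Magnetization transfer ratio (MTR) from an MT-off/MT-on image pair.

MTR = 100 * (S0 - S1) / S0, where S0 and S1 are the ROI-mean signals
without and with the off-resonance saturation pulse. The ROI mean is taken
on each volume *before* forming the ratio (mean-then-ratio), which is the
noise-robust order for ROI statistics; the slice-wise MTR values are then
averaged (unweighted) over the six central analysis slices. No
computational co-registration between the two volumes is applied by
default; the acquisition is assumed to be at identical slice positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateRoiError, GeometryError, InvalidSignalError
from .synthetic import MTPair, RoiMask

logger = logging.getLogger("qmrn.mti")


@dataclass
class MtrResult:
    """MTR per slice plus the six-slice mean."""

    mtr_percent: float
    per_slice: pd.DataFrame = field(default_factory=pd.DataFrame)


def _slice_record(pair: MTPair, mask: RoiMask, slice_index: int) -> dict:
    if pair.grid != mask.grid:
        raise GeometryError("pair and mask are on different grids")
    m = mask.slice(slice_index)
    n = int(m.sum())
    if n == 0:
        raise DegenerateRoiError(
            f"mask '{mask.label}' is empty on slice {slice_index}")
    s0_mean = float(pair.s0[slice_index][m].mean())
    s1_mean = float(pair.s1[slice_index][m].mean())
    if s0_mean <= 0:
        raise InvalidSignalError(
            f"non-positive S0 mean ({s0_mean:.4g}) on slice {slice_index}")
    mtr = 100.0 * (s0_mean - s1_mean) / s0_mean
    if mtr < 0:
        logger.warning("negative MTR (%.3f%%) on slice %d; reported as-is",
                       mtr, slice_index)
    return {"slice": slice_index, "s0_mean": s0_mean, "s1_mean": s1_mean,
            "mtr_percent": mtr, "n_voxels": n}


def mtr_slice(pair: MTPair, mask: RoiMask, slice_index: int) -> MtrResult:
    """MTR of a single slice (ROI means first, then the ratio)."""
    rec = _slice_record(pair, mask, slice_index)
    return MtrResult(mtr_percent=rec["mtr_percent"],
                     per_slice=pd.DataFrame([rec]))


def nerve_mtr(pair: MTPair, mask: RoiMask,
              analysis_slices: list[int] | None = None) -> MtrResult:
    """Slice-wise MTR averaged (unweighted) over the analysis slices."""
    if analysis_slices is None:
        analysis_slices = pair.grid.central_slices()
    records = [_slice_record(pair, mask, idx) for idx in analysis_slices]
    per_slice = pd.DataFrame(records)
    return MtrResult(mtr_percent=float(per_slice["mtr_percent"].mean()),
                     per_slice=per_slice)
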