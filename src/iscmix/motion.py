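"""Head-motion quantification: framewise displacement, censoring, run exclusion.

Framewise displacement (FD) summarizes per-volume head motion as the sum of
absolute backward differences of the six rigid-body realignment parameters,
with rotations expressed as arc length on a sphere (50 mm by default).
Volumes whose FD exceeds a threshold (0.5 mm in the reference pipeline) are
censored, and runs where the censored count passes a fraction of the run
(>9%, i.e. 16 of 176 volumes) are excluded outright.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MotionTrace",
    "CensorMask",
    "RunExclusion",
    "compute_fd",
    "make_censor_mask",
    "run_exclusion",
    "read_motion_1d",
    "write_motion_1d",
    "read_censor_1d",
    "write_censor_1d",
]


@dataclass(frozen=True)
class MotionTrace:
    """Six rigid-body realignment parameters per functional volume.

    Parameters
    ----------
    translations : (n_volumes, 3) array
        Displacements (d_x, d_y, d_z) in mm.
    rotations : (n_volumes, 3) array
        Angular parameters (alpha, beta, gamma), radians unless
        ``rotations_in_degrees`` is set.
    rotations_in_degrees : bool
        Unit flag for the rotation columns (AFNI 3dvolreg writes degrees).
    """

    translations: np.ndarray
    rotations: np.ndarray
    rotations_in_degrees: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.translations, dtype=float)
        r = np.asarray(self.rotations, dtype=float)
        if t.ndim != 2 or t.shape[1] != 3 or r.shape != t.shape:
            raise ValueError(
                "translations and rotations must both be (n_volumes, 3); got "
                f"{t.shape} and {r.shape}"
            )
        if not (np.isfinite(t).all() and np.isfinite(r).all()):
            raise ValueError("motion parameters must be finite")
        object.__setattr__(self, "translations", t)
        object.__setattr__(self, "rotations", r)

    @property
    def n_volumes(self) -> int:
        return self.translations.shape[0]


@dataclass(frozen=True)
class CensorMask:
    """Per-volume keep/censor flags derived from an FD series."""

    keep: np.ndarray
    fd_threshold_mm: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "keep", np.asarray(self.keep, dtype=bool))

    @property
    def n_censored(self) -> int:
        return int((~self.keep).sum())

    @property
    def n_volumes(self) -> int:
        return self.keep.size


@dataclass(frozen=True)
class RunExclusion:
    """Outcome of the run-level high-motion exclusion rule."""

    exclude: bool
    volume_limit: int
    n_censored: int
    n_volumes: int
    max_fraction: float


def compute_fd(motion: MotionTrace, rotation_radius_mm: float = 50.0) -> np.ndarray:
    """Framewise displacement per volume, in mm.

    FD_i = |Δd_ix| + |Δd_iy| + |Δd_iz| + |Δα_i| + |Δβ_i| + |Δγ_i|

    where Δ is the backward difference and the rotation terms are converted
    to displacement as arc length on a sphere of ``rotation_radius_mm``
    (radius 0 sums the raw angular values, reproducing the formula verbatim).
    FD of the first volume is 0 by convention (no predecessor).
    """
    if motion.n_volumes < 2:
        raise ValueError("compute_fd requires at least 2 volumes")
    if rotation_radius_mm < 0:
        raise ValueError("rotation_radius_mm must be >= 0")
    rot = motion.rotations
    if motion.rotations_in_degrees:
        rot = np.deg2rad(rot)
    dt = np.abs(np.diff(motion.translations, axis=0)).sum(axis=1)
    dr = np.abs(np.diff(rot, axis=0)).sum(axis=1)
    if rotation_radius_mm > 0:
        dr = rotation_radius_mm * dr
    fd = np.zeros(motion.n_volumes)
    fd[1:] = dt + dr
    return fd


def make_censor_mask(fd: np.ndarray, fd_threshold_mm: float = 0.5) -> CensorMask:
    """Censor every volume whose FD strictly exceeds the threshold."""
    if fd_threshold_mm <= 0:
        raise ValueError("fd_threshold_mm must be > 0")
    fd = np.asarray(fd, dtype=float)
    return CensorMask(keep=~(fd > fd_threshold_mm), fd_threshold_mm=fd_threshold_mm)


def run_exclusion(
    mask: CensorMask, n_volumes: int | None = None, max_fraction: float = 0.09
) -> RunExclusion:
    """Apply the run-level exclusion rule (>``max_fraction`` of volumes censored).

    ``volume_limit`` is the smallest integer strictly greater than
    ``max_fraction * n_volumes``; the run is excluded when the censored count
    reaches that limit.  At 176 volumes and 9% the limit is 16.
    """
    if not 0 < max_fraction < 1:
        raise ValueError("max_fraction must be in (0, 1)")
    if n_volumes is None:
        n_volumes = mask.n_volumes
    # floor-with-epsilon so an exact product (9.0) still yields the next integer (10)
    volume_limit = int(math.floor(max_fraction * n_volumes + 1e-9)) + 1
    return RunExclusion(
        exclude=mask.n_censored >= volume_limit,
        volume_limit=volume_limit,
        n_censored=mask.n_censored,
        n_volumes=n_volumes,
        max_fraction=max_fraction,
    )


def read_motion_1d(
    path: str | Path,
    order: str = "rotations-first",
    rotations_in_degrees: bool = True,
) -> MotionTrace:
    """Read an AFNI-style whitespace-delimited 6-column motion file.

    ``order="rotations-first"`` is the 3dvolreg dialect (roll pitch yaw dS dL dP,
    rotations in degrees); ``"translations-first"`` covers SPM/FSL-style files.
    """
    arr = np.loadtxt(Path(path), comments=["#", "%"], ndmin=2)
    if arr.shape[1] != 6:
        raise ValueError(f"expected 6 columns in {path}, got {arr.shape[1]}")
    if order == "rotations-first":
        rot, trans = arr[:, :3], arr[:, 3:]
    elif order == "translations-first":
        trans, rot = arr[:, :3], arr[:, 3:]
    else:
        raise ValueError(f"unknown column order {order!r}")
    return MotionTrace(
        translations=trans, rotations=rot, rotations_in_degrees=rotations_in_degrees
    )


def write_motion_1d(
    motion: MotionTrace, path: str | Path, order: str = "rotations-first"
) -> None:
    if order == "rotations-first":
        arr = np.hstack([motion.rotations, motion.translations])
    elif order == "translations-first":
        arr = np.hstack([motion.translations, motion.rotations])
    else:
        raise ValueError(f"unknown column order {order!r}")
    np.savetxt(Path(path), arr, fmt="%.6f")


def read_censor_1d(path: str | Path, fd_threshold_mm: float = 0.5) -> CensorMask:
    """Read an AFNI censor file: one 0 (censor) / 1 (keep) value per line."""
    keep = np.loadtxt(Path(path), ndmin=1).astype(int)
    if not np.isin(keep, (0, 1)).all():
        raise ValueError(f"censor file {path} must contain only 0/1 values")
    return CensorMask(keep=keep.astype(bool), fd_threshold_mm=fd_threshold_mm)


def write_censor_1d(mask: CensorMask, path: str | Path) -> None:
    np.savetxt(Path(path), mask.keep.astype(int), fmt="%d")
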