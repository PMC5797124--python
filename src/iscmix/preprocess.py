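"""Nuisance regression of node x time BOLD-like series.

One single regression removes: polynomial trends (orders 0-3), a 0.01-0.1 Hz
retention band implemented as band-stop sine/cosine regressors on the DFT
grid of the run (so censored volumes can simply be dropped from the fit
rather than interpolated, preserving temporal continuity), the six demeaned
motion parameters and their backward-difference derivatives, tissue signals
of no interest (white matter, ventricle), and optionally a frontal-eye-field
(FEF) mean signal as an attention proxy.  Censored volumes are omitted from
the least-squares fit and returned as NaN gaps in the residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .motion import CensorMask, MotionTrace

__all__ = [
    "SubjectTimeSeries",
    "NuisanceDesign",
    "scale_to_mean_100",
    "build_nuisance_design",
    "regress_nuisance",
    "read_timeseries_tsv",
    "write_timeseries_tsv",
]


@dataclass
class SubjectTimeSeries:
    """A subject's node x time signal matrix with metadata.

    ``keep`` flags uncensored volumes; censored columns of ``data`` are NaN
    after :func:`regress_nuisance` (flagged, never imputed).
    """

    data: np.ndarray
    subject_id: str
    group: str = ""
    age_months: float = float("nan")
    sex: str = ""
    keep: np.ndarray | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D node x time matrix")
        if self.keep is not None:
            self.keep = np.asarray(self.keep, dtype=bool)
            if self.keep.size != self.n_volumes:
                raise ValueError("keep mask length must equal n_volumes")

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


@dataclass
class NuisanceDesign:
    """Named nuisance regressors evaluated on the full time grid."""

    matrix: np.ndarray  # (n_volumes, n_columns)
    names: list[str]
    censor: CensorMask | None = None

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def keep(self) -> np.ndarray:
        if self.censor is None:
            return np.ones(self.n_volumes, dtype=bool)
        return self.censor.keep

    def condition_number(self) -> float:
        """2-norm condition number of the column-scaled design on kept rows."""
        kept = self.matrix[self.keep]
        norms = np.linalg.norm(kept, axis=0)
        norms[norms == 0] = 1.0
        return float(np.linalg.cond(kept / norms))


def scale_to_mean_100(ts: SubjectTimeSeries) -> SubjectTimeSeries:
    """Scale each node's series to a temporal mean of 100.

    Nodes with zero temporal mean cannot be scaled; they are set to all-zero
    and recorded in ``flags["zero_mean_nodes"]`` with a warning.
    """
    means = ts.data.mean(axis=1)
    zero = np.isclose(means, 0.0)
    out = np.empty_like(ts.data)
    safe = np.where(zero, 1.0, means)
    out[:] = ts.data * (100.0 / safe)[:, None]
    flags = dict(ts.flags)
    if zero.any():
        idx = np.flatnonzero(zero)
        warnings.warn(
            f"{idx.size} node(s) with zero temporal mean set to 0 for subject "
            f"{ts.subject_id}",
            RuntimeWarning,
            stacklevel=2,
        )
        out[zero] = 0.0
        flags["zero_mean_nodes"] = idx.tolist()
    return replace(ts, data=out, flags=flags)


def _legendre_trends(n_volumes: int, order: int) -> np.ndarray:
    """Orthogonal polynomial trend columns, orders 0..order, on [-1, 1]."""
    x = np.linspace(-1.0, 1.0, n_volumes)
    return np.polynomial.legendre.legvander(x, order)


def bandstop_regressors(
    n_volumes: int, tr_seconds: float, band_hz: tuple[float, float] = (0.01, 0.1)
) -> tuple[np.ndarray, list[str]]:
    """Sine/cosine pairs at every DFT frequency outside the retention band.

    Frequencies are k / (n_volumes * TR) for k = 1 .. n_volumes // 2; a pair
    (sin, cos) is produced for each k whose frequency falls below the low
    edge or above the high edge.  The Nyquist frequency (even n) contributes
    only the cosine term, its sine being identically zero on the grid.
    """
    low, high = band_hz
    t = np.arange(n_volumes)
    cols: list[np.ndarray] = []
    names: list[str] = []
    total = n_volumes * tr_seconds
    for k in range(1, n_volumes // 2 + 1):
        f = k / total
        if low <= f <= high:
            continue
        phase = 2.0 * np.pi * k * t / n_volumes
        cols.append(np.cos(phase))
        names.append(f"cos_f{k}")
        if not (n_volumes % 2 == 0 and k == n_volumes // 2):
            cols.append(np.sin(phase))
            names.append(f"sin_f{k}")
    if not cols:
        return np.empty((n_volumes, 0)), []
    return np.column_stack(cols), names


def build_nuisance_design(
    motion: MotionTrace | None,
    tissue: Mapping[str, np.ndarray] | None = None,
    censor: CensorMask | None = None,
    include_fef: bool = False,
    tr_seconds: float = 2.0,
    n_volumes: int | None = None,
    trend_order: int = 3,
    band_hz: tuple[float, float] = (0.01, 0.1),
) -> NuisanceDesign:
    """Assemble the single nuisance design.

    Columns: Legendre trends (orders 0..3), band-stop sine/cosine pairs
    retaining ``band_hz``, six demeaned motion parameters plus their backward
    differences, tissue means (white_matter, ventricle), and the FEF mean if
    ``include_fef``.  Raises if the design is rank deficient on the kept rows.
    """
    if n_volumes is None:
        if motion is not None:
            n_volumes = motion.n_volumes
        elif censor is not None:
            n_volumes = censor.n_volumes
        else:
            raise ValueError("n_volumes required when no motion/censor given")

    cols = [_legendre_trends(n_volumes, trend_order)]
    names = [f"trend_{k}" for k in range(trend_order + 1)]

    bs, bs_names = bandstop_regressors(n_volumes, tr_seconds, band_hz)
    cols.append(bs)
    names += bs_names

    if motion is not None:
        if motion.n_volumes != n_volumes:
            raise ValueError("motion trace length mismatch")
        mp = np.hstack([motion.translations, motion.rotations])
        mp = mp - mp.mean(axis=0)
        dmp = np.zeros_like(mp)
        dmp[1:] = np.diff(mp, axis=0)  # backward differences, first element 0
        cols += [mp, dmp]
        base = ["tx", "ty", "tz", "rx", "ry", "rz"]
        names += [f"motion_{b}" for b in base] + [f"dmotion_{b}" for b in base]

    tissue = dict(tissue or {})
    if include_fef and "fef" not in tissue:
        raise ValueError("include_fef=True but no 'fef' signal supplied")
    for key in sorted(tissue):
        if key == "fef" and not include_fef:
            continue
        sig = np.asarray(tissue[key], dtype=float)
        if sig.shape != (n_volumes,):
            raise ValueError(f"tissue signal {key!r} has wrong length")
        cols.append((sig - sig.mean())[:, None])
        names.append(key)

    matrix = np.hstack([c if c.ndim == 2 else c[:, None] for c in cols])
    design = NuisanceDesign(matrix=matrix, names=names, censor=censor)

    kept = matrix[design.keep]
    if kept.shape[0] <= matrix.shape[1]:
        raise ValueError(
            f"design not estimable: {matrix.shape[1]} columns but only "
            f"{kept.shape[0]} uncensored volumes"
        )
    rank = np.linalg.matrix_rank(kept)
    if rank < matrix.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = []
        for j in range(matrix.shape[1]):
            sub = np.delete(kept, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(names[j])
        raise ValueError(
            f"design rank deficient after censoring (rank {rank} < "
            f"{matrix.shape[1]}); dependent columns include: {bad}"
        )
    return design


def regress_nuisance(
    ts: SubjectTimeSeries, design: NuisanceDesign
) -> SubjectTimeSeries:
    """Per-node OLS residuals of the time series against the nuisance design.

    The fit uses uncensored volumes only (row omission, not zero-weighting);
    censored positions are returned as NaN and flagged via ``keep``.
    Residuals are orthogonal to every design column over the kept volumes.
    """
    if design.n_volumes != ts.n_volumes:
        raise ValueError("design/time-series volume mismatch")
    keep = design.keep
    X = design.matrix[keep]
    Y = ts.data[:, keep].T  # (kept volumes, nodes)
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("design rank deficient on uncensored volumes")
    resid = Y - X @ beta
    out = np.full_like(ts.data, np.nan)
    out[:, keep] = resid.T
    flags = dict(ts.flags)
    flags["n_censored"] = int((~keep).sum())
    return replace(ts, data=out, keep=keep.copy(), flags=flags)


def read_timeseries_tsv(path: str | Path, **meta) -> SubjectTimeSeries:
    """Read a delimited node x time matrix (one node per row)."""
    data = np.loadtxt(Path(path), ndmin=2)
    return SubjectTimeSeries(data=data, subject_id=meta.pop("subject_id", Path(path).stem), **meta)


def write_timeseries_tsv(ts: SubjectTimeSeries, path: str | Path) -> None:
    """Write the node x time matrix; a sidecar ``<path>.censored`` file lists
    censored volume indices when a keep mask is present."""
    np.savetxt(Path(path), ts.data, fmt="%.8g", delimiter="\t")
    if ts.keep is not None:
        censored = np.flatnonzero(~ts.keep)
        Path(str(path) + ".censored").write_text(
            "\n".join(str(i) for i in censored) + ("\n" if censored.size else "")
        )
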