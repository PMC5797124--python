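"""Pairwise inter-subject correlation (inter-SC) matrices.

For every mesh node, the Pearson correlation between each pair of subjects'
time series is computed over the volumes uncensored in *both* subjects
(pairwise-complete), Fisher z-transformed (atanh), and stored in a
node x N x N array with the diagonal excluded.  The child-to-adult average
("neural maturity") and a traditional per-child regression on age are also
provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import SubjectTimeSeries

__all__ = [
    "CohortISCMatrix",
    "pairwise_isc",
    "fisher_z",
    "inverse_fisher",
    "extract_block",
    "neural_maturity",
    "traditional_age_analysis",
]

CLIP_BOUND = 1.0 - 1e-12


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z-transform z = atanh(r); |r| >= 1 - 1e-12 is clipped first
    (the mixed model requires finite responses)."""
    r = np.clip(np.asarray(r, dtype=float), -CLIP_BOUND, CLIP_BOUND)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher(z: np.ndarray | float) -> np.ndarray | float:
    """Inverse transform r = tanh(z)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


@dataclass
class CohortISCMatrix:
    """Per-node N x N Fisher-z pairwise inter-SC structure.

    ``z[v, i, j]`` is symmetric in (i, j) with NaN diagonal; ``flagged`` marks
    pairs with fewer mutually uncensored volumes than the floor or clipped
    |r| = 1 entries — flagged pairs propagate downstream as missing, never as
    zeros.
    """

    z: np.ndarray  # (n_nodes, N, N), diagonal NaN
    subjects: pd.DataFrame  # columns: subject_id, group, age_months
    pair_counts: np.ndarray  # (N, N) int
    flagged: np.ndarray  # (N, N) bool
    min_pair_volumes: int

    def __post_init__(self) -> None:
        n = self.n_subjects
        if self.z.shape[1:] != (n, n):
            raise ValueError("z must be (n_nodes, N, N)")
        self.validate()

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]

    def validate(self) -> None:
        """Symmetry and diagonal exclusion, asserted on every build."""
        if not np.allclose(self.z, np.transpose(self.z, (0, 2, 1)), equal_nan=True):
            raise ValueError("ISC matrices must be symmetric in (i, j)")
        diag = self.z[:, np.arange(self.n_subjects), np.arange(self.n_subjects)]
        if not np.isnan(diag).all():
            raise ValueError("ISC diagonal must be excluded (NaN)")

    def group_indices(self, selector: str | Sequence[str]) -> np.ndarray:
        if isinstance(selector, str):
            selector = [selector]
        mask = self.subjects["group"].isin(list(selector)).to_numpy()
        return np.flatnonzero(mask)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format export: node, subject_i, subject_j, z, pair_count
        (each unordered pair once)."""
        n = self.n_subjects
        iu, ju = np.triu_indices(n, k=1)
        ids = self.subjects["subject_id"].to_numpy()
        frames = []
        for v in range(self.n_nodes):
            frames.append(
                pd.DataFrame(
                    {
                        "node": v,
                        "subject_i": ids[iu],
                        "subject_j": ids[ju],
                        "z": self.z[v, iu, ju],
                        "pair_count": self.pair_counts[iu, ju],
                        "flagged": self.flagged[iu, ju],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(Path(path), index=False)


def pairwise_isc(
    residuals: Sequence[SubjectTimeSeries], min_pair_volumes: int = 100
) -> CohortISCMatrix:
    """Build the per-node pairwise inter-SC matrix for a cohort.

    Pearson r is computed per node over volumes kept in both subjects of the
    pair, then Fisher z-transformed.  Pairs with fewer than
    ``min_pair_volumes`` usable volumes, or with degenerate (zero-variance or
    |r| = 1) series, are flagged.
    """
    n = len(residuals)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    n_nodes = residuals[0].n_nodes
    n_vol = residuals[0].n_volumes
    for ts in residuals:
        if ts.n_nodes != n_nodes or ts.n_volumes != n_vol:
            raise ValueError("all subjects must share node and volume counts")

    keeps = np.stack(
        [
            ts.keep if ts.keep is not None else np.ones(n_vol, dtype=bool)
            for ts in residuals
        ]
    )
    data = np.stack([ts.data for ts in residuals])  # (N, nodes, T)

    z = np.full((n_nodes, n, n), np.nan)
    counts = np.zeros((n, n), dtype=int)
    flagged = np.zeros((n, n), dtype=bool)

    for i in range(n):
        for j in range(i + 1, n):
            both = keeps[i] & keeps[j]
            m = int(both.sum())
            counts[i, j] = counts[j, i] = m
            if m < max(min_pair_volumes, 3):
                flagged[i, j] = flagged[j, i] = True
                continue
            x = data[i][:, both]
            y = data[j][:, both]
            x = x - x.mean(axis=1, keepdims=True)
            y = y - y.mean(axis=1, keepdims=True)
            sx = np.einsum("vt,vt->v", x, x)
            sy = np.einsum("vt,vt->v", y, y)
            sxy = np.einsum("vt,vt->v", x, y)
            denom = np.sqrt(sx * sy)
            bad = denom == 0
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(bad, np.nan, sxy / np.where(bad, 1.0, denom))
            clipped = np.abs(r) >= CLIP_BOUND
            if bad.any() or clipped.any():
                flagged[i, j] = flagged[j, i] = True
            zv = fisher_z(np.where(np.isnan(r), 0.0, r))
            zv = np.where(np.isnan(r), np.nan, zv)
            z[:, i, j] = z[:, j, i] = zv

    return CohortISCMatrix(
        z=z,
        subjects=pd.DataFrame(
            {
                "subject_id": [ts.subject_id for ts in residuals],
                "group": [ts.group for ts in residuals],
                "age_months": [ts.age_months for ts in residuals],
            }
        ),
        pair_counts=counts,
        flagged=flagged,
        min_pair_volumes=min_pair_volumes,
    )


def extract_block(
    m: CohortISCMatrix,
    rows: str | Sequence[str],
    cols: str | Sequence[str],
    doubled: bool = False,
) -> pd.DataFrame:
    """Subject-pair table for a block of the inter-SC matrix.

    Within-group blocks (identical selectors) list each unordered pair once,
    or both (i, j) and (j, i) orderings when ``doubled`` — the both-triangles
    listing used by the crossed random-effects model.  Between-group blocks
    list each (row, col) pair once; ``doubled`` is meaningless there.
    Columns: i, j (subject indices), subject/group/age metadata.
    """
    ri = m.group_indices(rows)
    ci = m.group_indices(cols)
    if ri.size == 0 or ci.size == 0:
        raise ValueError("empty group selector")
    same = np.array_equal(ri, ci)
    if not same and np.intersect1d(ri, ci).size:
        raise ValueError("selectors must be disjoint or identical")
    if same:
        iu, ju = np.triu_indices(ri.size, k=1)
        ii, jj = ri[iu], ri[ju]
        if doubled:
            ii, jj = np.concatenate([ii, jj]), np.concatenate([jj, ii])
    else:
        ii = np.repeat(ri, ci.size)
        jj = np.tile(ci, ri.size)
    meta = m.subjects
    return pd.DataFrame(
        {
            "i": ii,
            "j": jj,
            "subject_i": meta["subject_id"].to_numpy()[ii],
            "subject_j": meta["subject_id"].to_numpy()[jj],
            "group_i": meta["group"].to_numpy()[ii],
            "group_j": meta["group"].to_numpy()[jj],
            "age_i": meta["age_months"].to_numpy()[ii],
            "age_j": meta["age_months"].to_numpy()[jj],
        }
    )


def neural_maturity(
    m: CohortISCMatrix,
    child: int | str,
    adult_group: str = "adult",
) -> np.ndarray:
    """Per-node average Fisher z between one child and every adult.

    This is the "neural maturity" index: how adult-like the child's
    stimulus-evoked response is.  Flagged child-adult pairs are dropped from
    the average; if all pairs are flagged the node is NaN.
    """
    if isinstance(child, str):
        matches = np.flatnonzero(
            (m.subjects["subject_id"] == child).to_numpy()
        )
        if matches.size != 1:
            raise KeyError(f"unknown subject {child!r}")
        child = int(matches[0])
    adults = m.group_indices(adult_group)
    if adults.size == 0:
        raise ValueError("no adults present")
    adults = adults[adults != child]
    ok = ~m.flagged[child, adults]
    if not ok.any():
        return np.full(m.n_nodes, np.nan)
    return m.z[:, child, adults[ok]].mean(axis=1)


def traditional_age_analysis(
    m: CohortISCMatrix,
    child_groups: Sequence[str] = ("child4", "child6"),
    adult_group: str = "adult",
) -> pd.DataFrame:
    """Supplementary-style analysis: per node, OLS of each child's average
    child-to-adult z on age in months (one point per child).

    Returns a per-node frame with slope, intercept, r, t, p, n_children.
    """
    children = m.group_indices(child_groups)
    if children.size < 3:
        raise ValueError("need at least 3 children for the regression")
    ages = m.subjects["age_months"].to_numpy()[children]
    maturity = np.stack([neural_maturity(m, int(c), adult_group) for c in children])
    rows = []
    for v in range(m.n_nodes):
        y = maturity[:, v]
        ok = ~np.isnan(y)
        if ok.sum() < 3 or np.ptp(ages[ok]) == 0:
            rows.append(
                {"node": v, "slope": np.nan, "intercept": np.nan, "r": np.nan,
                 "t": np.nan, "p": np.nan, "n_children": int(ok.sum())}
            )
            continue
        res = stats.linregress(ages[ok], y[ok])
        n_ok = int(ok.sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            t = res.slope / res.stderr if res.stderr > 0 else np.nan
        rows.append(
            {
                "node": v,
                "slope": res.slope,
                "intercept": res.intercept,
                "r": res.rvalue,
                "t": t,
                "p": res.pvalue,
                "n_children": n_ok,
            }
        )
    return pd.DataFrame(rows)
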