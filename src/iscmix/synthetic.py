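"""Synthetic naturalistic-viewing cohorts with known inter-SC structure.

Each subject's node x time series is built as

    y_iv(t) = c_iv * s_v(t) + sqrt(1 - c_iv^2) * eps_iv(t)

where s_v is a shared, unit-variance stimulus-locked signal (white noise
convolved with a Gaussian of ~3 TR FWHM, mimicking hemodynamic smoothness),
eps_iv is unit-variance subject noise (a mixture of an idiosyncratic smooth
signal and AR(1) scanner noise), and the coupling c_iv is set by group and
child age.  The expected Pearson correlation between subjects i and j at
node v is then the closed form c_iv * c_jv, which serves as the oracle for
every downstream recovery test.

Defaults emulate the reference study's design: groups of 23 / 23 / 21
(4-year-olds, 6-year-olds, adults), 176 retained volumes at TR 2 s, child
ages clustered in two narrow bands near 53 and 79 months, adult coupling
elevated (0.6 vs 0.4) in a subset of "effect" nodes, and a small positive
age slope of coupling for children in those nodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mesh import SurfaceMesh, planar_grid_mesh
from .motion import MotionTrace
from .preprocess import SubjectTimeSeries

__all__ = [
    "SyntheticCohortConfig",
    "SyntheticCohort",
    "CohortTruth",
    "simulate_cohort",
    "expected_isc",
    "write_cohort",
]

_GAUSS_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: child age bands (mean, sd, months) matching the study's 4.44 +/- 0.29 yr
#: and 6.55 +/- 0.30 yr groups
AGE_BANDS = {"child4": (53.3, 3.5), "child6": (78.6, 3.6)}
ADULT_AGE = (259.2, 35.3)


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Generating parameters of a synthetic cohort.

    ``coupling`` gives each group's shared-signal coupling inside
    ``effect_nodes``; outside them every group couples at
    ``baseline_coupling`` (so group differences and the child age slope are
    confined to the effect nodes).  All couplings, including the age
    contribution, must stay in [0, 1).
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"child4": 23, "child6": 23, "adult": 21}
    )
    n_volumes: int = 176
    tr_seconds: float = 2.0
    mesh_spec: SurfaceMesh | tuple[int, int, float] = (8, 8, 3.0)
    coupling: Mapping[str, float] = field(
        default_factory=lambda: {"child4": 0.4, "child6": 0.4, "adult": 0.6}
    )
    baseline_coupling: float = 0.4
    effect_nodes: tuple[int, ...] | None = None  # default: first quarter
    age_slope: float = 0.002  # coupling units per month, children, effect nodes
    coupling_subject_sd: float = 0.04  # between-subject coupling spread
    age_range_months: tuple[float, float] = (48.0, 84.0)
    two_cluster_ages: bool = True
    noise_ar1: float = 0.3
    idiosyncratic_frac: float = 0.3
    motion_spike_rate: float = 0.05
    couple_spikes_to_signal: bool = False
    signal_fwhm_trs: float = 3.0
    raw_mean: float = 1000.0
    raw_amplitude: float = 10.0
    seed: int = 0

    @property
    def mesh(self) -> SurfaceMesh:
        if isinstance(self.mesh_spec, SurfaceMesh):
            return self.mesh_spec
        nx, ny, spacing = self.mesh_spec
        return planar_grid_mesh(int(nx), int(ny), float(spacing))

    @property
    def n_nodes(self) -> int:
        return self.mesh.n_nodes

    def resolved_effect_nodes(self) -> np.ndarray:
        if self.effect_nodes is not None:
            return np.asarray(self.effect_nodes, dtype=int)
        return np.arange(max(1, self.n_nodes // 4))

    def validate(self) -> None:
        lo, hi = self.age_range_months
        half_span = (hi - lo) / 2.0
        for g, c in self.coupling.items():
            worst = abs(c)
            if g != "adult":
                worst = max(worst, c + abs(self.age_slope) * half_span,
                            -(c - abs(self.age_slope) * half_span))
            if not 0.0 <= c < 1.0 or worst >= 1.0:
                raise ValueError(
                    f"coupling for group {g!r} (with age contribution) must "
                    "remain in [0, 1)"
                )
        if not 0.0 <= self.baseline_coupling < 1.0:
            raise ValueError("baseline_coupling must be in [0, 1)")
        if not 0.0 <= self.noise_ar1 < 1.0:
            raise ValueError("noise_ar1 must be in [0, 1)")
        if not 0.0 <= self.idiosyncratic_frac <= 1.0:
            raise ValueError("idiosyncratic_frac must be in [0, 1]")
        # enough volumes for the non-frequency part of the nuisance design
        # (trends + 12 motion + 3 tissue signals)
        if self.n_volumes < 2 * 19:
            raise ValueError("n_volumes too small for the default design")
        if self.n_volumes < 2:
            raise ValueError("n_volumes must be >= 2")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["n_per_group"] = dict(self.n_per_group)
        d["coupling"] = dict(self.coupling)
        if isinstance(self.mesh_spec, SurfaceMesh):
            d["mesh_spec"] = {"n_nodes": self.mesh_spec.n_nodes}
        Path(path).write_text(json.dumps(d, indent=2, default=list) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticCohortConfig":
        d = json.loads(Path(path).read_text())
        if "mesh_spec" in d and isinstance(d["mesh_spec"], list):
            d["mesh_spec"] = tuple(d["mesh_spec"])
        for key in ("effect_nodes", "age_range_months"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class CohortTruth:
    """Generating parameters sufficient to predict every pairwise ISC."""

    coupling: np.ndarray  # (N, n_nodes)
    subject_ids: tuple[str, ...]
    groups: tuple[str, ...]
    ages_months: np.ndarray
    effect_nodes: np.ndarray
    age_slope: float
    seed: int

    def index_of(self, subject: int | str) -> int:
        if isinstance(subject, str):
            try:
                return self.subject_ids.index(subject)
            except ValueError:
                raise KeyError(f"unknown subject {subject!r}") from None
        if not 0 <= subject < len(self.subject_ids):
            raise KeyError(f"subject index {subject} out of range")
        return subject


@dataclass
class SyntheticCohort:
    subjects: list[SubjectTimeSeries]
    motion: list[MotionTrace]
    nuisance_signals: list[dict[str, np.ndarray]]
    truth: CohortTruth
    mesh: SurfaceMesh
    config: SyntheticCohortConfig


def expected_isc(truth: CohortTruth, i: int | str, j: int | str, v: int) -> float:
    """Closed-form expected Pearson correlation c_iv * c_jv (test oracle)."""
    ii, jj = truth.index_of(i), truth.index_of(j)
    if not 0 <= v < truth.coupling.shape[1]:
        raise KeyError(f"node {v} out of range")
    return float(truth.coupling[ii, v] * truth.coupling[jj, v])


def _standardize(x: np.ndarray, axis: int = -1) -> np.ndarray:
    m = x.mean(axis=axis, keepdims=True)
    s = x.std(axis=axis, keepdims=True)
    s = np.where(s == 0, 1.0, s)
    return (x - m) / s


def _smooth_noise(rng: np.random.Generator, shape: tuple, fwhm_trs: float) -> np.ndarray:
    """White Gaussian noise convolved with a temporal Gaussian, standardized."""
    sigma = max(fwhm_trs * _GAUSS_FWHM_TO_SIGMA, 1e-6)
    half = int(np.ceil(4 * sigma))
    kernel = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
    kernel /= kernel.sum()
    n_t = shape[-1]
    pad = shape[:-1] + (n_t + 2 * half,)
    x = rng.standard_normal(pad)
    sm = np.apply_along_axis(np.convolve, -1, x, kernel, mode="same")
    return _standardize(sm[..., half : half + n_t])


def _ar1_noise(rng: np.random.Generator, shape: tuple, rho: float) -> np.ndarray:
    e = rng.standard_normal(shape)
    if rho > 0:
        x = np.empty_like(e)
        x[..., 0] = e[..., 0]
        c = np.sqrt(1.0 - rho**2)
        for t in range(1, shape[-1]):
            x[..., t] = rho * x[..., t - 1] + c * e[..., t]
    else:
        x = e
    return _standardize(x)


def _simulate_motion(
    rng: np.random.Generator, n_volumes: int, spike_rate: float
) -> tuple[MotionTrace, np.ndarray]:
    """Slow random-walk motion parameters plus transient high-FD spikes.

    Returns the trace and the spike volume indices.  Each transient spike
    raises FD above 0.5 mm at the spike volume and the one after, so the
    number of spikes is spike_rate * n_volumes / 2.
    """
    trans = np.cumsum(rng.normal(0.0, 0.03, size=(n_volumes, 3)), axis=0)
    rot = np.cumsum(rng.normal(0.0, 0.0003, size=(n_volumes, 3)), axis=0)
    n_spikes = int(round(spike_rate * n_volumes / 2.0))
    spikes = np.array([], dtype=int)
    if n_spikes > 0:
        candidates = np.arange(1, n_volumes - 1)
        spikes = np.sort(rng.choice(candidates, size=min(n_spikes, candidates.size),
                                    replace=False))
        amp = rng.uniform(0.6, 1.2, size=spikes.size)
        axis = rng.integers(0, 3, size=spikes.size)
        for s, a, ax in zip(spikes, amp, axis):
            trans[s, ax] += a
    return MotionTrace(translations=trans, rotations=rot), spikes


def simulate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate a full cohort: time series, motion, nuisance signals, truth.

    Deterministic given ``config.seed``.  Raw series are emitted at mean
    ``raw_mean`` with fluctuation amplitude ``raw_amplitude`` so the
    mean-100 scaling step has real work to do; Pearson correlations are
    unaffected by that affine map.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    mesh = config.mesh
    n_nodes, n_t = mesh.n_nodes, config.n_volumes
    effect = config.resolved_effect_nodes()
    if effect.size and (effect.min() < 0 or effect.max() >= n_nodes):
        raise ValueError("effect_nodes out of mesh range")

    groups: list[str] = []
    ids: list[str] = []
    ages: list[float] = []
    sexes: list[str] = []
    lo, hi = config.age_range_months
    for g, count in config.n_per_group.items():
        for k in range(count):
            groups.append(g)
            ids.append(f"sub-{g}-{k:02d}")
            sexes.append("F" if rng.random() < 0.5 else "M")
            if g == "adult":
                ages.append(float(rng.normal(*ADULT_AGE)))
            elif config.two_cluster_ages and g in AGE_BANDS:
                mu, sd = AGE_BANDS[g]
                ages.append(float(np.clip(rng.normal(mu, sd), lo, hi)))
            else:
                ages.append(float(rng.uniform(lo, hi)))
    n_sub = len(ids)
    ages_arr = np.array(ages)
    mid_age = (lo + hi) / 2.0

    # per-subject, per-node coupling; subject-level spread gives the cohort
    # genuine crossed random effects (the realized values are recorded in
    # the truth table, so the c_i * c_j oracle stays exact)
    coupling = np.empty((n_sub, n_nodes))
    for s, g in enumerate(groups):
        c = np.full(n_nodes, config.baseline_coupling)
        c[effect] = config.coupling[g]
        if g != "adult":
            c[effect] += config.age_slope * (ages_arr[s] - mid_age)
        if c.min() < 0 or c.max() >= 1:
            raise ValueError("coupling out of [0, 1) after age adjustment")
        if config.coupling_subject_sd > 0:
            c = np.clip(
                c + rng.normal(0.0, config.coupling_subject_sd, n_nodes),
                0.0, 0.97,
            )
        coupling[s] = c

    shared = _smooth_noise(rng, (n_nodes, n_t), config.signal_fwhm_trs)

    subjects: list[SubjectTimeSeries] = []
    motions: list[MotionTrace] = []
    nuisance: list[dict[str, np.ndarray]] = []
    for s in range(n_sub):
        idio = _smooth_noise(rng, (n_nodes, n_t), config.signal_fwhm_trs)
        ar = _ar1_noise(rng, (n_nodes, n_t), config.noise_ar1)
        f = config.idiosyncratic_frac
        eps = np.sqrt(f) * idio + np.sqrt(1.0 - f) * ar
        # orthogonalize noise against the shared signal per node so the
        # composite has exactly unit variance and the pairwise correlation
        # carries no shared-by-chance component
        proj = np.einsum("vt,vt->v", eps, shared) / n_t
        eps = eps - proj[:, None] * shared
        eps = _standardize(eps)
        c = coupling[s][:, None]
        core = c * shared + np.sqrt(1.0 - c**2) * eps

        trace, spikes = _simulate_motion(rng, n_t, config.motion_spike_rate)
        if config.couple_spikes_to_signal and spikes.size:
            core[:, spikes] += rng.normal(8.0, 1.0, size=spikes.size)

        raw = config.raw_mean + config.raw_amplitude * core
        subjects.append(
            SubjectTimeSeries(
                data=raw, subject_id=ids[s], group=groups[s],
                age_months=ages_arr[s], sex=sexes[s],
            )
        )
        motions.append(trace)
        nuisance.append(
            {
                "white_matter": _smooth_noise(rng, (n_t,), config.signal_fwhm_trs),
                "ventricle": _smooth_noise(rng, (n_t,), config.signal_fwhm_trs),
                "fef": _smooth_noise(rng, (n_t,), config.signal_fwhm_trs),
            }
        )

    truth = CohortTruth(
        coupling=coupling,
        subject_ids=tuple(ids),
        groups=tuple(groups),
        ages_months=ages_arr,
        effect_nodes=effect,
        age_slope=config.age_slope,
        seed=config.seed,
    )
    return SyntheticCohort(
        subjects=subjects, motion=motions, nuisance_signals=nuisance,
        truth=truth, mesh=mesh, config=config,
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write the cohort as plain-text files.

    Per subject: a node x time TSV, an AFNI-style 6-column motion .1D file
    (rotations first, degrees) and a nuisance-signal TSV; plus a cohort-level
    participants.csv and the generating config (seed included) as JSON.
    """
    from .motion import write_motion_1d
    from .preprocess import write_timeseries_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts, mt, nui in zip(cohort.subjects, cohort.motion, cohort.nuisance_signals):
        write_timeseries_tsv(ts, out / f"{ts.subject_id}_bold.tsv")
        deg = MotionTrace(
            translations=mt.translations,
            rotations=np.rad2deg(mt.rotations),
            rotations_in_degrees=True,
        )
        write_motion_1d(deg, out / f"{ts.subject_id}_motion.1D")
        pd.DataFrame(nui).to_csv(
            out / f"{ts.subject_id}_nuisance.tsv", sep="\t", index=False
        )
        rows.append(
            {
                "subject_id": ts.subject_id, "group": ts.group,
                "age_months": ts.age_months, "sex": ts.sex,
            }
        )
    pd.DataFrame(rows).to_csv(out / "participants.csv", index=False)
    cohort.config.to_json(out / "config.json")
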