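"""Synthetic three-group cohorts of regional time series.

Generates patient / sibling / control cohorts whose group correlation
structure embeds known edge effects, so every downstream stage of the
pipeline has a recoverable ground truth:

* state edges       -- perturbed in patients only
* trait edges       -- perturbed in patients AND siblings
* compensatory edges -- perturbed in siblings only

Subjects are sampled as lag-1 autoregressive Gaussian processes whose
stationary cross-sectional correlation equals the group matrix, plus an
equal-loading global component and smooth motion-like confounds that the
preprocessing stage can regress out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .connectivity import pair_to_edge
from .timeseries import RegionalTimeSeries, default_region_labels

__all__ = [
    "CLASS_ORDER",
    "PlantedEdgeSet",
    "CohortConfig",
    "GroundTruth",
    "SyntheticCohort",
    "n_volumes_for_session",
    "random_planted_edges",
    "make_group_covariance",
    "simulate_subject",
    "generate_cohort",
]

#: Fixed class ordering used throughout the pipeline.
CLASS_ORDER: tuple[str, str, str] = ("patient", "sibling", "control")

_SPD_EPS = 1e-6


def n_volumes_for_session(duration_seconds: float, tr_seconds: float) -> int:
    """Volumes acquired in a session: duration / TR (360 s at TR 2 s -> 180)."""
    if duration_seconds <= 0 or tr_seconds <= 0:
        raise ValueError("duration and TR must be positive")
    n = duration_seconds / tr_seconds
    if abs(n - round(n)) > 1e-9:
        raise ValueError("session duration is not a whole number of volumes")
    return int(round(n))


@dataclass(frozen=True)
class PlantedEdgeSet:
    """A list of region pairs (i < j, 0-based) sharing one effect size."""

    edges: tuple[tuple[int, int], ...] = ()
    delta_r: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "edges", tuple((int(i), int(j)) for i, j in self.edges)
        )


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort.

    ``n_per_group`` follows the class order (patient, sibling, control);
    the default 24/25/22 split mirrors the retained sample the pipeline
    was designed around. ``n_volumes`` counts *retained* volumes.
    """

    n_per_group: tuple[int, int, int] = (24, 25, 22)
    n_regions: int = 116
    n_volumes: int = 175
    tr_seconds: float = 2.0
    base_correlation: float = 0.1
    state: PlantedEdgeSet = field(default_factory=PlantedEdgeSet)
    trait: PlantedEdgeSet = field(default_factory=PlantedEdgeSet)
    compensatory: PlantedEdgeSet = field(default_factory=PlantedEdgeSet)
    ar_coefficient: float = 0.3
    global_signal_sd: float = 0.5
    n_motion_regressors: int = 6
    motion_sd: float = 0.3
    seed: int = 0

    @property
    def planted(self) -> Mapping[str, PlantedEdgeSet]:
        return {
            "state": self.state,
            "trait": self.trait,
            "compensatory": self.compensatory,
        }

    def validate(self) -> None:
        if any(n < 1 for n in self.n_per_group) or len(self.n_per_group) != 3:
            raise ValueError("n_per_group must be three positive counts")
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if self.n_volumes < 2:
            raise ValueError("need at least 2 volumes")
        if not 0 <= abs(self.ar_coefficient) < 1:
            raise ValueError("|ar_coefficient| must be < 1")
        if abs(self.base_correlation) >= 1:
            raise ValueError("|base_correlation| must be < 1")
        if self.global_signal_sd < 0 or self.motion_sd < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if self.n_motion_regressors < 0:
            raise ValueError("n_motion_regressors must be non-negative")
        seen: set[tuple[int, int]] = set()
        for name, spec in self.planted.items():
            for i, j in spec.edges:
                if not (0 <= i < j < self.n_regions):
                    raise ValueError(
                        f"{name} edge ({i}, {j}) is not a valid pair i<j "
                        f"for {self.n_regions} regions"
                    )
                if (i, j) in seen:
                    raise ValueError(f"planted edge ({i}, {j}) appears twice")
                seen.add((i, j))
            if spec.edges and abs(self.base_correlation + spec.delta_r) >= 1:
                raise ValueError(
                    f"|base_correlation + delta_r| >= 1 for {name} edges"
                )


@dataclass
class GroundTruth:
    """Planted edge sets (canonical edge indices) and group correlations."""

    state_edges: frozenset[int]
    trait_edges: frozenset[int]
    compensatory_edges: frozenset[int]
    group_covariances: dict[str, np.ndarray]

    def edges_for(self, signature: str) -> frozenset[int]:
        return {
            "state": self.state_edges,
            "trait": self.trait_edges,
            "compensatory": self.compensatory_edges,
        }[signature]


@dataclass
class SyntheticCohort:
    """Generated subjects, per-subject motion tables, labels and truth."""

    subjects: list[RegionalTimeSeries]
    motion: list[np.ndarray]  # each volumes x q
    labels: np.ndarray  # class name per subject
    ground_truth: GroundTruth
    config: CohortConfig

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def random_planted_edges(
    n_regions: int,
    n_state: int,
    n_trait: int,
    n_compensatory: int,
    rng: np.random.Generator,
) -> tuple[tuple[tuple[int, int], ...], ...]:
    """Draw three disjoint random edge lists over ``n_regions`` regions."""
    total = n_state + n_trait + n_compensatory
    rows, cols = np.triu_indices(n_regions, k=1)
    if total > rows.size:
        raise ValueError("more planted edges than available region pairs")
    pick = rng.choice(rows.size, size=total, replace=False)
    pairs = [(int(rows[k]), int(cols[k])) for k in pick]
    return (
        tuple(pairs[:n_state]),
        tuple(pairs[n_state : n_state + n_trait]),
        tuple(pairs[n_state + n_trait :]),
    )


def _apply_edges(
    mat: np.ndarray, spec: PlantedEdgeSet
) -> np.ndarray:
    for i, j in spec.edges:
        mat[i, j] += spec.delta_r
        mat[j, i] = mat[i, j]
    return mat


def make_group_covariance(
    config: CohortConfig, group: str
) -> tuple[np.ndarray, dict]:
    """Target correlation matrix for one class.

    Control carries only the shared background network; patient adds the
    state and trait effects; sibling adds the trait and compensatory
    effects. A non-positive-definite result is repaired by eigenvalue
    flooring followed by diagonal re-normalization, and the repair is
    recorded in the returned metadata.
    """
    config.validate()
    if group not in CLASS_ORDER:
        raise ValueError(f"unknown group {group!r}")
    r = config.n_regions
    mat = np.full((r, r), config.base_correlation, dtype=float)
    np.fill_diagonal(mat, 1.0)
    if group == "patient":
        _apply_edges(mat, config.state)
        _apply_edges(mat, config.trait)
    elif group == "sibling":
        _apply_edges(mat, config.trait)
        _apply_edges(mat, config.compensatory)
    off = mat[~np.eye(r, dtype=bool)]
    if np.any(np.abs(off) >= 1.0):
        raise ValueError("planted effect drives |correlation| >= 1")

    meta = {"group": group, "repaired": False}
    eigval = np.linalg.eigvalsh(mat)
    meta["min_eigenvalue_before"] = float(eigval[0])
    if eigval[0] <= _SPD_EPS:
        w, v = np.linalg.eigh(mat)
        w = np.maximum(w, _SPD_EPS)
        mat = (v * w) @ v.T
        d = np.sqrt(np.diag(mat))
        mat = mat / np.outer(d, d)
        mat = (mat + mat.T) / 2.0
        np.fill_diagonal(mat, 1.0)
        meta["repaired"] = True
    meta["min_eigenvalue"] = float(np.linalg.eigvalsh(mat)[0])
    return mat, meta


def _ar1_series(
    n_series: int, n_volumes: int, phi: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance AR(1) rows, initialized from the stationary law."""
    x = np.empty((n_series, n_volumes))
    x[:, 0] = rng.standard_normal(n_series)
    scale = np.sqrt(1.0 - phi**2)
    eps = rng.standard_normal((n_series, n_volumes - 1)) * scale
    for t in range(1, n_volumes):
        x[:, t] = phi * x[:, t - 1] + eps[:, t - 1]
    return x


def simulate_subject(
    cov: np.ndarray,
    config: CohortConfig,
    rng: np.random.Generator,
    subject_id: str = "",
    region_labels: tuple[str, ...] = (),
) -> tuple[RegionalTimeSeries, np.ndarray]:
    """Sample one subject's regions x volumes matrix plus its motion table.

    The neural part is a lag-1 autoregressive Gaussian process whose
    stationary cross-sectional correlation equals ``cov``; an
    equal-loading global component (scaled by ``global_signal_sd``) and
    linear contamination by smooth motion-like regressors are added on
    top. The motion regressors are returned (volumes x q) so nuisance
    regression can remove them.
    """
    cov = np.asarray(cov, dtype=float)
    r, t = config.n_regions, config.n_volumes
    if cov.shape != (r, r):
        raise ValueError("covariance shape does not match config.n_regions")
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance matrix is not positive definite") from exc

    phi = config.ar_coefficient
    # innovations with cross-sectional correlation cov -> stationary corr cov
    neural = chol @ _ar1_series(r, t, phi, rng)

    data = neural
    if config.global_signal_sd > 0:
        g = _ar1_series(1, t, phi, rng)[0]
        data = data + config.global_signal_sd * g[None, :]

    q = config.n_motion_regressors
    motion = np.zeros((t, 0))
    if q > 0:
        # slow drifts: heavily autocorrelated, unit-variance regressors
        motion = _ar1_series(q, t, 0.95, rng).T
        if config.motion_sd > 0:
            loadings = rng.standard_normal((r, q)) * config.motion_sd
            data = data + loadings @ motion.T

    ts = RegionalTimeSeries(
        data=data,
        tr_seconds=config.tr_seconds,
        region_labels=region_labels or default_region_labels(r),
        subject_id=subject_id,
    )
    return ts, motion


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full three-group cohort with ground truth attached."""
    config.validate()
    covs = {g: make_group_covariance(config, g)[0] for g in CLASS_ORDER}
    labels_list: list[str] = []
    for group, n in zip(CLASS_ORDER, config.n_per_group):
        labels_list.extend([group] * n)

    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(len(labels_list))
    region_labels = default_region_labels(config.n_regions)

    subjects: list[RegionalTimeSeries] = []
    motion_tables: list[np.ndarray] = []
    for k, (group, ss) in enumerate(zip(labels_list, streams)):
        ts, motion = simulate_subject(
            covs[group],
            config,
            np.random.default_rng(ss),
            subject_id=f"sub-{k + 1:03d}",
            region_labels=region_labels,
        )
        subjects.append(ts)
        motion_tables.append(motion)

    def _indices(spec: PlantedEdgeSet) -> frozenset[int]:
        return frozenset(
            pair_to_edge(i, j, config.n_regions) for i, j in spec.edges
        )

    truth = GroundTruth(
        state_edges=_indices(config.state),
        trait_edges=_indices(config.trait),
        compensatory_edges=_indices(config.compensatory),
        group_covariances=covs,
    )
    return SyntheticCohort(
        subjects=subjects,
        motion=motion_tables,
        labels=np.array(labels_list),
        ground_truth=truth,
        config=config,
    )
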