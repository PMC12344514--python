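"""Synthetic cohorts with known network structure and heterogeneity.

Cohorts are generated from a block-structured group correlation matrix. A
heterogeneity knob eta in [0, 1] mixes each subject's true correlation matrix
between the shared group structure (eta = 0) and an independent random
correlation matrix (eta = 1). Outcomes follow a similarity-attenuated linear
model so that the downstream moderation analysis has a planted effect (or a
planted null) with known sign.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .connectivity import (
    EdgeVector,
    Parcellation,
    SubjectScan,
    enumerate_edges,
)

__all__ = [
    "OutcomeParams",
    "GroundTruth",
    "SyntheticCohort",
    "nearest_correlation",
    "random_correlation",
    "make_group_structure",
    "sample_subject_matrix",
    "sample_timeseries",
    "sample_outcomes",
    "make_fig1_fixture",
    "default_group_structure",
    "make_cohort",
    "true_edge_vector",
    "write_cohort",
]

EIG_FLOOR = 1e-8
MAX_REPAIR_CHANGE = 0.05


def nearest_correlation(mat: np.ndarray, floor: float = EIG_FLOOR) -> np.ndarray:
    """Project a symmetric matrix to a valid correlation matrix.

    Eigenvalues are clipped at ``floor`` and the diagonal is renormalized to
    one. Cheap and structure-preserving for mild PSD violations.
    """
    a = np.asarray(mat, dtype=float)
    a = (a + a.T) / 2.0
    w, v = np.linalg.eigh(a)
    if w[0] < floor:
        w = np.clip(w, floor, None)
        a = (v * w) @ v.T
    d = np.sqrt(np.diag(a))
    a = a / np.outer(d, d)
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return a


def random_correlation(
    n: int, rng: np.random.Generator, n_factors: int | None = None
) -> np.ndarray:
    """Random correlation matrix from normalized Gaussian factor loadings.

    With ``n_factors`` factors (default ``n``), row-normalizing a Gaussian
    loading matrix W gives a full-support, seedable correlation matrix
    W W^T with unit diagonal. Fewer factors widen the off-diagonal spread.
    """
    k = n if n_factors is None else int(n_factors)
    if k < 1:
        raise ValueError("n_factors must be >= 1")
    w = rng.standard_normal((n, k))
    norms = np.linalg.norm(w, axis=1, keepdims=True)
    # resample any degenerate all-zero row (probability zero in practice)
    while np.any(norms == 0):
        bad = np.flatnonzero(norms[:, 0] == 0)
        w[bad] = rng.standard_normal((bad.size, k))
        norms = np.linalg.norm(w, axis=1, keepdims=True)
    w = w / norms
    r = w @ w.T
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return r


def make_group_structure(
    network_sizes: Sequence[int],
    within_r: float | Sequence[float],
    between_r: float | np.ndarray = 0.0,
) -> np.ndarray:
    """Block correlation matrix: within_r inside blocks, between_r across.

    The raw block matrix is projected to the nearest correlation matrix by
    eigenvalue clipping. If the projection moves any element by more than
    0.05 the inputs are considered non-repairable and an error identifies the
    offending blocks.
    """
    sizes = [int(s) for s in network_sizes]
    if not sizes or any(s < 1 for s in sizes):
        raise ValueError("network_sizes must be positive integers")
    k = len(sizes)
    within = np.broadcast_to(np.asarray(within_r, dtype=float), (k,)).copy()
    if np.any(np.abs(within) >= 1.0):
        raise ValueError("|within_r| must be < 1")
    between = np.asarray(between_r, dtype=float)
    if between.ndim == 0:
        between = np.full((k, k), float(between))
    if between.shape != (k, k):
        raise ValueError(f"between_r must be scalar or {k}x{k}")
    if np.any(np.abs(between) >= 1.0):
        raise ValueError("|between_r| must be < 1")
    between = (between + between.T) / 2.0

    n = sum(sizes)
    raw = np.zeros((n, n))
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    for a in range(k):
        sa = slice(bounds[a], bounds[a + 1])
        raw[sa, sa] = within[a]
        for b in range(a + 1, k):
            sb = slice(bounds[b], bounds[b + 1])
            raw[sa, sb] = between[a, b]
            raw[sb, sa] = between[a, b]
    np.fill_diagonal(raw, 1.0)

    repaired = nearest_correlation(raw)
    delta = np.abs(repaired - raw)
    if delta.max() > MAX_REPAIR_CHANGE:
        i, j = np.unravel_index(np.argmax(delta), delta.shape)
        block_of = np.searchsorted(bounds, [i, j], side="right") - 1
        raise ValueError(
            "block structure is not repairable to a correlation matrix "
            f"(max change {delta.max():.3f} between blocks "
            f"{int(block_of[0])} and {int(block_of[1])})"
        )
    return repaired


def sample_subject_matrix(
    group_R: np.ndarray, eta: float, rng: np.random.Generator
) -> np.ndarray:
    """Subject-level correlation matrix at heterogeneity eta.

    Returns the nearest-correlation projection of
    ``(1 - eta) * group_R + eta * Q`` where Q is an independent random
    correlation matrix. ``eta = 0`` returns ``group_R`` unchanged.
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError(f"eta must be in [0, 1], got {eta}")
    group_R = np.asarray(group_R, dtype=float)
    if eta == 0.0:
        return group_R.copy()
    q = random_correlation(group_R.shape[0], rng)
    return nearest_correlation((1.0 - eta) * group_R + eta * q)


def _fd_trace(
    T: int,
    censor_fraction: float,
    rng: np.random.Generator,
    fd_threshold: float,
) -> np.ndarray:
    """Lognormal baseline motion trace with spikes above the censor threshold."""
    base = rng.lognormal(mean=np.log(0.4 * fd_threshold), sigma=0.35, size=T)
    fd = np.minimum(base, 0.95 * fd_threshold)
    n_spike = int(round(censor_fraction * T))
    if n_spike:
        idx = rng.choice(T, size=n_spike, replace=False)
        fd[idx] = fd_threshold * (1.05 + rng.lognormal(-1.0, 0.5, size=n_spike))
    return fd


def sample_timeseries(
    R_i: np.ndarray,
    T: int,
    censor_fraction: float,
    rng: np.random.Generator,
    tr: float = 0.8,
    fd_threshold: float = 0.10,
    mean_offset: float | np.ndarray = 100.0,
    roi_ids: Sequence[str] | None = None,
) -> SubjectScan:
    """Multivariate-normal time series with covariance ``R_i`` plus an offset.

    The positive per-ROI mean offset keeps tSnR finite and positive. The FD
    trace has approximately ``censor_fraction`` of frames above
    ``fd_threshold`` by construction.
    """
    R_i = np.asarray(R_i, dtype=float)
    n = R_i.shape[0]
    if not 0.0 <= censor_fraction < 1.0:
        raise ValueError("censor_fraction must be in [0, 1)")
    w, v = np.linalg.eigh((R_i + R_i.T) / 2.0)
    if w[0] < -1e-8:
        raise ValueError(f"R_i is not positive semidefinite (min eig {w[0]:.2e})")
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    series = rng.standard_normal((T, n)) @ factor.T
    series = series + np.broadcast_to(np.asarray(mean_offset, float), (n,))
    fd = _fd_trace(T, censor_fraction, rng, fd_threshold)
    return SubjectScan(
        series, fd, tr=tr, roi_ids=tuple(roi_ids) if roi_ids else None
    )


@dataclass(frozen=True)
class OutcomeParams:
    """Parameters of the similarity-attenuated outcome model.

    ``y_i = intercept + (base_coupling + attenuation * s_i) * (w . z_i) + eps``
    with ``eps ~ Normal(0, noise_sd^2)``. ``attenuation = 0`` encodes the null
    of no similarity moderation.
    """

    intercept: float
    weights: np.ndarray
    base_coupling: float = 1.0
    attenuation: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "weights", np.asarray(self.weights, dtype=float).ravel()
        )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def sample_outcomes(
    edge_features: np.ndarray,
    similarities: np.ndarray,
    params: OutcomeParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """One outcome per subject under the attenuated coupling model."""
    z = np.asarray(edge_features, dtype=float)
    s = np.asarray(similarities, dtype=float).ravel()
    if z.ndim != 2:
        raise ValueError("edge_features must be subjects x edges")
    if z.shape[0] != s.shape[0]:
        raise ValueError("similarities length must match subject count")
    if z.shape[1] != params.weights.shape[0]:
        raise ValueError(
            f"weight vector length {params.weights.shape[0]} does not match "
            f"{z.shape[1]} edge features"
        )
    signal = z @ params.weights
    coupling = params.base_coupling + params.attenuation * s
    noise = rng.normal(0.0, params.noise_sd, size=s.shape[0])
    return params.intercept + coupling * signal + noise


@dataclass
class GroundTruth:
    """Generative parameters behind a synthetic cohort."""

    group_correlation: np.ndarray
    heterogeneity: float
    subject_similarities: np.ndarray
    outcome_params: Mapping[str, OutcomeParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        r = np.asarray(self.group_correlation, dtype=float)
        if not np.allclose(r, r.T, atol=1e-10):
            raise ValueError("group correlation must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-10):
            raise ValueError("group correlation must have unit diagonal")
        if np.linalg.eigvalsh(r)[0] < -1e-8:
            raise ValueError("group correlation must be positive semidefinite")
        self.group_correlation = r
        if not 0.0 <= self.heterogeneity <= 1.0:
            raise ValueError("heterogeneity must be in [0, 1]")
        s = np.asarray(self.subject_similarities, dtype=float).ravel()
        if np.any((s < 0) | (s > 1)):
            raise ValueError("subject similarities must be in [0, 1]")
        self.subject_similarities = s


@dataclass
class SyntheticCohort:
    """A simulated multi-subject dataset with full ground truth."""

    scans: dict[str, SubjectScan]
    parcellation: Parcellation
    outcomes: pd.DataFrame
    truth: GroundTruth
    seed: int
    subject_matrices: dict[str, np.ndarray] = field(default_factory=dict)
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        n = self.parcellation.n_rois
        for sid, scan in self.scans.items():
            if scan.n_rois != n:
                raise ValueError(f"scan {sid} ROI count differs from parcellation")
        if len(self.outcomes) != len(self.scans):
            raise ValueError("outcomes must have one row per subject")

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(self.scans)


def default_group_structure(
    network_sizes: Sequence[int] = (10, 10, 10, 10),
) -> np.ndarray:
    """Default block structure: distinct within- and between-network levels."""
    k = len(network_sizes)
    within = np.linspace(0.65, 0.35, k)
    between = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            between[a, b] = between[b, a] = 0.05 * (a + b + 1)
    return make_group_structure(network_sizes, within, between)


def _toy_parcellation(network_sizes: Sequence[int]) -> Parcellation:
    roi_ids, networks = [], []
    i = 0
    for b, size in enumerate(network_sizes):
        for _ in range(size):
            i += 1
            roi_ids.append(f"roi{i:03d}")
            networks.append(f"net{b + 1}")
    flags = {f"net{b + 1}": True for b in range(len(network_sizes))}
    return Parcellation(roi_ids, networks, flags)


def true_edge_vector(R_i: np.ndarray, roi_ids: Sequence[str]) -> EdgeVector:
    """Noise-free Fisher-z edge vector of a subject's true correlation matrix."""
    r = np.asarray(R_i, dtype=float)
    iu = np.triu_indices(r.shape[0], k=1)
    vals = np.clip(r[iu], -(1 - 1e-12), 1 - 1e-12)
    return EdgeVector(enumerate_edges(roi_ids), np.arctanh(vals), scale="z")


def make_cohort(
    n_subjects: int = 60,
    network_sizes: Sequence[int] = (10, 10, 10, 10),
    heterogeneity: float | Sequence[float] = 0.2,
    T: int = 2000,
    censor_fraction: float = 0.1,
    tr: float = 0.8,
    seed: int = 0,
    group_R: np.ndarray | None = None,
    outcome_specs: Mapping[str, dict] | None = None,
    n_signal_edges: int = 10,
) -> SyntheticCohort:
    """Simulate a full cohort: scans, motion traces, outcomes, ground truth.

    ``heterogeneity`` may be a scalar (shared eta) or one eta per subject;
    each subject's generative similarity is ``s_i = 1 - eta_i``. Outcomes are
    drawn from the subjects' noise-free edge features via
    :func:`sample_outcomes`; by default two measures are produced, one with a
    planted moderation effect (``behavior_mod``) and one null
    (``behavior_null``).
    """
    rng = np.random.default_rng(seed)
    if group_R is None:
        group_R = default_group_structure(network_sizes)
    group_R = np.asarray(group_R, dtype=float)
    parcellation = _toy_parcellation(network_sizes)
    if parcellation.n_rois != group_R.shape[0]:
        raise ValueError("network_sizes do not match group correlation size")

    etas = np.broadcast_to(
        np.asarray(heterogeneity, dtype=float), (n_subjects,)
    ).copy()
    if np.any((etas < 0) | (etas > 1)):
        raise ValueError("heterogeneity values must be in [0, 1]")

    subject_ids = [f"sub{i + 1:03d}" for i in range(n_subjects)]
    scans: dict[str, SubjectScan] = {}
    matrices: dict[str, np.ndarray] = {}
    features = []
    for sid, eta in zip(subject_ids, etas):
        R_i = sample_subject_matrix(group_R, float(eta), rng)
        matrices[sid] = R_i
        scans[sid] = sample_timeseries(
            R_i,
            T,
            censor_fraction,
            rng,
            tr=tr,
            roi_ids=parcellation.roi_ids,
        )
        features.append(true_edge_vector(R_i, parcellation.roi_ids).values)
    feature_matrix = np.vstack(features)
    similarities = 1.0 - etas

    n_edges = feature_matrix.shape[1]
    signal_idx = rng.choice(n_edges, size=min(n_signal_edges, n_edges), replace=False)
    weights = np.zeros(n_edges)
    weights[signal_idx] = 1.0 / np.sqrt(signal_idx.size)

    if outcome_specs is None:
        outcome_specs = {
            "behavior_mod": {
                "intercept": 10.0,
                "base_coupling": 0.5,
                "attenuation": 1.0,
                "noise_sd": 1.0,
            },
            "behavior_null": {
                "intercept": 10.0,
                "base_coupling": 1.0,
                "attenuation": 0.0,
                "noise_sd": 1.0,
            },
        }
    params: dict[str, OutcomeParams] = {}
    outcome_cols: dict[str, np.ndarray] = {}
    for measure, spec in outcome_specs.items():
        p = OutcomeParams(weights=weights, **spec)
        params[measure] = p
        outcome_cols[measure] = sample_outcomes(
            feature_matrix, similarities, p, rng
        )
    outcomes = pd.DataFrame({"subject_id": subject_ids, **outcome_cols})

    covariates = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "age": rng.uniform(132.0, 156.0, n_subjects),  # months
            "sex": rng.choice(["F", "M"], n_subjects),
            "site": rng.choice(
                [f"site{i:02d}" for i in range(1, 5)], n_subjects
            ),
        }
    )

    truth = GroundTruth(
        group_correlation=group_R,
        heterogeneity=float(np.mean(etas)),
        subject_similarities=similarities,
        outcome_params=params,
    )
    return SyntheticCohort(
        scans=scans,
        parcellation=parcellation,
        outcomes=outcomes,
        truth=truth,
        seed=seed,
        subject_matrices=matrices,
        covariates=covariates,
    )


def make_fig1_fixture(
    mode: str,
    n_subjects: int = 9,
    n_rois: int = 12,
    rng: np.random.Generator | None = None,
    project: bool = True,
) -> list[np.ndarray]:
    """Homogeneous vs fully randomized per-subject correlation matrices.

    Homogeneous: a shared per-edge base value plus independent per-subject
    uniform jitter on [-0.15, +0.15] (total range 0.30), then PSD projection.
    Heterogeneous: an independent random correlation matrix per subject.
    ``project=False`` returns the raw (pre-projection) homogeneous matrices so
    the jitter envelope can be checked exactly.
    """
    if mode not in ("homogeneous", "heterogeneous"):
        raise ValueError("mode must be 'homogeneous' or 'heterogeneous'")
    rng = rng or np.random.default_rng(0)
    if mode == "heterogeneous":
        return [
            random_correlation(n_rois, rng, n_factors=max(2, n_rois // 3))
            for _ in range(n_subjects)
        ]
    third = n_rois // 3
    sizes = [third, third, n_rois - 2 * third]
    base = make_group_structure(sizes, within_r=0.5, between_r=0.15)
    iu = np.triu_indices(n_rois, k=1)
    out = []
    for _ in range(n_subjects):
        jitter = rng.uniform(-0.15, 0.15, size=iu[0].size)
        mat = base.copy()
        mat[iu] = np.clip(mat[iu] + jitter, -0.999, 0.999)
        mat.T[iu] = mat[iu]
        out.append(nearest_correlation(mat) if project else mat)
    return out


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write a cohort as plain-text files (TSV/CSV/JSON) under ``outdir``.

    Layout: ``<sub>_series.tsv`` (frames x ROIs, header = ROI ids),
    ``<sub>_fd.tsv`` (one column), ``parcellation.tsv``, ``outcomes.csv``,
    ``covariates.csv`` and ``truth.json``.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.parcellation.to_tsv(outdir / "parcellation.tsv")
    cohort.outcomes.to_csv(outdir / "outcomes.csv", index=False)
    if cohort.covariates is not None:
        cohort.covariates.to_csv(outdir / "covariates.csv", index=False)
    for sid, scan in cohort.scans.items():
        pd.DataFrame(scan.series, columns=list(cohort.parcellation.roi_ids)).to_csv(
            outdir / f"{sid}_series.tsv", sep="\t", index=False
        )
        pd.DataFrame({"fd": scan.fd}).to_csv(
            outdir / f"{sid}_fd.tsv", sep="\t", index=False
        )
    truth = {
        "seed": cohort.seed,
        "heterogeneity": cohort.truth.heterogeneity,
        "subject_similarities": cohort.truth.subject_similarities.tolist(),
        "group_correlation": cohort.truth.group_correlation.tolist(),
        "outcome_params": {
            m: {
                "intercept": p.intercept,
                "base_coupling": p.base_coupling,
                "attenuation": p.attenuation,
                "noise_sd": p.noise_sd,
                "weights": p.weights.tolist(),
            }
            for m, p in cohort.truth.outcome_params.items()
        },
        "tr": next(iter(cohort.scans.values())).tr if cohort.scans else None,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh)
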