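"""Per-subject connectivity estimation and group-model construction.

This module turns censored ROI time series into Fisher-z edge vectors and
network-aggregated matrices, applies ROI/edge quality filters (tSnR,
inter-individual variance), and averages training subjects into a group
referent model.

Conventions
-----------
* Edges are enumerated canonically: for an ordered ROI list, all pairs
  ``(i, j)`` with ``i < j`` in row-major order of the upper triangle.
* All averaging happens on the Fisher-z scale; network cells are means of
  per-edge z values (not z of mean r).
* Frame censoring is strict: a frame is dropped iff ``fd > threshold``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Parcellation",
    "SubjectScan",
    "EdgeVector",
    "NetworkMatrix",
    "FeatureSet",
    "GroupModel",
    "default_parcellation",
    "enumerate_edges",
    "censor_and_concatenate",
    "subject_included",
    "compute_tsnr",
    "select_rois",
    "correlation_edges",
    "select_high_variance_edges",
    "restrict_to_features",
    "network_matrix",
    "group_average",
]

# Gordon cortical parcel counts per intrinsic network (333 parcels total).
# The eight association networks plus the 19-ROI subcortical set give the
# 196-ROI analysis pool.
GORDON_NETWORK_SIZES: dict[str, int] = {
    "Default": 41,
    "SMhand": 38,
    "SMmouth": 8,
    "Visual": 39,
    "FrontoParietal": 24,
    "Auditory": 24,
    "CinguloParietal": 5,
    "RetrosplenialTemporal": 8,
    "CinguloOperc": 40,
    "VentralAttn": 23,
    "Salience": 4,
    "DorsalAttn": 32,
    "None": 47,
}

ASSOCIATION_NETWORKS: tuple[str, ...] = (
    "Default",
    "Salience",
    "FrontoParietal",
    "CinguloParietal",
    "RetrosplenialTemporal",
    "CinguloOperc",
    "VentralAttn",
    "DorsalAttn",
)

SUBCORTICAL_NETWORK = "Subcortical"
N_SUBCORTICAL = 19


class Parcellation:
    """Ordered ROI table with network labels and association flags.

    Parameters
    ----------
    roi_ids:
        Ordered, unique ROI identifiers. The order fixes the canonical edge
        enumeration shared by every subject.
    networks:
        Network label per ROI (parallel to ``roi_ids``).
    association_flag:
        Mapping from network label to whether the network belongs to the
        association set used in the primary analysis. Networks absent from
        the mapping default to False.
    """

    def __init__(
        self,
        roi_ids: Sequence[str],
        networks: Sequence[str],
        association_flag: Mapping[str, bool] | None = None,
    ) -> None:
        roi_ids = tuple(str(r) for r in roi_ids)
        networks = tuple(str(n) for n in networks)
        if len(roi_ids) != len(networks):
            raise ValueError("roi_ids and networks must be parallel sequences")
        if len(set(roi_ids)) != len(roi_ids):
            dupes = sorted({r for r in roi_ids if list(roi_ids).count(r) > 1})
            raise ValueError(f"duplicate ROI ids: {dupes[:5]}")
        self.roi_ids = roi_ids
        self._networks = networks
        self.network_of: dict[str, str] = dict(zip(roi_ids, networks))
        flags = dict(association_flag or {})
        self.association_flag: dict[str, bool] = {
            n: bool(flags.get(n, False)) for n in self.network_labels
        }

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    @property
    def network_labels(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for n in self._networks:
            seen.setdefault(n, None)
        return tuple(seen)

    @property
    def association_networks(self) -> tuple[str, ...]:
        return tuple(n for n in self.network_labels if self.association_flag[n])

    def rois_in(self, network: str) -> tuple[str, ...]:
        return tuple(r for r, n in zip(self.roi_ids, self._networks) if n == network)

    def rois_in_networks(self, networks: Iterable[str]) -> tuple[str, ...]:
        wanted = set(networks)
        return tuple(
            r for r, n in zip(self.roi_ids, self._networks) if n in wanted
        )

    def restrict(self, roi_subset: Iterable[str]) -> "Parcellation":
        keep = set(roi_subset)
        ids = [r for r in self.roi_ids if r in keep]
        nets = [self.network_of[r] for r in ids]
        return Parcellation(ids, nets, self.association_flag)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": self.roi_ids,
                "network": self._networks,
                "association_flag": [
                    int(self.association_flag[n]) for n in self._networks
                ],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Parcellation":
        flags: dict[str, bool] = {}
        for net, grp in frame.groupby("network"):
            vals = set(grp["association_flag"].astype(int))
            if len(vals) > 1:
                raise ValueError(f"inconsistent association_flag for network {net!r}")
            flags[str(net)] = bool(vals.pop())
        return cls(frame["roi_id"].tolist(), frame["network"].tolist(), flags)

    @classmethod
    def from_tsv(cls, path) -> "Parcellation":
        # keep_default_na: the Gordon "None" network label is a real name
        return cls.from_frame(pd.read_csv(path, sep="\t", keep_default_na=False))

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Parcellation)
            and self.roi_ids == other.roi_ids
            and self._networks == other._networks
            and self.association_flag == other.association_flag
        )

    def __repr__(self) -> str:
        return (
            f"Parcellation(n_rois={self.n_rois}, "
            f"n_networks={len(self.network_labels)})"
        )


def default_parcellation() -> Parcellation:
    """Gordon-style cortical parcellation (333 ROIs) plus 19 subcortical ROIs."""
    roi_ids: list[str] = []
    networks: list[str] = []
    i = 0
    for net, size in GORDON_NETWORK_SIZES.items():
        for _ in range(size):
            i += 1
            roi_ids.append(f"roi{i:03d}")
            networks.append(net)
    for _ in range(N_SUBCORTICAL):
        i += 1
        roi_ids.append(f"roi{i:03d}")
        networks.append(SUBCORTICAL_NETWORK)
    flags = {n: (n in ASSOCIATION_NETWORKS) for n in GORDON_NETWORK_SIZES}
    flags[SUBCORTICAL_NETWORK] = False
    return Parcellation(roi_ids, networks, flags)


@dataclass
class SubjectScan:
    """Frames-by-ROI signal matrix with a per-frame motion trace.

    ``fd`` is the filtered framewise displacement in mm, one value per frame;
    ``tr`` is the repetition time in seconds.
    """

    series: np.ndarray
    fd: np.ndarray
    tr: float = 0.8
    roi_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        self.fd = np.asarray(self.fd, dtype=float)
        if self.series.ndim != 2:
            raise ValueError("series must be a 2-D frames x ROI matrix")
        if self.fd.shape != (self.series.shape[0],):
            raise ValueError(
                f"fd length {self.fd.shape} does not match "
                f"{self.series.shape[0]} frames"
            )
        if not self.tr > 0:
            raise ValueError("tr must be positive")
        if self.roi_ids is not None:
            self.roi_ids = tuple(self.roi_ids)
            if len(self.roi_ids) != self.series.shape[1]:
                raise ValueError("roi_ids length does not match series columns")

    @property
    def n_frames(self) -> int:
        return self.series.shape[0]

    @property
    def n_rois(self) -> int:
        return self.series.shape[1]


@dataclass(frozen=True)
class EdgeVector:
    """Connectivity values over a canonical ordered edge set."""

    edges: tuple[tuple[str, str], ...]
    values: np.ndarray
    scale: str = "z"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.edges),):
            raise ValueError("values length does not match edge count")
        if self.scale not in ("r", "z"):
            raise ValueError("scale must be 'r' or 'z'")
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-pair edge ({a}, {b})")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges in enumeration")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite edge values")

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class NetworkMatrix:
    """Symmetric network-by-network aggregate of edge values.

    Diagonal cells are within-network means, off-diagonal cells are
    between-network means; with K networks there are K(K+1)/2 distinct cells.
    """

    networks: tuple[str, ...]
    cells: np.ndarray
    scale: str = "z"

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", np.asarray(self.cells, dtype=float))
        k = len(self.networks)
        if self.cells.shape != (k, k):
            raise ValueError("cells must be K x K")
        if not np.allclose(self.cells, self.cells.T, atol=1e-12):
            raise ValueError("cells must be symmetric")

    @property
    def n_networks(self) -> int:
        return len(self.networks)

    @property
    def n_distinct(self) -> int:
        k = self.n_networks
        return k * (k + 1) // 2

    def values_vector(self) -> np.ndarray:
        """Distinct cells (diagonal + upper triangle) in row-major order."""
        k = self.n_networks
        iu = np.triu_indices(k)
        return self.cells[iu]


@dataclass(frozen=True)
class FeatureSet:
    """Edges retained by training-set feature selection, plus the rule used."""

    edges: tuple[tuple[str, str], ...]
    indices: np.ndarray
    rule: dict = field(default_factory=dict)
    variances: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", np.asarray(self.indices, dtype=int))
        if self.indices.shape != (len(self.edges),):
            raise ValueError("indices length does not match edge count")

    @property
    def n_selected(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class GroupModel:
    """Training-set mean connectivity used as the similarity referent."""

    referent: EdgeVector | NetworkMatrix
    n_train: int


def enumerate_edges(roi_ids: Sequence[str]) -> tuple[tuple[str, str], ...]:
    """Canonical (i < j, row-major) unordered ROI pairs."""
    ids = list(roi_ids)
    return tuple(
        (ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))
    )


def censor_and_concatenate(
    runs: Sequence[SubjectScan], fd_threshold: float = 0.10
) -> SubjectScan:
    """Drop frames with fd strictly above threshold and concatenate runs."""
    if not runs:
        raise ValueError("no runs supplied")
    n_rois = runs[0].n_rois
    roi_ids = runs[0].roi_ids
    tr = runs[0].tr
    for run in runs[1:]:
        if run.n_rois != n_rois or run.roi_ids != roi_ids:
            raise ValueError("runs do not share ROI ordering")
    series_parts, fd_parts = [], []
    for run in runs:
        keep = run.fd <= fd_threshold
        series_parts.append(run.series[keep])
        fd_parts.append(run.fd[keep])
    series = np.concatenate(series_parts, axis=0)
    fd = np.concatenate(fd_parts)
    if series.shape[0] == 0:
        raise ValueError(
            f"no frames survive censoring at fd_threshold={fd_threshold}"
        )
    return SubjectScan(series, fd, tr=tr, roi_ids=roi_ids)


def subject_included(
    scan: SubjectScan, min_minutes: float = 10.0, fd_threshold: float = 0.10
) -> bool:
    """True iff the low-motion data meets the minimum-duration criterion."""
    retained = int(np.sum(scan.fd <= fd_threshold))
    return retained * scan.tr >= min_minutes * 60.0


def compute_tsnr(scan: SubjectScan) -> pd.Series:
    """Temporal signal-to-noise ratio per ROI: mean / sample SD."""
    if scan.n_frames < 2:
        raise ValueError("need at least 2 frames to compute tSnR")
    mean = scan.series.mean(axis=0)
    sd = scan.series.std(axis=0, ddof=1)
    labels = scan.roi_ids or tuple(str(i) for i in range(scan.n_rois))
    degenerate = np.flatnonzero(sd == 0.0)
    if degenerate.size:
        bad = [labels[i] for i in degenerate]
        raise ValueError(f"zero temporal SD for ROIs: {bad[:5]}")
    return pd.Series(mean / sd, index=list(labels))


def select_rois(
    training_tsnr: pd.DataFrame,
    parcellation: Parcellation,
    sd_k: float = 2.0,
    networks: Sequence[str] | None = None,
    include_subcortical: bool = True,
) -> tuple[str, ...]:
    """Keep association-network ROIs whose mean tSnR clears the SD cutoff.

    ``training_tsnr`` is a subjects x ROI table computed on training subjects
    only. ROIs with mean tSnR below ``grand mean - sd_k * SD`` (statistics over
    the ROI-wise means) are dropped. The returned ROI subset is reused verbatim
    for test subjects.
    """
    if networks is None:
        networks = parcellation.association_networks
    pool = list(networks)
    if include_subcortical and SUBCORTICAL_NETWORK in parcellation.network_labels:
        pool.append(SUBCORTICAL_NETWORK)
    candidate = parcellation.rois_in_networks(pool)
    if len(candidate) < 2:
        raise ValueError("fewer than 2 candidate ROIs")
    missing = [r for r in candidate if r not in training_tsnr.columns]
    if missing:
        raise ValueError(f"tSnR table missing ROIs: {missing[:5]}")
    roi_means = training_tsnr[list(candidate)].mean(axis=0)
    grand = roi_means.mean()
    spread = roi_means.std(ddof=1)
    cutoff = grand - sd_k * spread
    kept = tuple(r for r in candidate if roi_means[r] >= cutoff)
    if not kept:
        raise ValueError("tSnR selection removed every ROI")
    return kept


_CLAMP = 1.0 - 1e-12


def correlation_edges(
    scan: SubjectScan, rois: Sequence[str] | None = None
) -> EdgeVector:
    """Pairwise Pearson correlations over retained frames, Fisher z-transformed.

    ``rois`` restricts (and orders) the columns used; by default all ROIs in
    scan order are used. Correlations are clamped to +/-(1 - 1e-12) before the
    atanh transform so duplicated ROIs degrade gracefully.
    """
    if scan.n_frames < 3:
        raise ValueError("need at least 3 frames for correlation estimates")
    labels = list(scan.roi_ids or (str(i) for i in range(scan.n_rois)))
    if rois is None:
        cols = list(range(scan.n_rois))
        use_labels = labels
    else:
        index = {r: i for i, r in enumerate(labels)}
        missing = [r for r in rois if r not in index]
        if missing:
            raise ValueError(f"ROIs not in scan: {missing[:5]}")
        cols = [index[r] for r in rois]
        use_labels = list(rois)
    data = scan.series[:, cols]
    sd = data.std(axis=0)
    flat = np.flatnonzero(sd == 0.0)
    if flat.size:
        raise ValueError(
            f"constant time series for ROIs: {[use_labels[i] for i in flat][:5]}"
        )
    r = np.corrcoef(data, rowvar=False)
    iu = np.triu_indices(len(cols), k=1)
    vals = np.clip(r[iu], -_CLAMP, _CLAMP)
    return EdgeVector(enumerate_edges(use_labels), np.arctanh(vals), scale="z")


def select_high_variance_edges(
    training_vectors: Sequence[EdgeVector], p: float = 0.10
) -> FeatureSet:
    """Retain the ceil(p * E) edges with the largest between-subject variance.

    Variance uses the n-1 denominator; ties are broken by canonical edge order
    (earlier edge wins). Selection is defined on training data only.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"variance fraction must be in (0, 1], got {p}")
    if len(training_vectors) < 2:
        raise ValueError("need at least 2 training subjects")
    edges = training_vectors[0].edges
    for ev in training_vectors[1:]:
        if ev.edges != edges:
            raise ValueError("edge enumerations differ across training subjects")
    stack = np.vstack([ev.values for ev in training_vectors])
    variances = stack.var(axis=0, ddof=1)
    k = math.ceil(p * len(edges))
    # stable sort keeps earlier (canonical) edges first among ties
    order = np.argsort(-variances, kind="stable")
    chosen = np.sort(order[:k])
    return FeatureSet(
        edges=tuple(edges[i] for i in chosen),
        indices=chosen,
        rule={"variance_fraction": p, "n_candidates": len(edges)},
        variances=variances[chosen],
    )


def restrict_to_features(ev: EdgeVector, features: FeatureSet) -> EdgeVector:
    """Apply a training-set feature selection to any subject's edge vector."""
    sel = tuple(ev.edges[i] for i in features.indices)
    if sel != features.edges:
        raise ValueError("edge enumeration does not match the feature set")
    return EdgeVector(features.edges, ev.values[features.indices], scale=ev.scale)


def _edge_matrix(ev: EdgeVector, roi_order: Sequence[str]) -> np.ndarray:
    """Dense symmetric value matrix (zero diagonal) over ``roi_order``."""
    index = {r: i for i, r in enumerate(roi_order)}
    n = len(roi_order)
    expected = enumerate_edges(roi_order)
    lookup = dict(zip(ev.edges, ev.values))
    mat = np.zeros((n, n))
    for a, b in expected:
        if (a, b) in lookup:
            v = lookup[(a, b)]
        elif (b, a) in lookup:
            v = lookup[(b, a)]
        else:
            raise ValueError(f"edge ({a}, {b}) missing from edge vector")
        i, j = index[a], index[b]
        mat[i, j] = mat[j, i] = v
    return mat


def network_cells_from_dense(
    mat: np.ndarray, labels: np.ndarray, n_networks: int
) -> np.ndarray:
    """Aggregate a dense symmetric edge matrix into network cell means.

    ``labels`` assigns each row/column an integer network index in
    ``[0, n_networks)``. Vectorized so the permutation null can call it in a
    tight loop.
    """
    n = mat.shape[0]
    ind = np.zeros((n, n_networks))
    ind[np.arange(n), labels] = 1.0
    sums = ind.T @ mat @ ind
    counts = ind.sum(axis=0)
    denom = np.outer(counts, counts)
    np.fill_diagonal(denom, counts * (counts - 1))
    if np.any(np.diag(denom) == 0):
        small = [k for k in range(n_networks) if counts[k] < 2]
        raise ValueError(f"networks with fewer than 2 ROIs: {small}")
    return sums / denom


def network_matrix(
    edge_vector: EdgeVector,
    parcellation: Parcellation,
    networks: Sequence[str] | None = None,
) -> NetworkMatrix:
    """Within/between-network mean connectivity over the named networks."""
    if networks is None:
        networks = parcellation.association_networks
    networks = tuple(networks)
    for net in networks:
        if len(parcellation.rois_in(net)) < 2:
            raise ValueError(f"network {net!r} has fewer than 2 ROIs")
    roi_order = parcellation.rois_in_networks(networks)
    mat = _edge_matrix(edge_vector, roi_order)
    net_index = {n: k for k, n in enumerate(networks)}
    labels = np.array([net_index[parcellation.network_of[r]] for r in roi_order])
    cells = network_cells_from_dense(mat, labels, len(networks))
    cells = (cells + cells.T) / 2.0
    return NetworkMatrix(networks, cells, scale=edge_vector.scale)


def group_average(
    items: Sequence[EdgeVector] | Sequence[NetworkMatrix],
) -> GroupModel:
    """Elementwise mean on the z scale across subjects (no back-transform)."""
    if not items:
        raise ValueError("need at least one subject")
    first = items[0]
    if isinstance(first, EdgeVector):
        for ev in items[1:]:
            if not isinstance(ev, EdgeVector) or ev.edges != first.edges:
                raise ValueError("edge enumerations differ across subjects")
        mean = np.mean([ev.values for ev in items], axis=0)
        referent: EdgeVector | NetworkMatrix = EdgeVector(
            first.edges, mean, scale=first.scale
        )
    elif isinstance(first, NetworkMatrix):
        for nm in items[1:]:
            if not isinstance(nm, NetworkMatrix) or nm.networks != first.networks:
                raise ValueError("network enumerations differ across subjects")
        mean = np.mean([nm.cells for nm in items], axis=0)
        referent = NetworkMatrix(first.networks, mean, scale=first.scale)
    else:
        raise TypeError(f"unsupported referent type {type(first)!r}")
    return GroupModel(referent=referent, n_train=len(items))
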