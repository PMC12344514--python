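"""Group-to-individual similarity: ICC(A,1), benchmarks, permutation null.

The similarity index is the intraclass correlation from a two-way random
effects model with absolute agreement and single-rater units, computed
between the training-set group model and each individual. The two "raters"
are {group model, individual}; the "objects" are connectivity features, so
each individual receives exactly one ICC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import (
    EdgeVector,
    GroupModel,
    NetworkMatrix,
    Parcellation,
    _edge_matrix,
    network_cells_from_dense,
)

__all__ = [
    "IccResult",
    "SimilarityTable",
    "PermutationNullResult",
    "icc_a1",
    "classify_icc",
    "cohort_similarity",
    "shuffled_network_null",
]


@dataclass(frozen=True)
class IccResult:
    """ICC(A,1) value with its ANOVA mean-square components."""

    value: float
    n_objects: int
    msr: float
    msc: float
    mse: float


def icc_a1(x: Sequence[float], y: Sequence[float]) -> IccResult:
    """Two-way random effects, absolute agreement, single-rater ICC.

    With k = 2 raters (the two inputs) and n objects (paired values),

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    where MSR, MSC, MSE are the rows (objects), columns (raters) and residual
    mean squares of the two-way layout with one observation per cell. The
    value may be negative; it is never truncated.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 objects")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("both sequences are constant; ICC undefined")
    k = 2
    data = np.column_stack([x, y])
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise ValueError("degenerate layout: zero denominator in ICC")
    return IccResult(
        value=float((msr - mse) / denom),
        n_objects=n,
        msr=float(msr),
        msc=float(msc),
        mse=float(mse),
    )


ICC_BENCHMARKS = (
    (0.90, "excellent"),
    (0.75, "good"),
    (0.50, "moderate"),
)


def classify_icc(value: float) -> str:
    """Benchmark label: poor < .50 <= moderate < .75 <= good < .90 <= excellent."""
    if value > 1.0 + 1e-12:
        raise ValueError("ICC cannot exceed 1")
    for cutoff, label in ICC_BENCHMARKS:
        if value >= cutoff:
            return label
    return "poor"


@dataclass
class SimilarityTable:
    """Per-subject ICC against the training group model."""

    table: pd.DataFrame  # columns: subject_id, icc, label
    set_label: str

    def __post_init__(self) -> None:
        required = {"subject_id", "icc", "label"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"table must contain columns {sorted(required)}")

    @property
    def summary(self) -> dict:
        icc = self.table["icc"]
        return {
            "mean": float(icc.mean()),
            "sd": float(icc.std(ddof=1)) if len(icc) > 1 else 0.0,
            "min": float(icc.min()),
            "max": float(icc.max()),
            "n": int(len(icc)),
        }


def _referent_values(item: EdgeVector | NetworkMatrix) -> np.ndarray:
    if isinstance(item, EdgeVector):
        return item.values
    if isinstance(item, NetworkMatrix):
        return item.values_vector()
    raise TypeError(f"unsupported referent type {type(item)!r}")


def _check_enumeration(
    group: EdgeVector | NetworkMatrix, subject: EdgeVector | NetworkMatrix
) -> None:
    if isinstance(group, EdgeVector):
        if not isinstance(subject, EdgeVector) or subject.edges != group.edges:
            raise ValueError("subject edge enumeration differs from group model")
    else:
        if (
            not isinstance(subject, NetworkMatrix)
            or subject.networks != group.networks
        ):
            raise ValueError("subject network enumeration differs from group model")


def cohort_similarity(
    group: GroupModel,
    subjects: Sequence[EdgeVector] | Sequence[NetworkMatrix],
    set_label: str = "train",
    subject_ids: Sequence[str] | None = None,
) -> SimilarityTable:
    """One ICC(A,1) per subject against the training-set group referent."""
    ref = _referent_values(group.referent)
    ids = (
        list(subject_ids)
        if subject_ids is not None
        else [f"sub{i + 1:03d}" for i in range(len(subjects))]
    )
    if len(ids) != len(subjects):
        raise ValueError("subject_ids length mismatch")
    rows = []
    for sid, subject in zip(ids, subjects):
        _check_enumeration(group.referent, subject)
        res = icc_a1(ref, _referent_values(subject))
        rows.append({"subject_id": sid, "icc": res.value, "label": classify_icc(res.value)})
    return SimilarityTable(pd.DataFrame(rows), set_label=set_label)


@dataclass
class PermutationNullResult:
    """Summary of the shuffled-network-assignment null distribution."""

    n_iter: int
    iteration_means: np.ndarray
    seed: int | None = None
    true_mean: float | None = None

    def __post_init__(self) -> None:
        self.iteration_means = np.asarray(self.iteration_means, dtype=float)
        if self.iteration_means.shape != (self.n_iter,):
            raise ValueError("iteration_means length must equal n_iter")

    @property
    def overall_mean(self) -> float:
        return float(self.iteration_means.mean())

    @property
    def sd_across_iterations(self) -> float:
        if self.n_iter < 2:
            return 0.0
        return float(self.iteration_means.std(ddof=1))

    @property
    def max_iteration_mean(self) -> float:
        return float(self.iteration_means.max())


def shuffled_network_null(
    subject_edge_vectors: Sequence[EdgeVector],
    parcellation: Parcellation,
    networks: Sequence[str] | None = None,
    n_iter: int = 500,
    rng: np.random.Generator | None = None,
    forced_permutations: Sequence[np.ndarray] | None = None,
) -> PermutationNullResult:
    """Null distribution of mean cohort ICC under shuffled network labels.

    Each iteration draws one uniformly random permutation of the ROI -> network
    assignment (network sizes preserved), shared by all subjects and by the
    group model, then recomputes network matrices, the group referent and all
    subject ICCs, recording the sample-mean ICC.

    ``forced_permutations`` substitutes explicit label permutations (mainly
    for tests, e.g. the identity).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = rng or np.random.default_rng(0)
    if networks is None:
        networks = parcellation.association_networks
    networks = tuple(networks)
    roi_order = parcellation.rois_in_networks(networks)
    net_index = {n: k for k, n in enumerate(networks)}
    labels = np.array(
        [net_index[parcellation.network_of[r]] for r in roi_order]
    )
    k = len(networks)
    dense = [_edge_matrix(ev, roi_order) for ev in subject_edge_vectors]
    iu = np.triu_indices(k)

    def mean_icc(lab: np.ndarray) -> float:
        cell_vectors = np.vstack(
            [network_cells_from_dense(m, lab, k)[iu] for m in dense]
        )
        group_ref = cell_vectors.mean(axis=0)
        return float(
            np.mean([icc_a1(group_ref, row).value for row in cell_vectors])
        )

    true_mean = mean_icc(labels)
    means = np.empty(n_iter)
    for it in range(n_iter):
        if forced_permutations is not None:
            perm = np.asarray(forced_permutations[it])
        else:
            perm = rng.permutation(labels.size)
        means[it] = mean_icc(labels[perm])
    return PermutationNullResult(
        n_iter=n_iter, iteration_means=means, true_mean=true_mean
    )
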