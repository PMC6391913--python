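"""Profile distances and the raw within/between cluster distance matrix.

Distances are Euclidean over the fractions where both profiles are
observed, rescaled by ``sqrt(p / m)`` where ``p`` is the total number of
fractions and ``m`` the number of jointly observed ones. This
"scaled pairwise-complete" convention keeps distances comparable across
protein pairs with different missingness patterns; a pair with zero
overlapping fractions has an undefined distance and is dropped from all
downstream averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MarkerAnnotation, ProfileExperiment, QSepError

logger = logging.getLogger(__name__)


def profile_distance(x, y) -> float:
    """Scaled pairwise-complete Euclidean distance between two profiles.

    ``d = sqrt((p / m) * sum_complete (x_f - y_f)^2)`` over the ``m``
    fractions where both entries are present. Returns ``NaN`` (undefined)
    when the profiles share no observed fraction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise QSepError(f"profile length mismatch: {x.shape} vs {y.shape}")
    both = np.isfinite(x) & np.isfinite(y)
    m = int(both.sum())
    if m == 0:
        logger.warning("profile pair with zero overlapping fractions: distance undefined")
        return float("nan")
    p = x.size
    return float(np.sqrt((p / m) * np.sum((x[both] - y[both]) ** 2)))


def pairwise_distances(values: np.ndarray) -> np.ndarray:
    """All pairwise scaled pairwise-complete Euclidean distances.

    Vectorised equivalent of calling :func:`profile_distance` on every
    row pair of ``values`` (n x p). Undefined pairs are ``NaN``.
    """
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    mask = np.isfinite(values)
    z = np.where(mask, values, 0.0)
    maskf = mask.astype(float)
    # sum over jointly observed fractions of (x_i - x_j)^2, via BLAS:
    #   sum x_i^2 [j observed] + sum x_j^2 [i observed] - 2 x_i . x_j
    sq = z**2
    cross = z @ z.T
    d2 = sq @ maskf.T + maskf @ sq.T - 2.0 * cross
    m = maskf @ maskf.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = np.where(m > 0, d2 * (p / m), np.nan)
    d2 = np.maximum(d2, 0.0, where=np.isfinite(d2), out=d2)  # numeric guard
    dist = np.sqrt(d2)
    np.fill_diagonal(dist, 0.0)
    return dist


@dataclass(frozen=True)
class ClusterDistanceMatrix:
    """Symmetric k x k matrix of average within/between cluster distances.

    The diagonal holds average within-cluster distances (over unordered
    marker pairs, self-pairs excluded); off-diagonal entry (i, j) the
    average distance over all cross pairs. ``pair_counts`` records how
    many finite pairwise distances went into each average.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    pair_counts: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        counts = np.asarray(self.pair_counts, dtype=int)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "pair_counts", counts)
        k = len(self.labels)
        if values.shape != (k, k) or counts.shape != (k, k):
            raise QSepError("distance matrix shape does not match labels")
        if not np.array_equal(values, values.T):
            raise QSepError("cluster distance matrix must be symmetric")
        if (values < 0).any():
            raise QSepError("cluster distances must be non-negative")

    @property
    def k(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pair_counts, index=list(self.labels), columns=list(self.labels))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def subset(self, labels) -> "ClusterDistanceMatrix":
        """Restrict to the given clusters (order preserved as given)."""
        index = {l: i for i, l in enumerate(self.labels)}
        try:
            rows = [index[l] for l in labels]
        except KeyError as exc:
            raise QSepError(f"unknown cluster label: {exc.args[0]}") from exc
        if len(rows) < 2:
            raise QSepError("need at least two clusters")
        sel = np.ix_(rows, rows)
        return ClusterDistanceMatrix(
            labels=tuple(labels),
            values=self.values[sel],
            pair_counts=self.pair_counts[sel],
        )


def cluster_distance_matrix(
    exp: ProfileExperiment, markers: MarkerAnnotation
) -> ClusterDistanceMatrix:
    """Average within/between marker-cluster distances of an experiment.

    Distances are computed on the raw (non-imputed) profile matrix.
    Undefined pairwise distances are dropped from both numerator and
    denominator of every cell average.
    """
    markers = markers.restrict_to(exp)
    labels = markers.cluster_labels
    if len(labels) < 2:
        raise QSepError(f"need at least two marker clusters, found {len(labels)}")

    order = {pid: i for i, pid in enumerate(exp.protein_ids)}
    groups: dict[str, list[int]] = {}
    for label in labels:
        rows = [order[pid] for pid in markers.members(label)]
        if len(rows) < 2:
            raise QSepError(
                f"cluster {label!r} has {len(rows)} marker(s) in the experiment; need >= 2"
            )
        groups[label] = rows

    marker_rows = [i for label in labels for i in groups[label]]
    sub = exp.values[marker_rows]
    dist = pairwise_distances(sub)
    np.fill_diagonal(dist, np.nan)  # self-distances never enter averages

    # positions of each cluster inside the marker-only distance matrix
    pos: dict[str, np.ndarray] = {}
    offset = 0
    for label in labels:
        n = len(groups[label])
        pos[label] = np.arange(offset, offset + n)
        offset += n

    k = len(labels)
    values = np.zeros((k, k))
    counts = np.zeros((k, k), dtype=int)
    for i, li in enumerate(labels):
        for j in range(i, k):
            lj = labels[j]
            block = dist[np.ix_(pos[li], pos[lj])]
            finite = np.isfinite(block)
            n_finite = int(finite.sum())
            if i == j:
                n_finite //= 2  # unordered pairs
            if n_finite == 0:
                raise QSepError(
                    f"every pairwise distance between clusters {li!r} and {lj!r} "
                    "is undefined (no overlapping fractions)"
                )
            mean = float(block[finite].mean())
            values[i, j] = values[j, i] = mean
            counts[i, j] = counts[j, i] = n_finite

    return ClusterDistanceMatrix(labels=labels, values=values, pair_counts=counts)
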