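"""Normalised cluster-separation matrix, summaries, and comparisons.

Each raw between-cluster distance is divided by the *reference* cluster's
average within-cluster distance (row-wise division by the diagonal), so
entry (i, j) reads "how far is cluster j from cluster i, in units of
cluster i's own spread". The matrix is therefore generally asymmetric
with a unit diagonal; larger off-diagonal entries mean better separation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import QSepError
from .distances import ClusterDistanceMatrix


@dataclass(frozen=True)
class QSepMatrix:
    """Row-normalised separation matrix with unit diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "values", values)
        k = len(self.labels)
        if values.shape != (k, k):
            raise QSepError("separation matrix shape does not match labels")
        if not np.allclose(np.diag(values), 1.0):
            raise QSepError("separation matrix diagonal must be 1")

    @property
    def k(self) -> int:
        return len(self.labels)

    def off_diagonal(self) -> np.ndarray:
        """The k*(k-1) ordered off-diagonal entries (row-major)."""
        mask = ~np.eye(self.k, dtype=bool)
        return self.values[mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def subset(self, labels) -> "QSepMatrix":
        index = {l: i for i, l in enumerate(self.labels)}
        try:
            rows = [index[l] for l in labels]
        except KeyError as exc:
            raise QSepError(f"unknown cluster label: {exc.args[0]}") from exc
        if len(rows) < 2:
            raise QSepError("need at least two clusters")
        return QSepMatrix(labels=tuple(labels), values=self.values[np.ix_(rows, rows)])


@dataclass(frozen=True)
class QSepSummary:
    """Experiment-wide summary of a :class:`QSepMatrix`."""

    median_between: float
    per_cluster: dict[str, np.ndarray]
    n_clusters: int
    n_markers_used: int | None = None

    def to_json(self, path=None) -> str:
        payload = {
            "median_between": self.median_between,
            "n_clusters": self.n_clusters,
            "n_markers_used": self.n_markers_used,
            "per_cluster": {
                label: {
                    "q25": float(np.percentile(v, 25)),
                    "median": float(np.median(v)),
                    "q75": float(np.percentile(v, 75)),
                    "values": [float(x) for x in v],
                }
                for label, v in self.per_cluster.items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def normalize(raw: ClusterDistanceMatrix) -> QSepMatrix:
    """Divide each row of the raw matrix by its diagonal (within) entry."""
    diag = np.diag(raw.values)
    zero = np.flatnonzero(diag <= 0)
    if zero.size:
        bad = ", ".join(raw.labels[i] for i in zero)
        raise QSepError(f"zero within-cluster distance for cluster(s): {bad}")
    return QSepMatrix(labels=raw.labels, values=raw.values / diag[:, None])


def summarize(
    q: QSepMatrix, n_markers_used: int | None = None
) -> QSepSummary:
    """Median of the k*(k-1) off-diagonal entries plus per-cluster vectors.

    Per-cluster vectors are each reference cluster's row of normalised
    distances to the other clusters (for boxplots).
    """
    if q.k < 2:
        raise QSepError("need at least two clusters to summarise")
    off = q.off_diagonal()
    per_cluster = {}
    for i, label in enumerate(q.labels):
        row = np.delete(q.values[i], i)
        per_cluster[label] = row
    return QSepSummary(
        median_between=float(np.median(off)),
        per_cluster=per_cluster,
        n_clusters=q.k,
        n_markers_used=n_markers_used,
    )


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    pvalue: float
    mean_log_a: float
    mean_log_b: float
    n_a: int
    n_b: int

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "mean_log_a": self.mean_log_a,
            "mean_log_b": self.mean_log_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
        }


def welch_log_test(a, b) -> ComparisonResult:
    """Welch (unequal-variance) two-sided t-test on natural-log values."""
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise QSepError("each sample needs at least two values")
    if (xa <= 0).any() or (xb <= 0).any():
        raise QSepError("non-positive normalised distance: log-scale test undefined")
    la, lb = np.log(xa), np.log(xb)
    res = stats.ttest_ind(la, lb, equal_var=False)
    statistic = float(res.statistic)
    pvalue = float(res.pvalue)
    if not np.isfinite(statistic) and np.array_equal(np.sort(la), np.sort(lb)):
        # two zero-variance identical samples: 0/0 in Welch; define as no effect
        statistic = 0.0
        pvalue = 1.0
    return ComparisonResult(
        statistic=statistic,
        pvalue=pvalue,
        mean_log_a=float(la.mean()),
        mean_log_b=float(lb.mean()),
        n_a=int(la.size),
        n_b=int(lb.size),
    )


def compare_qsep(a: QSepMatrix, b: QSepMatrix) -> ComparisonResult:
    """Welch t-test on the log off-diagonal entries of two matrices."""
    return welch_log_test(a.off_diagonal(), b.off_diagonal())
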