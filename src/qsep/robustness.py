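"""Class-removal robustness scan of the separation summary.

A useful experiment-wide score should not hinge on which sub-cellular
classes happen to be annotated. The scan removes every combination of up
to ``max_removed`` clusters, recomputes the median normalised
between-cluster distance on the survivors, and fits a least-squares line
of median against the number of removed classes; a slope near zero means
the score is robust to the annotated class roster.

Because marker-pair distances do not depend on other clusters, removal
only requires subsetting the raw distance matrix — distances are never
recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core import MarkerAnnotation, ProfileExperiment, QSepError
from .distances import ClusterDistanceMatrix, cluster_distance_matrix
from .metric import normalize, summarize


@dataclass(frozen=True)
class RemovalScanResult:
    """Outcome of an exhaustive class-removal scan."""

    records: pd.DataFrame  # columns: n_removed, removed (tuple), median_between
    max_removed: int
    baseline_median: float
    slope: float
    intercept: float

    def to_tsv(self, path) -> None:
        out = self.records.copy()
        out["removed"] = out["removed"].map(lambda t: ";".join(t))
        out.to_csv(path, sep="\t", index=False)


def scan_distance_matrix(
    raw: ClusterDistanceMatrix,
    max_removed: int = 3,
    include_baseline: bool = True,
) -> RemovalScanResult:
    """Run the removal scan on a precomputed raw distance matrix."""
    k = raw.k
    if k - max_removed < 2:
        raise QSepError(
            f"cannot remove {max_removed} of {k} clusters: fewer than 2 would survive"
        )
    rows = []
    for r in range(0, max_removed + 1):
        for removed in combinations(raw.labels, r):
            gone = set(removed)
            survivors = [l for l in raw.labels if l not in gone]
            med = summarize(normalize(raw.subset(survivors))).median_between
            rows.append({"n_removed": r, "removed": removed, "median_between": med})
    records = pd.DataFrame(rows)

    fit_data = records if include_baseline else records[records["n_removed"] > 0]
    fit = stats.linregress(
        fit_data["n_removed"].to_numpy(float),
        fit_data["median_between"].to_numpy(float),
    )
    baseline = float(records.loc[records["n_removed"] == 0, "median_between"].iloc[0])
    return RemovalScanResult(
        records=records,
        max_removed=max_removed,
        baseline_median=baseline,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def class_removal_scan(
    exp: ProfileExperiment,
    markers: MarkerAnnotation,
    max_removed: int = 3,
    include_baseline: bool = True,
) -> RemovalScanResult:
    """Exhaustive removal scan starting from profiles and markers."""
    raw = cluster_distance_matrix(exp, markers)
    return scan_distance_matrix(
        raw, max_removed=max_removed, include_baseline=include_baseline
    )


def expected_record_count(k: int, max_removed: int) -> int:
    """Sum of C(k, r) for r in 0..max_removed."""
    from math import comb

    return sum(comb(k, r) for r in range(max_removed + 1))
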