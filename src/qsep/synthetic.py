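"""Generator of marker-structured profile datasets with known ground truth.

Marker proteins are drawn from isotropic Gaussian clusters in fraction
space; cluster centers sit on a scaled simplex so that "separation" is a
single scalar (the common pairwise center distance). Background
("unknown") proteins come from a mixture of the clusters plus a diffuse
component, and entries can be masked missing at random. Everything is
reproducible from an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import MarkerAnnotation, ProfileExperiment, QSepError
from .distances import cluster_distance_matrix
from .metric import normalize, summarize


@dataclass(frozen=True)
class SyntheticTruth:
    """Generative parameters for a simulated experiment.

    ``delta`` is the minimum (and, for simplex centers, exact) pairwise
    center separation; ``sigma`` the isotropic within-cluster standard
    deviation per fraction.
    """

    k: int = 3
    p: int = 10
    n_per_cluster: int = 20
    n_unknown: int = 50
    delta: float = 1.0
    sigma: float = 0.1
    missing_rate: float = 0.0
    seed: int = 0
    random_centers: bool = False
    diffuse_weight: float = 0.3
    diffuse_scale: float = 1.0
    normalise_rows: bool = False

    def __post_init__(self) -> None:
        if self.k < 2:
            raise QSepError("need at least two clusters")
        if self.p < 2:
            raise QSepError("need at least two fractions")
        if self.n_per_cluster < 2:
            raise QSepError("need at least two markers per cluster")
        if self.sigma < 0:
            raise QSepError("sigma must be non-negative")
        if not (0 <= self.missing_rate < 1):
            raise QSepError("missing_rate must be in [0, 1)")
        if not self.random_centers and self.p < self.k:
            raise QSepError("simplex centers need p >= k fractions")

    def centers(self) -> np.ndarray:
        """Cluster centers with pairwise separation >= delta (k x p)."""
        if self.random_centers:
            rng = np.random.default_rng(self.seed + 1)
            for _ in range(200):
                c = rng.normal(scale=max(self.delta, 1e-12), size=(self.k, self.p))
                d = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(-1))
                np.fill_diagonal(d, np.inf)
                if (d >= self.delta).all():
                    return c
            raise QSepError("failed to place random centers at the requested separation")
        # simplex: delta/sqrt(2) * e_i gives exact pairwise distance delta
        c = np.zeros((self.k, self.p))
        c[np.arange(self.k), np.arange(self.k)] = self.delta / np.sqrt(2.0)
        return c


def generate(truth: SyntheticTruth) -> tuple[ProfileExperiment, MarkerAnnotation]:
    """Draw a profile experiment plus marker annotation from ``truth``."""
    rng = np.random.default_rng(truth.seed)
    centers = truth.centers()

    rows = []
    ids = []
    labels = {}
    for ci in range(truth.k):
        label = f"cluster{ci + 1}"
        draws = rng.normal(loc=centers[ci], scale=truth.sigma,
                           size=(truth.n_per_cluster, truth.p))
        rows.append(draws)
        for m in range(truth.n_per_cluster):
            pid = f"M{ci + 1}_{m + 1}"
            ids.append(pid)
            labels[pid] = label

    if truth.n_unknown > 0:
        weights = np.full(truth.k + 1, (1 - truth.diffuse_weight) / truth.k)
        weights[-1] = truth.diffuse_weight
        component = rng.choice(truth.k + 1, size=truth.n_unknown, p=weights)
        bg = np.empty((truth.n_unknown, truth.p))
        for i, comp in enumerate(component):
            if comp < truth.k:
                bg[i] = rng.normal(loc=centers[comp], scale=truth.sigma, size=truth.p)
            else:
                spread = max(truth.delta, truth.sigma, 1e-12) * truth.diffuse_scale
                bg[i] = rng.normal(loc=centers.mean(axis=0), scale=spread, size=truth.p)
        rows.append(bg)
        ids.extend(f"U{i + 1}" for i in range(truth.n_unknown))

    values = np.vstack(rows)
    if truth.normalise_rows:
        values = values - values.min(axis=1, keepdims=True)
        totals = values.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        values = values / totals
    if truth.missing_rate > 0:
        mask = rng.random(values.shape) < truth.missing_rate
        values = values.copy()
        values[mask] = np.nan

    exp = ProfileExperiment(
        protein_ids=tuple(ids),
        fraction_ids=tuple(f"F{j + 1}" for j in range(truth.p)),
        values=values,
    )
    return exp, MarkerAnnotation(labels)


def separation_sweep(base: SyntheticTruth, deltas) -> pd.DataFrame:
    """Median separation score across a grid of center separations.

    Each grid point regenerates the dataset at the same seed, so the
    only thing that varies is the separation itself.
    """
    records = []
    for delta in deltas:
        truth = replace(base, delta=float(delta))
        exp, markers = generate(truth)
        med = summarize(normalize(cluster_distance_matrix(exp, markers))).median_between
        records.append({"delta": float(delta), "median_between": med})
    return pd.DataFrame(records)
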