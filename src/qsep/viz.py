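"""Visual diagnostics: PCA projections, profile plots, dendrograms,
separation heatmaps and boxplots.

All plotting functions are pure renderers: they take computed results,
write a figure to disk, and return the underlying plot data so tests can
assert on the data layer instead of pixels. PCA is always applied to the
zero-imputed view of an experiment; distances never are.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .core import MarkerAnnotation, ProfileExperiment, QSepError, zero_imputed_view
from .distances import ClusterDistanceMatrix, pairwise_distances
from .metric import QSepMatrix, summarize

PCA_STYLES = ("plain", "alpha", "hexbin", "annotated")


@dataclass(frozen=True)
class PCAResult:
    """Principal-component scores and per-component variance fractions."""

    scores: np.ndarray
    variance_fraction: np.ndarray
    components_plotted: tuple[int, int] = (1, 2)

    def axis_label(self, component: int) -> str:
        frac = self.variance_fraction[component - 1]
        return f"PC{component} ({100 * frac:.2f}%)"


def pca_project(
    exp: ProfileExperiment,
    n_components: int | None = None,
    scale: bool = False,
) -> PCAResult:
    """Mean-centred (optionally unit-variance-scaled) PCA of the profiles.

    Missing entries are zero-imputed first. Component signs are fixed
    deterministically: the largest-magnitude loading of each component is
    made positive.
    """
    values = zero_imputed_view(exp).values
    n, p = values.shape
    if n_components is None:
        n_components = min(n, p)
    if n_components > min(n, p):
        raise QSepError(f"n_components={n_components} exceeds min(n, p)={min(n, p)}")
    centred = values - values.mean(axis=0)
    total_var = float((centred**2).sum())
    if total_var == 0.0:
        raise QSepError("profile matrix is constant: PCA undefined")
    if scale:
        sd = centred.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        values = values / sd

    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(values)
    # deterministic sign: largest-|loading| positive per component
    for c in range(n_components):
        loading = model.components_[c]
        pivot = loading[np.argmax(np.abs(loading))]
        if pivot < 0:
            scores[:, c] *= -1
    return PCAResult(scores=scores, variance_fraction=model.explained_variance_ratio_.copy())


def plot_pca(
    res: PCAResult,
    markers: MarkerAnnotation | None = None,
    style: str = "plain",
    out=None,
    protein_ids=None,
    alpha: float = 0.3,
    gridsize: int = 40,
):
    """Scatter/hexbin rendering of two principal components.

    Styles: ``plain`` (opaque scatter), ``alpha`` (transparent scatter to
    expose density), ``hexbin`` (2-D hexagonal binning with a count
    colour key), ``annotated`` (markers coloured by cluster, unknowns
    grey; requires ``markers`` and ``protein_ids``).
    """
    if style not in PCA_STYLES:
        raise QSepError(f"unknown PCA plot style {style!r}; choose from {PCA_STYLES}")
    ci, cj = res.components_plotted
    x, y = res.scores[:, ci - 1], res.scores[:, cj - 1]

    fig, ax = plt.subplots(figsize=(6, 5))
    data = {"x": x, "y": y}
    if style == "plain":
        ax.scatter(x, y, s=8, color="black")
    elif style == "alpha":
        ax.scatter(x, y, s=8, color="black", alpha=alpha)
    elif style == "hexbin":
        hb = ax.hexbin(x, y, gridsize=gridsize, cmap="viridis", mincnt=1)
        fig.colorbar(hb, ax=ax, label="count")
    else:  # annotated
        if markers is None:
            raise QSepError("annotated style requires a marker annotation")
        if protein_ids is None:
            raise QSepError("annotated style requires protein ids matching the scores")
        labels = np.array([markers.label_of(p) for p in protein_ids])
        unknown = markers.unknown_label
        ax.scatter(x[labels == unknown], y[labels == unknown], s=8,
                   color="lightgrey", label=unknown)
        cmap = plt.get_cmap("tab20")
        for i, label in enumerate(markers.cluster_labels):
            sel = labels == label
            ax.scatter(x[sel], y[sel], s=14, color=cmap(i % 20), label=label)
        ax.legend(fontsize=7, markerscale=1.5, loc="best")
        data["labels"] = labels
    ax.set_xlabel(res.axis_label(ci))
    ax.set_ylabel(res.axis_label(cj))
    if out is not None:
        fig.savefig(out, bbox_inches="tight")
    plt.close(fig)
    return data


def plot_profiles(
    exp: ProfileExperiment,
    markers: MarkerAnnotation,
    clusters,
    out=None,
):
    """One line per marker protein across ordered fractions, by cluster."""
    clusters = list(clusters)
    if not clusters:
        raise QSepError("at least one cluster label is required")
    known = set(markers.cluster_labels)
    for label in clusters:
        if label not in known:
            raise QSepError(f"unknown cluster label {label!r}")
    order = {pid: i for i, pid in enumerate(exp.protein_ids)}

    fig, ax = plt.subplots(figsize=(8, 4))
    cmap = plt.get_cmap("tab10")
    xs = np.arange(exp.n_fractions)
    n_lines = 0
    for c, label in enumerate(clusters):
        for pid in markers.members(label):
            if pid not in order:
                continue
            ax.plot(xs, exp.values[order[pid]], color=cmap(c % 10), alpha=0.5, lw=0.8)
            n_lines += 1
        ax.plot([], [], color=cmap(c % 10), label=label)
    ax.set_xticks(xs)
    ax.set_xticklabels(exp.fraction_ids, rotation=90, fontsize=7)
    ax.set_ylabel("quantitation")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out)
    plt.close(fig)
    return {"n_lines": n_lines, "clusters": clusters}


def marker_dendrogram(
    exp: ProfileExperiment,
    markers: MarkerAnnotation,
    out=None,
):
    """Average-linkage tree over per-cluster mean profiles.

    Cluster mean profiles use a missing-aware per-fraction mean; the
    pairwise distances between mean profiles use the same scaled
    pairwise-complete convention as the separation metric.
    """
    markers = markers.restrict_to(exp)
    labels = markers.cluster_labels
    if len(labels) < 2:
        raise QSepError("dendrogram needs at least two clusters")
    order = {pid: i for i, pid in enumerate(exp.protein_ids)}
    means = np.vstack([
        np.nanmean(exp.values[[order[p] for p in markers.members(label)]], axis=0)
        for label in labels
    ])
    dist = pairwise_distances(means)
    condensed = dist[np.triu_indices(len(labels), k=1)]
    if not np.isfinite(condensed).all():
        raise QSepError("undefined distance between cluster mean profiles")
    linkage = hierarchy.linkage(condensed, method="average")

    fig, ax = plt.subplots(figsize=(6, 4))
    hierarchy.dendrogram(linkage, labels=list(labels), ax=ax, leaf_rotation=90)
    ax.set_ylabel("average profile distance")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out)
    plt.close(fig)
    return {"linkage": linkage, "labels": labels}


def plot_qsep(
    raw: ClusterDistanceMatrix,
    q: QSepMatrix,
    out_prefix=None,
    norm_vlim: tuple[float, float] | None = None,
    fig_format: str = "png",
):
    """Raw/normalised heatmaps plus per-reference-cluster boxplots.

    ``norm_vlim`` pins the normalised heatmap's colour scale, allowing a
    shared scale across experiments. Returns the plotted data layers.
    """
    if raw.labels != q.labels:
        raise QSepError("label mismatch between raw and normalised matrices")
    k = raw.k
    labels = list(raw.labels)

    fig, axes = plt.subplots(1, 2, figsize=(11, 5))
    im0 = axes[0].imshow(raw.values, cmap="viridis")
    axes[0].set_title("raw distances")
    vmin, vmax = norm_vlim if norm_vlim is not None else (None, None)
    im1 = axes[1].imshow(q.values, cmap="RdBu_r", vmin=vmin, vmax=vmax)
    axes[1].set_title("normalised distances")
    for ax, im in zip(axes, (im0, im1)):
        ax.set_xticks(range(k))
        ax.set_yticks(range(k))
        ax.set_xticklabels(labels, rotation=90, fontsize=7)
        ax.set_yticklabels(labels, fontsize=7)
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    heatmap_path = None
    if out_prefix is not None:
        heatmap_path = f"{out_prefix}_heatmaps.{fig_format}"
        fig.savefig(heatmap_path)
    plt.close(fig)

    summary = summarize(q)
    fig, ax = plt.subplots(figsize=(6, 0.45 * k + 2))
    rows = [summary.per_cluster[label] for label in labels]
    ax.boxplot(rows, orientation="horizontal", tick_labels=labels)
    ax.axvline(1.0, color="red", lw=1, label="within (= 1)")
    ax.axvline(summary.median_between, color="grey", ls="--", lw=1,
               label=f"median = {summary.median_between:.2f}")
    ax.set_xlabel("normalised distance to reference cluster")
    ax.legend(fontsize=8)
    fig.tight_layout()
    boxplot_path = None
    if out_prefix is not None:
        boxplot_path = f"{out_prefix}_boxplots.{fig_format}"
        fig.savefig(boxplot_path)
    plt.close(fig)

    return {
        "heatmap_raw": raw.values,
        "heatmap_norm": q.values,
        "box_data": rows,
        "median_line": summary.median_between,
        "heatmap_path": heatmap_path,
        "boxplot_path": boxplot_path,
    }
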