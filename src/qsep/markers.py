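"""Marker-set hygiene and cross-dataset marker transfer.

Sub-cellular clusters are only as trustworthy as their marker lists; a
cluster backed by a handful of proteins yields unstable within-cluster
averages. The conventional floor is seven markers per cluster; smaller
clusters are dissolved (their proteins relabelled unknown) rather than
silently kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

from .core import MarkerAnnotation, ProfileExperiment, QSepError

logger = logging.getLogger(__name__)

DEFAULT_MIN_MARKERS = 7


@dataclass(frozen=True)
class FilterReport:
    """What a minimum-size filter did."""

    dissolved: dict[str, int] = field(default_factory=dict)  # label -> size
    kept: dict[str, int] = field(default_factory=dict)

    def __str__(self) -> str:
        if not self.dissolved:
            return f"kept all {len(self.kept)} clusters"
        gone = ", ".join(f"{l} ({n})" for l, n in sorted(self.dissolved.items()))
        return f"dissolved {len(self.dissolved)} cluster(s): {gone}; kept {len(self.kept)}"


def filter_min_markers(
    markers: MarkerAnnotation,
    exp: ProfileExperiment,
    min_n: int = DEFAULT_MIN_MARKERS,
) -> tuple[MarkerAnnotation, FilterReport]:
    """Dissolve clusters with fewer than ``min_n`` markers present in ``exp``.

    Returns the filtered annotation and a report of dissolved clusters.
    Idempotent. Raises if fewer than two clusters survive.
    """
    if min_n < 2:
        raise QSepError(f"min_n must be >= 2, got {min_n}")
    sizes = markers.cluster_sizes(exp)
    dissolved = {l: n for l, n in sizes.items() if n < min_n}
    kept = {l: n for l, n in sizes.items() if n >= min_n}
    if len(kept) < 2:
        raise QSepError(
            f"fewer than two clusters with >= {min_n} markers survive the filter "
            f"(kept: {sorted(kept) or 'none'})"
        )
    present = set(exp.protein_ids)
    filtered = MarkerAnnotation(
        {
            pid: label
            for pid, label in markers.assignments.items()
            if label in kept and pid in present
        },
        unknown_label=markers.unknown_label,
    )
    report = FilterReport(dissolved=dissolved, kept=kept)
    if dissolved:
        logger.info("marker filter: %s", report)
    return filtered, report


def transfer_markers(
    source: MarkerAnnotation,
    target_exp: ProfileExperiment,
    min_n: int = DEFAULT_MIN_MARKERS,
    id_normalizer: Callable[[str], str] | None = None,
) -> tuple[MarkerAnnotation, FilterReport]:
    """Annotate ``target_exp`` with ``source``'s labels by identifier match.

    Each target protein found in the source receives the source label
    (replacing any native annotation); all others become unknown. The
    minimum-size filter is then re-applied, because the identifier
    intersection shrinks clusters. Matching is exact string equality by
    default; pass ``id_normalizer`` to, e.g., strip accession versions.
    """
    norm = id_normalizer if id_normalizer is not None else (lambda s: s)
    source_map = {norm(pid): label for pid, label in source.assignments.items()}
    assignments = {}
    for pid in target_exp.protein_ids:
        label = source_map.get(norm(pid))
        if label is not None:
            assignments[pid] = label
    if not assignments:
        raise QSepError("no target protein matches any source marker identifier")
    transferred = MarkerAnnotation(assignments, unknown_label=source.unknown_label)
    return filter_min_markers(transferred, target_exp, min_n=min_n)
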