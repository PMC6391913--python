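"""Core data model and delimited-text I/O for fractionation profile data.

A spatial proteomics experiment is a proteins x fractions matrix of
relative quantitation values ("occupancy profiles"), together with
per-protein metadata, of which one column may hold curated sub-cellular
marker labels. Missing quantitation values are first-class citizens:
they are preserved on input and only replaced by zeros in an explicit
view used for visualisation, never for distance computations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Cell contents recognised as missing quantitation on input (case-insensitive).
DEFAULT_NA_TOKENS = ("", "na", "nan")

#: Reserved label for proteins without a sub-cellular assignment.
UNKNOWN_LABEL = "unknown"


class QSepError(Exception):
    """Base class for input/validation errors raised by this package."""


@dataclass(frozen=True)
class ProfileExperiment:
    """Proteins x fractions quantitation matrix with identifiers and metadata.

    Parameters
    ----------
    protein_ids
        Unique, non-empty protein identifiers (row names).
    fraction_ids
        Ordered fraction identifiers (column names), at least two.
    values
        Real matrix of shape ``(n_proteins, n_fractions)``. Missing
        entries are ``NaN``; every non-missing entry must be finite.
    feature_meta
        Per-protein annotations indexed by ``protein_ids``. May be empty.
    """

    protein_ids: tuple[str, ...]
    fraction_ids: tuple[str, ...]
    values: np.ndarray
    feature_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "protein_ids", tuple(str(p) for p in self.protein_ids))
        object.__setattr__(self, "fraction_ids", tuple(str(f) for f in self.fraction_ids))

        n, p = values.shape if values.ndim == 2 else (0, 0)
        if values.ndim != 2:
            raise QSepError("profile matrix must be two-dimensional")
        if n < 1:
            raise QSepError("experiment must contain at least one protein")
        if p < 2:
            raise QSepError("experiment must contain at least two fractions")
        if len(self.protein_ids) != n:
            raise QSepError(
                f"{len(self.protein_ids)} protein ids for {n} matrix rows"
            )
        if len(self.fraction_ids) != p:
            raise QSepError(
                f"{len(self.fraction_ids)} fraction ids for {p} matrix columns"
            )
        if any(not pid for pid in self.protein_ids):
            raise QSepError("protein ids must be non-empty strings")
        dupes = _duplicates(self.protein_ids)
        if dupes:
            raise QSepError(f"duplicate protein ids: {', '.join(sorted(dupes))}")
        if np.isinf(values).any():
            raise QSepError("profile matrix contains non-finite (infinite) values")

        meta = self.feature_meta
        if meta is None or meta.empty:
            meta = pd.DataFrame(index=pd.Index(self.protein_ids, name="protein_id"))
        else:
            meta = meta.copy()
            meta.index = pd.Index(self.protein_ids, name="protein_id")
        object.__setattr__(self, "feature_meta", meta)

    # -- basic introspection -------------------------------------------------

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_fractions(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Profile matrix as a DataFrame (rows: proteins, columns: fractions)."""
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.protein_ids, name="protein_id"),
            columns=list(self.fraction_ids),
        )

    def subset(self, protein_ids: Sequence[str]) -> "ProfileExperiment":
        """Row-subset the experiment, keeping the given protein order."""
        index = {pid: i for i, pid in enumerate(self.protein_ids)}
        try:
            rows = [index[pid] for pid in protein_ids]
        except KeyError as exc:
            raise QSepError(f"unknown protein id: {exc.args[0]}") from exc
        return ProfileExperiment(
            protein_ids=tuple(protein_ids),
            fraction_ids=self.fraction_ids,
            values=self.values[rows],
            feature_meta=self.feature_meta.iloc[rows],
        )


@dataclass(frozen=True)
class MarkerAnnotation:
    """Mapping of protein identifiers to sub-cellular cluster labels.

    Proteins absent from ``assignments`` (or mapped to ``unknown_label``)
    are unannotated; the unknown label is never counted as a cluster.
    """

    assignments: Mapping[str, str]
    unknown_label: str = UNKNOWN_LABEL

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for pid, label in dict(self.assignments).items():
            label = str(label)
            if not label:
                raise QSepError(f"empty cluster label for protein {pid!r}")
            if label != self.unknown_label:
                clean[str(pid)] = label
        object.__setattr__(self, "assignments", clean)

    @property
    def cluster_labels(self) -> tuple[str, ...]:
        """Distinct non-unknown labels, in order of first appearance."""
        seen: dict[str, None] = {}
        for label in self.assignments.values():
            seen.setdefault(label, None)
        return tuple(seen)

    def label_of(self, protein_id: str) -> str:
        return self.assignments.get(protein_id, self.unknown_label)

    def members(self, label: str) -> tuple[str, ...]:
        """Protein ids assigned to ``label``, in insertion order."""
        return tuple(p for p, l in self.assignments.items() if l == label)

    def cluster_sizes(self, exp: ProfileExperiment | None = None) -> dict[str, int]:
        """Cluster sizes, optionally restricted to proteins present in ``exp``."""
        present = set(exp.protein_ids) if exp is not None else None
        sizes: dict[str, int] = {label: 0 for label in self.cluster_labels}
        for pid, label in self.assignments.items():
            if present is None or pid in present:
                sizes[label] += 1
        return sizes

    def restrict_to(self, exp: ProfileExperiment) -> "MarkerAnnotation":
        """Drop assignments whose protein id is absent from ``exp``."""
        present = set(exp.protein_ids)
        return MarkerAnnotation(
            {p: l for p, l in self.assignments.items() if p in present},
            unknown_label=self.unknown_label,
        )

    def validate_against(self, exp: ProfileExperiment) -> None:
        missing = [p for p in self.assignments if p not in set(exp.protein_ids)]
        if missing:
            raise QSepError(
                "marker annotation references proteins absent from the "
                f"experiment: {', '.join(sorted(missing)[:5])}"
                + ("..." if len(missing) > 5 else "")
            )


# ---------------------------------------------------------------------------
# I/O


def read_experiment(
    path,
    marker_column: str | None = None,
    delimiter: str = "\t",
    unknown_label: str = UNKNOWN_LABEL,
    id_column: str | None = None,
    na_tokens: Iterable[str] = DEFAULT_NA_TOKENS,
) -> tuple[ProfileExperiment, MarkerAnnotation]:
    """Read a delimited-text profile table.

    The first column (or ``id_column`` if given) holds protein identifiers;
    all columns that parse as numeric become the fraction matrix; remaining
    columns become feature metadata. ``marker_column`` designates the
    metadata column holding cluster labels; empty/NA marker cells map to
    ``unknown_label``. Missing quantitation cells are preserved as ``NaN``.
    """
    na_set = {t.lower() for t in na_tokens}
    table = pd.read_csv(
        path, sep=delimiter, dtype=str, keep_default_na=False, encoding="utf-8"
    )
    if table.shape[1] < 2:
        raise QSepError(f"{path}: expected at least an id column and one data column")

    id_col = id_column if id_column is not None else table.columns[0]
    if id_col not in table.columns:
        raise QSepError(f"{path}: id column {id_col!r} not found")
    ids = [s.strip() for s in table[id_col].tolist()]
    dupes = _duplicates(ids)
    if dupes:
        raise QSepError(f"{path}: duplicate protein ids: {', '.join(sorted(dupes))}")

    if marker_column is not None and marker_column not in table.columns:
        raise QSepError(f"{path}: marker column {marker_column!r} not found")

    numeric_cols: list[str] = []
    meta_cols: list[str] = []
    parsed: dict[str, np.ndarray] = {}
    for col in table.columns:
        if col == id_col or col == marker_column:
            if col == marker_column:
                meta_cols.append(col)
            continue
        values, kind, bad_row = _parse_numeric(table[col], na_set)
        if kind == "numeric":
            if np.isinf(values).any():
                row = int(np.flatnonzero(np.isinf(values))[0])
                raise QSepError(
                    f"{path}: non-finite value in fraction column {col!r}, row {row + 2}"
                )
            numeric_cols.append(col)
            parsed[col] = values
        elif kind == "mixed":
            # a column with both numbers and stray tokens is a corrupt
            # fraction column, not metadata
            raise QSepError(
                f"{path}: non-numeric value in fraction column {col!r}, row {bad_row + 2}"
            )
        else:
            meta_cols.append(col)

    if len(numeric_cols) < 2:
        raise QSepError(f"{path}: found {len(numeric_cols)} numeric fraction columns, need >= 2")

    matrix = np.column_stack([parsed[c] for c in numeric_cols])
    meta = table[meta_cols].copy() if meta_cols else pd.DataFrame(index=table.index)
    meta.index = pd.Index(ids, name="protein_id")

    exp = ProfileExperiment(
        protein_ids=tuple(ids),
        fraction_ids=tuple(numeric_cols),
        values=matrix,
        feature_meta=meta,
    )

    assignments: dict[str, str] = {}
    if marker_column is not None:
        for pid, raw in zip(ids, table[marker_column].tolist()):
            label = raw.strip()
            if not label or label.lower() in na_set:
                continue
            assignments[pid] = label
    markers = MarkerAnnotation(assignments, unknown_label=unknown_label)
    return exp, markers


def write_experiment(
    exp: ProfileExperiment,
    path,
    markers: MarkerAnnotation | None = None,
    marker_column: str = "markers",
    delimiter: str = "\t",
) -> None:
    """Write an experiment (and optional marker column) as delimited text.

    Round-trips exactly through :func:`read_experiment`: missing entries
    are written as empty cells.
    """
    frame = exp.to_frame()
    if markers is not None:
        frame[marker_column] = [markers.label_of(p) for p in exp.protein_ids]
    frame.to_csv(path, sep=delimiter, na_rep="", encoding="utf-8")


# ---------------------------------------------------------------------------
# Dataset-level conventions


def combine_replicates(experiments: Sequence[ProfileExperiment]) -> ProfileExperiment:
    """Join replicate experiments on the protein-id intersection.

    Fraction columns are concatenated in input order and disambiguated by
    a ``.repN`` suffix; feature metadata is taken from the first replicate.
    """
    if len(experiments) < 2:
        raise QSepError("need at least two experiments to combine")
    common: list[str] = [pid for pid in experiments[0].protein_ids]
    for exp in experiments[1:]:
        present = set(exp.protein_ids)
        common = [pid for pid in common if pid in present]
    if not common:
        raise QSepError("protein-id intersection of the replicates is empty")

    blocks = []
    fraction_ids: list[str] = []
    for r, exp in enumerate(experiments, start=1):
        sub = exp.subset(common)
        blocks.append(sub.values)
        fraction_ids.extend(f"{fid}.rep{r}" for fid in sub.fraction_ids)
    dupes = _duplicates(fraction_ids)
    if dupes:
        raise QSepError(f"duplicate fraction ids after suffixing: {', '.join(sorted(dupes))}")

    first_meta = experiments[0].subset(common).feature_meta
    return ProfileExperiment(
        protein_ids=tuple(common),
        fraction_ids=tuple(fraction_ids),
        values=np.hstack(blocks),
        feature_meta=first_meta,
    )


def zero_imputed_view(exp: ProfileExperiment) -> ProfileExperiment:
    """Copy of ``exp`` with every missing entry replaced by zero.

    For dimensionality reduction and visualisation only — the distance
    engine always consumes the raw, non-imputed matrix.
    """
    values = exp.values.copy()
    mask = np.isnan(values)
    if mask.all(axis=1).any():
        n_bad = int(mask.all(axis=1).sum())
        logger.warning("zero-imputing %d all-missing protein profile(s)", n_bad)
    values[mask] = 0.0
    return ProfileExperiment(
        protein_ids=exp.protein_ids,
        fraction_ids=exp.fraction_ids,
        values=values,
        feature_meta=exp.feature_meta,
    )


def missing_fraction(exp: ProfileExperiment) -> float:
    """Proportion of missing entries in the quantitation matrix, in [0, 1]."""
    return float(np.isnan(exp.values).mean())


# ---------------------------------------------------------------------------


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for item in items:
        if item in seen:
            dupes.add(item)
        seen.add(item)
    return dupes


def _parse_numeric(
    column: pd.Series, na_set: set[str]
) -> tuple[np.ndarray, str, int]:
    """Parse a string column to floats.

    Returns ``(values, kind, first_bad_row)`` where kind is "numeric"
    (all non-NA cells parse), "meta" (no cell parses) or "mixed" (some
    parse, some don't — a corrupt fraction column). NA tokens become NaN.
    """
    out = np.empty(len(column), dtype=float)
    n_parsed = 0
    first_bad = -1
    for i, cell in enumerate(column.tolist()):
        text = cell.strip()
        if not text or text.lower() in na_set:
            out[i] = np.nan
            continue
        try:
            out[i] = float(text)
            n_parsed += 1
        except ValueError:
            out[i] = np.nan
            if first_bad < 0:
                first_bad = i
    if first_bad < 0:
        return out, "numeric", -1
    if n_parsed > 0:
        return out, "mixed", first_bad
    return out, "meta", first_bad
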