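"""Loader for flat exports of published benchmark datasets.

The published numbers this package can reproduce are computed on datasets
distributed through the Bioconductor ``pRolocdata`` package. Those data
cannot be redistributed here; to use them, export each dataset as an
uncompressed TSV with a ``markers`` column (see the README for an R
snippet) and place it under ``data/external/<name>.tsv`` in the
repository root (or point ``QSEP_DATA_DIR`` elsewhere).
"""

from __future__ import annotations

import os
from pathlib import Path

from .core import MarkerAnnotation, ProfileExperiment, read_experiment

#: Dataset names used by the published benchmark computations.
KNOWN_DATASETS = (
    "hyperLOPIT2015",
    "itzhak2016stcSILAC",
    "E14TG2aS1",
    "foster2006",
)


def external_data_dir() -> Path:
    env = os.environ.get("QSEP_DATA_DIR")
    if env:
        return Path(env)
    return Path(__file__).resolve().parents[2] / "data" / "external"


def external_data_path(name: str) -> Path:
    return external_data_dir() / f"{name}.tsv"


def has_external_data(name: str) -> bool:
    return external_data_path(name).is_file()


def load_external(name: str) -> tuple[ProfileExperiment, MarkerAnnotation]:
    """Load a flat export of a published dataset.

    Raises ``FileNotFoundError`` with setup instructions when the export
    is absent (the data must be produced locally from pRolocdata; it is
    not bundled and cannot be downloaded in an offline environment).
    """
    path = external_data_path(name)
    if not path.is_file():
        raise FileNotFoundError(
            f"flat export not found: {path}. Export {name!r} from the "
            "Bioconductor pRolocdata package as TSV with a 'markers' column "
            "(see README, section 'Reproducing published numbers') and place "
            "it at that path, or set QSEP_DATA_DIR."
        )
    return read_experiment(path, marker_column="markers")
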