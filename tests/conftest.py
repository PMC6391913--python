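import numpy as np
import pytest

from qsep import MarkerAnnotation, ProfileExperiment
from qsep.synthetic import SyntheticTruth, generate


@pytest.fixture
def toy_experiment():
    """Two 2-marker clusters on an effectively 1-D profile space.

    Cluster A at coordinates {0, 2}, cluster B at {10, 12}: within-A = 2,
    within-B = 2, between = mean(10, 12, 8, 10) = 10.
    """
    values = np.array([[0.0, 0.0], [2.0, 0.0], [10.0, 0.0], [12.0, 0.0]])
    exp = ProfileExperiment(
        protein_ids=("a1", "a2", "b1", "b2"),
        fraction_ids=("F1", "F2"),
        values=values,
    )
    markers = MarkerAnnotation({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
    return exp, markers


@pytest.fixture
def symmetric_three_clusters():
    """Three pairwise-equidistant 2-marker clusters.

    Centers at e1, e2, e3 (pairwise distance sqrt(2) computed identically
    from the same coordinates); each cluster's second marker is offset by
    0.5 along the fourth axis, orthogonal to the center plane. All within
    distances and all between-pair averages are bitwise identical.
    """
    centers = np.eye(3, 4)
    offset = np.array([0.0, 0.0, 0.0, 0.5])
    rows, ids, labels = [], [], {}
    for c in range(3):
        label = f"C{c + 1}"
        for m, point in enumerate((centers[c], centers[c] + offset)):
            pid = f"{label}m{m + 1}"
            rows.append(point)
            ids.append(pid)
            labels[pid] = label
    exp = ProfileExperiment(
        protein_ids=tuple(ids),
        fraction_ids=("F1", "F2", "F3", "F4"),
        values=np.array(rows),
    )
    return exp, MarkerAnnotation(labels)


@pytest.fixture
def synthetic_dataset():
    truth = SyntheticTruth(
        k=4, p=8, n_per_cluster=10, n_unknown=20, delta=1.5, sigma=0.15, seed=11
    )
    return generate(truth)


@pytest.fixture
def sim_tsv(tmp_path, synthetic_dataset):
    from qsep import write_experiment

    exp, markers = synthetic_dataset
    path = tmp_path / "sim.tsv"
    write_experiment(exp, path, markers=markers)
    return path
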