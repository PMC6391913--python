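import numpy as np
import pytest

from qsep import (
    MarkerAnnotation,
    ProfileExperiment,
    QSepError,
    cluster_distance_matrix,
    marker_dendrogram,
    normalize,
    pca_project,
    plot_pca,
    plot_profiles,
    plot_qsep,
    summarize,
)
from qsep.synthetic import SyntheticTruth, generate


class TestPCAProject:
    def test_rank2_data_sums_to_one(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 5))
        coords = rng.normal(size=(30, 2))
        values = coords @ basis + rng.normal(size=5)  # affine rank-2
        exp = ProfileExperiment(
            tuple(f"P{i}" for i in range(30)),
            tuple(f"F{j}" for j in range(5)),
            values,
        )
        res = pca_project(exp, n_components=2)
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-12)

    def test_variance_fractions_match_eigendecomposition(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(6, 4))
        exp = ProfileExperiment(
            tuple(f"P{i}" for i in range(6)), tuple(f"F{j}" for j in range(4)), values
        )
        res = pca_project(exp)
        centred = values - values.mean(axis=0)
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(centred.T)))[::-1]
        np.testing.assert_allclose(
            res.variance_fraction, eigvals[: len(res.variance_fraction)] / eigvals.sum(),
            atol=1e-12,
        )

    def test_total_variance_conserved(self, synthetic_dataset):
        exp, _ = synthetic_dataset
        res = pca_project(exp)
        centred = exp.values - exp.values.mean(axis=0)
        total = (centred**2).sum()
        recovered = (res.scores**2).sum()
        assert recovered == pytest.approx(total, rel=1e-12)

    def test_variance_fractions_non_increasing(self, synthetic_dataset):
        exp, _ = synthetic_dataset
        res = pca_project(exp)
        assert (np.diff(res.variance_fraction) <= 1e-15).all()
        assert res.variance_fraction.sum() <= 1 + 1e-12

    def test_row_order_invariance(self, synthetic_dataset):
        exp, _ = synthetic_dataset
        res = pca_project(exp)
        perm = np.random.default_rng(2).permutation(exp.n_proteins)
        shuffled = exp.subset([exp.protein_ids[i] for i in perm])
        res2 = pca_project(shuffled)
        np.testing.assert_allclose(res.scores[perm], res2.scores, atol=1e-9)

    def test_constant_matrix_rejected(self):
        exp = ProfileExperiment(("a", "b"), ("F1", "F2"), np.ones((2, 2)))
        with pytest.raises(QSepError, match="constant"):
            pca_project(exp)

    def test_deterministic_sign(self, synthetic_dataset):
        exp, _ = synthetic_dataset
        a = pca_project(exp)
        b = pca_project(exp)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_uses_zero_imputed_view(self, synthetic_dataset):
        from qsep import zero_imputed_view

        exp, _ = synthetic_dataset
        values = exp.values.copy()
        values[0, 0] = np.nan
        exp_na = ProfileExperiment(exp.protein_ids, exp.fraction_ids, values)
        res = pca_project(exp_na)
        res_imputed = pca_project(zero_imputed_view(exp_na))
        np.testing.assert_allclose(res.scores, res_imputed.scores, atol=1e-12)


class TestPlotPCA:
    @pytest.fixture
    def projected(self, synthetic_dataset):
        exp, markers = synthetic_dataset
        return exp, markers, pca_project(exp, n_components=2)

    @pytest.mark.parametrize("style", ["plain", "alpha", "hexbin"])
    def test_smoke(self, tmp_path, projected, style):
        exp, markers, res = projected
        out = tmp_path / f"{style}.png"
        plot_pca(res, style=style, out=out)
        assert out.exists() and out.stat().st_size > 0

    def test_annotated_legend_contract(self, tmp_path, projected):
        exp, markers, res = projected
        out = tmp_path / "annot.png"
        data = plot_pca(res, markers=markers, style="annotated", out=out,
                        protein_ids=exp.protein_ids)
        labels = set(data["labels"])
        assert labels == set(markers.cluster_labels) | {"unknown"}

    def test_annotated_without_markers_errors(self, projected):
        _, _, res = projected
        with pytest.raises(QSepError, match="marker"):
            plot_pca(res, style="annotated")

    def test_plain_and_alpha_share_coordinates(self, projected):
        _, _, res = projected
        a = plot_pca(res, style="plain")
        b = plot_pca(res, style="alpha")
        np.testing.assert_array_equal(a["x"], b["x"])
        np.testing.assert_array_equal(a["y"], b["y"])

    def test_unknown_style_rejected(self, projected):
        _, _, res = projected
        with pytest.raises(QSepError, match="style"):
            plot_pca(res, style="fancy")


class TestPlotProfiles:
    def test_smoke_and_line_count(self, tmp_path, synthetic_dataset):
        exp, markers = synthetic_dataset
        chosen = list(markers.cluster_labels[:2])
        out = tmp_path / "profiles.png"
        data = plot_profiles(exp, markers, chosen, out=out)
        assert out.exists() and out.stat().st_size > 0
        expected = sum(len(markers.members(l)) for l in chosen)
        assert data["n_lines"] == expected

    def test_zero_clusters_errors(self, synthetic_dataset):
        exp, markers = synthetic_dataset
        with pytest.raises(QSepError, match="at least one"):
            plot_profiles(exp, markers, [])

    def test_unknown_cluster_errors(self, synthetic_dataset):
        exp, markers = synthetic_dataset
        with pytest.raises(QSepError, match="nope"):
            plot_profiles(exp, markers, ["nope"])


class TestMarkerDendrogram:
    def test_two_clusters_single_merge(self, tmp_path, toy_experiment):
        exp, markers = toy_experiment
        out = tmp_path / "dendro.png"
        data = marker_dendrogram(exp, markers, out=out)
        assert out.exists()
        linkage = data["linkage"]
        assert linkage.shape == (1, 4)
        # merge height = distance between mean profiles: means at 1 and 11
        assert linkage[0, 2] == pytest.approx(10.0)

    def test_distant_cluster_merges_last(self):
        # centers: A at 0, B at 1, C at 50 along F1
        rows, ids, labels = [], [], {}
        for label, center in (("A", 0.0), ("B", 1.0), ("C", 50.0)):
            for m in range(2):
                pid = f"{label}{m}"
                ids.append(pid)
                rows.append([center + 0.1 * m, 0.0])
                labels[pid] = label
        exp = ProfileExperiment(tuple(ids), ("F1", "F2"), np.array(rows))
        data = marker_dendrogram(exp, MarkerAnnotation(labels))
        linkage = data["linkage"]
        # first merge joins A and B (leaves 0 and 1); C joins at the root
        assert set(linkage[0, :2].astype(int)) == {0, 1}
        assert linkage[1, 2] > linkage[0, 2]

    def test_cluster_order_invariance(self, synthetic_dataset):
        exp, markers = synthetic_dataset
        data = marker_dendrogram(exp, markers)
        reordered = MarkerAnnotation(
            dict(sorted(markers.assignments.items(), reverse=True))
        )
        data2 = marker_dendrogram(exp, reordered)
        np.testing.assert_allclose(
            np.sort(data["linkage"][:, 2]), np.sort(data2["linkage"][:, 2]),
            atol=1e-12,
        )

    def test_single_cluster_errors(self, toy_experiment):
        exp, _ = toy_experiment
        markers = MarkerAnnotation({"a1": "A", "a2": "A"})
        with pytest.raises(QSepError, match="two clusters"):
            marker_dendrogram(exp, markers)


class TestPlotQSep:
    def test_smoke_and_contracts(self, tmp_path, synthetic_dataset):
        exp, markers = synthetic_dataset
        raw = cluster_distance_matrix(exp, markers)
        q = normalize(raw)
        data = plot_qsep(raw, q, out_prefix=str(tmp_path / "qsep"))
        assert (tmp_path / "qsep_heatmaps.png").exists()
        assert (tmp_path / "qsep_boxplots.png").exists()
        assert len(data["box_data"]) == raw.k
        assert data["median_line"] == summarize(q).median_between

    def test_label_mismatch_errors(self, synthetic_dataset, toy_experiment):
        exp, markers = synthetic_dataset
        raw = cluster_distance_matrix(exp, markers)
        exp2, markers2 = toy_experiment
        q2 = normalize(cluster_distance_matrix(exp2, markers2))
        with pytest.raises(QSepError, match="mismatch"):
            plot_qsep(raw, q2)

    def test_inputs_not_mutated(self, synthetic_dataset):
        exp, markers = synthetic_dataset
        raw = cluster_distance_matrix(exp, markers)
        q = normalize(raw)
        before_raw = raw.values.copy()
        before_q = q.values.copy()
        plot_qsep(raw, q)
        np.testing.assert_array_equal(raw.values, before_raw)
        np.testing.assert_array_equal(q.values, before_q)
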