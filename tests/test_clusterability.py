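import numpy as np
import pandas as pd
import pytest

from cgemkit.clusterability import (
    FluxMatrix,
    build_flux_matrix,
    pca_cluster,
    rf_importance,
    subsystem_barcode,
)
from cgemkit.flux_core import FluxState
from cgemkit.model_io import MetabolicModel, Reaction


def fm_from_array(X, columns=None):
    columns = columns or [f"r{i}" for i in range(X.shape[1])]
    values = pd.DataFrame(X, index=[f"s{i}" for i in range(X.shape[0])],
                          columns=columns)
    return FluxMatrix(values=values, metadata=pd.DataFrame(index=values.index))


def blobs(rng, centers, n_per, sd=0.05, p=10):
    rows, labels = [], []
    for k, center in enumerate(centers):
        for _ in range(n_per):
            rows.append(center + rng.normal(0, sd, size=p))
            labels.append(k)
    return np.array(rows), labels


class TestPcaCluster:
    def test_two_separated_blobs(self):
        rng = np.random.default_rng(0)
        c = np.zeros(10)
        X, _ = blobs(rng, [c, c + 5.0], n_per=10)
        rep = pca_cluster(fm_from_array(X), random_state=0)
        assert rep.n_clusters == 2

    def test_single_isotropic_cloud_reports_one_cluster(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, size=(30, 10))
        rep = pca_cluster(fm_from_array(X), random_state=0)
        assert rep.n_clusters == 1

    def test_constant_matrix_degenerates_gracefully(self):
        rep = pca_cluster(fm_from_array(np.ones((5, 4))), random_state=0)
        assert rep.n_clusters == 1
        assert rep.labels is None

    def test_four_planted_groups_recovered(self):
        rng = np.random.default_rng(2)
        centers = [np.zeros(12) for _ in range(4)]
        for k in range(4):
            centers[k] = np.zeros(12)
            centers[k][3 * k : 3 * k + 3] = 2.0 + 0.3 * k
        X, labels = blobs(rng, centers, n_per=6, sd=0.05, p=12)
        rep = pca_cluster(fm_from_array(X), random_state=0)
        from sklearn.metrics import adjusted_rand_score

        assert rep.n_clusters == 4
        got = [rep.labels[s] for s in rep.pc_scores.index]
        assert adjusted_rand_score(labels, got) >= 0.8

    def test_explained_variance_sums_to_one(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, size=(15, 6))
        rep = pca_cluster(fm_from_array(X), random_state=0)
        assert sum(rep.explained_variance) == pytest.approx(1.0, abs=1e-9)
        assert all(0 <= f <= 1 for f in rep.explained_variance)
        assert list(rep.explained_variance) == sorted(
            rep.explained_variance, reverse=True
        )

    def test_invariant_to_column_permutation(self):
        rng = np.random.default_rng(4)
        c = np.zeros(8)
        X, _ = blobs(rng, [c, c + 3.0, c - 3.0], n_per=5, p=8)
        fm = fm_from_array(X)
        perm = rng.permutation(X.shape[1])
        fm_p = fm_from_array(X[:, perm])
        a = pca_cluster(fm, random_state=0)
        b = pca_cluster(fm_p, random_state=0)
        assert a.n_clusters == b.n_clusters
        from sklearn.metrics import adjusted_rand_score

        got_a = [a.labels[s] for s in fm.samples]
        got_b = [b.labels[s] for s in fm.samples]
        assert adjusted_rand_score(got_a, got_b) == pytest.approx(1.0)

    def test_isotropic_noise_needs_nearly_all_components(self):
        # no low-rank structure: the first two PCs explain little variance
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, size=(40, 32))
        rep = pca_cluster(fm_from_array(X), random_state=0)
        assert sum(rep.explained_variance[:2]) < 0.25

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pca_cluster(fm_from_array(np.ones((2, 3))))


class TestRfImportance:
    def test_single_informative_feature_ranked_first(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, size=(40, 10))
        y = (np.arange(40) >= 20).astype(int)
        X[:, 7] = y * 5.0 + rng.normal(0, 0.01, size=40)
        fm = fm_from_array(X)
        labels = {s: int(v) for s, v in zip(fm.samples, y)}
        rep = rf_importance(fm, labels, k=3, random_state=0)
        assert rep.top_k[0] == "r7"

    def test_permuted_labels_yield_no_dominant_feature(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, size=(30, 8))
        fm = fm_from_array(X)
        y = np.array([0] * 15 + [1] * 15)
        maxima = []
        for shuffle in range(50):
            rng.shuffle(y)
            labels = {s: int(v) for s, v in zip(fm.samples, y)}
            rep = rf_importance(fm, labels, ntree=50, random_state=shuffle)
            maxima.append(rep.importances.iloc[0])
        # under the permutation null importances stay spread out
        assert np.mean(maxima) < 0.5

    def test_reproducible_bit_for_bit_with_fixed_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, size=(30, 12))
        fm = fm_from_array(X)
        labels = {s: i % 3 for i, s in enumerate(fm.samples)}
        a = rf_importance(fm, labels, random_state=7)
        b = rf_importance(fm, labels, random_state=7)
        assert a.importances.equals(b.importances)
        assert a.top_k == b.top_k

    def test_single_class_rejected(self):
        fm = fm_from_array(np.random.default_rng(3).normal(size=(10, 4)))
        with pytest.raises(ValueError, match="2 classes"):
            rf_importance(fm, {s: 0 for s in fm.samples})

    def test_subsystem_frequency_sums_to_k(self):
        model = MetabolicModel(
            "m", [],
            [Reaction(f"r{i}", 0, 1, {}, subsystem=f"s{i % 3}") for i in range(12)],
        )
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, size=(20, 12))
        fm = fm_from_array(X)
        labels = {s: i % 2 for i, s in enumerate(fm.samples)}
        rep = rf_importance(fm, labels, model=model, k=5, random_state=0)
        assert sum(rep.subsystem_frequency.values()) == 5


class TestBarcode:
    def _report(self, freq, top):
        from cgemkit.clusterability import ImportanceReport

        return ImportanceReport(
            importances=pd.Series(dtype=float), top_k=tuple(top),
            subsystem_frequency=freq,
        )

    def test_single_report_passthrough(self):
        bc = subsystem_barcode([self._report({"glycolysis": 5}, ["a"] * 5)])
        assert bc.to_dict() == {"glycolysis": 5}

    def test_disjoint_reports_union(self):
        bc = subsystem_barcode(
            [self._report({"s1": 3}, []), self._report({"s2": 2}, [])]
        )
        assert bc.to_dict() == {"s1": 3, "s2": 2}
        assert list(bc.index) == ["s1", "s2"]  # ordered by count

    def test_shared_subsystem_accumulates_and_ranks_first(self):
        bc = subsystem_barcode(
            [
                self._report({"shared": 2, "s1": 1}, []),
                self._report({"shared": 3, "s2": 1}, []),
            ]
        )
        assert bc.index[0] == "shared"
        assert bc["shared"] == 5

    def test_empty_reports_rejected(self):
        with pytest.raises(ValueError):
            subsystem_barcode([])


class TestFluxMatrix:
    def test_absent_reactions_imputed_zero(self):
        a = FluxState("a", ("r1", "r2"), np.array([1.0, 2.0]), 0.0, None)
        b = FluxState("b", ("r1", "r3"), np.array([1.0, 3.0]), 0.0, None)
        fm = build_flux_matrix([a, b], ["r1", "r2", "r3"])
        assert fm.values.loc["a", "r3"] == 0.0
        assert fm.values.loc["b", "r2"] == 0.0

    def test_missing_entries_rejected(self):
        values = pd.DataFrame({"r": [np.nan]}, index=["s"])
        with pytest.raises(ValueError, match="missing"):
            FluxMatrix(values=values, metadata=pd.DataFrame(index=["s"]))
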