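"""Flux-fingerprint clusterability: PCA + k-means, random-forest feature
selection, and subsystem barcodes.

A *flux matrix* (samples x reactions, absent reactions imputed as zero) is the
feature table.  Cluster structure is assessed on the first two principal
components of the column-centered matrix; the number of clusters is the k in
2..max_k maximizing the mean silhouette of k-means on those scores, with a
single cluster declared when the best silhouette is below 0.55 — a floor
chosen above the maximum silhouette that k-means attains on the first two PCs
of isotropic (structure-free) Gaussian data, so that a noise cloud reports a
single cluster.  Where two or
more clusters exist, a random-forest classifier (impurity importance,
mTry = floor(sqrt(p)) candidate features per split) ranks the reactions that
discriminate the clusters; the top-k reactions are aggregated by subsystem
into a "barcode" of affected pathways.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import silhouette_score

from .flux_core import FluxState
from .model_io import MetabolicModel

__all__ = [
    "FluxMatrix",
    "ClusterReport",
    "ImportanceReport",
    "build_flux_matrix",
    "pca_cluster",
    "rf_importance",
    "subsystem_barcode",
]

SILHOUETTE_FLOOR = 0.55


@dataclass(frozen=True)
class FluxMatrix:
    """Samples x reactions flux table with row metadata."""

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("flux matrix must not contain missing entries")
        if not self.values.index.equals(self.metadata.index):
            raise ValueError("metadata index must match the flux matrix rows")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def reactions(self) -> list[str]:
        return list(self.values.columns)


def build_flux_matrix(
    flux_states: Sequence[FluxState],
    reactions: Sequence[str],
    metadata: pd.DataFrame | None = None,
    sample_ids: Sequence[str] | None = None,
    decimals: int = 6,
) -> FluxMatrix:
    """Assemble a flux matrix over a fixed reaction order.

    Reactions absent from a flux state are imputed as zero flux (they were
    removed from that CGEM and can carry none).  Fluxes are rounded at the
    solver's feasibility tolerance (``decimals``) — differences below it are
    numerical dust, not signal.
    """
    if sample_ids is None:
        sample_ids = [fs.model_id for fs in flux_states]
    rows = []
    for fs in flux_states:
        d = fs.as_dict()
        rows.append([round(d.get(r, 0.0), decimals) for r in reactions])
    values = pd.DataFrame(rows, index=list(sample_ids), columns=list(reactions))
    if metadata is None:
        metadata = pd.DataFrame(index=values.index)
    return FluxMatrix(values=values, metadata=metadata.loc[values.index])


@dataclass(frozen=True)
class ClusterReport:
    pc_scores: pd.DataFrame  # samples x 2
    explained_variance: tuple[float, ...]
    n_clusters: int
    labels: Mapping[str, int] | None
    silhouette: float

    def __post_init__(self) -> None:
        if self.labels is not None:
            object.__setattr__(self, "labels", dict(self.labels))


def pca_cluster(
    fm: FluxMatrix, max_k: int = 8, random_state: int = 0
) -> ClusterReport:
    """PCA of the centered flux matrix and silhouette-selected k-means.

    Columns are centered but not scaled to unit variance — flux magnitudes are
    the signal of interest.  Degenerate (constant) matrices report a single
    cluster with no labels.
    """
    X = fm.values.to_numpy(dtype=float)
    n_samples = X.shape[0]
    if n_samples < 3:
        raise ValueError("PCA clustering needs at least 3 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    nonconstant = (Xc.std(axis=0) > 0).sum()
    if nonconstant < 2:
        scores = pd.DataFrame(
            np.zeros((n_samples, 2)), index=fm.values.index, columns=["PC1", "PC2"]
        )
        return ClusterReport(
            pc_scores=scores,
            explained_variance=(),
            n_clusters=1,
            labels=None,
            silhouette=float("nan"),
        )
    n_comp = min(n_samples, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    transformed = pca.fit_transform(Xc)
    explained = tuple(float(f) for f in pca.explained_variance_ratio_)
    scores = pd.DataFrame(
        transformed[:, :2], index=fm.values.index, columns=["PC1", "PC2"]
    )
    pts = scores.to_numpy()
    # k-means cannot meaningfully exceed the number of distinct score points;
    # beyond it every extra cluster just splits coincident fingerprints
    n_distinct = len(np.unique(np.round(pts, 9), axis=0))
    best_k, best_sil, best_labels = 1, -1.0, None
    for k in range(2, min(max_k, n_samples - 1, n_distinct) + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=random_state)
        labels = km.fit_predict(pts)
        if len(np.unique(labels)) < 2:
            continue
        sil = float(silhouette_score(pts, labels))
        # strict improvement required: on ties (e.g. duplicated fingerprints)
        # the smallest cluster count wins
        if sil > best_sil + 1e-9:
            best_k, best_sil, best_labels = k, sil, labels
    if best_labels is None or best_sil < SILHOUETTE_FLOOR:
        return ClusterReport(
            pc_scores=scores,
            explained_variance=explained,
            n_clusters=1,
            labels=None,
            silhouette=best_sil,
        )
    return ClusterReport(
        pc_scores=scores,
        explained_variance=explained,
        n_clusters=best_k,
        labels=dict(zip(fm.values.index, (int(l) for l in best_labels))),
        silhouette=best_sil,
    )


@dataclass(frozen=True)
class ImportanceReport:
    importances: pd.Series  # reaction -> importance, descending
    top_k: tuple[str, ...]
    subsystem_frequency: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "subsystem_frequency", dict(self.subsystem_frequency))


def rf_importance(
    fm: FluxMatrix,
    labels: Mapping[str, int],
    model: MetabolicModel | None = None,
    ntree: int = 500,
    k: int = 15,
    random_state: int = 0,
) -> ImportanceReport:
    """Random-forest ranking of cluster-discriminative reactions.

    Fits a forest of ``ntree`` trees with sqrt(p) candidate features per split
    on the flux matrix against the given cluster labels (>= 2 classes
    required, mirroring the exclusion of unclusterable flux tables), ranks
    reactions by mean impurity decrease, and aggregates the top ``k`` by
    subsystem when a model is supplied.
    """
    y = np.array([labels[s] for s in fm.samples])
    if len(np.unique(y)) < 2:
        raise ValueError("random-forest feature selection needs >= 2 classes")
    X = fm.values.to_numpy(dtype=float)
    forest = RandomForestClassifier(
        n_estimators=ntree,
        max_features="sqrt",
        random_state=random_state,
    )
    forest.fit(X, y)
    imp = pd.Series(forest.feature_importances_, index=fm.reactions)
    imp = imp.sort_values(ascending=False, kind="mergesort")  # stable for ties
    top = tuple(imp.index[: min(k, len(imp))])
    freq: dict[str, int] = {}
    if model is not None:
        for rid in top:
            sub = model.reaction(rid).subsystem
            freq[sub] = freq.get(sub, 0) + 1
    return ImportanceReport(importances=imp, top_k=top, subsystem_frequency=freq)


def subsystem_barcode(
    reports: Iterable[ImportanceReport], model: MetabolicModel | None = None
) -> pd.Series:
    """Aggregate top-feature subsystem counts across dataset-algorithm cells.

    Returns counts ordered by decreasing frequency (ties broken by name); this
    is the data behind the per-subsystem barcode display.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("no importance reports to aggregate")
    total: dict[str, int] = {}
    for rep in reports:
        freq = rep.subsystem_frequency
        if not freq and model is not None:
            for rid in rep.top_k:
                sub = model.reaction(rid).subsystem
                freq = {**freq, sub: freq.get(sub, 0) + 1}
        for sub, count in freq.items():
            total[sub] = total.get(sub, 0) + count
    series = pd.Series(total, dtype=int)
    return series.sort_index().sort_values(ascending=False, kind="mergesort")
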