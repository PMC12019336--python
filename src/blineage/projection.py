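"""Healthy-reference projection and nearest-neighbor cell assignment.

Tumor cells are mapped into the principal-component space fitted on
healthy bone-marrow CITE-seq profiles (3000 most-variable genes plus
antibody tags, top 30 PCs) and each cell is associated with its closest
healthy population by 10-nearest-neighbor majority vote. Any nonlinear
embedding of that space is display-only; all assignments happen in the
PC coordinates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors

__all__ = [
    "select_mvg",
    "ProjectionModel",
    "ReferenceProjector",
    "AssignmentResult",
    "fit_projection",
    "project",
    "fit_knn",
    "assign",
]


def select_mvg(norm: pd.DataFrame, n: int = 3000) -> list[str]:
    """Top-``n`` most variable features of a normalized features x cells matrix.

    Ranked by variance of the normalized expression, descending, with ties
    broken by feature id so the order is deterministic. Asking for more
    features than exist returns all of them (with a warning).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    var = norm.var(axis=1, ddof=1)
    order = sorted(var.index, key=lambda g: (-var[g], g))
    if n >= len(order):
        if n > len(order):
            warnings.warn(
                f"requested {n} features but only {len(order)} exist; using all",
                stacklevel=2,
            )
        return order
    return order[:n]


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude loading of each component positive."""
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    return loadings * flip


@dataclass
class ProjectionModel:
    """Frozen healthy-reference PCA + k-NN state.

    ``loadings`` (features x n_pc) are orthonormal; ``center`` (and the
    optional ``scale``) come from the healthy cells only, so query samples
    are placed in the healthy coordinate frame rather than their own.
    """

    features: list[str]
    center: np.ndarray
    scale: np.ndarray | None
    loadings: np.ndarray                # (n_features, n_pc)
    explained_variance: np.ndarray      # (n_pc,)
    healthy_scores: np.ndarray          # (n_cells, n_pc)
    healthy_labels: np.ndarray
    k: int = 10
    cv_accuracy: float | None = None
    cv_seed: int | None = None
    _nn: NearestNeighbors | None = field(default=None, repr=False, compare=False)

    @property
    def n_pc(self) -> int:
        return self.loadings.shape[1]

    @property
    def label_order(self) -> list[str]:
        return sorted(pd.unique(self.healthy_labels))

    # -- serialization: directory of TSVs + JSON metadata ---------------
    def save(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savetxt(d / "loadings.tsv", self.loadings, delimiter="\t")
        np.savetxt(d / "healthy_scores.tsv", self.healthy_scores, delimiter="\t")
        meta = {
            "features": self.features,
            "center": self.center.tolist(),
            "scale": None if self.scale is None else self.scale.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "healthy_labels": list(map(str, self.healthy_labels)),
            "k": self.k,
            "cv_accuracy": self.cv_accuracy,
            "cv_seed": self.cv_seed,
        }
        (d / "model.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, directory) -> "ProjectionModel":
        from pathlib import Path

        d = Path(directory)
        meta = json.loads((d / "model.json").read_text())
        return cls(
            features=meta["features"],
            center=np.array(meta["center"]),
            scale=None if meta["scale"] is None else np.array(meta["scale"]),
            loadings=np.loadtxt(d / "loadings.tsv", delimiter="\t"),
            explained_variance=np.array(meta["explained_variance"]),
            healthy_scores=np.loadtxt(d / "healthy_scores.tsv", delimiter="\t"),
            healthy_labels=np.array(meta["healthy_labels"], dtype=object),
            k=meta["k"],
            cv_accuracy=meta["cv_accuracy"],
            cv_seed=meta["cv_seed"],
        )


def fit_projection(
    healthy: pd.DataFrame,
    labels: np.ndarray,
    n_pc: int = 30,
    scale: bool = False,
) -> ProjectionModel:
    """PCA of healthy features x cells data, keeping the top ``n_pc`` PCs.

    Features are centered (optionally standardized); the component sign
    convention makes the largest-magnitude loading of each PC positive so
    refits are bit-reproducible. ``healthy`` rows are the model features
    (selected genes plus CLR-transformed antibody tags), columns cells.
    """
    labels = np.asarray(labels, dtype=object)
    features = list(healthy.index)
    if len(set(features)) != len(features):
        raise ValueError("duplicate features in projection input")
    X = healthy.to_numpy(dtype=float).T  # cells x features
    n_cells, n_feat = X.shape
    if labels.shape[0] != n_cells:
        raise ValueError("label vector length mismatch")
    if n_feat < n_pc:
        raise ValueError(f"{n_feat} features < {n_pc} requested PCs")
    if n_cells < n_pc:
        raise ValueError(f"{n_cells} cells < {n_pc} requested PCs")

    center = X.mean(axis=0)
    Xc = X - center
    sd = None
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    # thin SVD; loadings are right singular vectors
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = _fix_signs(Vt[:n_pc].T)
    scores = Xc @ loadings
    explained = (s[:n_pc] ** 2) / (n_cells - 1)
    return ProjectionModel(
        features=features,
        center=center,
        scale=sd,
        loadings=loadings,
        explained_variance=explained,
        healthy_scores=scores,
        healthy_labels=labels,
    )


def project(query: pd.DataFrame, model: ProjectionModel) -> np.ndarray:
    """Predict PC scores of query cells in the healthy coordinate frame.

    ``query`` is features x cells, normalized with the same recipe as the
    healthy data. Model features absent from the query are imputed as the
    healthy feature mean (zero after centering); more than 50% missing is
    an error.
    """
    present = [f for f in model.features if f in query.index]
    n_missing = len(model.features) - len(present)
    if n_missing > 0.5 * len(model.features):
        raise ValueError(
            f"{n_missing}/{len(model.features)} model features missing from query"
        )
    if n_missing:
        warnings.warn(
            f"{n_missing} model features missing from query; imputed as the "
            "healthy mean",
            stacklevel=2,
        )
    n_cells = query.shape[1]
    X = np.tile(model.center, (n_cells, 1))  # missing -> healthy mean
    idx = [model.features.index(f) for f in present]
    X[:, idx] = query.loc[present].to_numpy(dtype=float).T
    Xc = X - model.center
    if model.scale is not None:
        Xc = Xc / model.scale
    return Xc @ model.loadings


def fit_knn(
    model: ProjectionModel, k: int = 10, n_folds: int = 10, seed: int = 0
) -> ProjectionModel:
    """Attach an exact Euclidean k-NN index over healthy PC scores.

    A stratified ``n_folds``-fold cross-validation accuracy on the healthy
    labels is computed as a diagnostic; the final index is built on all
    cells. Populations with fewer cells than folds reduce the fold count
    (with a warning).
    """
    labels = model.healthy_labels
    min_pop = pd.Series(labels).value_counts().min()
    folds = int(min(n_folds, min_pop))
    if folds < n_folds:
        warnings.warn(
            f"smallest population has {min_pop} cells; reducing CV folds to {folds}",
            stacklevel=2,
        )
    if folds >= 2:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        correct = 0
        for train, test in skf.split(model.healthy_scores, labels):
            clf = KNeighborsClassifier(
                n_neighbors=min(k, len(train)), algorithm="brute"
            )
            clf.fit(model.healthy_scores[train], labels[train].astype(str))
            correct += int(
                (clf.predict(model.healthy_scores[test]) == labels[test].astype(str)).sum()
            )
        model.cv_accuracy = correct / len(labels)
    model.cv_seed = seed
    model.k = k
    model._nn = NearestNeighbors(n_neighbors=k, algorithm="brute").fit(
        model.healthy_scores
    )
    return model


@dataclass
class AssignmentResult:
    """Per-query-cell healthy-population assignments from k-NN voting."""

    assignments: np.ndarray           # (n,)
    vote_counts: pd.DataFrame         # (n, labels) votes among k neighbors
    mean_neighbor_distance: np.ndarray
    k: int

    def to_frame(self) -> pd.DataFrame:
        out = self.vote_counts.copy()
        out.insert(0, "assigned", self.assignments)
        out["mean_neighbor_distance"] = self.mean_neighbor_distance
        return out

    def frequencies(self) -> pd.Series:
        n = len(self.assignments)
        counts = pd.Series(self.assignments).value_counts()
        return pd.Series(
            {lab: counts.get(lab, 0) / n for lab in self.vote_counts.columns},
            name="frequency",
        )

    def summary(self) -> str:
        freq = self.frequencies()
        lines = [
            "k-NN reference assignment",
            f"  query cells: {len(self.assignments)}   k = {self.k}",
            "  assigned-population frequencies:",
        ]
        lines += [f"    {lab:>16s}  {f:.4f}" for lab, f in freq.items()]
        return "\n".join(lines)


def assign(query_scores: np.ndarray, model: ProjectionModel) -> AssignmentResult:
    """Majority vote among the k nearest healthy cells in PC space.

    Vote ties are broken by the smaller mean distance to the tied label's
    voting neighbors, then by label sort order.
    """
    if model._nn is None:
        raise RuntimeError("call fit_knn before assign")
    if model.healthy_scores.shape[0] < model.k:
        raise ValueError("fewer healthy cells than neighbors requested")
    query_scores = np.atleast_2d(np.asarray(query_scores, dtype=float))
    dist, idx = model._nn.kneighbors(query_scores)
    neigh_labels = model.healthy_labels[idx]  # (n, k)

    label_order = model.label_order
    lab_to_col = {lab: j for j, lab in enumerate(label_order)}
    n = query_scores.shape[0]
    votes = np.zeros((n, len(label_order)), dtype=int)
    dist_sum = np.zeros((n, len(label_order)))
    for j in range(model.k):
        cols = np.array([lab_to_col[lab] for lab in neigh_labels[:, j]])
        votes[np.arange(n), cols] += 1
        dist_sum[np.arange(n), cols] += dist[:, j]

    assignments = np.empty(n, dtype=object)
    max_votes = votes.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_dist_per_label = np.where(votes > 0, dist_sum / np.maximum(votes, 1), np.inf)
    for i in range(n):
        tied = np.flatnonzero(votes[i] == max_votes[i])
        if len(tied) == 1:
            assignments[i] = label_order[tied[0]]
        else:
            # nearer-on-average tied label wins; then label order
            best = min(tied, key=lambda c: (mean_dist_per_label[i, c], label_order[c]))
            assignments[i] = label_order[best]
    return AssignmentResult(
        assignments=assignments,
        vote_counts=pd.DataFrame(votes, columns=label_order),
        mean_neighbor_distance=dist.mean(axis=1),
        k=model.k,
    )


class ReferenceProjector:
    """End-to-end healthy-reference mapping model.

    ``fit`` selects the most-variable genes on the healthy normalized
    expression, concatenates antibody-tag features, fits the PCA and the
    k-NN index; ``assign`` projects query cells and votes. Mirrors the
    fit/result idiom: ``fit`` returns self with ``model_`` populated and
    ``assign`` returns an :class:`AssignmentResult`.
    """

    def __init__(
        self,
        n_mvg: int = 3000,
        n_pc: int = 30,
        k: int = 10,
        n_folds: int = 10,
        scale: bool = False,
        seed: int = 0,
    ) -> None:
        self.n_mvg = n_mvg
        self.n_pc = n_pc
        self.k = k
        self.n_folds = n_folds
        self.scale = scale
        self.seed = seed
        self.model_: ProjectionModel | None = None

    def fit(
        self,
        healthy_norm: pd.DataFrame,
        labels: np.ndarray,
        healthy_tags: pd.DataFrame | None = None,
    ) -> "ReferenceProjector":
        mvg = select_mvg(healthy_norm, self.n_mvg)
        feat = healthy_norm.loc[mvg]
        if healthy_tags is not None:
            feat = pd.concat([feat, healthy_tags])
        self.model_ = fit_projection(feat, labels, n_pc=self.n_pc, scale=self.scale)
        fit_knn(self.model_, k=self.k, n_folds=self.n_folds, seed=self.seed)
        return self

    def transform(
        self, query_norm: pd.DataFrame, query_tags: pd.DataFrame | None = None
    ) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("projector is not fitted")
        q = query_norm if query_tags is None else pd.concat([query_norm, query_tags])
        return project(q, self.model_)

    def assign(
        self, query_norm: pd.DataFrame, query_tags: pd.DataFrame | None = None
    ) -> AssignmentResult:
        return assign(self.transform(query_norm, query_tags), self.model_)
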