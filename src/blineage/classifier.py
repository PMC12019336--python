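"""Single-cell developmental classifier.

Each leukemia cell is assigned to the most similar healthy B-cell
developmental population by Mahalanobis distance in the space of the ten
proteins used to gate normal B lymphopoiesis (CD19, CD20, CD24, CD34,
CD38, CD45, CD127, CD179b, IgMi, TdT). A cell whose distance to every
population is at or above the classification threshold (default 10,
matched to the dimensionality) is reported as "unclassified".

The reference geometry is per-population: each healthy population
contributes its own mean vector and covariance matrix, estimated from
gated healthy bone-marrow cells and shrunk toward its diagonal so that
small gated populations remain invertible in ten dimensions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular

from .cytof import MarkerMatrix

__all__ = [
    "CLASSIFIER_MARKERS",
    "UNCLASSIFIED",
    "ReferenceModel",
    "ClassificationResult",
    "DevClassifier",
    "fit_reference",
    "mahalanobis_distance",
    "classify",
    "population_frequencies",
]

#: The ten B-cell developmental proteins used for gating and classification.
CLASSIFIER_MARKERS = (
    "CD19", "CD20", "CD24", "CD34", "CD38",
    "CD45", "CD127", "CD179b", "IgMi", "TdT",
)

UNCLASSIFIED = "unclassified"


@dataclass
class ReferenceModel:
    """Fitted healthy-reference geometry for Mahalanobis classification.

    Holds, for each population k, the mean vector mu_k and the regularized
    covariance Sigma_k = (1 - lambda) * S + lambda * diag(S) + eps * I,
    where S is the sample covariance, together with the marker order and
    the shrinkage actually used. Cholesky factors are cached so distances
    never form an explicit inverse.
    """

    marker_order: tuple[str, ...]
    population_names: tuple[str, ...]
    means: np.ndarray          # (K, p)
    covariances: np.ndarray    # (K, p, p) regularized
    cell_counts: np.ndarray    # (K,)
    shrinkage: float
    epsilons: np.ndarray       # (K,) ridge added per population
    _chol: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        K, p = self.means.shape
        if self.covariances.shape != (K, p, p):
            raise ValueError("covariance stack shape mismatch")
        if len(self.population_names) != K:
            raise ValueError("population name count mismatch")

    @property
    def n_populations(self) -> int:
        return len(self.population_names)

    def cholesky_factors(self) -> np.ndarray:
        """Lower Cholesky factor of each Sigma_k; fails if any is not SPD."""
        if self._chol is None:
            L = np.empty_like(self.covariances)
            for k, (name, S) in enumerate(
                zip(self.population_names, self.covariances)
            ):
                try:
                    L[k] = cholesky(S, lower=True)
                except np.linalg.LinAlgError as exc:  # pragma: no cover
                    raise np.linalg.LinAlgError(
                        f"covariance of population {name!r} is not positive "
                        "definite after regularization"
                    ) from exc
            self._chol = L
        return self._chol

    # -- serialization -------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "marker_order": list(self.marker_order),
            "population_names": list(self.population_names),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "cell_counts": self.cell_counts.tolist(),
            "shrinkage": self.shrinkage,
            "epsilons": self.epsilons.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ReferenceModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            marker_order=tuple(d["marker_order"]),
            population_names=tuple(d["population_names"]),
            means=np.array(d["means"]),
            covariances=np.array(d["covariances"]),
            cell_counts=np.array(d["cell_counts"]),
            shrinkage=d["shrinkage"],
            epsilons=np.array(d["epsilons"]),
        )


def fit_reference(
    healthy: MarkerMatrix,
    markers: tuple[str, ...] = CLASSIFIER_MARKERS,
    shrinkage: float = 0.1,
) -> ReferenceModel:
    """Estimate per-population (mean, covariance) from gated healthy cells.

    The sample covariance S (ddof=1) of each population is shrunk as
    ``(1 - shrinkage) * S + shrinkage * diag(S) + eps * I`` with
    ``eps = 1e-6 * mean(diag(S))``, so that populations with few cells in
    ten dimensions remain positive definite.
    """
    if healthy.labels is None:
        raise ValueError("healthy reference must carry population labels")
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must be in [0, 1]")
    missing = [mk for mk in markers if mk not in healthy.marker_names]
    if missing:
        raise KeyError(f"classifier markers missing from reference: {missing}")
    cols = [healthy.marker_names.index(mk) for mk in markers]
    X = healthy.values[:, cols]
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in reference matrix")

    pops = list(pd.unique(healthy.labels))
    p = len(markers)
    means = np.empty((len(pops), p))
    covs = np.empty((len(pops), p, p))
    counts = np.empty(len(pops), dtype=int)
    epsilons = np.empty(len(pops))
    for k, pop in enumerate(pops):
        sub = X[healthy.labels == pop]
        if sub.shape[0] < 2:
            raise ValueError(
                f"population {pop!r} has {sub.shape[0]} cell(s); "
                "at least 2 are required to estimate a covariance"
            )
        means[k] = sub.mean(axis=0)
        S = np.cov(sub, rowvar=False, ddof=1)
        eps = 1e-6 * float(np.mean(np.diag(S)))
        covs[k] = (
            (1.0 - shrinkage) * S
            + shrinkage * np.diag(np.diag(S))
            + eps * np.eye(p)
        )
        counts[k] = sub.shape[0]
        epsilons[k] = eps
    return ReferenceModel(
        marker_order=tuple(markers),
        population_names=tuple(pops),
        means=means,
        covariances=covs,
        cell_counts=counts,
        shrinkage=shrinkage,
        epsilons=epsilons,
    )


def mahalanobis_distance(
    x: np.ndarray, model: ReferenceModel, population: str
) -> float:
    """Mahalanobis distance sqrt((x-mu)' Sigma^-1 (x-mu)) to one population.

    Computed through the cached Cholesky factor; no explicit inverse.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (len(model.marker_order),):
        raise ValueError("cell vector dimension mismatch")
    if not np.isfinite(x).all():
        raise ValueError("non-finite cell vector")
    k = model.population_names.index(population)
    L = model.cholesky_factors()[k]
    z = solve_triangular(L, x - model.means[k], lower=True)
    return float(np.sqrt(z @ z))


def _all_distances(X: np.ndarray, model: ReferenceModel) -> np.ndarray:
    """(n_cells, K) matrix of Mahalanobis distances, vectorized per population."""
    Ls = model.cholesky_factors()
    n = X.shape[0]
    D = np.empty((n, model.n_populations))
    for k in range(model.n_populations):
        Z = solve_triangular(Ls[k], (X - model.means[k]).T, lower=True)
        D[:, k] = np.sqrt(np.einsum("ij,ij->j", Z, Z))
    return D


@dataclass
class ClassificationResult:
    """Per-cell population assignments with Mahalanobis distances."""

    assignments: np.ndarray        # (n,) population name or "unclassified"
    min_distance: np.ndarray       # (n,)
    threshold: float
    population_names: tuple[str, ...]
    distances: np.ndarray | None = None   # (n, K) optional full matrix

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"population": self.assignments, "min_distance": self.min_distance}
        )

    def frequencies(self) -> pd.Series:
        return population_frequencies(self)

    def summary(self) -> str:
        freq = self.frequencies()
        lines = [
            "Developmental classification",
            f"  cells: {len(self.assignments)}",
            f"  threshold: Mahalanobis distance {self.threshold:g}",
            "  population frequencies:",
        ]
        lines += [f"    {pop:>16s}  {f:.4f}" for pop, f in freq.items()]
        return "\n".join(lines)


class DevClassifier:
    """Mahalanobis nearest-population classifier against a healthy reference.

    Usage::

        clf = DevClassifier(threshold=10.0, shrinkage=0.1)
        clf.fit(healthy_marker_matrix)          # gated, arcsinh-transformed
        result = clf.classify(tumor_matrix)     # ClassificationResult
    """

    def __init__(
        self,
        markers: tuple[str, ...] = CLASSIFIER_MARKERS,
        threshold: float = 10.0,
        shrinkage: float = 0.1,
    ) -> None:
        self.markers = tuple(markers)
        self.threshold = float(threshold)
        self.shrinkage = float(shrinkage)
        self.model_: ReferenceModel | None = None

    def fit(self, healthy: MarkerMatrix) -> "DevClassifier":
        self.model_ = fit_reference(healthy, self.markers, self.shrinkage)
        return self

    def classify(
        self, cells: MarkerMatrix, keep_distances: bool = False
    ) -> ClassificationResult:
        if self.model_ is None:
            raise RuntimeError("classifier is not fitted")
        return classify(
            cells, self.model_, self.threshold, keep_distances=keep_distances
        )


def classify(
    cells: MarkerMatrix,
    model: ReferenceModel,
    threshold: float = 10.0,
    keep_distances: bool = False,
) -> ClassificationResult:
    """Assign every cell to its nearest healthy population.

    Columns are reordered to the model's marker order. A cell is assigned
    ``argmin_k d(x, k)`` when the minimum distance is strictly below the
    threshold, else "unclassified". Exact ties go to the earlier
    population in the model's declared order (argmin first-wins).
    """
    missing = [mk for mk in model.marker_order if mk not in cells.marker_names]
    if missing:
        raise KeyError(f"classifier markers missing from input: {missing}")
    cols = [cells.marker_names.index(mk) for mk in model.marker_order]
    X = cells.values[:, cols]
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in query matrix")

    D = _all_distances(X, model)
    best = np.argmin(D, axis=1)
    dmin = D[np.arange(D.shape[0]), best]
    names = np.array(model.population_names, dtype=object)
    assigned = names[best]
    assigned[dmin >= threshold] = UNCLASSIFIED
    return ClassificationResult(
        assignments=assigned,
        min_distance=dmin,
        threshold=threshold,
        population_names=model.population_names,
        distances=D if keep_distances else None,
    )


def population_frequencies(result: ClassificationResult) -> pd.Series:
    """Fraction of cells per population (plus "unclassified"); sums to 1.

    Populations with zero assigned cells are reported as 0, not dropped.
    """
    n = len(result.assignments)
    if n == 0:
        raise ValueError("empty classification table")
    order = list(result.population_names) + [UNCLASSIFIED]
    counts = pd.Series(result.assignments).value_counts()
    freq = pd.Series(
        [counts.get(pop, 0) / n for pop in order], index=order, name="frequency"
    )
    return freq
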