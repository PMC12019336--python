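"""Mass-cytometry preprocessing.

Per-cell protein intensities are variance-stabilized with the inverse
hyperbolic sine (arcsinh) transform, summarized per developmental
population by medians, and optionally subsampled for visualization or
balanced downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "arcsinh_transform",
    "inverse_arcsinh",
    "population_median",
    "subsample",
]

RAW = "raw"


@dataclass
class MarkerMatrix:
    """Cells x protein-markers matrix with optional labels and metadata.

    Parameters
    ----------
    values : ndarray, shape (n_cells, n_markers)
        Marker intensities. Raw ion counts or arcsinh-transformed,
        according to ``transform_state``.
    marker_names : list of str
        Unique marker names, one per column.
    labels : ndarray of str, optional
        Per-cell population labels (e.g. gating results).
    metadata : dict
        Sample-level annotations such as ``sample_id`` and ``group``.
    transform_state : str
        ``"raw"`` or ``"arcsinh(c=<cofactor>)"``. Never double-applied.
    """

    values: np.ndarray
    marker_names: list[str]
    labels: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)
    transform_state: str = RAW

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x markers matrix")
        if self.values.shape[1] != len(self.marker_names):
            raise ValueError(
                f"{self.values.shape[1]} columns but "
                f"{len(self.marker_names)} marker names"
            )
        if len(set(self.marker_names)) != len(self.marker_names):
            raise ValueError("marker names must be unique")
        if np.isnan(self.values).any():
            raise ValueError("marker matrix contains NaN")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape[0] != self.values.shape[0]:
                raise ValueError("label vector length mismatch")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def marker(self, name: str) -> np.ndarray:
        """Column for one marker."""
        try:
            j = self.marker_names.index(name)
        except ValueError:
            raise KeyError(f"marker {name!r} not present") from None
        return self.values[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.marker_names)
        if self.labels is not None:
            df["population"] = self.labels
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, transform_state: str = RAW) -> "MarkerMatrix":
        df = pd.read_csv(path, sep="\t")
        labels = None
        if "population" in df.columns:
            labels = df.pop("population").to_numpy(dtype=object)
        return cls(
            values=df.to_numpy(dtype=float),
            marker_names=list(df.columns),
            labels=labels,
            transform_state=transform_state,
        )


def arcsinh_transform(m: MarkerMatrix, cofactor: float = 5.0) -> MarkerMatrix:
    """asinh(x / cofactor), the standard CyTOF variance stabilization.

    Refuses to transform twice: ``m.transform_state`` must be raw.
    """
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    if m.transform_state != RAW:
        raise ValueError(
            f"matrix already transformed ({m.transform_state}); "
            "arcsinh must not be applied twice"
        )
    return replace(
        m,
        values=np.arcsinh(m.values / cofactor),
        transform_state=f"arcsinh(c={cofactor:g})",
    )


def inverse_arcsinh(m: MarkerMatrix) -> MarkerMatrix:
    """Undo the arcsinh transform, recovering raw intensities."""
    state = m.transform_state
    if not state.startswith("arcsinh(c="):
        raise ValueError(f"matrix is not arcsinh-transformed ({state})")
    cofactor = float(state[len("arcsinh(c=") : -1])
    return replace(m, values=np.sinh(m.values) * cofactor, transform_state=RAW)


def population_median(
    m: MarkerMatrix, labels: np.ndarray | None = None
) -> pd.DataFrame:
    """Median marker expression per population, after arcsinh transform.

    Returns a population x marker DataFrame. Populations with no cells are
    simply absent (missing, never reported as zero). The even-count median
    is the mean of the two middle values.
    """
    if not m.transform_state.startswith("arcsinh"):
        raise ValueError("population medians are defined on arcsinh data")
    if labels is None:
        labels = m.labels
    if labels is None:
        raise ValueError("no labels supplied and matrix carries none")
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != m.n_cells:
        raise ValueError("label vector length mismatch")
    df = pd.DataFrame(m.values, columns=m.marker_names)
    out = df.groupby(pd.Series(labels, name="population"), sort=True).median()
    return out


def subsample(
    m: MarkerMatrix,
    n: int = 1000,
    seed: int | None = None,
    stratify_by: str | None = None,
) -> MarkerMatrix:
    """Uniform without-replacement subsample, at most ``n`` cells per stratum.

    ``stratify_by`` is ``None`` (whole matrix is one stratum),
    ``"population"`` (per-label subsampling) or ``"sample"`` (uses
    ``metadata["sample_ids"]``, a per-cell array). Strata with at most
    ``n`` cells are returned whole.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    if stratify_by is None:
        strata = np.zeros(m.n_cells, dtype=object)
    elif stratify_by == "population":
        if m.labels is None:
            raise ValueError("population stratification requires labels")
        strata = m.labels
    elif stratify_by == "sample":
        strata = np.asarray(m.metadata["sample_ids"], dtype=object)
    else:
        raise ValueError(f"unknown stratum {stratify_by!r}")

    keep: list[np.ndarray] = []
    for s in pd.unique(strata):
        idx = np.flatnonzero(strata == s)
        if idx.size > n:
            idx = rng.choice(idx, size=n, replace=False)
        keep.append(np.sort(idx))
    sel = np.concatenate(keep) if keep else np.array([], dtype=int)
    return replace(
        m,
        values=m.values[sel],
        labels=None if m.labels is None else m.labels[sel],
        metadata={
            **m.metadata,
            **(
                {"sample_ids": np.asarray(m.metadata["sample_ids"], dtype=object)[sel]}
                if "sample_ids" in m.metadata
                else {}
            ),
        },
    )
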