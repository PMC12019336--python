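"""CITE-seq expression stage.

Quality control of per-cell molecule counts, a documented normalization
(library-size scaling + log1p with regression-based removal of the
mitochondrial-fraction covariate), centered log-ratio transformation of
antibody-tag counts, Wilcoxon rank-sum differential expression with
fraction/fold-change/Bonferroni filters, and a per-cell gene-signature
module score against expression-matched control genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.io import mmread, mmwrite

__all__ = [
    "CountMatrix",
    "QCReport",
    "qc_filter",
    "normalize",
    "clr_normalize",
    "wilcoxon_de",
    "module_score",
]


@dataclass
class CountMatrix:
    """Genes x cells molecule counts with optional antibody-tag counts.

    ``counts`` holds non-negative integers (RSEC-style error-corrected
    molecule counts). ``mito_flags`` marks mitochondrial genes used by QC.
    """

    counts: np.ndarray                  # (n_genes, n_cells) int
    gene_ids: list[str]
    cell_ids: list[str]
    mito_flags: np.ndarray              # (n_genes,) bool
    tag_counts: np.ndarray | None = None   # (n_tags, n_cells)
    tag_names: list[str] | None = None
    groups: np.ndarray | None = None    # (n_cells,) condition labels
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be genes x cells")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.cell_ids) != n_cells:
            raise ValueError("id lengths do not match matrix shape")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene ids must be unique")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell ids must be unique")
        self.mito_flags = np.asarray(self.mito_flags, dtype=bool)
        if self.mito_flags.shape != (n_genes,):
            raise ValueError("mito_flags must align with genes")
        if self.groups is not None:
            self.groups = np.asarray(self.groups, dtype=object)
            if self.groups.shape != (n_cells,):
                raise ValueError("groups must align with cells")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return replace(
            self,
            counts=self.counts[:, idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            tag_counts=None if self.tag_counts is None else self.tag_counts[:, idx],
            groups=None if self.groups is None else self.groups[idx],
        )

    def to_anndata(self):
        """Cells x genes AnnData view (for interop with scanpy et al.)."""
        import anndata

        ad = anndata.AnnData(
            X=sparse.csr_matrix(self.counts.T.astype(np.float32)),
            obs=pd.DataFrame(index=self.cell_ids),
            var=pd.DataFrame({"mito": self.mito_flags}, index=self.gene_ids),
        )
        if self.groups is not None:
            ad.obs["group"] = self.groups
        return ad

    # -- MTX / CSV I/O -------------------------------------------------
    def to_mtx(self, prefix) -> None:
        """Write matrix.mtx + genes.tsv + barcodes.tsv under ``prefix``."""
        from pathlib import Path

        prefix = Path(prefix)
        prefix.mkdir(parents=True, exist_ok=True)
        mmwrite(str(prefix / "matrix.mtx"), sparse.coo_matrix(self.counts))
        pd.DataFrame({"gene": self.gene_ids, "mito": self.mito_flags.astype(int)}).to_csv(
            prefix / "genes.tsv", sep="\t", index=False, header=False
        )
        pd.Series(self.cell_ids).to_csv(
            prefix / "barcodes.tsv", sep="\t", index=False, header=False
        )

    @classmethod
    def from_mtx(cls, prefix) -> "CountMatrix":
        from pathlib import Path

        prefix = Path(prefix)
        counts = np.asarray(mmread(str(prefix / "matrix.mtx")).todense())
        genes = pd.read_csv(prefix / "genes.tsv", sep="\t", header=None)
        barcodes = pd.read_csv(prefix / "barcodes.tsv", sep="\t", header=None)
        return cls(
            counts=counts.astype(np.int64),
            gene_ids=list(genes[0]),
            cell_ids=list(barcodes[0].astype(str)),
            mito_flags=genes[1].to_numpy(dtype=bool)
            if genes.shape[1] > 1
            else np.zeros(counts.shape[0], dtype=bool),
        )


@dataclass
class QCReport:
    """Per-criterion and overall cell-removal counts from qc_filter."""

    n_input: int
    n_removed: int
    removed_low_genes: int
    removed_low_counts: int
    removed_high_mito: int
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"QC: removed {self.n_removed}/{self.n_input} cells "
            f"(<genes: {self.removed_low_genes}, <counts: "
            f"{self.removed_low_counts}, >mito: {self.removed_high_mito}; "
            f"rule={self.rule})"
        )


def qc_filter(
    c: CountMatrix,
    min_genes: int = 500,
    min_counts: int = 200,
    max_mito: float = 0.5,
    rule: str = "any",
) -> tuple[CountMatrix, QCReport]:
    """Remove low-quality cells.

    With the default ``rule="any"`` a cell is removed if it has fewer than
    ``min_genes`` expressed genes, OR fewer than ``min_counts`` total
    molecules, OR a mitochondrial count fraction above ``max_mito``.
    ``rule="genes_or_counts_and_mito"`` instead removes only cells that
    fail (genes OR counts) AND the mitochondrial criterion — the
    alternative reading of the combined exclusion rule.
    """
    if min_genes < 0 or min_counts < 0 or not 0 <= max_mito <= 1:
        raise ValueError("QC thresholds out of range")
    expressed = (c.counts > 0).sum(axis=0)
    totals = c.counts.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mito_frac = np.where(
            totals > 0, c.counts[c.mito_flags].sum(axis=0) / np.maximum(totals, 1), 1.0
        )
    low_genes = expressed < min_genes
    low_counts = totals < min_counts
    high_mito = mito_frac > max_mito
    if rule == "any":
        remove = low_genes | low_counts | high_mito
    elif rule == "genes_or_counts_and_mito":
        remove = (low_genes | low_counts) & high_mito
    else:
        raise ValueError(f"unknown rule {rule!r}")
    report = QCReport(
        n_input=c.n_cells,
        n_removed=int(remove.sum()),
        removed_low_genes=int(low_genes.sum()),
        removed_low_counts=int(low_counts.sum()),
        removed_high_mito=int(high_mito.sum()),
        rule=rule,
    )
    return c.subset_cells(~remove), report


def normalize(
    c: CountMatrix,
    target_sum: float = 1e4,
    regress_mito: bool = True,
) -> pd.DataFrame:
    """Library-size normalization + log1p, then mito-covariate removal.

    Counts are scaled per cell to ``target_sum`` and log1p-transformed.
    If ``regress_mito`` is set, each gene is regressed on the per-cell
    mitochondrial count fraction and the covariate's contribution
    ``b * (mito - mean(mito))`` is subtracted, so the gene mean is
    preserved while the confounding trend is removed. The recipe is
    recorded in the result's ``attrs``.

    Returns a genes x cells DataFrame of normalized expression.
    """
    totals = c.counts.sum(axis=0).astype(float)
    if np.any(totals == 0):
        raise ValueError("zero-count cell present; run qc_filter first")
    X = np.log1p(c.counts / totals * target_sum)  # genes x cells
    recipe = f"log1p(counts/libsize*{target_sum:g})"
    if regress_mito:
        mito_frac = c.counts[c.mito_flags].sum(axis=0) / totals
        centered = mito_frac - mito_frac.mean()
        ss = float(centered @ centered)
        if ss > 1e-12:
            # per-gene OLS slope on the centered covariate, vectorized
            slopes = (X @ centered) / ss
            X = X - np.outer(slopes, centered)
            recipe += " - b*(mito_frac - mean)"
    out = pd.DataFrame(X, index=c.gene_ids, columns=c.cell_ids)
    out.attrs["recipe"] = recipe
    return out


def clr_normalize(tag_counts: np.ndarray) -> np.ndarray:
    """Centered log-ratio transform of antibody-tag counts, per cell.

    value = ln(x + 1) - mean_over_tags(ln(x + 1)); columns are cells.
    """
    tag_counts = np.asarray(tag_counts, dtype=float)
    if np.any(tag_counts < 0):
        raise ValueError("tag counts must be non-negative")
    logged = np.log1p(tag_counts)
    return logged - logged.mean(axis=0, keepdims=True)


def wilcoxon_de(
    norm: pd.DataFrame,
    groups: np.ndarray,
    min_frac: float = 0.10,
    min_fc: float = 1.25,
    alpha: float = 0.05,
    pseudocount: float = 1e-9,
) -> pd.DataFrame:
    """Two-group Wilcoxon rank-sum differential expression with filters.

    A gene is tested only if expressed (value > 0) in at least
    ``min_frac`` of cells in one of the two groups. P-values come from the
    two-sided rank-sum test with normal approximation and tie correction;
    Bonferroni correction uses m = number of *tested* genes. A gene is
    significant when tested, ``|log2 fc| >= log2(min_fc)`` and adjusted
    p < ``alpha``. Fold change is the ratio of expm1-scale group means
    (plus ``pseudocount``), group A over group B in label-sorted order.

    Returns a per-gene DataFrame with fractions, log2 fold change, raw and
    adjusted p, significance, and a ``reason`` code ("", "frac", "fc",
    "alpha") explaining each failure.
    """
    groups = np.asarray(groups, dtype=object)
    labels = sorted(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    a_mask = groups == labels[0]
    b_mask = groups == labels[1]
    if a_mask.sum() < 3 or b_mask.sum() < 3:
        raise ValueError("each group needs at least 3 cells")

    X = norm.to_numpy()
    A, B = X[:, a_mask], X[:, b_mask]
    frac_a = (A > 0).mean(axis=1)
    frac_b = (B > 0).mean(axis=1)
    tested = (frac_a >= min_frac) | (frac_b >= min_frac)

    # negative residuals from covariate removal are clipped so the
    # expm1-scale means stay in fold-change domain
    mean_a = np.maximum(np.expm1(A).mean(axis=1), 0.0) + pseudocount
    mean_b = np.maximum(np.expm1(B).mean(axis=1), 0.0) + pseudocount
    log2fc = np.log2(mean_a / mean_b)
    fc_pass = np.abs(log2fc) >= np.log2(min_fc)

    pvals = np.full(X.shape[0], np.nan)
    if tested.any():
        res = stats.mannwhitneyu(
            A[tested], B[tested], axis=1, alternative="two-sided",
            method="asymptotic",
        )
        pvals[tested] = res.pvalue
    m = int(tested.sum())
    padj = np.minimum(pvals * m, 1.0)
    alpha_pass = padj < alpha

    significant = tested & fc_pass & alpha_pass
    reason = np.where(
        ~tested, "frac", np.where(~fc_pass, "fc", np.where(~alpha_pass, "alpha", ""))
    )
    return pd.DataFrame(
        {
            f"frac_{labels[0]}": frac_a,
            f"frac_{labels[1]}": frac_b,
            "log2_fold_change": log2fc,
            "pvalue": pvals,
            "pvalue_adj": padj,
            "tested": tested,
            "significant": significant,
            "reason": reason,
        },
        index=norm.index,
    )


def module_score(
    norm: pd.DataFrame,
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int | None = None,
) -> pd.Series:
    """Per-cell enrichment score of a gene signature.

    Genes are binned by average expression (rank-based equal-count bins);
    each signature gene draws ``n_ctrl`` control genes from its own bin,
    and the score is mean(signature expression) - mean(control expression)
    per cell — positive where the program is active beyond expression-
    matched background.
    """
    present = [g for g in gene_set if g in norm.index]
    missing = [g for g in gene_set if g not in norm.index]
    if not present:
        raise ValueError(f"no signature genes found in matrix; missing: {missing}")
    rng = np.random.default_rng(seed)

    avg = norm.mean(axis=1)
    n_bins_eff = min(n_bins, len(avg))
    bins = pd.qcut(avg.rank(method="first"), n_bins_eff, labels=False)
    bins = pd.Series(bins, index=norm.index)

    sig_mask = norm.index.isin(present)
    controls: list[str] = []
    for g in present:
        pool = bins.index[(bins == bins[g]) & ~sig_mask]
        if len(pool) == 0:
            continue  # bin holds only signature genes; nothing to match
        take = rng.choice(pool, size=n_ctrl, replace=len(pool) < n_ctrl)
        controls.extend(take)
    if not controls:
        raise ValueError("no control genes available outside the signature")
    score = norm.loc[present].mean(axis=0) - norm.loc[controls].mean(axis=0)
    score.name = "module_score"
    score.attrs["control_genes"] = controls
    score.attrs["signature_genes"] = present
    return score
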