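"""Synthetic inputs with known ground truth for every pipeline stage.

Emulates the study designs the pipeline consumes: a healthy bone-marrow
reference of 15 B-cell developmental populations with distinct 10-marker
arcsinh profiles; patient cohorts drawn as population mixtures with a
planted IKAROS shift confined to one population of one clinical group;
negative-binomial CITE-seq count matrices with planted differentially
expressed genes and a planted gene program; and gapped read alignments
over a toy gene model with known intron-retention levels.

Distributional choices (multivariate normal marker noise, NB counts with
gene-level dispersion, log-normal library sizes) are explicit modelling
stand-ins and are exposed through the config objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cytof import MarkerMatrix
from .expression import CountMatrix
from .splicing import AlignmentSet, ToyGeneModel

__all__ = [
    "ReferenceConfig",
    "PlantedShift",
    "CohortConfig",
    "DESpec",
    "SignatureSpec",
    "MitoSpec",
    "default_population_names",
    "default_marker_names",
    "default_population_means",
    "generate_reference_bm",
    "generate_patient_cohort",
    "generate_citeseq_counts",
    "generate_population_counts",
    "generate_splice_reads",
    "default_toy_gene",
]

# ---------------------------------------------------------------------------
# Healthy bone-marrow reference geometry
# ---------------------------------------------------------------------------

_POPULATIONS = (
    "pre-pro-B", "pro-BI", "pro-BII", "pre-BI", "pre-BII",
    "immature-BI", "immature-BII", "immature-BIII",
    "mature-BI", "mature-BII",
    "early-non-BI", "early-non-BII",
    "non-BI", "non-BII", "non-BIII",
)

_CLASSIFIER_MARKERS = (
    "CD19", "CD20", "CD24", "CD34", "CD38",
    "CD45", "CD127", "CD179b", "IgMi", "TdT",
)
_EXTRA_MARKERS = ("IKAROS", "CD22", "PAX5")

# expression levels in arcsinh(cofactor 5) units: negative / mid / high
_L, _M, _H = 0.2, 2.5, 4.8

# 15 populations x 10 classifier markers. The staging is a stylized sketch
# of normal B lymphopoiesis (CD34/TdT early, CD179b in pro/pre stages,
# surface IgM from the immature stages, CD20/CD45 rising toward maturity)
# arranged so every pair of populations differs by >= 2 arcsinh units on
# at least 2 markers, which keeps default-noise classification well-posed.
_MEANS_10 = np.array([
    #        CD19 CD20 CD24 CD34 CD38 CD45 CD127 179b IgMi TdT
    [_L, _L, _L, _H, _H, _L, _H, _L, _L, _H],   # pre-pro-B
    [_M, _L, _M, _H, _H, _L, _H, _M, _L, _H],   # pro-BI
    [_H, _L, _M, _M, _H, _M, _L, _H, _L, _M],   # pro-BII
    [_H, _L, _H, _L, _H, _M, _L, _H, _L, _L],   # pre-BI
    [_H, _M, _H, _L, _M, _M, _L, _M, _M, _L],   # pre-BII
    [_H, _M, _H, _L, _M, _H, _L, _L, _H, _L],   # immature-BI
    [_H, _H, _M, _L, _M, _H, _L, _L, _H, _L],   # immature-BII
    [_H, _H, _L, _L, _L, _H, _L, _L, _M, _L],   # immature-BIII
    [_M, _H, _L, _L, _L, _H, _M, _L, _H, _L],   # mature-BI
    [_M, _H, _L, _L, _M, _H, _M, _L, _L, _L],   # mature-BII
    [_L, _L, _L, _H, _M, _M, _M, _L, _L, _M],   # early-non-BI
    [_L, _L, _M, _H, _H, _M, _L, _L, _L, _L],   # early-non-BII
    [_L, _L, _L, _L, _L, _H, _H, _L, _L, _L],   # non-BI
    [_L, _L, _M, _L, _H, _H, _L, _L, _L, _L],   # non-BII
    [_L, _L, _L, _L, _H, _M, _L, _L, _M, _L],   # non-BIII
])

# IKAROS / CD22 / PAX5 ride along for planted-shift experiments: IKAROS and
# PAX5 mark the B lineage, CD22 tracks CD19.
_MEANS_EXTRA = np.array(
    [[1.5, 0.3, 1.0]] +            # pre-pro-B
    [[3.0, 2.0, 3.5]] +            # pro-BI
    [[3.0, 3.5, 3.5]] * 8 +        # pro-BII .. mature-BII
    [[1.5, 0.3, 0.3]] * 5          # non-B fractions
)


def default_population_names() -> tuple[str, ...]:
    return _POPULATIONS


def default_marker_names() -> tuple[str, ...]:
    return _CLASSIFIER_MARKERS + _EXTRA_MARKERS


def default_population_means() -> pd.DataFrame:
    """Population x marker mean table in arcsinh units."""
    return pd.DataFrame(
        np.hstack([_MEANS_10, _MEANS_EXTRA]),
        index=list(_POPULATIONS),
        columns=list(default_marker_names()),
    )


@dataclass
class ReferenceConfig:
    """Healthy bone-marrow reference: 15 populations, arcsinh marker space."""

    population_names: tuple[str, ...] = _POPULATIONS
    marker_names: tuple[str, ...] = field(default_factory=default_marker_names)
    population_means: np.ndarray | None = None   # (K, p); default table
    population_cov_scale: np.ndarray | float = 0.35
    population_cov: list[np.ndarray] | None = None  # optional full covariances
    cells_per_population: np.ndarray | int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        K = len(self.population_names)
        if K != 15:
            raise ValueError(f"reference must have exactly 15 populations, got {K}")
        missing = [m for m in _CLASSIFIER_MARKERS if m not in self.marker_names]
        if missing:
            raise ValueError(f"classifier markers missing: {missing}")
        if self.population_means is None:
            table = default_population_means()
            self.population_means = table[list(self.marker_names)].to_numpy()
        self.population_means = np.asarray(self.population_means, dtype=float)
        if self.population_means.shape != (K, len(self.marker_names)):
            raise ValueError("population_means shape mismatch")
        scale = np.broadcast_to(
            np.asarray(self.population_cov_scale, dtype=float), (K,)
        ).copy()
        if np.any(scale <= 0):
            raise ValueError("covariance scales must be positive")
        self.population_cov_scale = scale
        self.cells_per_population = np.broadcast_to(
            np.asarray(self.cells_per_population, dtype=int), (K,)
        ).copy()
        if np.any(self.cells_per_population <= 0):
            raise ValueError("cells_per_population must be positive")

    def covariance(self, k: int) -> np.ndarray:
        p = len(self.marker_names)
        if self.population_cov is not None:
            S = np.asarray(self.population_cov[k], dtype=float)
            try:
                np.linalg.cholesky(S)
            except np.linalg.LinAlgError:
                raise ValueError(
                    f"requested covariance for population "
                    f"{self.population_names[k]!r} is not positive definite"
                ) from None
            return S
        return float(self.population_cov_scale[k]) ** 2 * np.eye(p)


def generate_reference_bm(config: ReferenceConfig) -> MarkerMatrix:
    """Draw labeled healthy reference cells, population by population.

    Cells are multivariate normal around each population's mean profile in
    arcsinh space; draw order is deterministic given the seed (populations
    in declared order).
    """
    rng = np.random.default_rng(config.seed)
    blocks, labels = [], []
    for k, name in enumerate(config.population_names):
        n = int(config.cells_per_population[k])
        blocks.append(
            rng.multivariate_normal(
                config.population_means[k], config.covariance(k), size=n,
                method="cholesky",
            )
        )
        labels.extend([name] * n)
    return MarkerMatrix(
        values=np.vstack(blocks),
        marker_names=list(config.marker_names),
        labels=np.array(labels, dtype=object),
        metadata={"source": "synthetic healthy BM"},
        transform_state="arcsinh(c=5)",
    )


# ---------------------------------------------------------------------------
# Patient cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedShift:
    """Additive marker shift confined to one population of one group."""

    group: str
    population: str
    marker: str
    delta: float


@dataclass
class CohortConfig:
    """Patient cohort drawn as population mixtures over the reference."""

    groups: tuple[str, ...] = ("CR", "relapse")
    samples_per_group: dict | int = 6
    cells_per_sample: int = 2000
    population_mixture: dict | None = None   # group -> (K,) simplex
    planted_shift: PlantedShift | None = None
    seed: int = 0

    def mixtures(self, config: ReferenceConfig) -> dict:
        K = len(config.population_names)
        if self.population_mixture is None:
            mix = np.full(K, 1.0 / K)
            out = {g: mix for g in self.groups}
        else:
            out = {g: np.asarray(self.population_mixture[g], dtype=float)
                   for g in self.groups}
        for g, m in out.items():
            if m.shape != (K,):
                raise ValueError(f"mixture for {g!r} has wrong length")
            if abs(m.sum() - 1.0) > 1e-9:
                raise ValueError(f"mixture for {g!r} does not sum to 1")
            if np.any(m < 0):
                raise ValueError(f"mixture for {g!r} has negative weights")
        return out

    def n_samples(self, group: str) -> int:
        if isinstance(self.samples_per_group, dict):
            return int(self.samples_per_group[group])
        return int(self.samples_per_group)


def generate_patient_cohort(
    config: CohortConfig, reference: ReferenceConfig
) -> list[MarkerMatrix]:
    """Labeled patient samples as population mixtures, with a planted shift.

    Each sample's per-population cell counts are multinomial draws from
    its group mixture; cells come from the reference geometry. When a
    planted shift is configured, ``delta`` is added to the stated marker
    for true members of the stated population in the stated group only.
    """
    shift = config.planted_shift
    if shift is not None:
        if shift.population not in reference.population_names:
            raise ValueError(f"unknown population {shift.population!r} in planted_shift")
        if shift.marker not in reference.marker_names:
            raise ValueError(f"unknown marker {shift.marker!r} in planted_shift")
        if shift.group not in config.groups:
            raise ValueError(f"unknown group {shift.group!r} in planted_shift")
        if not np.isfinite(shift.delta):
            raise ValueError("planted delta must be finite")

    rng = np.random.default_rng(config.seed)
    mixtures = config.mixtures(reference)
    marker_idx = {m: j for j, m in enumerate(reference.marker_names)}
    samples: list[MarkerMatrix] = []
    for group in config.groups:
        for s in range(config.n_samples(group)):
            counts = rng.multinomial(config.cells_per_sample, mixtures[group])
            blocks, labels = [], []
            for k, name in enumerate(reference.population_names):
                if counts[k] == 0:
                    continue
                cells = rng.multivariate_normal(
                    reference.population_means[k],
                    reference.covariance(k),
                    size=int(counts[k]),
                    method="cholesky",
                )
                if (
                    shift is not None
                    and group == shift.group
                    and name == shift.population
                ):
                    cells[:, marker_idx[shift.marker]] += shift.delta
                blocks.append(cells)
                labels.extend([name] * int(counts[k]))
            samples.append(
                MarkerMatrix(
                    values=np.vstack(blocks),
                    marker_names=list(reference.marker_names),
                    labels=np.array(labels, dtype=object),
                    metadata={"sample_id": f"{group}_{s + 1}", "group": group},
                    transform_state="arcsinh(c=5)",
                )
            )
    return samples


# ---------------------------------------------------------------------------
# CITE-seq count matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DESpec:
    """Planted differential expression: gene up (fold > 1) in ``group``.

    ``base_mean`` optionally pins the gene's baseline mean count so planted
    effects are simulated at a known expression level.
    """

    gene: str
    fold_change: float
    group: str = "relapse"
    base_mean: float | None = None


@dataclass(frozen=True)
class SignatureSpec:
    """Gene program jointly elevated by ``fold`` in ``group``."""

    genes: tuple[str, ...]
    fold: float = 2.0
    group: str = "relapse"
    base_mean: float | None = None


@dataclass
class MitoSpec:
    """Mitochondrial content: flagged genes and per-cell target fractions."""

    n_mito: int = 13
    base_fraction: float = 0.05
    cell_targets: dict = field(default_factory=dict)  # cell index -> fraction

    def __post_init__(self) -> None:
        fracs = [self.base_fraction, *self.cell_targets.values()]
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("mito fractions must lie in [0, 1]")


def _nb_counts(mean: np.ndarray, dispersion: float, rng) -> np.ndarray:
    """Gamma-Poisson (negative binomial) draw, var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    lam = rng.gamma(shape=r, scale=np.maximum(mean, 1e-12) / r)
    return rng.poisson(lam)


def generate_population_counts(
    populations: dict,
    n_genes: int = 2000,
    base_mean: float = 0.5,
    dispersion: float = 0.1,
    libsize_sigma: float = 0.3,
    mito_spec: MitoSpec | None = None,
    n_tags: int = 8,
    mean_overrides: dict | None = None,
    gene_ids: list[str] | None = None,
    base_means: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[CountMatrix, dict]:
    """NB count matrix over labeled cell populations with planted programs.

    ``populations`` maps a label to ``(n_cells, {gene: fold})``: each named
    gene's baseline mean is multiplied by ``fold`` in that population's
    cells. Default genes are ``G0000..`` with the first ``n_mito`` flagged
    ``MT-..``; pass ``gene_ids`` to use real gene names (``MT-`` prefix
    marks mitochondrial) and ``base_means`` to pin the per-gene baseline
    (e.g. to share one baseline between a healthy reference and tumor
    samples). Returns the matrix (with ``groups`` = labels) and a truth
    dict (baseline means, library factors, per-cell mito targets).
    """
    if mito_spec is None:
        mito_spec = MitoSpec()
    rng = np.random.default_rng(seed)
    n_mito = mito_spec.n_mito
    if gene_ids is None:
        gene_ids = [f"MT-{i:02d}" for i in range(n_mito)] + [
            f"G{i:04d}" for i in range(n_genes - n_mito)
        ]
    elif len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    mito_flags = np.array([g.startswith("MT-") for g in gene_ids])
    gene_idx = {g: i for i, g in enumerate(gene_ids)}

    if base_means is not None:
        base = np.asarray(base_means, dtype=float).copy()
        if base.shape != (n_genes,):
            raise ValueError("base_means length must equal n_genes")
    else:
        base = base_mean * rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    for gene, mu in (mean_overrides or {}).items():
        if gene not in gene_idx:
            raise KeyError(f"unknown gene {gene!r} in mean_overrides")
        base[gene_idx[gene]] = mu

    cells_mean, labels = [], []
    for label, (n_cells, folds) in populations.items():
        mu = base.copy()
        for gene, fold in folds.items():
            if fold <= 0:
                raise ValueError(f"fold change for {gene!r} must be positive")
            if gene not in gene_idx:
                raise KeyError(f"unknown gene {gene!r}")
            mu[gene_idx[gene]] *= fold
        cells_mean.append(np.tile(mu, (n_cells, 1)))
        labels.extend([label] * n_cells)
    M = np.vstack(cells_mean)              # cells x genes
    labels = np.array(labels, dtype=object)
    n_total = M.shape[0]

    lib = rng.lognormal(mean=0.0, sigma=libsize_sigma, size=n_total)
    M = M * lib[:, None]

    # steer the expected mitochondrial share per cell to its target
    targets = np.full(n_total, mito_spec.base_fraction)
    for j, f in mito_spec.cell_targets.items():
        targets[j] = f
    sum_m = M[:, mito_flags].sum(axis=1)
    sum_o = M[:, ~mito_flags].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(
            (targets < 1.0) & (sum_m > 0),
            targets * sum_o / np.maximum((1.0 - targets) * sum_m, 1e-300),
            1.0,
        )
    M[:, mito_flags] *= alpha[:, None]
    if np.any(targets >= 1.0):
        M[targets >= 1.0][:, ~mito_flags] = 0.0

    counts = _nb_counts(M, dispersion, rng).T.astype(np.int64)  # genes x cells

    tag_mean = rng.lognormal(mean=3.0, sigma=0.5, size=n_tags)
    tag_counts = _nb_counts(
        np.tile(tag_mean, (n_total, 1)) * lib[:, None], dispersion, rng
    ).T.astype(np.int64)

    cm = CountMatrix(
        counts=counts,
        gene_ids=gene_ids,
        cell_ids=[f"cell{j:05d}" for j in range(n_total)],
        mito_flags=mito_flags,
        tag_counts=tag_counts,
        tag_names=[f"AB{t}" for t in range(n_tags)],
        groups=labels,
    )
    truth = {
        "base_mean": pd.Series(base, index=gene_ids),
        "library_factors": lib,
        "mito_targets": targets,
        "populations": {k: v for k, v in populations.items()},
    }
    return cm, truth


def generate_citeseq_counts(
    n_cells: int | tuple[int, int] = 400,
    n_genes: int = 2000,
    de_spec: list[DESpec] = (),
    signature_spec: SignatureSpec | None = None,
    mito_spec: MitoSpec | None = None,
    seed: int = 0,
    groups: tuple[str, str] = ("CR", "relapse"),
    **kwargs,
) -> tuple[CountMatrix, dict]:
    """Two-condition CITE-seq count matrix with planted DE and a signature.

    ``n_cells`` is a total (split evenly) or an explicit per-group pair.
    ``de_spec`` genes have their baseline mean multiplied by the stated
    fold change in the stated group; ``signature_spec`` elevates its whole
    gene program in one group. Ground truth is returned alongside.
    """
    if isinstance(n_cells, int):
        n_a, n_b = n_cells // 2, n_cells - n_cells // 2
    else:
        n_a, n_b = n_cells
    folds: dict[str, dict[str, float]] = {groups[0]: {}, groups[1]: {}}
    overrides: dict[str, float] = dict(kwargs.pop("mean_overrides", {}) or {})
    for spec in de_spec:
        if spec.fold_change <= 0:
            raise ValueError(f"fold change for {spec.gene!r} must be positive")
        folds[spec.group][spec.gene] = spec.fold_change
        if spec.base_mean is not None:
            overrides[spec.gene] = spec.base_mean
    if signature_spec is not None:
        for gene in signature_spec.genes:
            folds[signature_spec.group][gene] = (
                folds[signature_spec.group].get(gene, 1.0) * signature_spec.fold
            )
            if signature_spec.base_mean is not None:
                overrides[gene] = signature_spec.base_mean
    populations = {
        groups[0]: (n_a, folds[groups[0]]),
        groups[1]: (n_b, folds[groups[1]]),
    }
    cm, truth = generate_population_counts(
        populations, n_genes=n_genes, mito_spec=mito_spec,
        mean_overrides=overrides, seed=seed, **kwargs
    )
    truth["de_spec"] = list(de_spec)
    truth["signature_spec"] = signature_spec
    return cm, truth


# ---------------------------------------------------------------------------
# Splice-read simulation
# ---------------------------------------------------------------------------

def default_toy_gene() -> ToyGeneModel:
    """Toy surface-receptor gene: 4 exons / 3 introns on one contig."""
    return ToyGeneModel(
        gene_id="TOY19",
        exons=((100, 400), (700, 1000), (1400, 1700), (2100, 2400)),
        strand="+",
    )


def generate_splice_reads(
    model: ToyGeneModel,
    psi_per_intron: np.ndarray | float,
    depth: int = 1000,
    read_len: int = 50,
    seed: int = 0,
) -> AlignmentSet:
    """Simulate uniquely placed single-end reads around each intron.

    For intron i with retention level psi_i, each of ``depth`` reads is
    retention-supporting with probability
    ``psi * lI / (psi * lI + (1 - psi) * lS)`` where ``lI = li + L - 1``
    start positions overlap the intron on the unspliced molecule and
    ``lS = L - 1`` positions span the splice junction — i.e. reads are
    sampled uniformly from a transcript pool containing a ``psi`` fraction
    of intron-retaining molecules. Retained reads are contiguous blocks
    overlapping the intron; spliced reads are gapped junction reads whose
    gap is exactly the intron. No sequence content or errors are modelled.
    """
    introns = model.introns
    psi = np.broadcast_to(np.asarray(psi_per_intron, dtype=float), (len(introns),))
    if np.any((psi < 0) | (psi > 1)):
        raise ValueError("psi values must lie in [0, 1]")
    if depth <= 0 or read_len <= 0:
        raise ValueError("depth and read_len must be positive")
    min_exon = min(e - s for s, e in model.exons)
    if read_len > min_exon:
        raise ValueError(
            f"read_len {read_len} exceeds the shortest exon ({min_exon}); "
            "junction reads would be ill-defined"
        )

    rng = np.random.default_rng(seed)
    reads: list[tuple[str, tuple[tuple[int, int], ...]]] = []
    L = read_len
    for i, (istart, iend) in enumerate(introns):
        li = iend - istart
        lI, lS = li + L - 1, L - 1
        p_incl = psi[i] * lI / (psi[i] * lI + (1 - psi[i]) * lS) \
            if 0 < psi[i] < 1 else psi[i]
        exon_l, exon_r = model.exons[i], model.exons[i + 1]
        retained = rng.random(depth) < p_incl
        for j in range(depth):
            rid = f"intron{i}_read{j:05d}"
            if retained[j]:
                s = int(rng.integers(istart - (L - 1), iend))
                reads.append((rid, ((s, s + L),)))
            else:
                a = int(rng.integers(1, L))  # bases on the left exon
                reads.append(
                    (rid, ((exon_l[1] - a, exon_l[1]), (exon_r[0], exon_r[0] + L - a)))
                )
    return AlignmentSet(
        reads=reads,
        sample_id=f"sim_seed{seed}",
        chrom=model.chrom,
        reference_length=model.span[1] + 100,
    )
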