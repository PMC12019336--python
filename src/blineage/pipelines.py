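"""End-to-end evaluation pipelines on synthetic cohorts.

Each function wires the synthetic generators through the corresponding
analysis stage and measures how well the pipeline recovers what was
planted: the IKAROS shift confined to pro-BII cells of the relapse group
(CyTOF arm), the lowered IKZF1 plus elevated stem/progenitor program in
relapse pro-B-like cells (CITE-seq arm), false/true positive rates of the
filtered Wilcoxon differential expression, intron-retention estimator
accuracy, and exactness of the classifier and projection numerics against
brute-force linear algebra.

Problem sizes default to the cohort scales the pipeline is designed
around (6 vs 11 samples of 2,000 cells for the CyTOF contrast; hundreds
of cells and a few hundred genes per CITE-seq condition).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import ranksums

from . import synthetic
from .classifier import DevClassifier, classify
from .cytof import MarkerMatrix
from .expression import (
    CountMatrix,
    module_score,
    normalize,
    qc_filter,
    wilcoxon_de,
)
from .projection import ReferenceProjector, assign, fit_knn, fit_projection, project
from .splicing import quantify_intron
from .synthetic import (
    CohortConfig,
    DESpec,
    PlantedShift,
    ReferenceConfig,
    SignatureSpec,
    default_toy_gene,
    generate_citeseq_counts,
    generate_patient_cohort,
    generate_population_counts,
    generate_reference_bm,
    generate_splice_reads,
)

__all__ = [
    "child_seeds",
    "classifier_oracle_check",
    "cytof_shift_recovery",
    "projection_self_consistency",
    "citeseq_relapse_recovery",
    "de_error_control",
    "psi_recovery",
    "qc_fixture_check",
    "build_qc_fixture",
]


def child_seeds(seed: int, n: int) -> np.ndarray:
    """Independent per-replicate seeds derived from one base seed."""
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


# ---------------------------------------------------------------------------
# Classifier numerics
# ---------------------------------------------------------------------------

def classifier_oracle_check(n_cells: int = 500, seed: int = 0) -> dict:
    """Cholesky-based Mahalanobis distances vs a dense-inverse oracle.

    Fits the 15-population reference, classifies ``n_cells`` random query
    cells, and recomputes every distance with explicit matrix inverses.
    Returns the maximal relative distance discrepancy and the fraction of
    identical assignments.
    """
    ref_cfg = ReferenceConfig(cells_per_population=300, seed=int(seed))
    clf = DevClassifier().fit(generate_reference_bm(ref_cfg))
    model = clf.model_
    rng = np.random.default_rng(int(seed) + 1)
    X = rng.uniform(-1.0, 6.0, size=(n_cells, 10))
    cells = MarkerMatrix(
        values=X, marker_names=list(model.marker_order),
        transform_state="arcsinh(c=5)",
    )
    res = classify(cells, model, keep_distances=True)

    inv = [np.linalg.inv(S) for S in model.covariances]
    D = np.empty_like(res.distances)
    for k in range(model.n_populations):
        diff = X - model.means[k]
        D[:, k] = np.sqrt(np.einsum("ij,jk,ik->i", diff, inv[k], diff))
    rel_err = np.max(np.abs(res.distances - D) / np.maximum(D, 1e-300))

    names = np.array(model.population_names, dtype=object)
    oracle_assign = names[np.argmin(D, axis=1)].copy()
    oracle_assign[np.min(D, axis=1) >= res.threshold] = "unclassified"
    agree = float(np.mean(res.assignments == oracle_assign))
    return {"max_relative_distance_error": float(rel_err),
            "assignment_agreement": agree, "n": n_cells}


# ---------------------------------------------------------------------------
# CyTOF planted-shift recovery (relapse cohort contrast)
# ---------------------------------------------------------------------------

def cytof_shift_recovery(
    n_seeds: int = 100,
    seed: int = 0,
    n_cr: int = 6,
    n_relapse: int = 11,
    cells_per_sample: int = 2000,
    delta: float = -1.0,
    marker: str = "IKAROS",
    population: str = "pro-BII",
    alpha: float = 0.05,
) -> dict:
    """Recovery of a planted IKAROS decrease in relapse pro-BII cells.

    For each replicate cohort (``n_cr`` CR vs ``n_relapse`` relapse
    samples), cells are classified against a fixed healthy reference and
    the per-sample median marker level of each assigned population is
    compared between groups by rank-sum test. Reports how often the
    shifted population is detected (two-sided p < alpha with the correct
    direction) and, per unshifted population, how often a spurious
    difference appears.
    """
    ref_cfg = ReferenceConfig(cells_per_population=500, seed=int(seed) + 7)
    clf = DevClassifier().fit(generate_reference_bm(ref_cfg))
    pops = list(ref_cfg.population_names)

    detected = 0
    null_hits = {p: 0 for p in pops if p != population}
    for s in child_seeds(seed, n_seeds):
        cohort = generate_patient_cohort(
            CohortConfig(
                samples_per_group={"CR": n_cr, "relapse": n_relapse},
                cells_per_sample=cells_per_sample,
                planted_shift=PlantedShift("relapse", population, marker, delta),
                seed=int(s),
            ),
            ref_cfg,
        )
        medians: dict[str, dict[str, list[float]]] = {p: {} for p in pops}
        for sample in cohort:
            res = clf.classify(sample)
            vals = sample.marker(marker)
            group = sample.metadata["group"]
            for p in pops:
                mask = res.assignments == p
                if mask.any():
                    medians[p].setdefault(group, []).append(
                        float(np.median(vals[mask]))
                    )
        for p in pops:
            cr = medians[p].get("CR", [])
            rel = medians[p].get("relapse", [])
            if len(cr) < 2 or len(rel) < 2:
                continue
            pval = ranksums(cr, rel).pvalue
            if p == population:
                if pval < alpha and np.median(rel) < np.median(cr):
                    detected += 1
            elif pval < alpha:
                null_hits[p] += 1
    return {
        "n_seeds": n_seeds,
        "shift_detected": detected,
        "max_null_rejections": max(null_hits.values()),
        "null_rejections": null_hits,
        "n": n_seeds * (n_cr + n_relapse) * cells_per_sample,
    }


# ---------------------------------------------------------------------------
# Projection numerics
# ---------------------------------------------------------------------------

def projection_self_consistency(n_cells: int = 2000, seed: int = 0) -> dict:
    """Reprojection exactness and k-NN agreement with all-pairs search.

    Healthy cells are split over four Gaussian clusters in feature space;
    the fitted reference must reproduce its own PC scores on reprojection
    and the k-NN index must return exactly the brute-force neighbor vote.
    """
    rng = np.random.default_rng(int(seed))
    n_feat, n_clusters = 60, 4
    centers = rng.normal(0, 3, size=(n_clusters, n_feat))
    per = n_cells // n_clusters
    X = np.vstack([
        rng.normal(centers[c], 1.0, size=(per, n_feat)) for c in range(n_clusters)
    ])
    labels = np.repeat([f"cluster{c}" for c in range(n_clusters)], per)
    healthy = pd.DataFrame(X.T, index=[f"g{j}" for j in range(n_feat)])
    model = fit_projection(healthy, labels, n_pc=30)
    fit_knn(model, k=10, n_folds=10, seed=int(seed))

    reproj = project(healthy, model)
    max_err = float(np.max(np.abs(reproj - model.healthy_scores)))

    Q = rng.normal(0, 3, size=(200, n_feat))
    query = pd.DataFrame(Q.T, index=healthy.index)
    scores = project(query, model)
    res = assign(scores, model)

    mismatches = 0
    for i in range(scores.shape[0]):
        d = np.linalg.norm(model.healthy_scores - scores[i], axis=1)
        nn = np.argsort(d, kind="stable")[:10]
        votes = pd.Series(model.healthy_labels[nn]).value_counts()
        top = votes[votes == votes.max()]
        if len(top) == 1:
            if res.assignments[i] != top.index[0]:
                mismatches += 1
        else:  # distance tie-break replicated independently
            cand = {
                lab: d[nn][model.healthy_labels[nn] == lab].mean()
                for lab in top.index
            }
            win = min(sorted(cand), key=lambda lab: cand[lab])
            if res.assignments[i] != win:
                mismatches += 1
    return {
        "max_reprojection_error": max_err,
        "knn_assignment_mismatches": mismatches,
        "cv_accuracy": model.cv_accuracy,
        "n": n_cells,
    }


# ---------------------------------------------------------------------------
# CITE-seq relapse-program recovery (projection + DE + module score)
# ---------------------------------------------------------------------------

_SIGNATURE = tuple(f"HSC{i:02d}" for i in range(10))


def _citeseq_gene_space(n_genes: int) -> list[str]:
    ids = [f"MT-{i:02d}" for i in range(13)] + ["IKZF1"] + list(_SIGNATURE)
    ids += [f"G{i:04d}" for i in range(n_genes - len(ids))]
    return ids


def citeseq_relapse_recovery(
    n_seeds: int = 100,
    seed: int = 0,
    n_genes: int = 400,
    healthy_per_pop: int = 250,
    tumor_per_group: int = 300,
    ikzf1_fold: float = 0.4,
    signature_fold: float = 2.0,
    alpha: float = 0.05,
) -> dict:
    """Fig-style CITE-seq contrast: relapse pro-B-like cells carry lower
    IKZF1 and an elevated stem/progenitor program.

    A healthy reference of three expression populations (pro-B-like,
    mature-B-like, progenitor-like) is fitted once; per replicate, CR and
    relapse tumor cells resembling the pro-B program are generated (the
    relapse cells with ``ikzf1_fold`` on IKZF1 and ``signature_fold`` on
    the signature genes), projected, assigned by 10-NN vote, and the
    assigned-pro-B subset is tested for IKZF1 differential expression
    (full filter chain) and a higher module score (one-sided rank sum).
    """
    gene_ids = _citeseq_gene_space(n_genes)

    def program(i0: int, n: int = 20, fold: float = 4.0) -> dict:
        return {f"G{j:04d}": fold for j in range(i0, i0 + n)}

    prob_prog = {**program(10), "IKZF1": 3.0}
    healthy_pops = {
        "pro-B": (healthy_per_pop, prob_prog),
        "mature-B": (healthy_per_pop, program(50)),
        "progenitor": (
            healthy_per_pop,
            {**program(90), **{g: signature_fold for g in _SIGNATURE}},
        ),
    }
    healthy, truth = generate_population_counts(
        healthy_pops, n_genes=n_genes, gene_ids=gene_ids, seed=int(seed) + 13
    )
    projector = ReferenceProjector(n_mvg=3 * n_genes // 4, n_pc=30, seed=int(seed)).fit(
        normalize(healthy), healthy.groups
    )
    base = truth["base_mean"].to_numpy()

    ikzf1_hits = module_hits = 0
    assigned_fracs = []
    for s in child_seeds(seed, n_seeds):
        tumor_pops = {
            "CR": (tumor_per_group, prob_prog),
            "relapse": (
                tumor_per_group,
                {
                    **prob_prog,
                    "IKZF1": 3.0 * ikzf1_fold,
                    **{g: signature_fold for g in _SIGNATURE},
                },
            ),
        }
        tumor, _ = generate_population_counts(
            tumor_pops, n_genes=n_genes, gene_ids=gene_ids,
            base_means=base, seed=int(s),
        )
        tnorm = normalize(tumor)
        res = projector.assign(tnorm)
        mask = res.assignments == "pro-B"
        assigned_fracs.append(float(mask.mean()))
        sub = tnorm.loc[:, mask.tolist()]
        groups = tumor.groups[mask]
        if (groups == "CR").sum() < 3 or (groups == "relapse").sum() < 3:
            continue
        de = wilcoxon_de(sub, groups)
        if bool(de.loc["IKZF1", "significant"]) and (
            de.loc["IKZF1", "log2_fold_change"] > 0  # CR over relapse
        ):
            ikzf1_hits += 1
        score = module_score(sub, list(_SIGNATURE), seed=int(s))
        p = ranksums(
            score[groups == "relapse"], score[groups == "CR"],
            alternative="greater",
        ).pvalue
        if p < alpha:
            module_hits += 1
    return {
        "n_seeds": n_seeds,
        "ikzf1_de_detected": ikzf1_hits,
        "module_score_detected": module_hits,
        "mean_assigned_pro_b_fraction": float(np.mean(assigned_fracs)),
        "reference_cv_accuracy": projector.model_.cv_accuracy,
        "n": n_seeds * 2 * tumor_per_group,
    }


# ---------------------------------------------------------------------------
# DE error control
# ---------------------------------------------------------------------------

def de_error_control(
    n_null_seeds: int = 200,
    n_power_seeds: int = 100,
    seed: int = 0,
    n_genes: int = 2000,
    cells_per_group: int = 200,
    planted_fold: float = 4.0,
) -> dict:
    """Family-wise error and power of the filtered Wilcoxon DE chain.

    Null replicates carry no planted genes; the chain (QC, normalization,
    fraction/fold-change/Bonferroni filters) should call any gene
    significant in at most ~alpha of replicates. Power replicates plant a
    single ``planted_fold`` gene at mean 5 counts.
    """
    def run(seed_i: int, spec: list[DESpec]) -> pd.DataFrame:
        cm, _ = generate_citeseq_counts(
            n_cells=(cells_per_group, cells_per_group),
            n_genes=n_genes, de_spec=spec, seed=seed_i,
        )
        filtered, _ = qc_filter(cm, min_genes=100, min_counts=100)
        return wilcoxon_de(normalize(filtered), filtered.groups)

    null_hits = 0
    for s in child_seeds(seed, n_null_seeds):
        res = run(int(s), [])
        null_hits += int(res["significant"].any())

    power_hits = 0
    for s in child_seeds(seed + 1, n_power_seeds):
        res = run(int(s), [DESpec("G0100", planted_fold, base_mean=5.0)])
        power_hits += int(res.loc["G0100", "significant"])
    return {
        "null_seeds": n_null_seeds,
        "null_any_significant": null_hits,
        "fwer_percent": 100.0 * null_hits / n_null_seeds,
        "power_seeds": n_power_seeds,
        "power_detected": power_hits,
        "power_percent": 100.0 * power_hits / n_power_seeds,
        "n": 2 * cells_per_group,
    }


# ---------------------------------------------------------------------------
# Splicing estimator
# ---------------------------------------------------------------------------

def psi_recovery(
    depth: int = 10_000,
    seed: int = 0,
    psis: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9),
    read_len: int = 50,
) -> dict:
    """Worst-case inclusion-level estimation error over planted psi values."""
    gene = default_toy_gene()
    max_err = 0.0
    for j, psi in enumerate(psis):
        aln = generate_splice_reads(
            gene, psi, depth=depth, read_len=read_len, seed=int(seed) + j
        )
        for i in range(len(gene.introns)):
            q = quantify_intron(aln, gene, i, read_len=read_len)
            max_err = max(max_err, abs(q.psi - psi))
    return {"max_psi_error": max_err, "depth": depth, "n": depth * len(psis) * 3}


# ---------------------------------------------------------------------------
# QC exactness
# ---------------------------------------------------------------------------

def build_qc_fixture(seed: int = 0) -> CountMatrix:
    """10-cell fixture with enumerated QC failures.

    Against thresholds (min_genes=500, min_counts=600, max_mito=0.5):
    5 clean cells, 2 gene-poor, 1 low-count, 1 high-mito, and 1 cell
    failing both the gene and the count rule -> exactly 5 survivors.
    """
    rng = np.random.default_rng(int(seed))
    n_genes = 600
    counts = np.zeros((n_genes, 10), dtype=np.int64)

    def fill(j: int, n_expressed: int, per_gene: int) -> None:
        idx = rng.choice(n_genes - 1, size=n_expressed, replace=False) + 1
        counts[idx, j] = per_gene

    for j in range(5):
        fill(j, 520, 2)
    fill(5, 450, 2)
    fill(6, 450, 2)
    fill(7, 510, 1)
    fill(8, 520, 2)
    counts[0, 8] = 2000  # gene 0 is mitochondrial
    fill(9, 450, 1)
    mito = np.zeros(n_genes, dtype=bool)
    mito[0] = True
    return CountMatrix(
        counts=counts,
        gene_ids=[f"g{i}" for i in range(n_genes)],
        cell_ids=[f"c{j}" for j in range(10)],
        mito_flags=mito,
    )


def qc_fixture_check(seed: int = 0) -> dict:
    filtered, report = qc_filter(
        build_qc_fixture(seed), min_genes=500, min_counts=600, max_mito=0.5
    )
    return {
        "survivors": filtered.n_cells,
        "removed": report.n_removed,
        "removed_low_genes": report.removed_low_genes,
        "removed_low_counts": report.removed_low_counts,
        "removed_high_mito": report.removed_high_mito,
        "n": 10,
    }
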