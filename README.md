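# blineage

**B-cell developmental mapping of leukemia from single-cell data.**

In B-cell acute lymphoblastic leukemia (B-ALL), relapse after CD19- or
CD22-targeted immunotherapy is often driven by *antigen escape*: the tumor
loses or reduces the targeted surface protein. Low levels of the B-lineage
transcription factor IKAROS (*IKZF1*) mark tumors at risk, and the risk
signal concentrates in leukemic cells that resemble a specific stage of
normal B-cell development (pro-B). `blineage` implements the single-cell
computational machinery needed to make and test that kind of claim:

1. **Developmental classifier (CyTOF).** Each leukemia cell is assigned to
   its most similar healthy bone-marrow population by Mahalanobis distance
   in the space of ten B-cell developmental proteins (CD19, CD20, CD24,
   CD34, CD38, CD45, CD127, CD179b, IgMi, TdT). For population *k* with
   mean μ<sub>k</sub> and covariance Σ<sub>k</sub>,

   d<sub>k</sub>(x) = √((x − μ<sub>k</sub>)ᵀ Σ<sub>k</sub>⁻¹ (x − μ<sub>k</sub>)),

   and a cell is *unclassified* when min<sub>k</sub> d<sub>k</sub> ≥ 10
   (a threshold matched to the ten dimensions). Intensities are arcsinh-
   transformed with cofactor 5; per-population covariances are shrunk
   toward their diagonal so small gated populations stay invertible.
2. **Healthy-reference projection (CITE-seq).** PCA is fitted on healthy
   bone-marrow cells over the 3000 most variable genes plus CLR-normalized
   antibody tags; tumor cells are *predicted* into the top 30 healthy PCs
   and associated with their closest healthy population by 10-nearest-
   neighbor majority vote (10-fold CV reported as a diagnostic).
3. **Expression stage.** QC (≥500 expressed genes, ≥200 molecules, ≤50%
   mitochondrial counts), library-size + log1p normalization with
   regression-based removal of the mitochondrial fraction, Wilcoxon
   rank-sum differential expression with the fraction ≥ 10% /
   |fold change| ≥ 25% / Bonferroni-adjusted p < 0.05 filter chain, and a
   per-cell gene-signature module score against expression-matched
   control genes.
4. **Intron retention (bulk RNA-seq).** From gapped alignments over a gene
   model: retention ratio (intron-overlapping reads over intron +
   flanking-exon reads) and the length-normalized retained-intron
   inclusion level ψ = (I/l<sub>I</sub>) / (I/l<sub>I</sub> + S/l<sub>S</sub>),
   with a pooled two-proportion comparison between groups under
   Benjamini–Hochberg correction.

A synthetic-data module generates every input with known ground truth —
a 15-population healthy reference, patient cohorts with a planted IKAROS
shift, negative-binomial CITE-seq counts with planted DE genes and a
planted progenitor signature, and splice reads with known retention — so
the whole pipeline is testable end to end.

## Worked example

```python
import numpy as np
import blineage as bl

# healthy reference and classifier
ref_cfg = bl.ReferenceConfig(cells_per_population=500, seed=0)
healthy = bl.generate_reference_bm(ref_cfg)
clf = bl.DevClassifier(threshold=10.0).fit(healthy)

# a relapse-like patient sample with an IKAROS deficit in pro-BII cells
cohort = bl.generate_patient_cohort(
    bl.CohortConfig(
        samples_per_group={"CR": 1, "relapse": 1}, cells_per_sample=2000,
        planted_shift=bl.PlantedShift("relapse", "pro-BII", "IKAROS", -1.0),
        seed=1,
    ),
    ref_cfg,
)
for sample in cohort:
    res = clf.classify(sample)
    pro_b = res.assignments == "pro-BII"
    med = np.median(sample.marker("IKAROS")[pro_b])
    print(f"{sample.metadata['sample_id']}: "
          f"{pro_b.mean():.3f} pro-BII-like, median IKAROS {med:.2f}")
```

prints

```
CR_1: 0.068 pro-BII-like, median IKAROS 2.98
relapse_1: 0.063 pro-BII-like, median IKAROS 2.05
```

Both samples contain a comparable pro-BII-like fraction, but the relapse
sample's pro-BII-like cells carry about one arcsinh unit less IKAROS —
exactly the planted deficit the CyTOF arm of the pipeline is built to
detect. `res.summary()` prints the full population-frequency table.

A thin CLI wraps the same functions
(`blineage simulate|preprocess|classify|qc|de|score|project|splice`).

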