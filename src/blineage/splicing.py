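"""Intron-retention quantification from read alignments.

Given a gene model and gapped single-end alignments, this module counts,
for a target intron, the reads supporting retention (any aligned base
inside the intron, including reads crossing an exon-intron boundary
contiguously), the junction reads whose gap exactly removes the intron,
and the reads confined to the two flanking exons. From these it derives

* the retention ratio — intron-overlapping reads over intron-overlapping
  plus flanking-exon reads (with the raw intron/exon quotient also
  reported), and
* the length-normalized retained-intron inclusion level
  psi = (I/lI) / (I/lI + S/lS),

plus a pooled two-proportion comparison between sample groups with
Benjamini-Hochberg correction across events.

All intervals are 0-based half-open internally; GTF coordinates are
converted on I/O. Counting is strand-symmetric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

__all__ = [
    "ToyGeneModel",
    "AlignmentSet",
    "SpliceQuantification",
    "count_region_reads",
    "retention_ratio",
    "ri_inclusion_level",
    "quantify_intron",
    "compare_inclusion",
]


@dataclass(frozen=True)
class ToyGeneModel:
    """Single-gene exon/intron model on one reference sequence.

    Exons are 0-based half-open, sorted and non-overlapping; introns are
    exactly the gaps between consecutive exons.
    """

    gene_id: str
    exons: tuple[tuple[int, int], ...]
    strand: str = "+"
    chrom: str = "chr_toy"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not self.exons:
            raise ValueError("gene model needs at least one exon")
        prev_end = -1
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"empty exon interval ({s}, {e})")
            if s <= prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = e
        for s, e in self.introns:
            if e <= s:
                raise ValueError("adjacent exons leave an empty intron")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    # -- GTF I/O (1-based closed on disk) ------------------------------
    def to_gtf(self, path) -> None:
        with open(path, "w") as fh:
            s0, e0 = self.span
            attrs = f'gene_id "{self.gene_id}";'
            fh.write(
                f"{self.chrom}\tblineage\tgene\t{s0 + 1}\t{e0}\t.\t"
                f"{self.strand}\t.\t{attrs}\n"
            )
            for s, e in self.exons:
                fh.write(
                    f"{self.chrom}\tblineage\texon\t{s + 1}\t{e}\t.\t"
                    f"{self.strand}\t.\t{attrs}\n"
                )

    @classmethod
    def from_gtf(cls, path) -> "ToyGeneModel":
        exons: list[tuple[int, int]] = []
        gene_id, strand, chrom = "gene", "+", "chr_toy"
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if f[2] != "exon":
                    continue
                chrom, strand = f[0], f[6]
                exons.append((int(f[3]) - 1, int(f[4])))
                if 'gene_id "' in f[8]:
                    gene_id = f[8].split('gene_id "')[1].split('"')[0]
        return cls(gene_id=gene_id, exons=tuple(sorted(exons)), strand=strand, chrom=chrom)


@dataclass
class AlignmentSet:
    """Gapped single-end alignments as per-read block lists.

    Each read is an ordered list of aligned blocks (0-based half-open on
    one reference); gaps between consecutive blocks are splice-junction
    gaps (CIGAR N operations).
    """

    reads: list[tuple[str, tuple[tuple[int, int], ...]]]
    sample_id: str = "sample"
    chrom: str = "chr_toy"
    reference_length: int | None = None

    def __post_init__(self) -> None:
        for rid, blocks in self.reads:
            prev_end = -1
            for s, e in blocks:
                if e <= s:
                    raise ValueError(f"read {rid}: empty block ({s}, {e})")
                if s < prev_end:
                    raise ValueError(f"read {rid}: blocks overlap or unsorted")
                prev_end = e
            if self.reference_length is not None and prev_end > self.reference_length:
                raise ValueError(
                    f"read {rid} extends beyond the reference "
                    f"({prev_end} > {self.reference_length})"
                )

    def __len__(self) -> int:
        return len(self.reads)

    # -- SAM I/O -------------------------------------------------------
    def to_sam(self, path) -> None:
        """Plain-text SAM with CIGAR M/N runs derived from the blocks."""
        ref_len = self.reference_length or max(
            (b[-1][1] for _, b in self.reads), default=1
        )
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            fh.write(f"@SQ\tSN:{self.chrom}\tLN:{ref_len}\n")
            for rid, blocks in self.reads:
                cigar = []
                for i, (s, e) in enumerate(blocks):
                    if i:
                        cigar.append(f"{s - blocks[i - 1][1]}N")
                    cigar.append(f"{e - s}M")
                seq_len = sum(e - s for s, e in blocks)
                fh.write(
                    f"{rid}\t0\t{self.chrom}\t{blocks[0][0] + 1}\t60\t"
                    f"{''.join(cigar)}\t*\t0\t0\t{'N' * seq_len}\t*\n"
                )

    @classmethod
    def from_sam(cls, path, sample_id: str | None = None) -> "AlignmentSet":
        import pysam

        reads = []
        chrom = "chr_toy"
        ref_len = None
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            if sam.nreferences:
                chrom = sam.references[0]
                ref_len = sam.lengths[0]
            for rec in sam:
                if rec.is_unmapped:
                    continue
                blocks = tuple((s, e) for s, e in rec.get_blocks())
                reads.append((rec.query_name, blocks))
        return cls(
            reads=reads,
            sample_id=sample_id or str(path),
            chrom=chrom,
            reference_length=ref_len,
        )

    # block TSV: read_id <tab> comma-joined start-end pairs
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tblocks\n")
            for rid, blocks in self.reads:
                fh.write(rid + "\t" + ",".join(f"{s}-{e}" for s, e in blocks) + "\n")

    @classmethod
    def from_tsv(cls, path, sample_id: str | None = None) -> "AlignmentSet":
        reads = []
        with open(path) as fh:
            next(fh)
            for line in fh:
                rid, blockstr = line.rstrip("\n").split("\t")
                blocks = tuple(
                    tuple(map(int, b.split("-"))) for b in blockstr.split(",")
                )
                reads.append((rid, blocks))
        return cls(reads=reads, sample_id=sample_id or str(path))


@dataclass
class SpliceQuantification:
    """Counts and derived statistics for one intron in one sample."""

    sample_id: str
    intron_index: int
    inclusion_count: int          # I: retention-supporting reads
    skipping_count: int           # S: exact-junction reads
    intron_overlap: int
    flank_exon: int
    inclusion_length: float
    skipping_length: float
    retention: float              # bounded I/(I+E) form; NaN when undefined
    retention_quotient: float     # raw intron/exon quotient; NaN when undefined
    psi: float                    # length-normalized inclusion level; NaN when undefined

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _overlaps(block: tuple[int, int], iv: tuple[int, int]) -> bool:
    return block[0] < iv[1] and block[1] > iv[0]


def _contained(block: tuple[int, int], iv: tuple[int, int]) -> bool:
    return block[0] >= iv[0] and block[1] <= iv[1]


def count_region_reads(
    a: AlignmentSet, g: ToyGeneModel, intron_index: int
) -> tuple[int, int, int, int]:
    """Count reads informative about one intron.

    Returns ``(I, S, intron_overlap, flank_exon)`` where

    * ``intron_overlap`` — reads with at least one aligned base inside the
      intron (this includes reads crossing an exon-intron boundary
      contiguously, so it equals the inclusion-supporting count ``I``);
    * ``S`` — reads with a junction gap exactly matching the intron;
    * ``flank_exon`` — reads whose blocks all lie within the two flanking
      exons and that carry no junction gap covering this intron.

    Every read lands in at most one of {S, intron_overlap}: a read whose
    gap removes the intron has no aligned base inside it.
    """
    introns = g.introns
    if not 0 <= intron_index < len(introns):
        raise IndexError(f"gene has {len(introns)} introns; asked for {intron_index}")
    intron = introns[intron_index]
    exon_l = g.exons[intron_index]
    exon_r = g.exons[intron_index + 1]
    gene_end = g.span[1]

    n_overlap = n_skip = n_flank = 0
    for rid, blocks in a.reads:
        if blocks[-1][1] > gene_end and a.reference_length is None:
            raise ValueError(f"read {rid} extends beyond the reference gene span")
        gaps = [
            (blocks[i][1], blocks[i + 1][0]) for i in range(len(blocks) - 1)
        ]
        overlaps_intron = any(_overlaps(b, intron) for b in blocks)
        skips_intron = intron in gaps
        if overlaps_intron:
            n_overlap += 1
        elif skips_intron:
            n_skip += 1
        in_flanks = all(
            _contained(b, exon_l) or _contained(b, exon_r) for b in blocks
        )
        gap_covers = any(gs <= intron[0] and ge >= intron[1] for gs, ge in gaps)
        if in_flanks and not gap_covers:
            n_flank += 1
    # inclusion evidence = any aligned base in the intron, boundary-crossing
    # contiguous reads included by construction
    return n_overlap, n_skip, n_overlap, n_flank


def retention_ratio(intron_overlap: int, flank_exon: int) -> tuple[float, float]:
    """Intron-read retention as a bounded proportion and as a raw quotient.

    Returns ``(intron/(intron+exon), intron/exon)``; each is NaN where its
    denominator is zero.
    """
    if intron_overlap < 0 or flank_exon < 0:
        raise ValueError("counts must be non-negative")
    total = intron_overlap + flank_exon
    bounded = intron_overlap / total if total > 0 else math.nan
    quotient = intron_overlap / flank_exon if flank_exon > 0 else math.nan
    return bounded, quotient


def ri_inclusion_level(I: int, S: int, lI: float, lS: float) -> float:
    """Length-normalized retained-intron inclusion level.

    psi = (I/lI) / (I/lI + S/lS); NaN when both counts are zero.
    """
    if lI <= 0 or lS <= 0:
        raise ValueError("effective lengths must be positive")
    if I < 0 or S < 0:
        raise ValueError("counts must be non-negative")
    if I == 0 and S == 0:
        return math.nan
    inc = I / lI
    return inc / (inc + S / lS)


def quantify_intron(
    a: AlignmentSet,
    g: ToyGeneModel,
    intron_index: int,
    read_len: int | None = None,
) -> SpliceQuantification:
    """Full per-sample quantification of one intron.

    Effective lengths follow the generating geometry of uniquely placed
    single-end reads of length L: an intron of length li offers
    ``li + L - 1`` start positions overlapping it, a junction offers
    ``L - 1`` spanning positions. When ``read_len`` is None it is taken
    as the modal aligned length of the reads.
    """
    I, S, n_overlap, n_flank = count_region_reads(a, g, intron_index)
    if read_len is None:
        lens = [sum(e - s for s, e in blocks) for _, blocks in a.reads]
        read_len = int(pd.Series(lens).mode().iloc[0]) if lens else 1
    intron = g.introns[intron_index]
    li = intron[1] - intron[0]
    lI = li + read_len - 1
    lS = max(read_len - 1, 1)
    bounded, quotient = retention_ratio(n_overlap, n_flank)
    psi = ri_inclusion_level(I, S, lI, lS) if (I or S) else math.nan
    return SpliceQuantification(
        sample_id=a.sample_id,
        intron_index=intron_index,
        inclusion_count=I,
        skipping_count=S,
        intron_overlap=n_overlap,
        flank_exon=n_flank,
        inclusion_length=lI,
        skipping_length=lS,
        retention=bounded,
        retention_quotient=quotient,
        psi=psi,
    )


def compare_inclusion(
    group_a: list[SpliceQuantification],
    group_b: list[SpliceQuantification],
    alpha_fdr: float = 0.05,
) -> pd.DataFrame:
    """Two-group comparison of inclusion across events (introns).

    Counts are pooled within each group per event and compared with a
    two-proportion z-test on length-normalized inclusion fractions,
    followed by Benjamini-Hochberg correction across events. Events with
    zero total counts are reported NA and excluded from the corrected
    family. This is a deliberately simple screening test, not a
    reimplementation of a full splicing likelihood model.
    """
    if not group_a or not group_b:
        raise ValueError("each group needs at least one sample")

    def pool(quants):
        d: dict[int, list[float]] = {}
        for q in quants:
            acc = d.setdefault(q.intron_index, [0.0, 0.0])
            # length-normalize before pooling so long introns don't dominate
            acc[0] += q.inclusion_count / q.inclusion_length * q.skipping_length
            acc[1] += q.skipping_count
        return d

    pa, pb = pool(group_a), pool(group_b)
    events = sorted(set(pa) | set(pb))
    rows = []
    for ev in events:
        ia, sa = pa.get(ev, [0.0, 0.0])
        ib, sb = pb.get(ev, [0.0, 0.0])
        na, nb = ia + sa, ib + sb
        if na == 0 or nb == 0:
            rows.append((ev, np.nan, np.nan, np.nan, np.nan))
            continue
        psi_a, psi_b = ia / na, ib / nb
        if (ia + ib == 0) or (sa + sb == 0):
            p = 1.0  # identical degenerate proportions
        else:
            _, p = proportions_ztest(
                np.round([ia, ib]), np.round([na, nb])
            )
        rows.append((ev, psi_a, psi_b, psi_a - psi_b, p))
    df = pd.DataFrame(
        rows, columns=["intron_index", "psi_a", "psi_b", "delta_psi", "pvalue"]
    ).set_index("intron_index")
    valid = df["pvalue"].notna()
    df["qvalue"] = np.nan
    if valid.any():
        df.loc[valid, "qvalue"] = multipletests(
            df.loc[valid, "pvalue"], method="fdr_bh"
        )[1]
    df["significant"] = df["qvalue"] < alpha_fdr
    return df
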