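"""Exonic/intronic TE annotation.

Per gene, exons of all transcripts are merged (distance-0 merge, so bookended
exons join); introns are the gene span minus the merged exons, kept only when
they lie within a single gene's span.  TEs intersecting merged exons are
classified into one of six structural categories relative to the gene:

* ``TSS``          — overlaps the first exonic nucleotide of the gene
* ``TTS``          — overlaps the last exonic nucleotide of the gene
* ``encompassing`` — the merged exon lies entirely within the TE
* ``acceptor``     — crosses the exon 5' boundary into the intron
* ``donor``        — crosses the exon 3' boundary into the intron
* ``inside``       — the TE lies entirely within the exon

When several definitions apply the precedence is
TSS > TTS > encompassing > acceptor > donor > inside.  Relative strand is
``sense`` when the TE's annotated strand equals the gene strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import intervals as iv
from .io_formats import GeneModel, GenomicInterval, TEInstance

__all__ = [
    "MergedExonSet",
    "IntronSet",
    "ExonicTERecord",
    "AnnotationError",
    "CATEGORIES",
    "merge_exons",
    "derive_introns",
    "classify_exonic_tes",
    "intersect_tes",
    "coverage_by_type",
    "exonic_records_table",
]

CATEGORIES = ("TSS", "acceptor", "donor", "inside", "encompassing", "TTS")


class AnnotationError(ValueError):
    pass


@dataclass
class MergedExonSet:
    gene_id: str
    chrom: str
    strand: str
    intervals: list[GenomicInterval]

    @property
    def total_nt(self) -> int:
        return sum(e.length for e in self.intervals)

    @property
    def span(self) -> tuple[int, int]:
        return self.intervals[0].start, self.intervals[-1].end


@dataclass
class IntronSet:
    gene_id: str
    chrom: str
    strand: str
    intervals: list[GenomicInterval]

    @property
    def total_nt(self) -> int:
        return sum(e.length for e in self.intervals)


@dataclass
class ExonicTERecord:
    """One (TE instance, merged exon) overlap."""

    te: TEInstance
    gene_id: str
    exon: GenomicInterval
    category: str
    relative_strand: Optional[str]  # "sense"/"antisense"; None for unstranded TE
    overlap_nt: int


def merge_exons(gene: GeneModel) -> MergedExonSet:
    """Union of all exons of all transcripts of ``gene`` (bookended merge)."""
    strands = {t.strand for t in gene.transcripts}
    chroms = {t.chrom for t in gene.transcripts}
    if len(strands) > 1 or len(chroms) > 1:
        raise AnnotationError(
            f"gene {gene.gene_id}: transcripts on conflicting strands/chromosomes"
        )
    starts = [e.start for t in gene.transcripts for e in t.exons]
    ends = [e.end for t in gene.transcripts for e in t.exons]
    ms, me = iv.merge(starts, ends, bookended=True)
    chrom, strand = chroms.pop(), strands.pop()
    return MergedExonSet(
        gene_id=gene.gene_id,
        chrom=chrom,
        strand=strand,
        intervals=[GenomicInterval(chrom, int(s), int(e), strand) for s, e in zip(ms, me)],
    )


def derive_introns(
    genes: Iterable[GeneModel], merged: Iterable[MergedExonSet]
) -> list[IntronSet]:
    """Gene span minus merged exons; introns overlapping a second gene's span
    are discarded so each retained intron belongs to a single gene."""
    merged = list(merged)
    by_gene = {m.gene_id: m for m in merged}
    spans_by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for m in merged:
        lo, hi = m.span
        spans_by_chrom.setdefault(m.chrom, []).append((lo, hi, m.gene_id))

    out = []
    for gene in genes:
        m = by_gene[gene.gene_id]
        lo, hi = m.span
        gs, ge = iv.subtract(
            (lo, hi), [e.start for e in m.intervals], [e.end for e in m.intervals]
        )
        kept = []
        for s, e in zip(gs, ge):
            n_genes = sum(
                1
                for (slo, shi, gid) in spans_by_chrom.get(m.chrom, [])
                if slo < e and s < shi
            )
            # own span always overlaps; any second span disqualifies
            if n_genes <= 1:
                kept.append(GenomicInterval(m.chrom, int(s), int(e), m.strand))
        out.append(
            IntronSet(gene_id=gene.gene_id, chrom=m.chrom, strand=m.strand, intervals=kept)
        )
    return out


def classify_exonic_tes(
    merged: Iterable[MergedExonSet],
    tes: Iterable[TEInstance],
    *,
    strict_strand: bool = False,
) -> list[ExonicTERecord]:
    """One record per overlapping (TE instance, merged exon interval) pair.

    Unstranded TEs get ``relative_strand=None`` (excluded from strand
    statistics downstream but retained for coverage).
    """
    tes = list(tes)
    by_chrom: dict[str, list[int]] = {}
    for i, te in enumerate(tes):
        by_chrom.setdefault(te.interval.chrom, []).append(i)
    idx_by_chrom = {
        chrom: (
            iv.IntervalIndex(
                [tes[i].interval.start for i in ids],
                [tes[i].interval.end for i in ids],
            ),
            ids,
        )
        for chrom, ids in by_chrom.items()
    }

    records: list[ExonicTERecord] = []
    for m in merged:
        if m.chrom not in idx_by_chrom:
            continue
        index, ids = idx_by_chrom[m.chrom]
        minus = m.strand == "-"
        # first/last exonic nucleotide in transcript orientation
        lo, hi = m.span
        first_nt = hi - 1 if minus else lo
        last_nt = lo if minus else hi - 1
        for exon in m.intervals:
            for j in index.overlapping(exon.start, exon.end):
                te = tes[ids[j]]
                s, e = te.interval.start, te.interval.end
                cat = _categorize_oriented(
                    s, e, exon.start, exon.end, first_nt, last_nt, minus
                )
                if te.interval.strand == ".":
                    rel = None
                else:
                    rel = "sense" if te.interval.strand == m.strand else "antisense"
                overlap = min(e, exon.end) - max(s, exon.start)
                records.append(
                    ExonicTERecord(
                        te=te,
                        gene_id=m.gene_id,
                        exon=exon,
                        category=cat,
                        relative_strand=rel,
                        overlap_nt=int(overlap),
                    )
                )
    return records


def _categorize_oriented(
    te_start: int,
    te_end: int,
    exon_start: int,
    exon_end: int,
    first_nt: int,
    last_nt: int,
    minus: bool,
) -> str:
    if te_start <= first_nt < te_end:
        return "TSS"
    if te_start <= last_nt < te_end:
        return "TTS"
    if te_start <= exon_start and te_end >= exon_end:
        return "encompassing"
    crosses_left = te_start < exon_start < te_end
    crosses_right = te_start < exon_end < te_end
    if crosses_left and crosses_right:
        # spans the whole exon — already handled by encompassing above
        return "encompassing"
    if crosses_left:
        return "donor" if minus else "acceptor"
    if crosses_right:
        return "acceptor" if minus else "donor"
    return "inside"


def intersect_tes(
    interval_sets: Iterable[MergedExonSet | IntronSet],
    tes: Iterable[TEInstance],
) -> pd.DataFrame:
    """TE x interval fragment table: one row per overlap with the clipped
    fragment coordinates.  Columns: chrom, frag_start, frag_end, te_type,
    te_index, gene_id, overlap_nt."""
    tes = list(tes)
    by_chrom: dict[str, list[int]] = {}
    for i, te in enumerate(tes):
        by_chrom.setdefault(te.interval.chrom, []).append(i)
    idx_by_chrom = {
        chrom: (
            iv.IntervalIndex(
                [tes[i].interval.start for i in ids],
                [tes[i].interval.end for i in ids],
            ),
            ids,
        )
        for chrom, ids in by_chrom.items()
    }
    rows = []
    for st in interval_sets:
        if st.chrom not in idx_by_chrom:
            continue
        index, ids = idx_by_chrom[st.chrom]
        for region in st.intervals:
            for j in index.overlapping(region.start, region.end):
                te = tes[ids[j]]
                fs = max(te.interval.start, region.start)
                fe = min(te.interval.end, region.end)
                rows.append(
                    (
                        st.chrom,
                        fs,
                        fe,
                        te.te_type,
                        ids[j],
                        st.gene_id,
                        fe - fs,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "frag_start", "frag_end", "te_type", "te_index",
            "gene_id", "overlap_nt",
        ],
    )


def coverage_by_type(
    interval_sets: Iterable[MergedExonSet | IntronSet],
    tes: Iterable[TEInstance],
) -> pd.DataFrame:
    """Per TE type, nucleotides of the interval union covered by >= 1 instance
    of that type (same-type overlaps counted once) and the covered fraction.

    Returns a DataFrame indexed by te_type with columns covered_nt, total_nt,
    fraction; every type present in ``tes`` appears (zero coverage included).
    """
    interval_sets = list(interval_sets)
    tes = list(tes)
    region_by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for st in interval_sets:
        for region in st.intervals:
            region_by_chrom.setdefault(st.chrom, ([], []))
            region_by_chrom[st.chrom][0].append(region.start)
            region_by_chrom[st.chrom][1].append(region.end)
    total_nt = 0
    merged_regions: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, (ss, ee) in region_by_chrom.items():
        ms, me = iv.merge(ss, ee, bookended=False)
        merged_regions[chrom] = (ms, me)
        total_nt += int(np.sum(me - ms))
    if total_nt == 0:
        raise AnnotationError("interval set has zero total length; fraction undefined")

    frag: dict[str, dict[str, tuple[list[int], list[int]]]] = {}
    all_types = sorted({te.te_type for te in tes})
    for te in tes:
        chrom = te.interval.chrom
        if chrom not in merged_regions:
            continue
        ms, me = merged_regions[chrom]
        # clip TE against merged region union (blocks are disjoint and sorted)
        lo_k = np.searchsorted(me, te.interval.start, side="right")
        hi_k = np.searchsorted(ms, te.interval.end, side="left")
        if hi_k <= lo_k:
            continue
        d = frag.setdefault(te.te_type, {}).setdefault(chrom, ([], []))
        for k in range(lo_k, hi_k):
            fs = max(int(ms[k]), te.interval.start)
            fe = min(int(me[k]), te.interval.end)
            if fe > fs:
                d[0].append(fs)
                d[1].append(fe)
    rows = []
    for t in all_types:
        covered = 0
        for chrom, (ss, ee) in frag.get(t, {}).items():
            covered += iv.union_length(ss, ee)
        rows.append((t, covered, total_nt, covered / total_nt))
    return pd.DataFrame(
        rows, columns=["te_type", "covered_nt", "total_nt", "fraction"]
    ).set_index("te_type")


def exonic_records_table(records: Iterable[ExonicTERecord]) -> pd.DataFrame:
    """Flatten classification records for TSV export."""
    rows = [
        {
            "chrom": r.te.interval.chrom,
            "te_start": r.te.interval.start,
            "te_end": r.te.interval.end,
            "te_strand": r.te.interval.strand,
            "te_type": r.te.te_type,
            "te_family": r.te.te_family,
            "te_class": r.te.te_class,
            "gene_id": r.gene_id,
            "exon_start": r.exon.start,
            "exon_end": r.exon.end,
            "category": r.category,
            "relative_strand": r.relative_strand if r.relative_strand else "NA",
            "overlap_nt": r.overlap_nt,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "te_start", "te_end", "te_strand", "te_type", "te_family",
            "te_class", "gene_id", "exon_start", "exon_end", "category",
            "relative_strand", "overlap_nt",
        ],
    )
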