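"""Shared fixtures: hand-built gene/TE fixtures and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from ridlmap.io_formats import GeneModel, GenomicInterval, TEInstance, Transcript


def mk_gene(gene_id, chrom, strand, exon_coords, n_tx=1, biotype="lncRNA"):
    """Gene with ``n_tx`` transcripts all sharing the given exon chain."""
    txs = [
        Transcript(
            transcript_id=f"{gene_id}.t{i + 1}",
            exons=[GenomicInterval(chrom, s, e, strand) for s, e in exon_coords],
        )
        for i in range(n_tx)
    ]
    return GeneModel(gene_id=gene_id, biotype=biotype, transcripts=txs)


def mk_te(chrom, start, end, strand="+", te_type="MIRb", cstart=1, cend=None, clen=None):
    length = end - start
    if clen is None:
        clen = max(length, cstart + length - 1)
    if cend is None:
        cend = cstart + length - 1
    return TEInstance(
        interval=GenomicInterval(chrom, start, end, strand),
        te_type=te_type,
        te_family="MIR",
        te_class="SINE",
        consensus_start=cstart,
        consensus_end=cend,
        consensus_length=clen,
    )


def brute_force_coverage(region_sets, tes, te_type):
    """Per-nucleotide oracle: covered nt of the region union touched by >= 1
    instance of ``te_type``."""
    region_nts = set()
    for st in region_sets:
        for r in st.intervals:
            region_nts.update((st.chrom, p) for p in range(r.start, r.end))
    covered = set()
    for te in tes:
        if te.te_type != te_type:
            continue
        for p in range(te.interval.start, te.interval.end):
            if (te.interval.chrom, p) in region_nts:
                covered.add((te.interval.chrom, p))
    return len(covered), len(region_nts)


def brute_force_overlap_pairs(a, b):
    """All (i, j) index pairs of overlapping intervals (chrom-aware)."""
    pairs = []
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            if x.chrom == y.chrom and x.start < y.end and y.start < x.end:
                pairs.append((i, j))
    return pairs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
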