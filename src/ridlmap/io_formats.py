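"""Readers and writers for the annotation formats the pipeline touches.

Internal convention is 0-based half-open coordinates everywhere; GTF (1-based,
closed) is converted at the boundary.  Strand ``.`` is accepted on input and
treated as unstranded downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "GenomicInterval",
    "Transcript",
    "GeneModel",
    "TEInstance",
    "ParseError",
    "parse_gtf",
    "write_gtf",
    "parse_te_bed",
    "write_te_bed",
    "parse_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "TE_COLUMNS",
]


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open stranded interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class Transcript:
    transcript_id: str
    exons: list[GenomicInterval]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand


@dataclass
class GeneModel:
    gene_id: str
    biotype: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        """min(start)..max(end) over all exons."""
        start = min(e.start for t in self.transcripts for e in t.exons)
        end = max(e.end for t in self.transcripts for e in t.exons)
        return GenomicInterval(self.chrom, start, end, self.strand)


@dataclass(frozen=True)
class TEInstance:
    """One RepeatMasker fragment with its consensus coordinates (1-based,
    closed, within the repeat consensus sequence)."""

    interval: GenomicInterval
    te_type: str
    te_family: str = "."
    te_class: str = "."
    consensus_start: int = 1
    consensus_end: int = 1
    consensus_length: int = 1

    def __post_init__(self):
        if not (
            1 <= self.consensus_start <= self.consensus_end <= self.consensus_length
        ):
            raise ValueError(
                f"invalid consensus coordinates for {self.te_type}: "
                f"{self.consensus_start}-{self.consensus_end}/{self.consensus_length}"
            )


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attrs(attr_field: str) -> dict[str, str]:
    return dict(_GTF_ATTR.findall(attr_field))


def parse_gtf(path, biotype_filter: Optional[str] = None) -> list[GeneModel]:
    """Read gene models from a GENCODE-dialect GTF.

    Only ``exon`` features are required; genes and transcripts are grouped via
    the ``gene_id``/``transcript_id`` attributes.  Biotype is taken from
    ``gene_type`` (falling back to ``gene_biotype``); when ``biotype_filter``
    is given, genes with a different biotype are dropped.
    """
    genes: dict[str, GeneModel] = {}
    tx_index: dict[tuple[str, str], Transcript] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 GTF fields")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates")
            if end_i < start_i:
                raise ParseError(f"{path}: line {lineno}: exon end < start")
            a = _parse_attrs(attrs)
            if "gene_id" not in a or "transcript_id" not in a:
                raise ParseError(
                    f"{path}: line {lineno}: missing gene_id/transcript_id"
                )
            biotype = a.get("gene_type", a.get("gene_biotype", "."))
            if biotype_filter is not None and biotype != biotype_filter:
                continue
            gid, tid = a["gene_id"], a["transcript_id"]
            gene = genes.setdefault(gid, GeneModel(gene_id=gid, biotype=biotype))
            key = (gid, tid)
            if key not in tx_index:
                tx = Transcript(transcript_id=tid, exons=[])
                tx_index[key] = tx
                gene.transcripts.append(tx)
            # GTF is 1-based closed; internal is 0-based half-open.
            tx_index[key].exons.append(
                GenomicInterval(chrom, start_i - 1, end_i, strand)
            )
    for gene in genes.values():
        for tx in gene.transcripts:
            tx.exons.sort(key=lambda e: (e.start, e.end))
    return list(genes.values())


def write_gtf(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(genes, key=lambda g: (g.chrom, g.span.start, g.gene_id)):
            for tx in gene.transcripts:
                for exon in tx.exons:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}"; '
                        f'gene_type "{gene.biotype}";'
                    )
                    fh.write(
                        "\t".join(
                            [
                                exon.chrom,
                                "ridlmap",
                                "exon",
                                str(exon.start + 1),
                                str(exon.end),
                                ".",
                                exon.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


#: internal name -> accepted column names (first match wins).  The UCSC rmsk
#: export dialect (genoName/genoStart/... repStart/repEnd) is accepted
#: alongside our own headers.
TE_COLUMNS: dict[str, tuple[str, ...]] = {
    "chrom": ("chrom", "genoName", "#chrom"),
    "start": ("start", "genoStart", "chromStart"),
    "end": ("end", "genoEnd", "chromEnd"),
    "strand": ("strand",),
    "te_type": ("repName", "te_type"),
    "te_class": ("repClass", "te_class"),
    "te_family": ("repFamily", "te_family"),
    "consensus_start": ("consensus_start", "repStart"),
    "consensus_end": ("consensus_end", "repEnd"),
    "consensus_length": ("consensus_length", "repLength"),
}


def parse_te_bed(path, column_map: Optional[dict[str, str]] = None) -> list[TEInstance]:
    """Read a RepeatMasker-style tab-separated TE table (with header row).

    ``column_map`` overrides the default internal-name -> file-column mapping.
    The parser is lossless: duplicated rows yield distinct instances.
    """
    df = pd.read_csv(path, sep="\t")
    resolved: dict[str, str] = {}
    for internal, candidates in TE_COLUMNS.items():
        if column_map and internal in column_map:
            candidates = (column_map[internal],)
        found = next((c for c in candidates if c in df.columns), None)
        if found is None:
            raise ParseError(f"{path}: missing required column for {internal!r} "
                             f"(accepted names: {candidates})")
        resolved[internal] = found
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rd = dict(zip(df.columns, row))
        start = int(rd[resolved["start"]])
        if start < 0:
            raise ParseError(f"{path}: line {i}: negative start")
        out.append(
            TEInstance(
                interval=GenomicInterval(
                    str(rd[resolved["chrom"]]),
                    start,
                    int(rd[resolved["end"]]),
                    str(rd[resolved["strand"]]),
                ),
                te_type=str(rd[resolved["te_type"]]),
                te_family=str(rd[resolved["te_family"]]),
                te_class=str(rd[resolved["te_class"]]),
                consensus_start=int(rd[resolved["consensus_start"]]),
                consensus_end=int(rd[resolved["consensus_end"]]),
                consensus_length=int(rd[resolved["consensus_length"]]),
            )
        )
    return out


def write_te_bed(tes: Iterable[TEInstance], path) -> None:
    rows = [
        {
            "chrom": te.interval.chrom,
            "start": te.interval.start,
            "end": te.interval.end,
            "repName": te.te_type,
            "strand": te.interval.strand,
            "repClass": te.te_class,
            "repFamily": te.te_family,
            "consensus_start": te.consensus_start,
            "consensus_end": te.consensus_end,
            "consensus_length": te.consensus_length,
        }
        for te in tes
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "repName", "strand", "repClass",
            "repFamily", "consensus_start", "consensus_end", "consensus_length",
        ],
    )
    df = df.sort_values(["chrom", "start", "end"], kind="stable")
    df.to_csv(path, sep="\t", index=False)


def parse_bed(path) -> list[tuple[GenomicInterval, str]]:
    """Read BED4/BED6 into (interval, name) pairs."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >= 3 BED fields")
            name = f[3] if len(f) > 3 else "."
            strand = f[5] if len(f) > 5 else "."
            out.append((GenomicInterval(f[0], int(f[1]), int(f[2]), strand), name))
    return out


def write_bed(records: Iterable[tuple[GenomicInterval, str]], path) -> None:
    """Write BED6, sorted by (chrom, start, end) for deterministic output."""
    recs = sorted(records, key=lambda r: (r[0].chrom, r[0].start, r[0].end, r[1]))
    with open(path, "w") as fh:
        for iv, name in recs:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.split()
            if len(f) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns")
            sizes[f[0]] = int(f[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")
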