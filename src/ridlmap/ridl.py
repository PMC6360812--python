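"""RIDL assembly: per-evidence instance filters, cross-evidence merging, the
minimum-length filter, and consensus insertion-profile comparisons.

Evidence semantics per candidate TE type:

* ``enrichment``   — every exonic instance of the type qualifies
* ``strand_bias``  — only instances in sense orientation to the host gene
* a conservation set — only instances overlapping >= 1 element of the
  specific conserved set that flagged the type

Qualifying instances are merged genome-wide (bedtools-merge semantics,
strand-ignorant); evidence labels and source instances are unioned on merge;
merged records shorter than 10 nt are discarded (length 10 survives).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from . import intervals as iv
from .annotation import ExonicTERecord
from .io_formats import GenomicInterval, TEInstance

__all__ = [
    "SelectedInstance",
    "RIDLInstance",
    "InsertionProfile",
    "ProfileComparison",
    "select_instances",
    "assemble_ridls",
    "insertion_profile",
    "compare_profiles",
    "ridls_to_bed_records",
    "count_ridls_per_transcript",
    "MIN_RIDL_LENGTH",
]

MIN_RIDL_LENGTH = 10


@dataclass(frozen=True)
class SelectedInstance:
    interval: GenomicInterval
    te_type: str
    gene_id: str
    evidence: str
    source_id: str


@dataclass
class RIDLInstance:
    interval: GenomicInterval
    te_type: str
    gene_ids: frozenset[str]
    evidence: frozenset[str]
    source_instances: frozenset[str]

    @property
    def length(self) -> int:
        return self.interval.length


def _te_key(te: TEInstance) -> str:
    return f"{te.interval.chrom}:{te.interval.start}-{te.interval.end}:{te.te_type}"


def select_instances(
    candidates: Mapping[str, Iterable[str]],
    exonic_records: Sequence[ExonicTERecord],
    conserved_sets: Optional[Mapping[str, Sequence[tuple[GenomicInterval, str]]]] = None,
) -> list[SelectedInstance]:
    """Apply the per-evidence instance filters.

    ``candidates`` maps evidence name -> candidate TE types.  Evidence names
    ``enrichment`` and ``strand_bias`` have fixed semantics; any other name
    must key into ``conserved_sets`` and selects instances overlapping that
    set's elements.
    """
    conserved_sets = conserved_sets or {}
    cons_idx: dict[str, dict[str, iv.IntervalIndex]] = {}
    for name, elements in conserved_sets.items():
        by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for c, _n in elements:
            by_chrom.setdefault(c.chrom, ([], []))
            by_chrom[c.chrom][0].append(c.start)
            by_chrom[c.chrom][1].append(c.end)
        cons_idx[name] = {
            chrom: iv.IntervalIndex(ss, ee) for chrom, (ss, ee) in by_chrom.items()
        }

    # deduplicate records: one TE may overlap several merged-exon intervals of
    # the same gene; the instance filter operates on (TE, gene) pairs
    seen: set[tuple[str, str, str]] = set()
    out: list[SelectedInstance] = []
    for evidence, types in candidates.items():
        types = set(types)
        if not types:
            continue
        if evidence not in ("enrichment", "strand_bias") and evidence not in conserved_sets:
            raise KeyError(f"unknown evidence source {evidence!r}")
        for r in exonic_records:
            if r.te.te_type not in types:
                continue
            if evidence == "strand_bias" and r.relative_strand != "sense":
                continue
            if evidence not in ("enrichment", "strand_bias"):
                index = cons_idx[evidence].get(r.te.interval.chrom)
                if index is None or index.overlapping(
                    r.te.interval.start, r.te.interval.end
                ).size == 0:
                    continue
            key = (evidence, _te_key(r.te), r.gene_id)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                SelectedInstance(
                    interval=r.te.interval,
                    te_type=r.te.te_type,
                    gene_id=r.gene_id,
                    evidence=evidence,
                    source_id=_te_key(r.te),
                )
            )
    return out


def assemble_ridls(selected: Sequence[SelectedInstance]) -> list[RIDLInstance]:
    """Merge overlapping selected fragments genome-wide and drop merged
    records shorter than ``MIN_RIDL_LENGTH`` nt.

    Evidence sets, gene ids and source instances are unioned on merge; the
    merged record is labelled with the te_type contributing the most
    nucleotides (ties broken alphabetically).  Idempotent on its own output.
    """
    by_chrom: dict[str, list[SelectedInstance]] = {}
    for s in selected:
        by_chrom.setdefault(s.interval.chrom, []).append(s)
    out: list[RIDLInstance] = []
    for chrom in sorted(by_chrom):
        insts = sorted(by_chrom[chrom], key=lambda s: (s.interval.start, s.interval.end))
        # bedtools-merge default joins overlapping and book-ended records
        ms, me = iv.merge(
            [s.interval.start for s in insts],
            [s.interval.end for s in insts],
            bookended=True,
        )
        block_of = np.searchsorted(ms, [s.interval.start for s in insts], side="right") - 1
        for b in range(ms.size):
            members = [insts[i] for i in np.flatnonzero(block_of == b)]
            start, end = int(ms[b]), int(me[b])
            if end - start < MIN_RIDL_LENGTH:
                continue
            contrib: dict[str, int] = {}
            for m in members:
                contrib[m.te_type] = contrib.get(m.te_type, 0) + m.interval.length
            dominant = sorted(contrib.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
            strands = {m.interval.strand for m in members}
            strand = strands.pop() if len(strands) == 1 else "."
            out.append(
                RIDLInstance(
                    interval=GenomicInterval(chrom, start, end, strand),
                    te_type=dominant,
                    gene_ids=frozenset(m.gene_id for m in members),
                    evidence=frozenset(m.evidence for m in members),
                    source_instances=frozenset(m.source_id for m in members),
                )
            )
    return out


def ridls_to_bed_records(ridls: Sequence[RIDLInstance]):
    """(interval, name) pairs for BED6+ export; name packs type, evidence and
    host genes as ``type|ev1+ev2|gene1+gene2``."""
    recs = []
    for r in sorted(ridls, key=lambda x: (x.interval.chrom, x.interval.start, x.interval.end)):
        name = "|".join(
            [
                r.te_type,
                "+".join(sorted(r.evidence)),
                "+".join(sorted(r.gene_ids)),
            ]
        )
        recs.append((r.interval, name))
    return recs


@dataclass
class InsertionProfile:
    te_type: str
    frequencies: np.ndarray  # inclusion frequency per consensus position 1..L
    n_instances: int


@dataclass
class ProfileComparison:
    te_type: str
    cc: float
    n_ridl: int
    n_intronic: int
    flagged: bool
    degenerate: bool = False


def insertion_profile(
    instances: Sequence[TEInstance], consensus_length: int, te_type: str = ""
) -> InsertionProfile:
    """Per-consensus-position inclusion frequency over a set of instances.

    Consensus coordinates are 1-based closed; ``profile[pos-1]`` is the
    fraction of instances whose fragment covers ``pos``.
    """
    if not instances:
        raise ValueError("insertion profile undefined for zero instances")
    counts = np.zeros(consensus_length, dtype=float)
    for te in instances:
        if te.consensus_end > consensus_length:
            raise ValueError(
                f"instance consensus_end {te.consensus_end} exceeds consensus "
                f"length {consensus_length}"
            )
        counts[te.consensus_start - 1 : te.consensus_end] += 1
    return InsertionProfile(
        te_type=te_type or instances[0].te_type,
        frequencies=counts / len(instances),
        n_instances=len(instances),
    )


def compare_profiles(
    ridl_profile: InsertionProfile,
    intronic_profile: InsertionProfile,
    flag_below: float = 0.9,
) -> ProfileComparison:
    """Spearman rank correlation of the two insertion profiles; a CC below
    ``flag_below`` flags possible selection on the RIDL insertions."""
    a = ridl_profile.frequencies
    b = intronic_profile.frequencies
    if a.size != b.size:
        raise ValueError("profiles must cover the same consensus length")
    if np.all(a == a[0]) or np.all(b == b[0]):
        return ProfileComparison(
            te_type=ridl_profile.te_type,
            cc=float("nan"),
            n_ridl=ridl_profile.n_instances,
            n_intronic=intronic_profile.n_instances,
            flagged=True,
            degenerate=True,
        )
    cc = float(stats.spearmanr(a, b).statistic)
    return ProfileComparison(
        te_type=ridl_profile.te_type,
        cc=cc,
        n_ridl=ridl_profile.n_instances,
        n_intronic=intronic_profile.n_instances,
        flagged=cc < flag_below,
    )


def count_ridls_per_transcript(
    ridls: Sequence[RIDLInstance],
    transcripts: Mapping[str, Sequence[GenomicInterval]],
) -> dict[str, dict[str, int]]:
    """Per transcript, number of RIDLs of each type overlapping its exons.

    ``transcripts`` maps transcript_id -> exon intervals.  Returns
    {transcript_id: {te_type: count}} with zero-count entries omitted.
    """
    by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(ridls):
        by_chrom.setdefault(r.interval.chrom, []).append(i)
    idx = {
        chrom: (
            iv.IntervalIndex(
                [ridls[i].interval.start for i in ids],
                [ridls[i].interval.end for i in ids],
            ),
            ids,
        )
        for chrom, ids in by_chrom.items()
    }
    out: dict[str, dict[str, int]] = {}
    for tid, exons in transcripts.items():
        counts: dict[str, int] = {}
        seen: set[int] = set()
        for exon in exons:
            entry = idx.get(exon.chrom)
            if entry is None:
                continue
            index, ids = entry
            for j in index.overlapping(exon.start, exon.end):
                gi = ids[j]
                if gi in seen:
                    continue
                seen.add(gi)
                t = ridls[gi].te_type
                counts[t] = counts.get(t, 0) + 1
        out[tid] = counts
    return out
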