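"""End-to-end RIDL discovery: annotation -> screens -> instance filters ->
merged RIDL annotation, with deterministic seeded outputs."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotation import (
    ExonicTERecord,
    IntronSet,
    MergedExonSet,
    classify_exonic_tes,
    coverage_by_type,
    derive_introns,
    exonic_records_table,
    intersect_tes,
    merge_exons,
)
from .io_formats import GeneModel, GenomicInterval, TEInstance, write_bed
from .ridl import RIDLInstance, assemble_ridls, ridls_to_bed_records, select_instances
from .selection import conservation_screen, enrichment_screen, strand_bias_screen

__all__ = ["DiscoveryResult", "run_discovery", "write_discovery_outputs"]


@dataclass
class DiscoveryResult:
    merged: list[MergedExonSet]
    introns: list[IntronSet]
    exonic_records: list[ExonicTERecord]
    exon_coverage: pd.DataFrame
    intron_coverage: pd.DataFrame
    enrichment: pd.DataFrame
    strand_bias: pd.DataFrame
    conservation: dict[str, pd.DataFrame]
    candidates: dict[str, set[str]]
    ridls: list[RIDLInstance]
    n_sim: int = 0
    seed: int = 0


def run_discovery(
    genes: Sequence[GeneModel],
    tes: Sequence[TEInstance],
    conserved_sets: Mapping[str, Sequence[tuple[GenomicInterval, str]]],
    chrom_sizes: dict[str, int],
    n_sim: int = 1000,
    seed: int = 0,
    fold_cutoff: float = 2.0,
) -> DiscoveryResult:
    """Run the three selection screens and assemble the RIDL annotation."""
    merged = [merge_exons(g) for g in genes]
    introns = derive_introns(genes, merged)
    records = classify_exonic_tes(merged, tes)

    exon_cov = coverage_by_type(merged, tes)
    intron_cov = coverage_by_type(introns, tes)
    enr = enrichment_screen(exon_cov, intron_cov, fold_cutoff=fold_cutoff)
    strand = strand_bias_screen(
        records, genes, tes, chrom_sizes, n_sim=n_sim, seed=seed
    )
    exonic_frags = intersect_tes(merged, tes)
    intronic_frags = intersect_tes(introns, tes)
    cons: dict[str, pd.DataFrame] = {}
    for i, name in enumerate(sorted(conserved_sets)):
        cons[name] = conservation_screen(
            exonic_frags,
            intronic_frags,
            conserved_sets[name],
            chrom_sizes,
            n_sim=n_sim,
            seed=seed + 1 + i,
        )

    candidates: dict[str, set[str]] = {
        "enrichment": set(enr.index[enr["candidate"]]),
        "strand_bias": set(strand.index[strand["candidate"]]),
    }
    for name, df in cons.items():
        candidates[name] = set(df.index[df["candidate"].fillna(False)])

    selected = select_instances(candidates, records, conserved_sets)
    ridls = assemble_ridls(selected)
    return DiscoveryResult(
        merged=merged,
        introns=introns,
        exonic_records=records,
        exon_coverage=exon_cov,
        intron_coverage=intron_cov,
        enrichment=enr,
        strand_bias=strand,
        conservation=cons,
        candidates=candidates,
        ridls=ridls,
        n_sim=n_sim,
        seed=seed,
    )


def write_discovery_outputs(result: DiscoveryResult, out_dir) -> dict[str, Path]:
    """TSV/BED exports with deterministic ordering (keyed by seed metadata)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["exonic_tes"] = out / "exonic_tes.tsv"
    exonic_records_table(result.exonic_records).sort_values(
        ["chrom", "te_start", "te_end", "gene_id", "exon_start"], kind="stable"
    ).to_csv(paths["exonic_tes"], sep="\t", index=False)

    paths["enrichment"] = out / "screen_enrichment.tsv"
    result.enrichment.sort_index().to_csv(paths["enrichment"], sep="\t")
    paths["strand_bias"] = out / "screen_strand_bias.tsv"
    result.strand_bias.sort_index().to_csv(paths["strand_bias"], sep="\t")
    for name, df in sorted(result.conservation.items()):
        p = out / f"screen_conservation_{name}.tsv"
        df.sort_index().to_csv(p, sep="\t")
        paths[f"conservation_{name}"] = p

    paths["ridls"] = out / "ridls.bed"
    write_bed(ridls_to_bed_records(result.ridls), paths["ridls"])

    meta = out / "run_metadata.tsv"
    meta.write_text(
        "n_sim\tseed\tn_ridls\tn_candidate_types\n"
        f"{result.n_sim}\t{result.seed}\t{len(result.ridls)}\t"
        f"{len(set().union(*result.candidates.values()) if result.candidates else set())}\n"
    )
    paths["metadata"] = meta
    return paths
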