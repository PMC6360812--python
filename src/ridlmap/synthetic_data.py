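"""Synthetic genome-annotation bundles with planted selection effects.

The generator emits every file shape the pipeline consumes — chromosome
sizes, a multi-transcript gene GTF, a RepeatMasker-style TE table, two
conserved-element BED sets, per-cell-line fractionation expression tables, a
SNP table with derived allele frequencies, and functional-gene lists — plus
truth tables of the planted effects, so each downstream screen can be tested
for calibration (no planted effect) and power (planted effect recovered).

Planted effects and their defaults:

* exonic enrichment      — listed types get ``enrichment_fold`` x the base
  per-type coverage inside exons (default fold 4)
* strand bias            — exonic instances of listed types lie in sense
  orientation to the host gene with ``sense_fraction`` (default 0.9)
* exonic conservation    — exonic fragments of listed types are covered by a
  conserved element with probability 0.5 versus 0.25 for intronic fragments
  (REIC ~ 2), on top of a uniform background element set
* localization           — each exonic copy of a listed type shifts its host
  transcript's true RCI by ``delta`` log2 units (default +0.5)
* DAF                    — SNPs in RIDL regions have an elevated rare-allele
  (DAF < 0.1) fraction

All randomness derives from ``SimulationConfig.seed``; identical configs
produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import intervals as iv
from .io_formats import (
    GeneModel,
    GenomicInterval,
    TEInstance,
    Transcript,
    write_bed,
    write_chrom_sizes,
    write_gtf,
    write_te_bed,
)

__all__ = [
    "TETypeSpec",
    "SimulationConfig",
    "SyntheticBundle",
    "default_catalog",
    "generate_annotation_bundle",
    "generate_localization_data",
    "generate_snp_table",
    "generate_functional_flags",
]


@dataclass(frozen=True)
class TETypeSpec:
    name: str
    family: str
    te_class: str
    consensus_length: int
    coverage: float  # target per-nt coverage fraction per compartment


_FAMILIES = [("MIR", "SINE"), ("L2", "LINE"), ("AluY", "SINE"), ("MLT1", "LTR"), ("L1M", "LINE")]


def default_catalog(
    n_types: int = 20,
    coverage: float = 0.03,
    planted_names: Sequence[str] = ("ENR1", "ENR2", "STR1", "STR2", "CON1", "CON2"),
    consensus_range: tuple[int, int] = (300, 1500),
    seed: int = 7,
) -> list[TETypeSpec]:
    """A TE-type catalog with the planted types first, then filler types."""
    rng = np.random.default_rng(seed)
    names = list(planted_names) + [
        f"TE{i:03d}" for i in range(n_types - len(planted_names))
    ]
    out = []
    for i, name in enumerate(names[:n_types]):
        fam, cls = _FAMILIES[i % len(_FAMILIES)]
        clen = int(rng.integers(consensus_range[0], consensus_range[1] + 1))
        out.append(TETypeSpec(name, fam, cls, clen, coverage))
    return out


@dataclass
class SimulationConfig:
    seed: int = 0
    # genome & gene geometry
    n_chroms: int = 2
    chrom_length: int = 4_000_000
    n_genes: int = 300
    transcripts_per_gene: tuple[int, int] = (1, 3)
    exons_per_transcript: tuple[int, int] = (3, 8)
    exon_length: tuple[int, int] = (150, 400)
    intron_length: tuple[int, int] = (800, 3000)
    # TE placement
    te_type_catalog: list[TETypeSpec] = field(default_factory=default_catalog)
    fragment_length: tuple[int, int] = (40, 120)
    boundary_fraction: float = 0.05  # exonic instances deliberately crossing a boundary
    # planted effects
    planted_enriched_types: tuple[str, ...] = ("ENR1", "ENR2")
    enrichment_fold: float = 4.0
    planted_strand_biased_types: tuple[str, ...] = ("STR1", "STR2")
    sense_fraction: float = 0.9
    planted_conserved: dict = field(
        default_factory=lambda: {"phastcons": ["CON1"], "ecs": ["CON2"]}
    )
    exonic_conserved_fraction: float = 0.5
    intronic_conserved_fraction: float = 0.25
    background_conservation_coverage: float = 0.06
    conserved_element_length: tuple[int, int] = (10, 20)
    # consensus-profile bias: te_type -> {"exonic": "3prime"/"5prime"/None, ...}
    profile_bias: dict = field(
        default_factory=lambda: {"CON1": {"exonic": "3prime", "intronic": "5prime"}}
    )
    # localization
    cell_lines: tuple[str, ...] = ("cellA", "cellB", "cellC", "cellD")
    localization_effects: dict = field(
        default_factory=lambda: {"CON1": 0.5, "CON2": 0.5}
    )
    rci_baseline_sd: float = 1.0
    rpkm_noise_sigma: float = 0.1
    whole_cell_meanlog: float = 2.3
    whole_cell_sdlog: float = 1.0
    dropout_rate: float = 0.0
    # SNP / DAF
    snps_per_class: int = 2000
    rare_fraction_ridl: float = 0.6
    rare_fraction_background: float = 0.4
    # functional-gene flags
    functional_base_rate: float = 0.15
    functional_log_odds_per_ridl: float = 0.8

    def __post_init__(self):
        names = {t.name for t in self.te_type_catalog}
        planted = (
            set(self.planted_enriched_types)
            | set(self.planted_strand_biased_types)
            | {t for ts in self.planted_conserved.values() for t in ts}
            | set(self.localization_effects)
        )
        unknown = planted - names
        if unknown:
            raise ValueError(f"planted types not in catalog: {sorted(unknown)}")
        for t in self.te_type_catalog:
            if not 0 <= t.coverage <= 1:
                raise ValueError(f"coverage outside [0,1] for {t.name}")
        if self.enrichment_fold <= 0:
            raise ValueError("enrichment_fold must be > 0")
        for frac in (
            self.sense_fraction,
            self.exonic_conserved_fraction,
            self.intronic_conserved_fraction,
            self.background_conservation_coverage,
            self.dropout_rate,
            self.rare_fraction_ridl,
            self.rare_fraction_background,
        ):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0,1]")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "te_type_catalog" in raw:
            raw["te_type_catalog"] = [TETypeSpec(**d) for d in raw["te_type_catalog"]]
        for key in (
            "transcripts_per_gene", "exons_per_transcript", "exon_length",
            "intron_length", "fragment_length", "conserved_element_length",
            "planted_enriched_types", "planted_strand_biased_types", "cell_lines",
        ):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_jsonable(asdict(self)), fh, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class SyntheticBundle:
    config: SimulationConfig
    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    tes: list[TEInstance]
    conserved: dict[str, list[tuple[GenomicInterval, str]]]
    truth: dict
    expression: Optional[pd.DataFrame] = None
    snps: Optional[pd.DataFrame] = None
    functional_flags: Optional[pd.DataFrame] = None

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["chrom_sizes"] = out / "genome.chrom.sizes"
        write_chrom_sizes(self.chrom_sizes, paths["chrom_sizes"])
        paths["gtf"] = out / "genes.gtf"
        write_gtf(self.genes, paths["gtf"])
        paths["te_bed"] = out / "repeats.tsv"
        write_te_bed(self.tes, paths["te_bed"])
        for name, elements in sorted(self.conserved.items()):
            p = out / f"conserved_{name}.bed"
            write_bed(elements, p)
            paths[f"conserved_{name}"] = p
        if self.expression is not None:
            paths["expression"] = out / "expression.tsv"
            self.expression.to_csv(paths["expression"], sep="\t", index=False)
        if self.snps is not None:
            paths["snps"] = out / "snps.tsv"
            self.snps.to_csv(paths["snps"], sep="\t", index=False)
        if self.functional_flags is not None:
            for flag in ("in_functional_db", "disease_associated", "has_exonic_trait_snp"):
                p = out / f"genes_{flag}.txt"
                ids = self.functional_flags.loc[
                    self.functional_flags[flag], "gene_id"
                ].sort_values()
                p.write_text("".join(f"{g}\n" for g in ids))
                paths[flag] = p
        paths["truth"] = out / "truth.json"
        paths["truth"].write_text(json.dumps(_jsonable(self.truth), indent=1, sort_keys=True))
        return paths


# ---------------------------------------------------------------------------
# gene and TE placement
# ---------------------------------------------------------------------------


def _build_gene_structures(cfg: SimulationConfig, rng: np.random.Generator):
    """Exon-chain templates: per gene a list of exon lengths and intron
    lengths; transcripts are contiguous exon subsets of the chain."""
    genes = []
    for i in range(cfg.n_genes):
        n_ex = int(rng.integers(cfg.exons_per_transcript[0], cfg.exons_per_transcript[1] + 1))
        ex_lens = rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1, size=n_ex)
        in_lens = rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1, size=max(n_ex - 1, 0))
        n_tx = int(rng.integers(cfg.transcripts_per_gene[0], cfg.transcripts_per_gene[1] + 1))
        genes.append((f"G{i:04d}", ex_lens, in_lens, n_tx))
    return genes


def _place_genes(cfg: SimulationConfig, rng: np.random.Generator, structures):
    """Non-overlapping placement: genes are dealt to chromosomes, then laid
    out left-to-right with random gaps from the free space."""
    chroms = [f"chrS{i + 1}" for i in range(cfg.n_chroms)]
    sizes = {c: cfg.chrom_length for c in chroms}
    assignment: dict[str, list] = {c: [] for c in chroms}
    order = rng.permutation(len(structures))
    for k, gi in enumerate(order):
        assignment[chroms[k % len(chroms)]].append(structures[gi])

    genes: list[GeneModel] = []
    for chrom in chroms:
        structs = assignment[chrom]
        spans = [int(ex.sum() + inl.sum()) for (_g, ex, inl, _t) in structs]
        free = sizes[chrom] - sum(spans)
        if free < 0:
            raise ValueError(
                f"chromosome {chrom} too short for {len(structs)} genes "
                f"({sum(spans)} nt of gene span)"
            )
        cuts = np.sort(rng.integers(0, free + 1, size=len(structs)))
        pos = 0
        prev_cut = 0
        for (gid, ex_lens, in_lens, n_tx), span, cut in zip(structs, spans, cuts):
            pos += int(cut - prev_cut)
            prev_cut = cut
            strand = "+" if rng.random() < 0.5 else "-"
            # exon chain coordinates
            starts, ends = [], []
            p = pos
            for j, el in enumerate(ex_lens):
                starts.append(p)
                ends.append(p + int(el))
                p = ends[-1] + (int(in_lens[j]) if j < len(in_lens) else 0)
            pos += span
            n_ex = len(ex_lens)
            tx = []
            for t in range(n_tx):
                if t == 0:
                    lo_e, hi_e = 0, n_ex  # one transcript always spans the chain
                else:
                    lo_e = int(rng.integers(0, n_ex))
                    hi_e = int(rng.integers(lo_e + 1, n_ex + 1))
                exons = [
                    GenomicInterval(chrom, starts[j], ends[j], strand)
                    for j in range(lo_e, hi_e)
                ]
                tx.append(Transcript(transcript_id=f"{gid}.t{t + 1}", exons=exons))
            genes.append(GeneModel(gene_id=gid, biotype="lncRNA", transcripts=tx))
    genes.sort(key=lambda g: g.gene_id)
    return sizes, genes


def _compartments(genes: Sequence[GeneModel], sizes: dict[str, int]):
    """(exon, intron, intergenic) interval lists per chromosome plus the gene
    owning each exon/intron interval."""
    exons: list[tuple[str, int, int, GeneModel]] = []
    introns: list[tuple[str, int, int, GeneModel]] = []
    span_by_chrom: dict[str, tuple[list[int], list[int]]] = {c: ([], []) for c in sizes}
    for g in genes:
        chain_s = []
        chain_e = []
        for t in g.transcripts:
            for e in t.exons:
                chain_s.append(e.start)
                chain_e.append(e.end)
        ms, me = iv.merge(chain_s, chain_e)
        for s, e in zip(ms, me):
            exons.append((g.chrom, int(s), int(e), g))
        span = g.span
        span_by_chrom[g.chrom][0].append(span.start)
        span_by_chrom[g.chrom][1].append(span.end)
        gs, ge = iv.subtract((span.start, span.end), ms, me)
        for s, e in zip(gs, ge):
            introns.append((g.chrom, int(s), int(e), g))
    intergenic: list[tuple[str, int, int, None]] = []
    for chrom, (ss, ee) in span_by_chrom.items():
        gs, ge = iv.subtract((0, sizes[chrom]), ss, ee)
        for s, e in zip(gs, ge):
            intergenic.append((chrom, int(s), int(e), None))
    return exons, introns, intergenic


def _sample_consensus(rng, clen: int, frag_len: int, bias: Optional[str]):
    frag_len = min(frag_len, clen)
    if bias == "3prime":
        start = clen - frag_len + 1
    elif bias == "5prime":
        start = 1
    else:
        start = int(rng.integers(1, clen - frag_len + 2))
    return start, start + frag_len - 1


def _place_type_in_compartment(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    spec: TETypeSpec,
    compartment: list,
    compartment_name: str,
    coverage: float,
    tes: list[TEInstance],
    truth_rows: list,
):
    lengths = np.array([e - s for (_c, s, e, _g) in compartment], dtype=float)
    total = lengths.sum()
    if total <= 0 or coverage <= 0:
        return
    frag_lo = min(cfg.fragment_length[0], spec.consensus_length)
    frag_hi = min(cfg.fragment_length[1], spec.consensus_length)
    mean_frag = (frag_lo + frag_hi) / 2
    n = int(round(coverage * total / mean_frag))
    if n == 0:
        return
    bias_cfg = cfg.profile_bias.get(spec.name, {})
    bias = bias_cfg.get("exonic" if compartment_name == "exon" else "intronic")
    sense_biased = (
        compartment_name == "exon" and spec.name in cfg.planted_strand_biased_types
    )
    frags = rng.integers(frag_lo, frag_hi + 1, size=n)
    for k in range(n):
        frag = int(frags[k])
        # interval chosen proportional to its number of valid start positions
        # so per-nucleotide placement density stays near-uniform across the
        # compartment (avoids center-clustering in short intervals)
        weights = np.maximum(lengths - frag + 1, 0.0)
        if weights.sum() == 0:
            weights = lengths
        pick = rng.choice(len(compartment), p=weights / weights.sum())
        chrom, lo, hi, gene = compartment[pick]
        frag = min(frag, hi - lo)
        if frag < 1:
            continue
        cross = (
            compartment_name == "exon"
            and gene is not None
            and rng.random() < cfg.boundary_fraction
        )
        if cross and hi + frag // 2 <= cfg.chrom_length:
            start = hi - max(frag // 2, 1)
        else:
            start = int(rng.integers(lo, hi - frag + 1))
        end = start + frag
        if sense_biased and gene is not None:
            strand = (
                gene.strand
                if rng.random() < cfg.sense_fraction
                else ("-" if gene.strand == "+" else "+")
            )
        else:
            strand = "+" if rng.random() < 0.5 else "-"
        cs, ce = _sample_consensus(rng, spec.consensus_length, frag, bias)
        tes.append(
            TEInstance(
                interval=GenomicInterval(chrom, start, end, strand),
                te_type=spec.name,
                te_family=spec.family,
                te_class=spec.te_class,
                consensus_start=cs,
                consensus_end=ce,
                consensus_length=spec.consensus_length,
            )
        )
        truth_rows.append(
            {
                "te_index": len(tes) - 1,
                "te_type": spec.name,
                "compartment": compartment_name,
                "gene_id": gene.gene_id if gene is not None else "",
                "crosses_boundary": bool(cross),
            }
        )


def generate_annotation_bundle(config: SimulationConfig) -> SyntheticBundle:
    """Genome sizes, gene models, TE instances, conserved-element sets and
    truth tables, all deterministic in ``config.seed``."""
    rng = np.random.default_rng([config.seed, 0])
    structures = _build_gene_structures(config, rng)
    sizes, genes = _place_genes(config, rng, structures)
    exons, introns, intergenic = _compartments(genes, sizes)

    tes: list[TEInstance] = []
    placement: list[dict] = []
    for spec in config.te_type_catalog:
        exon_cov = spec.coverage * (
            config.enrichment_fold if spec.name in config.planted_enriched_types else 1.0
        )
        _place_type_in_compartment(
            config, rng, spec, exons, "exon", exon_cov, tes, placement
        )
        _place_type_in_compartment(
            config, rng, spec, introns, "intron", spec.coverage, tes, placement
        )
        _place_type_in_compartment(
            config, rng, spec, intergenic, "intergenic", spec.coverage, tes, placement
        )

    # conserved-element sets: planted per-fragment elements + uniform background
    conserved: dict[str, list[tuple[GenomicInterval, str]]] = {}
    planted_conserved_idx: dict[str, list[int]] = {}
    lo_c, hi_c = config.conserved_element_length
    mean_c = (lo_c + hi_c) / 2
    genome = sum(sizes.values())
    chroms_sorted = sorted(sizes)
    exon_total = float(sum(e - s for (_c, s, e, _g) in exons))
    intron_total = float(sum(e - s for (_c, s, e, _g) in introns))
    for set_name in sorted(config.planted_conserved):
        planted_types = set(config.planted_conserved[set_name])
        elements: list[tuple[GenomicInterval, str]] = []
        hit_idx: list[int] = []
        planted_exon_nt = 0
        planted_intron_nt = 0
        for row in placement:
            if row["te_type"] not in planted_types:
                continue
            if row["compartment"] == "exon":
                frac = config.exonic_conserved_fraction
            elif row["compartment"] == "intron":
                frac = config.intronic_conserved_fraction
            else:
                continue
            if frac <= 0:
                continue
            # cover exactly `frac` of the fragment (random sub-segment), so
            # the per-nucleotide conserved fraction is planted without
            # per-instance Bernoulli noise
            te = tes[row["te_index"]]
            ln = max(1, int(round(frac * te.interval.length)))
            off = int(rng.integers(0, te.interval.length - ln + 1))
            el = GenomicInterval(
                te.interval.chrom,
                te.interval.start + off,
                te.interval.start + off + ln,
                ".",
            )
            elements.append((el, f"{set_name}_planted"))
            hit_idx.append(row["te_index"])
            if row["compartment"] == "exon":
                planted_exon_nt += ln
            else:
                planted_intron_nt += ln
        # balance the compartments: planted elements concentrate conserved
        # density in exon space; add plain intronic elements until the extra
        # per-nt density matches, so non-planted types stay REIC-neutral
        if exon_total > 0 and intron_total > 0:
            deficit = intron_total * planted_exon_nt / exon_total - planted_intron_nt
            mean_frag = (cfg_frag := config.fragment_length)[0] / 2 + cfg_frag[1] / 2
            n_bal = max(int(round(deficit / mean_frag)), 0)
            if n_bal:
                intron_lens = np.array([e - s for (_c, s, e, _g) in introns], dtype=float)
                bal_lens = rng.integers(
                    config.fragment_length[0], config.fragment_length[1] + 1, size=n_bal
                )
                for bl in bal_lens:
                    w = np.maximum(intron_lens - int(bl) + 1, 0.0)
                    if w.sum() == 0:
                        w = intron_lens
                    pick = rng.choice(len(introns), p=w / w.sum())
                    chrom, lo, hi, _g = introns[pick]
                    ln = min(int(bl), hi - lo)
                    s = int(rng.integers(lo, hi - ln + 1))
                    elements.append(
                        (GenomicInterval(chrom, s, s + ln, "."), f"{set_name}_balance")
                    )
        n_bg = int(round(config.background_conservation_coverage * genome / mean_c))
        bg_lens = rng.integers(lo_c, hi_c + 1, size=n_bg)
        from .selection import shuffle_intervals

        ci, starts = shuffle_intervals(bg_lens, sizes, rng)
        for k in range(n_bg):
            chrom = chroms_sorted[ci[k]]
            s = int(starts[k])
            e = min(s + int(bg_lens[k]), sizes[chrom])
            elements.append((GenomicInterval(chrom, s, e, "."), f"{set_name}_bg"))
        conserved[set_name] = elements
        planted_conserved_idx[set_name] = hit_idx

    truth = {
        "planted_enriched_types": list(config.planted_enriched_types),
        "enrichment_fold": config.enrichment_fold,
        "planted_strand_biased_types": list(config.planted_strand_biased_types),
        "sense_fraction": config.sense_fraction,
        "planted_conserved": {k: list(v) for k, v in config.planted_conserved.items()},
        "localization_effects": dict(config.localization_effects),
        "placement": placement,
        "conserved_hits": planted_conserved_idx,
    }
    return SyntheticBundle(
        config=config,
        chrom_sizes=sizes,
        genes=genes,
        tes=tes,
        conserved=conserved,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# expression / localization
# ---------------------------------------------------------------------------


def count_type_copies_per_transcript(
    bundle: SyntheticBundle, te_types: Sequence[str]
) -> pd.DataFrame:
    """Exonic TE copies per transcript for the given types (an instance
    counts once per transcript whose exons it overlaps)."""
    te_types = list(te_types)
    type_set = set(te_types)
    by_chrom: dict[str, list[int]] = {}
    for i, te in enumerate(bundle.tes):
        if te.te_type in type_set:
            by_chrom.setdefault(te.interval.chrom, []).append(i)
    idx = {
        chrom: (
            iv.IntervalIndex(
                [bundle.tes[i].interval.start for i in ids],
                [bundle.tes[i].interval.end for i in ids],
            ),
            ids,
        )
        for chrom, ids in by_chrom.items()
    }
    rows = []
    for g in bundle.genes:
        for t in g.transcripts:
            counts = {tt: 0 for tt in te_types}
            seen: set[int] = set()
            for e in t.exons:
                entry = idx.get(e.chrom)
                if entry is None:
                    continue
                index, ids = entry
                for j in index.overlapping(e.start, e.end):
                    gi = ids[j]
                    if gi in seen:
                        continue
                    seen.add(gi)
                    counts[bundle.tes[gi].te_type] += 1
            rows.append({"transcript_id": t.transcript_id, "gene_id": g.gene_id, **counts})
    return pd.DataFrame(rows)


def generate_localization_data(
    bundle: SyntheticBundle, config: Optional[SimulationConfig] = None
) -> pd.DataFrame:
    """Long expression table (transcript_id, gene_id, cell_line, fraction,
    rpkm) whose nuclear/cytoplasmic split realizes RCI = baseline + sum of
    per-copy shifts for the planted localization types, before measurement
    noise.  Also stores the per-transcript truth in ``bundle.truth``."""
    cfg = config or bundle.config
    unknown = set(cfg.localization_effects) - {t.name for t in cfg.te_type_catalog}
    if unknown:
        raise ValueError(f"localization_effects for unknown types: {sorted(unknown)}")
    rng = np.random.default_rng([cfg.seed, 1])
    loc_types = sorted(cfg.localization_effects)
    copies = count_type_copies_per_transcript(bundle, loc_types)
    rows = []
    truth_rows = []
    for _, tr in copies.iterrows():
        shift = sum(cfg.localization_effects[t] * tr[t] for t in loc_types)
        for cell in cfg.cell_lines:
            base = rng.normal(0.0, cfg.rci_baseline_sd)
            rci_true = base + shift
            w = float(np.exp(rng.normal(cfg.whole_cell_meanlog, cfg.whole_cell_sdlog)))
            ratio = 2.0**rci_true
            nuc = 2 * w * ratio / (1 + ratio)
            cyt = 2 * w / (1 + ratio)
            nuc *= float(np.exp(rng.normal(0, cfg.rpkm_noise_sigma)))
            cyt *= float(np.exp(rng.normal(0, cfg.rpkm_noise_sigma)))
            vals = {"nuclear": nuc, "cytoplasmic": cyt, "whole_cell": w}
            for fraction, rpkm in vals.items():
                if cfg.dropout_rate > 0 and rng.random() < cfg.dropout_rate:
                    rpkm = 0.0
                rows.append(
                    {
                        "transcript_id": tr["transcript_id"],
                        "gene_id": tr["gene_id"],
                        "cell_line": cell,
                        "fraction": fraction,
                        "rpkm": round(float(rpkm), 6),
                    }
                )
            truth_rows.append(
                {
                    "transcript_id": tr["transcript_id"],
                    "cell_line": cell,
                    "rci_true": rci_true,
                    "shift": shift,
                    **{f"copies_{t}": int(tr[t]) for t in loc_types},
                }
            )
    expr = pd.DataFrame(rows)
    bundle.expression = expr
    bundle.truth["localization_truth"] = truth_rows
    return expr


# ---------------------------------------------------------------------------
# SNPs and functional flags
# ---------------------------------------------------------------------------


def generate_snp_table(
    bundle: SyntheticBundle,
    ridl_intervals: Optional[Sequence[GenomicInterval]] = None,
    config: Optional[SimulationConfig] = None,
) -> pd.DataFrame:
    """SNP positions with derived allele frequencies per region class.

    When ``ridl_intervals`` is omitted, the truth table's conservation-hit
    instances stand in for the RIDL class.  The RIDL class receives the
    elevated rare-allele fraction; all other classes the background one.
    """
    cfg = config or bundle.config
    rng = np.random.default_rng([cfg.seed, 2])
    exons, introns, intergenic = _compartments(bundle.genes, bundle.chrom_sizes)

    if ridl_intervals is None:
        hit = sorted({i for ids in bundle.truth.get("conserved_hits", {}).values() for i in ids})
        # RIDLs are exonic by definition; intronic planted fragments are not RIDLs
        hit = [i for i in hit if bundle.truth["placement"][i]["compartment"] == "exon"]
        ridl_intervals = [bundle.tes[i].interval for i in hit]
    ridl_set = [(c.chrom, c.start, c.end) for c in ridl_intervals]

    exonic_te = []
    intronic_te = []
    for row in bundle.truth["placement"]:
        te = bundle.tes[row["te_index"]]
        key = (te.interval.chrom, te.interval.start, te.interval.end)
        if row["compartment"] == "exon" and key not in set(ridl_set):
            exonic_te.append(key)
        elif row["compartment"] == "intron":
            intronic_te.append(key)

    exonic_plain = [(c, s, e) for (c, s, e, _g) in exons]
    flanks = []
    for g in bundle.genes:
        span = g.span
        lo = max(0, span.start - 5000)
        if span.start - lo >= 50:
            flanks.append((g.chrom, lo, span.start))
    regions = {
        "RIDL": ridl_set,
        "exonic_TE_nonRIDL": exonic_te,
        "intronic_TE": intronic_te,
        "exonic_nonRIDL": exonic_plain,
        "ancestral_repeat_flank": flanks,
    }
    rows = []
    for cls in sorted(regions):
        ivs = regions[cls]
        if not ivs:
            continue
        lengths = np.array([e - s for (_c, s, e) in ivs], dtype=float)
        probs = lengths / lengths.sum()
        rare = (
            cfg.rare_fraction_ridl if cls == "RIDL" else cfg.rare_fraction_background
        )
        for _ in range(cfg.snps_per_class):
            k = rng.choice(len(ivs), p=probs)
            c, s, e = ivs[k]
            pos = int(rng.integers(s, e))
            if rng.random() < rare:
                daf = float(rng.uniform(0, 0.1))
            else:
                daf = float(rng.uniform(0.1, 1.0))
            rows.append(
                {"chrom": c, "pos": pos, "daf": round(daf, 6), "region_class": cls}
            )
    snps = pd.DataFrame(rows)
    bundle.snps = snps
    return snps


def generate_functional_flags(
    bundle: SyntheticBundle,
    ridl_counts: Optional[dict[str, int]] = None,
    config: Optional[SimulationConfig] = None,
) -> pd.DataFrame:
    """Per-gene boolean functional flags drawn from a logistic model in the
    gene's planted RIDL count (log-odds slope ``functional_log_odds_per_ridl``)."""
    cfg = config or bundle.config
    rng = np.random.default_rng([cfg.seed, 3])
    if ridl_counts is None:
        ridl_counts = {}
        # placement rows are appended in TE order, so row i describes TE i;
        # only exonic hits are RIDLs
        for set_name, ids in bundle.truth.get("conserved_hits", {}).items():
            for i in ids:
                row = bundle.truth["placement"][i]
                if row["compartment"] == "exon" and row["gene_id"]:
                    g = row["gene_id"]
                    ridl_counts[g] = ridl_counts.get(g, 0) + 1
    base_logit = float(np.log(cfg.functional_base_rate / (1 - cfg.functional_base_rate)))
    rows = []
    for g in bundle.genes:
        count = ridl_counts.get(g.gene_id, 0)
        p = 1.0 / (1.0 + np.exp(-(base_logit + cfg.functional_log_odds_per_ridl * count)))
        rows.append(
            {
                "gene_id": g.gene_id,
                "ridl_count_truth": count,
                "in_functional_db": bool(rng.random() < p),
                "disease_associated": bool(rng.random() < p),
                "has_exonic_trait_snp": bool(rng.random() < p),
            }
        )
    flags = pd.DataFrame(rows)
    bundle.functional_flags = flags
    return flags


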