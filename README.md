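# ridlmap

Discovery of **repeat insertion domains of lncRNAs (RIDLs)** — exonic
transposable-element (TE) fragments showing evidence of selection in the
mature transcript — together with the downstream host-gene and
nuclear/cytoplasmic localization statistics.

Most TEs inside lncRNA exons are neutral passengers.  `ridlmap` screens every
TE *type* (RepeatMasker repeat name) for three signatures of RNA-level
selection, using intronic TEs of the same lncRNAs as the neutral background:

1. **Exonic enrichment** — the ratio of exonic to intronic per-nucleotide
   coverage fractions; a type is a candidate when the ratio exceeds 2 (strict).
2. **Strand bias** — the sense/antisense nucleotide-coverage ratio of
   non-splice-junction-crossing exonic TEs, tested against an empirical null
   built by rigidly repositioning entire gene structures in the genome and
   re-intersecting with the full TE annotation.
3. **Exonic conservation** — the relative exonic–intronic conservation

   `REIC = (Ce/(Ce+Ne)) / (Ci/(Ci+Ni))`

   where `C`/`N` are conserved / non-conserved TE nucleotides and `e`/`i`
   denote exons/introns, tested against a null that positionally randomizes
   the conserved-element set (run separately per conserved-element annotation,
   e.g. phastCons-style and RNA-structure/ECS-style sets).

Empirical p-values follow `p = rank/(1 + n_sim)`; a statistic more extreme
than all shuffle replicates takes the conservative floor (`p = 0.001` at 1000
shuffles).  Per-screen Benjamini–Hochberg q-values are reported.  Candidate
types are converted to a RIDL annotation by per-evidence instance filters
(all exonic instances for enrichment; sense-orientation instances for strand
bias; instances intersecting the flagging conserved set for conservation),
merged genome-wide with bedtools-merge semantics, and filtered to ≥ 10 nt.

Downstream modules quantify what RIDLs do to their hosts:

* **localization** — per-transcript relative concentration index
  `RCI = log2(nuclear RPKM / cytoplasmic RPKM)` per cell line; a Wilcoxon
  rank-sum screen of RIDL-carrying vs other transcripts (BH-corrected
  globally, q < 0.01), Spearman dose–response in RIDL copy number, the linear
  model `RCI ~ ridl_count + transcript_length + expression` with VIF
  diagnostics, rank-based partial correlation, and a within-gene isoform
  contrast (one-sided t-test of Δ = mean RCI(RIDL isoforms) − mean RCI(other
  isoforms)).
* **genestats** — RIDL-per-gene clustering versus a length-weighted
  randomization, exonic-length-matched control sampling, Fisher exact tests
  for functional/disease annotation enrichment, multiple logistic regression
  `functional ~ ridl_count + length + conservation`, and derived-allele-
  frequency (DAF) spectra with the rare-allele (DAF < 0.1) fraction per
  region class.

The package runs on real inputs (GENCODE-dialect GTF, UCSC RepeatMasker
export, conserved-element BEDs, chrom.sizes, fractionation RPKM tables) or on
the bundled **synthetic-genome generator**, which emits all of these file
shapes with planted effects (enriched, strand-biased, exonically conserved
and localization-shifting TE types) plus truth tables, so every stage is
testable without downloads.

## Worked example

```python
from ridlmap import SimulationConfig, generate_annotation_bundle, run_discovery
from ridlmap.selection import compute_reic, ConservationCounts

cfg = SimulationConfig(seed=7)                      # planted study conditions
bundle = generate_annotation_bundle(cfg)
result = run_discovery(bundle.genes, bundle.tes, bundle.conserved,
                       bundle.chrom_sizes, n_sim=200, seed=8)

for evidence, types in sorted(result.candidates.items()):
    print(f"  {evidence}: {sorted(types)}")
print(f"exon/intron coverage ratio of ENR1: "
      f"{result.enrichment.loc['ENR1', 'ratio']:.2f}")
print(f"REIC of CON1 (phastcons screen):   "
      f"{result.conservation['phastcons'].loc['CON1', 'observed']:.2f} "
      f"(p = {result.conservation['phastcons'].loc['CON1', 'p_greater']:.3f})")
print(f"RIDL annotation: {len(result.ridls)} merged instances")
print("REIC closed form:", compute_reic(ConservationCounts(50, 50, 25, 75)))
```

prints

```
  ecs: ['CON2']
  enrichment: ['ENR1', 'ENR2']
  phastcons: ['CON1']
  strand_bias: ['STR1', 'STR2']
exon/intron coverage ratio of ENR1: 3.63
REIC of CON1 (phastcons screen):   1.74 (p = 0.005)
RIDL annotation: 1392 merged instances
REIC closed form: 2.0
```

The generator plants two fourfold exon-enriched types (`ENR1`, `ENR2`), two
90 %-sense types (`STR1`, `STR2`) and one exonically conserved type per
conserved set (`CON1`, `CON2`; exonic conserved fraction 0.5 vs intronic
0.25, so REIC ≈ 2 before background dilution).  All six are recovered by the
matching screens; the realized enrichment ratio sits slightly below the
planted fold because same-type fragment overlaps are counted once in the
coverage union.  `p = 0.005` is the empirical floor at `n_sim = 200`
(observed REIC above all 200 randomizations).

The same pipeline is exposed as a CLI:

```bash
ridlmap simulate --seed 3 --out-dir bundle/
ridlmap screen --gtf bundle/genes.gtf --te-bed bundle/repeats.tsv \
    --chrom-sizes bundle/genome.chrom.sizes \
    --conserved-bed phastcons bundle/conserved_phastcons.bed \
    --conserved-bed ecs bundle/conserved_ecs.bed \
    --n-sim 200 --seed 4 --out-dir out/
ridlmap localize --ridl-bed out/ridls.bed --expr bundle/expression.tsv \
    --gtf bundle/genes.gtf --out-dir loc/
```

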