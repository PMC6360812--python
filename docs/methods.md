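# Methods

## Coordinate conventions and annotation

All internal coordinates are 0-based half-open (BED convention); GTF input
(1-based closed) is converted at the parse boundary and the conversion is an
identity on round trip.  Strand `.` is accepted on input, retained for
coverage statistics and excluded from strand-relative statistics.

Per gene, exons of all transcripts are merged with distance-0 semantics
(book-ended exons join, matching `bedtools merge`).  Introns are the gene
span (min exon start to max exon end) minus the merged exons; an intron
overlapping a second gene's span is discarded, so every retained intron
belongs to a single gene and carries its host's strand.

Each overlapping (TE instance, merged-exon interval) pair yields one record
classified into one of six structural categories — TSS (covers the gene's
first exonic nucleotide), TTS (last exonic nucleotide), encompassing (exon
inside TE), acceptor / donor (crosses the exon 5′/3′ boundary, in transcript
orientation), inside (TE within exon).  When several definitions apply the
precedence is TSS > TTS > encompassing > acceptor > donor > inside; this
covers the degenerate mono-exonic case (a TE spanning the whole gene is TSS)
and keeps the boundary categories intact for the downstream noSJ exclusion.
A TE overlapping two genes' exons yields one record per gene, since category
and relative strand are gene-relative.

Coverage by type counts nucleotides of the interval union covered by ≥ 1
instance of the type (same-type overlaps counted once).  Conservation counts
(Ce/Ne/Ci/Ni) are instead summed per TE fragment, the behaviour of
intersection-based nucleotide totals; the two choices are each validated
against brute-force per-nucleotide oracles in the test suite.

## Screens and empirical nulls

*Enrichment*: exonic/intronic coverage-fraction ratio; candidate iff ratio
strictly exceeds 2.  Zero intronic coverage makes the ratio undefined; such
types are flagged and never candidates (controls false positives from rare
types, rather than treating the ratio as infinite).

*Strand bias*: restricted to stranded records in categories
inside/encompassing (noSJ), because TE-contributed promoters and splice
sites would otherwise fabricate strand bias.  The statistic is the
sense/antisense nucleotide-coverage ratio (an instance-count option exists).
Antisense coverage of zero gives +inf, ranked as maximal — no pseudocount,
because significance comes from the empirical null, not the magnitude.  The
null rigidly repositions every gene (structure and strand preserved) on a
chromosome drawn proportional to length, uniform offset, and re-intersects
against the full TE annotation.  Shuffled genes may overlap each other and
pre-existing annotation; the inner intersection kernel is vectorized and is
tested for exact agreement with the per-record classifier.  Types whose
observed ratio exceeds all `n_sim` null ratios are candidates; types
significant in the antisense direction are recorded but excluded from
candidacy (dominated by elements whose sense insertion interferes with
transcription, hence likely an insertion-selection artifact, not RNA-level
function).

*Conservation (REIC)*: conserved fraction of exonic TE nucleotides over the
intronic one, per type, computed per conserved-element set.  The null
positionally randomizes the conserved elements (lengths preserved,
chromosome proportional to length, overlaps permitted) — not the TEs —
because conserved elements are enriched in exons, and shuffling TEs would
overestimate the background exonic conservation.  The TE-shuffling
alternative remains available behind a flag for comparison only (it is
biased toward long TEs).  Both directions are reported; depleted types are
flagged but never candidates.  A type needs ≥ 1 exonic and ≥ 1 intronic
fragment to enter the screen (prevents 0/0), and zero conserved intronic
nucleotides leaves REIC undefined (flagged).

*Empirical p-values*: `p = rank/(1 + n_sim)` with rank = 1 + the number of
null values at least as extreme.  A statistic beyond every null value is
rounded up to the conservative floor `1/n_sim` (0.001 at 1000 shuffles), and
candidacy is exactly the rank-1 event.  Benjamini–Hochberg q-values are
computed within each screen.  Under an exchangeable null the p-values are
super-uniform, which the suite checks directly and via no-effect bundles.

*Element-level true-positive fraction*: for an evidence type,
`1 − intronic/exonic overlap frequency` of candidate-type instances, floored
at zero.

## RIDL assembly

Enrichment evidence admits all exonic instances of the type; strand-bias
evidence admits sense-orientation instances; conservation evidence admits
instances intersecting (≥ 1 nt) the specific conserved set that flagged the
type.  Qualifying instances are merged genome-wide (overlapping or
book-ended records join, regardless of type); evidence labels, host genes
and source instances are unioned, the type contributing the most nucleotides
labels the merged record, and merged records shorter than 10 nt are dropped
(length 10 survives).  The merge is idempotent and its output
non-overlapping.

Insertion profiles give, per consensus position, the fraction of instances
whose fragment covers it; RIDL and intronic profiles of a type are compared
by Spearman correlation, flagged below 0.9 (constant profiles are flagged
degenerate rather than correlated).

## Localization and host-gene statistics

RCI = log2(nuclear/cytoplasmic RPKM), defined only when both fractions are
nonzero ("expressed" means exactly that — no RPKM floor).  One representative
transcript per gene (most exons; ties broken by lexicographic transcript id)
enters the screen.  Each (RIDL type, cell line) pair with ≥ 3 carrier
transcripts is tested two-sided by Wilcoxon rank-sum against all other
detected transcripts, BH-corrected globally, significant at q < 0.01;
direction is read from the medians, so cytoplasmic-shifting types surface in
the same screen.  Dose–response is two-sided Spearman.  The linear model is
OLS `RCI ~ ridl_count + transcript_length + expression` (expression as raw
RPKM by default, log2 optional) with per-term VIFs.  Partial Spearman
correlation rank-transforms all variables, residualizes on the controls by
OLS and correlates residuals, with a t-distribution p on n − 2 − k degrees
of freedom; it matches `pingouin.partial_corr(method="spearman")`, which the
suite uses as an independent oracle.  The isoform contrast computes, per
gene with both RIDL and non-RIDL isoforms quantified in a cell line,
Δ = mean RCI(RIDL) − mean RCI(non-RIDL), and tests Δ > 0 one-sided (the
directional prior being nuclear enrichment).

Host-gene analyses: the clustering test reassigns each RIDL to a gene with
probability proportional to merged exonic length (a positional shuffle in
expectation; uniform option available) and reports the per-count gene
histogram with an empirical 95 % band; control genes are sampled from 20
log-spaced exonic-length bins; Fisher tests are exact two-sided with the
sample odds ratio (Haldane-corrected auxiliary estimate for zero cells);
the logistic model falls back to an L2-regularized fit on complete
separation, flagged; DAF spectra use decile bins with rare = DAF < 0.1.

## Synthetic data generator

The generator emulates the statistical structure the screens assume, not
sequence content.  Defaults (the study conditions): 2 chromosomes × 4 Mb;
300 non-overlapping genes of 1–3 transcripts built as contiguous subsets of
a 3–8 exon chain (exons 150–400 nt, introns 800–3000 nt); 20 TE types at 3 %
per-type target coverage in each compartment, fragments 40–120 nt placed
with probability proportional to valid start positions (keeps per-nucleotide
placement density uniform; naive center-clustering in short exons measurably
contaminated cross-type conservation), consensus fragments sampled uniformly
with optional 5′/3′ anchoring to exercise the insertion-profile analysis;
5 % of exonic instances deliberately cross an exon boundary so all six
structural categories occur.

Planted effects: fold-4 exonic placement rate for `ENR1`/`ENR2`; 90 % sense
orientation for exonic `STR1`/`STR2`; for `CON1` (phastCons-style set) and
`CON2` (ECS-style set), a conserved element covering exactly 50 % of each
exonic fragment and 25 % of each intronic fragment — deterministic per
fragment, so the planted per-nucleotide fractions carry no Bernoulli noise —
on top of a uniform background element set (6 % coverage, 10–20 nt).
Because planted elements concentrate conserved density in exon space,
compensating plain elements are added in introns until the planted density
excess matches between compartments; without this, every TE type inherits a
spurious REIC ≈ 1.2.  Residual leakage through physically overlapping
fragments of different types can still produce the occasional (~0–1 per
screen) false conservation candidate on planted bundles; no-effect bundles
are leakage-free and calibrate exactly.

Localization: per transcript and cell line, true RCI = N(0, 1) baseline
(symmetric null; the real-data RCI distribution is not modelled) plus
+0.5 log2 units per exonic copy of a planted localization type; whole-cell
RPKM is lognormal and the nuclear/cytoplasmic split is back-computed so
RCI = log2(N/C) holds exactly before multiplicative measurement noise
(σ = 0.1 on the natural-log scale); optional dropout zeroes fractions.
Four cell lines by default.  SNP tables plant a rare-allele fraction of 0.6
in RIDL regions vs 0.4 elsewhere (2000 SNPs per region class); functional
gene flags follow a logistic model with +0.8 log-odds per planted RIDL over
a 15 % base rate.  Every file round-trips through the package's own
readers, and identical configurations produce byte-identical files.

What passing tests on these bundles does *not* show: real TE phylogenies and
length distributions, sequence-level effects, correlated cell lines,
expression-dependent detection, or the genome-scale multiple-testing burden
of a full annotation.  The generator's scale was chosen once, as a power
design for the planted effect sizes above: ~170 exonic fragments per type
keep the REIC and strand-ratio nulls tight enough that the planted effects
exceed all 200 null replicates with high probability, while a full screen
triple runs in well under a minute on one CPU.

## Numerical and problem-size choices

Shuffle counts default to `n_sim = 1000` (the floor p = 0.001); the test
suite and acceptance script run `n_sim = 200` (floor p = 1/200) to keep the
complete run in tens of seconds at the default bundle scale — the
calibration and recovery properties are scale-invariant under the floor
rescaling.  Null-calibration bundles use 200 TE types at 0.4 % coverage with
no planted effects.  Seeds parameterize every random step; sub-seeds are
derived additively so independent stages decouple.  Degenerate inputs are
errors, not silent values: empty null distributions, constant dose or
control columns, rank-deficient designs, undefined REIC/ratios, zero-length
interval sets and zero-instance profiles all raise or flag explicitly.

## Known limitations

Orthology dating, genome-build liftover, mouse analyses and RBP candidate
identification are out of scope.  The strand statistic's nucleotide-coverage
form is the primary definition with an instance-count option, since either
reading is defensible.  Whether the merge in RIDL assembly should be
per-gene or genome-wide is ambiguous for overlapping genes; it is
genome-wide here, with all host genes recorded per merged record.  The
expression filter is nonzero-in-both-fractions only; replicate-concordance
(IDR-style) filtering is not modelled.
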