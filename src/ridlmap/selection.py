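"""Per-TE-type selection screens: exonic enrichment, strand bias with a
gene-shuffling empirical null, and exonic/intronic conservation (REIC) with a
conserved-element-shuffling null.

Empirical p-values follow rank/(1 + n_sim); a statistic more extreme than all
n_sim null replicates is floored at 1/(1 + n_sim) (0.001 for 1000 shuffles).
False-discovery rates are Benjamini-Hochberg, computed within each screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import intervals as iv
from .annotation import ExonicTERecord, MergedExonSet, merge_exons
from .io_formats import GeneModel, GenomicInterval, TEInstance, Transcript

__all__ = [
    "ConservationCounts",
    "EmpiricalTestResult",
    "empirical_pvalue",
    "adjust_fdr",
    "compute_reic",
    "enrichment_screen",
    "shuffle_gene_structures",
    "shuffle_intervals",
    "strand_bias_screen",
    "conservation_screen",
    "element_level_fdr",
    "NOSJ_CATEGORIES",
]

#: categories that do not cross a splice junction / transcript boundary
NOSJ_CATEGORIES = frozenset({"inside", "encompassing"})


@dataclass(frozen=True)
class ConservationCounts:
    """Conserved (C) and non-conserved (N) TE nucleotides, exonic (e) and
    intronic (i)."""

    Ce: float
    Ne: float
    Ci: float
    Ni: float


@dataclass
class EmpiricalTestResult:
    te_type: str
    observed: float
    null_values: np.ndarray
    rank: int
    p_empirical: float
    direction: str  # "greater" | "less"
    fdr_q: Optional[float] = None


def _emp_p(rank: int, n_sim: int) -> float:
    """rank/(1 + n_sim), with the rank-1 case rounded up to 1/n_sim — the
    conservative floor convention for a statistic beyond every null value
    (0.001 for 1000 shuffles)."""
    if rank == 1:
        return 1.0 / n_sim
    return rank / (1 + n_sim)


def empirical_pvalue(
    observed: float, null_values: Sequence[float], direction: str = "greater",
    te_type: str = "",
) -> EmpiricalTestResult:
    """Empirical p = rank/(1 + n_sim), rank = 1 + #{null at least as extreme}.

    An observed value more extreme than every null replicate receives the
    conservative floor 1/(1 + n_sim).
    """
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    if direction == "greater":
        rank = 1 + int(np.sum(null >= observed))
    elif direction == "less":
        rank = 1 + int(np.sum(null <= observed))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    p = _emp_p(rank, null.size)
    return EmpiricalTestResult(
        te_type=te_type,
        observed=float(observed),
        null_values=null,
        rank=rank,
        p_empirical=p,
        direction=direction,
    )


def adjust_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compute_reic(counts: ConservationCounts) -> float:
    """Relative exonic-intronic conservation:
    (Ce/(Ce+Ne)) / (Ci/(Ci+Ni))."""
    if counts.Ce + counts.Ne <= 0 or counts.Ci + counts.Ni <= 0:
        raise ValueError("REIC undefined: no exonic or intronic TE nucleotides")
    if counts.Ci <= 0:
        raise ValueError("REIC undefined: zero conserved intronic nucleotides")
    exonic = counts.Ce / (counts.Ce + counts.Ne)
    intronic = counts.Ci / (counts.Ci + counts.Ni)
    return exonic / intronic


def enrichment_screen(
    exon_cov: pd.DataFrame,
    intron_cov: pd.DataFrame,
    fold_cutoff: float = 2.0,
) -> pd.DataFrame:
    """Exonic/intronic coverage-fraction ratio per TE type.

    A type is a candidate iff ratio > ``fold_cutoff`` (strictly).  Types with
    zero intronic coverage have an undefined ratio and are flagged, never
    candidates.
    """
    types = sorted(set(exon_cov.index) | set(intron_cov.index))
    rows = []
    for t in types:
        ef = float(exon_cov["fraction"].get(t, 0.0))
        inf_ = float(intron_cov["fraction"].get(t, 0.0))
        if inf_ == 0.0:
            ratio = np.nan if ef > 0 else 0.0
            flag = "undefined" if ef > 0 else "absent"
            cand = False
        else:
            ratio = ef / inf_
            flag = ""
            cand = ratio > fold_cutoff
        rows.append((t, ef, inf_, ratio, cand, flag))
    return pd.DataFrame(
        rows,
        columns=[
            "te_type", "exonic_fraction", "intronic_fraction", "ratio",
            "candidate", "flag",
        ],
    ).set_index("te_type")


# ---------------------------------------------------------------------------
# shuffling nulls
# ---------------------------------------------------------------------------


def _chrom_sampler(chrom_sizes: dict[str, int]):
    chroms = sorted(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    return chroms, np.array([chrom_sizes[c] for c in chroms]), probs


def shuffle_gene_structures(
    genes: Iterable[GeneModel],
    chrom_sizes: dict[str, int],
    seed: int | np.random.Generator,
) -> list[GeneModel]:
    """Rigidly reposition each gene (exon/intron structure and strand kept) at
    a uniform random offset on a chromosome chosen proportional to length."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms, lengths, probs = _chrom_sampler(chrom_sizes)
    out = []
    for gene in genes:
        span = gene.span
        span_len = span.length
        fits = lengths >= span_len
        if not fits.any():
            raise ValueError(
                f"gene {gene.gene_id} ({span_len} nt) longer than every chromosome"
            )
        p = np.where(fits, probs, 0.0)
        p = p / p.sum()
        ci = rng.choice(len(chroms), p=p)
        offset = int(rng.integers(0, lengths[ci] - span_len + 1))
        shift = offset - span.start
        new_chrom = chroms[ci]
        new_tx = [
            Transcript(
                transcript_id=t.transcript_id,
                exons=[
                    GenomicInterval(new_chrom, e.start + shift, e.end + shift, e.strand)
                    for e in t.exons
                ],
            )
            for t in gene.transcripts
        ]
        out.append(GeneModel(gene_id=gene.gene_id, biotype=gene.biotype, transcripts=new_tx))
    return out


def shuffle_intervals(
    lengths: np.ndarray,
    chrom_sizes: dict[str, int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Place elements of the given lengths uniformly at random (chromosome
    proportional to length; elements may overlap).  Returns (chrom_idx,
    starts); chromosome order is sorted name order."""
    chroms, clens, probs = _chrom_sampler(chrom_sizes)
    lengths = np.asarray(lengths, dtype=np.int64)
    ci = rng.choice(len(chroms), size=lengths.size, p=probs)
    max_start = clens[ci] - lengths
    # elements longer than the chromosome are clipped to it
    max_start = np.maximum(max_start, 0)
    starts = (rng.random(lengths.size) * (max_start + 1)).astype(np.int64)
    return ci, starts


# ---------------------------------------------------------------------------
# strand-bias screen
# ---------------------------------------------------------------------------

_STRAND_CODE = {"+": 1, "-": -1, ".": 0}


class _TEIndex:
    """Per-chromosome numpy index over the full TE annotation."""

    def __init__(self, tes: Sequence[TEInstance], type_codes: dict[str, int]):
        self.by_chrom: dict[str, tuple[iv.IntervalIndex, np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        grouped: dict[str, list[int]] = {}
        for i, te in enumerate(tes):
            grouped.setdefault(te.interval.chrom, []).append(i)
        for chrom, ids in grouped.items():
            starts = np.array([tes[i].interval.start for i in ids], dtype=np.int64)
            ends = np.array([tes[i].interval.end for i in ids], dtype=np.int64)
            strands = np.array(
                [_STRAND_CODE[tes[i].interval.strand] for i in ids], dtype=np.int8
            )
            codes = np.array([type_codes[tes[i].te_type] for i in ids], dtype=np.int64)
            self.by_chrom[chrom] = (iv.IntervalIndex(starts, ends), starts, ends, strands, codes)


def _ratio(sense: np.ndarray, anti: np.ndarray) -> np.ndarray:
    """sense/antisense ratio; antisense 0 with sense > 0 ranks as +inf, types
    with no stranded signal at all yield nan."""
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(anti > 0, sense / np.maximum(anti, 1e-300), np.inf)
    r = np.where((sense == 0) & (anti == 0), np.nan, r)
    return r


def strand_bias_screen(
    exonic_records: Sequence[ExonicTERecord],
    genes: Sequence[GeneModel],
    tes: Sequence[TEInstance],
    chrom_sizes: dict[str, int],
    n_sim: int = 1000,
    seed: int = 0,
    statistic: str = "coverage",
) -> pd.DataFrame:
    """Sense/antisense screen on noSJ exonic TEs with a gene-shuffling null.

    The null rigidly repositions every gene structure, re-intersects against
    the full TE annotation and recomputes per-type ratios.  Candidates are
    types whose observed ratio exceeds all ``n_sim`` null ratios (direction
    greater); significant antisense enrichment is recorded via
    ``antisense_significant`` but never yields candidates.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)

    # eligible types: >=1 stranded noSJ exonic record
    obs_records = [
        r
        for r in exonic_records
        if r.category in NOSJ_CATEGORIES and r.relative_strand is not None
    ]
    types = sorted({r.te.te_type for r in obs_records})
    if not types:
        return pd.DataFrame(
            columns=[
                "te_type", "observed", "sense", "antisense", "p_greater",
                "p_less", "fdr_q", "candidate", "antisense_significant",
                "null_mean", "null_max",
            ]
        ).set_index("te_type")
    codes = {t: i for i, t in enumerate(types)}
    n_types = len(types)

    obs_sense = np.zeros(n_types)
    obs_anti = np.zeros(n_types)
    for r in obs_records:
        w = float(r.overlap_nt) if statistic == "coverage" else 1.0
        if r.relative_strand == "sense":
            obs_sense[codes[r.te.te_type]] += w
        else:
            obs_anti[codes[r.te.te_type]] += w
    observed = _ratio(obs_sense, obs_anti)

    te_index = _TEIndex(tes, {t: codes.get(t, -1) for t in {x.te_type for x in tes}})
    # drop TEs of types never seen exonic (code -1) by masking at accumulate
    null_ratios = np.empty((n_sim, n_types))
    for k in range(n_sim):
        shuffled = shuffle_gene_structures(genes, chrom_sizes, rng)
        merged = [merge_exons(g) for g in shuffled]
        sense, anti = _nosj_strand_nt_masked(merged, te_index, n_types, statistic)
        null_ratios[k] = _ratio(sense, anti)

    rows = []
    for t in types:
        i = codes[t]
        null = null_ratios[:, i]
        finite_obs = observed[i]
        # nan nulls (type absent from shuffled exons) count as non-exceeding
        null_g = np.where(np.isnan(null), -np.inf, null)
        null_l = np.where(np.isnan(null), np.inf, null)
        rank_g = 1 + int(np.sum(null_g >= finite_obs))
        rank_l = 1 + int(np.sum(null_l <= finite_obs))
        rows.append(
            (
                t, finite_obs, obs_sense[i], obs_anti[i],
                _emp_p(rank_g, n_sim), _emp_p(rank_l, n_sim),
                np.nan, rank_g == 1, rank_l == 1,
                float(np.nanmean(null)) if np.isfinite(null).any() else np.nan,
                float(np.nanmax(null_g)),
            )
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "te_type", "observed", "sense", "antisense", "p_greater", "p_less",
            "fdr_q", "candidate", "antisense_significant", "null_mean",
            "null_max",
        ],
    ).set_index("te_type")
    df["fdr_q"] = adjust_fdr(df["p_greater"].to_numpy())
    return df


def _nosj_strand_nt_masked(merged_sets, te_index, n_types, statistic):
    sense = np.zeros(n_types + 1, dtype=float)
    anti = np.zeros(n_types + 1, dtype=float)
    for m in merged_sets:
        entry = te_index.by_chrom.get(m.chrom)
        if entry is None:
            continue
        index, starts, ends, strands, codes = entry
        lo, hi = m.span
        first_nt = hi - 1 if m.strand == "-" else lo
        last_nt = lo if m.strand == "-" else hi - 1
        gcode = _STRAND_CODE[m.strand]
        for exon in m.intervals:
            js = index.overlapping(exon.start, exon.end)
            if js.size == 0:
                continue
            s, e = starts[js], ends[js]
            covers_first = (s <= first_nt) & (first_nt < e)
            covers_last = (s <= last_nt) & (last_nt < e)
            inside = (s >= exon.start) & (e <= exon.end)
            encomp = (s <= exon.start) & (e >= exon.end)
            keep = ~covers_first & ~covers_last & (inside | encomp)
            if not keep.any():
                continue
            s, e = s[keep], e[keep]
            sc, tc = strands[js][keep], codes[js][keep]
            ok = (sc != 0) & (tc >= 0)
            if not ok.any():
                continue
            s, e, sc, tc = s[ok], e[ok], sc[ok], tc[ok]
            if statistic == "coverage":
                w = (np.minimum(e, exon.end) - np.maximum(s, exon.start)).astype(float)
            else:
                w = np.ones(s.size)
            is_sense = sc == gcode
            np.add.at(sense, tc[is_sense], w[is_sense])
            np.add.at(anti, tc[~is_sense], w[~is_sense])
    return sense[:n_types], anti[:n_types]


# ---------------------------------------------------------------------------
# conservation screen
# ---------------------------------------------------------------------------


def _conserved_nt_per_type(
    frag_starts: dict[str, np.ndarray],
    frag_ends: dict[str, np.ndarray],
    frag_codes: dict[str, np.ndarray],
    cons_starts: dict[str, np.ndarray],
    cons_ends: dict[str, np.ndarray],
    n_types: int,
) -> np.ndarray:
    """Summed conserved nt per TE type over TE fragments (per-fragment
    overlap with the union of conserved elements)."""
    out = np.zeros(n_types, dtype=float)
    for chrom, fs in frag_starts.items():
        cs = cons_starts.get(chrom)
        if cs is None or cs.size == 0 or fs.size == 0:
            continue
        ov = iv.coverage_of(fs, frag_ends[chrom], cs, cons_ends[chrom])
        np.add.at(out, frag_codes[chrom], ov.astype(float))
    return out


def conservation_screen(
    exonic_fragments: pd.DataFrame,
    intronic_fragments: pd.DataFrame,
    conserved: Sequence[tuple[GenomicInterval, str]],
    chrom_sizes: dict[str, int],
    n_sim: int = 1000,
    seed: int = 0,
    shuffle_tes: bool = False,
) -> pd.DataFrame:
    """REIC screen against one conserved-element set.

    ``exonic_fragments``/``intronic_fragments`` are ``intersect_tes`` tables
    (TE clipped to merged exons / introns).  The null positionally randomizes
    the conserved elements (lengths preserved, chromosome proportional to
    length, overlaps permitted) and recomputes REIC per type.  Candidates are
    types whose REIC exceeds all null values; depleted types (below all null
    values) are flagged and excluded from candidacy.

    ``shuffle_tes=True`` switches to the alternative null that randomizes the
    TE fragments instead (for comparison only; biased toward long TEs).
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)

    ex_types = set(exonic_fragments["te_type"]) if len(exonic_fragments) else set()
    in_types = set(intronic_fragments["te_type"]) if len(intronic_fragments) else set()
    types = sorted(ex_types & in_types)  # minimum-data filter
    skipped = sorted((ex_types | in_types) - set(types))
    codes = {t: i for i, t in enumerate(types)}
    n_types = len(types)
    cols = [
        "te_type", "observed", "Ce", "Ne", "Ci", "Ni", "p_greater", "p_less",
        "fdr_q", "candidate", "depleted", "flag",
    ]
    if n_types == 0:
        df = pd.DataFrame(columns=cols).set_index("te_type")
        return df

    def _group(frags: pd.DataFrame):
        fs, fe, fc = {}, {}, {}
        sub = frags[frags["te_type"].isin(codes)]
        for chrom, g in sub.groupby("chrom"):
            fs[chrom] = g["frag_start"].to_numpy(dtype=np.int64)
            fe[chrom] = g["frag_end"].to_numpy(dtype=np.int64)
            fc[chrom] = g["te_type"].map(codes).to_numpy(dtype=np.int64)
        return fs, fe, fc

    ex_fs, ex_fe, ex_fc = _group(exonic_fragments)
    in_fs, in_fe, in_fc = _group(intronic_fragments)

    total_e = np.zeros(n_types)
    total_i = np.zeros(n_types)
    for chrom in ex_fs:
        np.add.at(total_e, ex_fc[chrom], (ex_fe[chrom] - ex_fs[chrom]).astype(float))
    for chrom in in_fs:
        np.add.at(total_i, in_fc[chrom], (in_fe[chrom] - in_fs[chrom]).astype(float))

    chroms_sorted = sorted(chrom_sizes)
    cons_lengths = np.array([c.length for c, _ in conserved], dtype=np.int64)

    def _cons_arrays(ci: np.ndarray, starts: np.ndarray):
        cs, ce = {}, {}
        for k, chrom in enumerate(chroms_sorted):
            mask = ci == k
            if mask.any():
                s = starts[mask]
                e = np.minimum(s + cons_lengths[mask], chrom_sizes[chrom])
                cs[chrom], ce[chrom] = s, e
        return cs, ce

    obs_cs: dict[str, list[int]] = {}
    obs_ce: dict[str, list[int]] = {}
    for c, _name in conserved:
        obs_cs.setdefault(c.chrom, []).append(c.start)
        obs_ce.setdefault(c.chrom, []).append(c.end)
    obs_cs_a = {c: np.array(v, dtype=np.int64) for c, v in obs_cs.items()}
    obs_ce_a = {c: np.array(v, dtype=np.int64) for c, v in obs_ce.items()}

    def _reic_vec(cs, ce):
        Ce = _conserved_nt_per_type(ex_fs, ex_fe, ex_fc, cs, ce, n_types)
        Ci = _conserved_nt_per_type(in_fs, in_fe, in_fc, cs, ce, n_types)
        with np.errstate(divide="ignore", invalid="ignore"):
            reic = (Ce / total_e) / (Ci / total_i)
        reic = np.where(Ci == 0, np.nan, reic)
        return reic, Ce, Ci

    observed, obs_Ce, obs_Ci = _reic_vec(obs_cs_a, obs_ce_a)

    null = np.empty((n_sim, n_types))
    if not shuffle_tes:
        for k in range(n_sim):
            ci, starts = shuffle_intervals(cons_lengths, chrom_sizes, rng)
            cs, ce = _cons_arrays(ci, starts)
            null[k] = _reic_vec(cs, ce)[0]
    else:
        # alternative null: randomize TE fragments, conserved elements fixed
        ex_all_s = np.concatenate([ex_fs[c] for c in ex_fs]) if ex_fs else np.empty(0, np.int64)
        ex_all_e = np.concatenate([ex_fe[c] for c in ex_fs]) if ex_fs else np.empty(0, np.int64)
        ex_all_c = np.concatenate([ex_fc[c] for c in ex_fs]) if ex_fs else np.empty(0, np.int64)
        in_all_s = np.concatenate([in_fs[c] for c in in_fs]) if in_fs else np.empty(0, np.int64)
        in_all_e = np.concatenate([in_fe[c] for c in in_fs]) if in_fs else np.empty(0, np.int64)
        in_all_c = np.concatenate([in_fc[c] for c in in_fs]) if in_fs else np.empty(0, np.int64)
        for k in range(n_sim):
            ex_ci, ex_st = shuffle_intervals(ex_all_e - ex_all_s, chrom_sizes, rng)
            in_ci, in_st = shuffle_intervals(in_all_e - in_all_s, chrom_sizes, rng)
            efs, efe, efc = {}, {}, {}
            ifs, ife, ifc = {}, {}, {}
            for kk, chrom in enumerate(chroms_sorted):
                em = ex_ci == kk
                if em.any():
                    efs[chrom] = ex_st[em]
                    efe[chrom] = ex_st[em] + (ex_all_e - ex_all_s)[em]
                    efc[chrom] = ex_all_c[em]
                im = in_ci == kk
                if im.any():
                    ifs[chrom] = in_st[im]
                    ife[chrom] = in_st[im] + (in_all_e - in_all_s)[im]
                    ifc[chrom] = in_all_c[im]
            Ce = _conserved_nt_per_type(efs, efe, efc, obs_cs_a, obs_ce_a, n_types)
            Ci = _conserved_nt_per_type(ifs, ife, ifc, obs_cs_a, obs_ce_a, n_types)
            with np.errstate(divide="ignore", invalid="ignore"):
                r = (Ce / total_e) / (Ci / total_i)
            null[k] = np.where(Ci == 0, np.nan, r)

    rows = []
    for t in types:
        i = codes[t]
        obs = observed[i]
        if np.isnan(obs):
            rows.append((t, np.nan, obs_Ce[i], total_e[i] - obs_Ce[i], obs_Ci[i],
                         total_i[i] - obs_Ci[i], np.nan, np.nan, np.nan, False,
                         False, "undefined"))
            continue
        nv = null[:, i]
        null_g = np.where(np.isnan(nv), -np.inf, nv)
        null_l = np.where(np.isnan(nv), np.inf, nv)
        rank_g = 1 + int(np.sum(null_g >= obs))
        rank_l = 1 + int(np.sum(null_l <= obs))
        rows.append(
            (
                t, obs, obs_Ce[i], total_e[i] - obs_Ce[i], obs_Ci[i],
                total_i[i] - obs_Ci[i], _emp_p(rank_g, n_sim), _emp_p(rank_l, n_sim),
                np.nan, rank_g == 1, rank_l == 1, "",
            )
        )
    df = pd.DataFrame(rows, columns=cols).set_index("te_type")
    defined = df["p_greater"].notna()
    q = np.full(len(df), np.nan)
    if defined.any():
        q[defined.to_numpy()] = adjust_fdr(df.loc[defined, "p_greater"].to_numpy())
    df["fdr_q"] = q
    for t in skipped:
        df.loc[t] = [np.nan] * 8 + [False, False, "skipped: absent from exons or introns"]
    return df


def element_level_fdr(
    exonic_overlap: Sequence[bool], intronic_overlap: Sequence[bool]
) -> float:
    """True-positive-fraction estimate for one evidence type:
    1 - (intronic overlap frequency / exonic overlap frequency), floored at 0.

    Inputs are per-instance booleans (does the instance of a candidate type
    overlap the evidence?) for exonic and intronic annotations.
    """
    ex = np.asarray(exonic_overlap, dtype=bool)
    intr = np.asarray(intronic_overlap, dtype=bool)
    if ex.size == 0 or intr.size == 0:
        raise ValueError("empty instance set")
    fe = ex.mean()
    fi = intr.mean()
    if fe == 0:
        raise ValueError("zero exonic overlap frequency: TP fraction undefined")
    return max(0.0, 1.0 - fi / fe)
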