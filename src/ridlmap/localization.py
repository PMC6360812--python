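"""Nuclear/cytoplasmic localization statistics.

The relative concentration index (RCI) of a transcript in a cell line is
log2(nuclear RPKM / cytoplasmic RPKM); it is defined only when both fractions
are nonzero.  The screen compares RCI of RIDL-carrying versus other
transcripts per (RIDL type, cell line) with a two-sided Wilcoxon rank-sum
test, BH-corrected globally; dose-response uses Spearman correlation; the
linear model is RCI ~ ridl_count + transcript_length + whole-cell expression
with VIF diagnostics; the isoform contrast compares RIDL and non-RIDL
isoforms of the same gene locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .io_formats import GeneModel
from .selection import adjust_fdr

__all__ = [
    "TranscriptLocalization",
    "ModelFit",
    "compute_rci",
    "pick_representative_transcript",
    "localization_screen",
    "dose_response",
    "fit_localization_model",
    "partial_correlation",
    "isoform_contrast",
]

FRACTIONS = ("nuclear", "cytoplasmic", "whole_cell")


@dataclass(frozen=True)
class TranscriptLocalization:
    transcript_id: str
    gene_id: str
    cell_line: str
    nuclear_rpkm: float
    cytoplasmic_rpkm: float
    whole_cell_rpkm: float
    rci: float


@dataclass
class ModelFit:
    terms: list[str]
    coefficients: dict[str, float]
    p_values: dict[str, float]
    vifs: dict[str, float]
    n_obs: int
    kind: str  # "ols" | "logit" | "logit_regularized"
    converged: bool = True
    flags: str = ""


def compute_rci(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-transcript, per-cell-line RCI from a long expression table.

    ``expr`` columns: transcript_id, gene_id, cell_line, fraction, rpkm with
    fraction in {nuclear, cytoplasmic, whole_cell}.  Only transcripts with
    nonzero nuclear and cytoplasmic RPKM get an RCI; others are excluded.
    Negative RPKM raises.
    """
    required = {"transcript_id", "gene_id", "cell_line", "fraction", "rpkm"}
    missing = required - set(expr.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    if (expr["rpkm"] < 0).any():
        raise ValueError("negative RPKM")
    wide = expr.pivot_table(
        index=["transcript_id", "gene_id", "cell_line"],
        columns="fraction",
        values="rpkm",
        aggfunc="first",
    ).reset_index()
    for frac in FRACTIONS:
        if frac not in wide.columns:
            wide[frac] = np.nan
    ok = (wide["nuclear"] > 0) & (wide["cytoplasmic"] > 0)
    wide = wide[ok].copy()
    wide["rci"] = np.log2(wide["nuclear"]) - np.log2(wide["cytoplasmic"])
    return wide.rename(
        columns={
            "nuclear": "nuclear_rpkm",
            "cytoplasmic": "cytoplasmic_rpkm",
            "whole_cell": "whole_cell_rpkm",
        }
    )[
        [
            "transcript_id", "gene_id", "cell_line", "nuclear_rpkm",
            "cytoplasmic_rpkm", "whole_cell_rpkm", "rci",
        ]
    ]


def pick_representative_transcript(gene: GeneModel) -> str:
    """The transcript with the most exons; ties broken by lexicographically
    smallest transcript_id for determinism."""
    return min(gene.transcripts, key=lambda t: (-t.n_exons, t.transcript_id)).transcript_id


def localization_screen(
    ridl_types_per_transcript: Mapping[str, set[str]],
    locs: pd.DataFrame,
    representative: Optional[set[str]] = None,
    min_carriers: int = 3,
    alpha_q: float = 0.01,
) -> pd.DataFrame:
    """Wilcoxon rank-sum screen of RIDL-carrying vs other transcripts.

    ``ridl_types_per_transcript`` maps transcript_id -> set of RIDL types it
    carries.  ``locs`` is a ``compute_rci`` table.  Tests run per (type, cell
    line) with >= ``min_carriers`` carrier transcripts having defined RCI;
    p-values are BH-adjusted globally across all tests.
    """
    if representative is not None:
        locs = locs[locs["transcript_id"].isin(representative)]
    all_types = sorted({t for s in ridl_types_per_transcript.values() for t in s})
    rows = []
    for cell, sub in locs.groupby("cell_line", sort=True):
        tids = sub["transcript_id"].to_numpy()
        rci = sub["rci"].to_numpy()
        for t in all_types:
            carrier_mask = np.array(
                [t in ridl_types_per_transcript.get(tid, ()) for tid in tids]
            )
            n_r = int(carrier_mask.sum())
            n_b = int((~carrier_mask).sum())
            if n_r < min_carriers or n_b == 0:
                continue
            a, b = rci[carrier_mask], rci[~carrier_mask]
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            rows.append(
                (
                    t, cell, n_r, n_b, float(np.median(a)), float(np.median(b)), p,
                )
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "te_type", "cell_line", "n_ridl_transcripts", "n_background",
            "median_rci_ridl", "median_rci_background", "p_wilcoxon",
        ],
    )
    if len(df):
        df["q_bh"] = adjust_fdr(df["p_wilcoxon"].to_numpy())
        df["significant"] = df["q_bh"] < alpha_q
    else:
        df["q_bh"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df


def dose_response(
    rci: Sequence[float], ridl_counts: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Spearman correlation of RIDL copy number with RCI."""
    rci = np.asarray(rci, dtype=float)
    counts = np.asarray(ridl_counts, dtype=float)
    if rci.size < 3:
        raise ValueError("dose-response requires >= 3 transcripts with RCI")
    if np.all(counts == counts[0]) or np.all(rci == rci[0]):
        raise ValueError("dose-response undefined for a constant variable")
    res = stats.spearmanr(counts, rci, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def fit_localization_model(
    rci: Sequence[float],
    ridl_counts: Sequence[float],
    lengths: Sequence[float],
    whole_cell_expr: Sequence[float],
    log_expression: bool = False,
) -> ModelFit:
    """OLS of RCI on RIDL count, transcript length and whole-cell expression.

    Expression enters as raw RPKM by default; ``log_expression`` applies
    log2(RPKM) instead.  VIFs are reported per term.
    """
    y = np.asarray(rci, dtype=float)
    X = pd.DataFrame(
        {
            "ridl_count": np.asarray(ridl_counts, dtype=float),
            "transcript_length": np.asarray(lengths, dtype=float),
            "expression": np.asarray(whole_cell_expr, dtype=float),
        }
    )
    if log_expression:
        X["expression"] = np.log2(X["expression"])
    if len(X) < 10:
        raise ValueError("linear model requires >= 10 observations")
    if X.isna().any().any() or np.isnan(y).any():
        raise ValueError("missing values in model inputs")
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        collinear = [c for c in X.columns if X[c].nunique() == 1]
        raise ValueError(f"rank-deficient design (collinear terms: {collinear or 'unknown'})")
    fit = sm.OLS(y, Xc).fit()
    vifs = {
        col: float(variance_inflation_factor(Xc.to_numpy(), i))
        for i, col in enumerate(Xc.columns)
        if col != "const"
    }
    return ModelFit(
        terms=list(X.columns),
        coefficients={c: float(fit.params[c]) for c in Xc.columns},
        p_values={c: float(fit.pvalues[c]) for c in Xc.columns},
        vifs=vifs,
        n_obs=int(fit.nobs),
        kind="ols",
    )


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    controls: Mapping[str, Sequence[float]],
) -> tuple[float, float]:
    """Rank-based (Spearman) partial correlation of x and y given controls.

    All variables are rank-transformed, each of x and y is regressed (OLS) on
    the controls, and the Pearson correlation of the residuals is returned
    with a t-distribution p-value on n - 2 - k degrees of freedom.
    """
    xr = stats.rankdata(np.asarray(x, dtype=float))
    yr = stats.rankdata(np.asarray(y, dtype=float))
    ctrl = np.column_stack(
        [stats.rankdata(np.asarray(v, dtype=float)) for v in controls.values()]
    )
    n, k = xr.size, ctrl.shape[1]
    if n - 2 - k <= 0:
        raise ValueError("too few observations for partial correlation")
    for name, v in controls.items():
        if np.all(np.asarray(v) == np.asarray(v)[0]):
            raise ValueError(f"constant control column {name!r}")
    if np.all(xr == xr[0]) or np.all(yr == yr[0]):
        raise ValueError("constant variable")
    Z = sm.add_constant(ctrl, has_constant="add")
    rx = xr - Z @ np.linalg.lstsq(Z, xr, rcond=None)[0]
    ry = yr - Z @ np.linalg.lstsq(Z, yr, rcond=None)[0]
    r = float(np.corrcoef(rx, ry)[0, 1])
    dof = n - 2 - k
    r_clip = min(max(r, -0.9999999), 0.9999999)
    tstat = r_clip * math.sqrt(dof / (1 - r_clip**2))
    p = 2 * stats.t.sf(abs(tstat), dof)
    return r, float(p)


def isoform_contrast(
    genes: Sequence[GeneModel],
    locs: pd.DataFrame,
    ridl_transcripts: set[str],
) -> pd.DataFrame:
    """Within-gene contrast of RIDL vs non-RIDL isoform localization.

    For each cell line and each gene with >= 1 RIDL isoform and >= 1 non-RIDL
    isoform having defined RCI, delta = mean RCI(RIDL) - mean RCI(non-RIDL).
    Returns one row per cell line with the per-gene deltas, their median and
    a one-sided (delta > 0) one-sample t-test p-value.
    """
    tx2gene = {
        t.transcript_id: g.gene_id for g in genes for t in g.transcripts
    }
    rows = []
    for cell, sub in locs.groupby("cell_line", sort=True):
        deltas = []
        for gid, gsub in sub.groupby("gene_id", sort=True):
            tids = gsub["transcript_id"].to_numpy()
            rci = gsub["rci"].to_numpy()
            is_r = np.array([tid in ridl_transcripts for tid in tids])
            if is_r.any() and (~is_r).any():
                deltas.append(float(rci[is_r].mean() - rci[~is_r].mean()))
        if not deltas:
            continue
        deltas_arr = np.array(deltas)
        if deltas_arr.size > 1 and deltas_arr.std() > 0:
            p = float(
                stats.ttest_1samp(deltas_arr, 0.0, alternative="greater").pvalue
            )
        else:
            p = float("nan")
        rows.append(
            (cell, len(deltas), float(np.median(deltas_arr)), float(deltas_arr.mean()), p, deltas)
        )
    return pd.DataFrame(
        rows,
        columns=["cell_line", "n_genes", "median_delta", "mean_delta", "p_ttest", "deltas"],
    )
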