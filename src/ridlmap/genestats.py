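"""Host-gene analyses: RIDL clustering randomization, length-matched control
sampling, Fisher functional-enrichment tests, multiple logistic regression and
derived-allele-frequency (DAF) spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .localization import ModelFit

__all__ = [
    "GeneFunctionRecord",
    "clustering_test",
    "sample_matched_controls",
    "fisher_enrichment",
    "fit_functional_model",
    "daf_spectrum",
    "REGION_CLASSES",
]

REGION_CLASSES = (
    "RIDL",
    "exonic_TE_nonRIDL",
    "intronic_TE",
    "exonic_nonRIDL",
    "ancestral_repeat_flank",
)


@dataclass(frozen=True)
class GeneFunctionRecord:
    gene_id: str
    in_functional_db: bool
    disease_associated: bool
    has_exonic_trait_snp: bool
    exonic_length: int
    exonic_conservation_fraction: float
    ridl_count: int


def clustering_test(
    ridl_counts: Mapping[str, int],
    gene_exonic_lengths: Mapping[str, int],
    n_sim: int = 1000,
    seed: int = 0,
    weighting: str = "length",
    max_count: Optional[int] = None,
) -> pd.DataFrame:
    """Observed per-gene RIDL-count histogram with an empirical 95% null band.

    The null reassigns every RIDL independently to a gene with probability
    proportional to its merged exonic length (``weighting="uniform"`` assigns
    uniformly instead); each replicate conserves the RIDL total.  Returns one
    row per count value with the observed number of genes and the 2.5/97.5
    percentile band over replicates.
    """
    genes = sorted(gene_exonic_lengths)
    n_ridls = int(sum(ridl_counts.values()))
    if n_ridls < 1:
        raise ValueError("clustering test requires >= 1 RIDL")
    if weighting == "length":
        w = np.array([gene_exonic_lengths[g] for g in genes], dtype=float)
    elif weighting == "uniform":
        w = np.ones(len(genes))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    probs = w / w.sum()
    rng = np.random.default_rng(seed)

    observed = np.zeros(len(genes), dtype=np.int64)
    gidx = {g: i for i, g in enumerate(genes)}
    for g, c in ridl_counts.items():
        if g in gidx:
            observed[gidx[g]] += c
    if max_count is None:
        max_count = max(int(observed.max()), 1) + 2
    bins = np.arange(0, max_count + 1)

    def _hist(counts_per_gene: np.ndarray) -> np.ndarray:
        clipped = np.minimum(counts_per_gene, max_count)
        return np.bincount(clipped, minlength=max_count + 1)

    obs_hist = _hist(observed)
    null_hists = np.empty((n_sim, max_count + 1), dtype=np.int64)
    for k in range(n_sim):
        assigned = rng.multinomial(n_ridls, probs)
        null_hists[k] = _hist(assigned)
        assert assigned.sum() == n_ridls
    lo = np.percentile(null_hists, 2.5, axis=0)
    hi = np.percentile(null_hists, 97.5, axis=0)
    return pd.DataFrame(
        {
            "ridl_count": bins,
            "observed_genes": obs_hist,
            "null_low": lo,
            "null_high": hi,
            "null_mean": null_hists.mean(axis=0),
        }
    )


def sample_matched_controls(
    target_lengths: Mapping[str, float],
    pool_lengths: Mapping[str, float],
    n_bins: int = 20,
    seed: int = 0,
) -> list[str]:
    """Histogram-matched control sampling on log-spaced length bins.

    Samples, per bin, as many pool genes as there are targets in the bin
    (without replacement; bin-capped when the pool is exhausted, with a
    warning when the shortfall covers >= 10% of targets).
    """
    if set(target_lengths) & set(pool_lengths):
        raise ValueError("pool must be disjoint from targets")
    rng = np.random.default_rng(seed)
    all_lengths = np.array(list(target_lengths.values()) + list(pool_lengths.values()), dtype=float)
    lo, hi = all_lengths.min(), all_lengths.max()
    edges = np.logspace(np.log10(max(lo, 1.0)), np.log10(hi + 1), n_bins + 1)
    edges[0] = min(edges[0], lo)
    edges[-1] = hi + 1

    t_ids = sorted(target_lengths)
    p_ids = sorted(pool_lengths)
    t_bins = np.digitize([target_lengths[g] for g in t_ids], edges) - 1
    p_bins = np.digitize([pool_lengths[g] for g in p_ids], edges) - 1

    chosen: list[str] = []
    shortfall = 0
    for b in range(n_bins):
        want = int(np.sum(t_bins == b))
        if want == 0:
            continue
        avail = [p_ids[i] for i in np.flatnonzero(p_bins == b)]
        take = min(want, len(avail))
        shortfall += want - take
        if take:
            chosen.extend(rng.choice(avail, size=take, replace=False).tolist())
    if shortfall >= 0.1 * len(t_ids):
        warnings.warn(
            f"length matching exhausted pool bins for {shortfall}/{len(t_ids)} targets",
            stacklevel=2,
        )
    return sorted(chosen)


def fisher_enrichment(
    n_target_pos: int, n_target_neg: int, n_control_pos: int, n_control_neg: int
) -> tuple[float, float]:
    """Two-sided Fisher exact test on the 2x2 table
    [[target+, target-], [control+, control-]].

    Returns (sample odds ratio, p).  A zero cell yields an infinite/zero OR;
    the p-value is still exact.
    """
    table = np.array([[n_target_pos, n_target_neg], [n_control_pos, n_control_neg]])
    if (table < 0).any():
        raise ValueError("negative cell count")
    res = stats.fisher_exact(table, alternative="two-sided")
    a, b = n_target_pos, n_target_neg
    c, d = n_control_pos, n_control_neg
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return odds, float(res.pvalue)


def haldane_odds_ratio(
    n_target_pos: int, n_target_neg: int, n_control_pos: int, n_control_neg: int
) -> float:
    """Haldane-Anscombe corrected sample odds ratio (0.5 added to each cell);
    auxiliary estimate for degenerate tables."""
    a, b, c, d = (x + 0.5 for x in (n_target_pos, n_target_neg, n_control_pos, n_control_neg))
    return (a * d) / (b * c)


def fit_functional_model(
    records: Sequence[GeneFunctionRecord], outcome: str
) -> ModelFit:
    """Logistic regression: outcome ~ ridl_count + exonic_length +
    exonic_conservation_fraction, with VIF diagnostics.

    ``outcome`` is one of in_functional_db / disease_associated /
    has_exonic_trait_snp.  Complete separation falls back to an
    L2-regularized fit, flagged in the result.
    """
    if outcome not in ("in_functional_db", "disease_associated", "has_exonic_trait_snp"):
        raise ValueError(f"unknown outcome {outcome!r}")
    y = np.array([float(getattr(r, outcome)) for r in records])
    if len(set(y)) < 2:
        raise ValueError("both outcome classes must be present")
    X = pd.DataFrame(
        {
            "ridl_count": [r.ridl_count for r in records],
            "transcript_length": [r.exonic_length for r in records],
            "exonic_conservation": [r.exonic_conservation_fraction for r in records],
        },
        dtype=float,
    )
    Xc = sm.add_constant(X, has_constant="add")
    vifs = {
        col: float(variance_inflation_factor(Xc.to_numpy(), i))
        for i, col in enumerate(Xc.columns)
        if col != "const"
    }
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True))
            if not converged:
                raise PerfectSeparationWarning("logit did not converge")
            return ModelFit(
                terms=list(X.columns),
                coefficients={c: float(fit.params[c]) for c in Xc.columns},
                p_values={c: float(fit.pvalues[c]) for c in Xc.columns},
                vifs=vifs,
                n_obs=int(fit.nobs),
                kind="logit",
            )
        except (PerfectSeparationWarning, PerfectSeparationError, np.linalg.LinAlgError):
            fit = sm.Logit(y, Xc).fit_regularized(alpha=1.0, disp=0, maxiter=500)
            return ModelFit(
                terms=list(X.columns),
                coefficients={c: float(fit.params[c]) for c in Xc.columns},
                p_values={c: float("nan") for c in Xc.columns},
                vifs=vifs,
                n_obs=len(y),
                kind="logit_regularized",
                converged=False,
                flags="separation_fallback",
            )


def daf_spectrum(
    snps: pd.DataFrame,
    n_bins: int = 10,
    rare_cutoff: float = 0.1,
    test_rare: bool = False,
) -> pd.DataFrame:
    """Per-region-class binned DAF proportions and the rare-allele fraction.

    ``snps`` needs columns ``daf`` in [0, 1] and ``region_class``.  Returns a
    row per class with the per-decile proportions (summing to 1), n and the
    fraction with DAF < ``rare_cutoff``; ``test_rare=True`` adds a two-sided
    Fisher p for each class's rare fraction against all other classes pooled.
    """
    if not {"daf", "region_class"} <= set(snps.columns):
        raise ValueError("snps table needs daf and region_class columns")
    if ((snps["daf"] < 0) | (snps["daf"] > 1)).any():
        raise ValueError("DAF outside [0, 1]")
    edges = np.linspace(0, 1, n_bins + 1)
    rows = []
    classes = [c for c in snps["region_class"].unique()]
    for cls in sorted(classes):
        sub = snps[snps["region_class"] == cls]
        if len(sub) == 0:
            warnings.warn(f"region class {cls!r} empty; omitted", stacklevel=2)
            continue
        hist, _ = np.histogram(sub["daf"].clip(upper=1 - 1e-12), bins=edges)
        props = hist / hist.sum()
        rare = float((sub["daf"] < rare_cutoff).mean())
        row = {
            "region_class": cls,
            "n": len(sub),
            "rare_fraction": rare,
            **{f"bin_{i}": float(p) for i, p in enumerate(props)},
        }
        if test_rare:
            rest = snps[snps["region_class"] != cls]
            a = int((sub["daf"] < rare_cutoff).sum())
            b = len(sub) - a
            c = int((rest["daf"] < rare_cutoff).sum())
            d = len(rest) - c
            row["p_rare_vs_rest"] = fisher_enrichment(a, b, c, d)[1]
        rows.append(row)
    return pd.DataFrame(rows)
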