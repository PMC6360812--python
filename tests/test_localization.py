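"""RCI computation, localization screen, dose-response, regression and
partial correlation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ridlmap.localization import (
    compute_rci,
    dose_response,
    fit_localization_model,
    isoform_contrast,
    localization_screen,
    partial_correlation,
    pick_representative_transcript,
)
from ridlmap.selection import adjust_fdr

from conftest import mk_gene


def expr_table(rows):
    out = []
    for tid, gid, cell, n, c, w in rows:
        out += [
            dict(transcript_id=tid, gene_id=gid, cell_line=cell, fraction="nuclear", rpkm=n),
            dict(transcript_id=tid, gene_id=gid, cell_line=cell, fraction="cytoplasmic", rpkm=c),
            dict(transcript_id=tid, gene_id=gid, cell_line=cell, fraction="whole_cell", rpkm=w),
        ]
    return pd.DataFrame(out)


class TestComputeRci:
    def test_log2_ratio(self):
        df = compute_rci(expr_table([("T", "G", "c1", 8.0, 2.0, 5.0)]))
        assert df.iloc[0].rci == pytest.approx(2.0)

    def test_equal_fractions_give_zero(self):
        df = compute_rci(expr_table([("T", "G", "c1", 3.0, 3.0, 3.0)]))
        assert df.iloc[0].rci == pytest.approx(0.0)

    def test_zero_cytoplasmic_excluded(self):
        df = compute_rci(expr_table([
            ("T1", "G", "c1", 8.0, 0.0, 5.0),
            ("T2", "G", "c1", 8.0, 2.0, 5.0),
        ]))
        assert list(df.transcript_id) == ["T2"]

    def test_negative_rpkm_rejected(self):
        with pytest.raises(ValueError):
            compute_rci(expr_table([("T", "G", "c1", -1.0, 2.0, 5.0)]))

    def test_antisymmetric_in_fraction_swap(self, rng):
        n = rng.uniform(0.5, 20, size=10)
        c = rng.uniform(0.5, 20, size=10)
        fwd = compute_rci(expr_table([
            (f"T{i}", "G", "c1", n[i], c[i], 1.0) for i in range(10)
        ]))
        rev = compute_rci(expr_table([
            (f"T{i}", "G", "c1", c[i], n[i], 1.0) for i in range(10)
        ]))
        assert np.allclose(fwd.rci.to_numpy(), -rev.rci.to_numpy())


class TestRepresentativeTranscript:
    def test_most_exons_wins(self):
        from ridlmap.io_formats import GeneModel, GenomicInterval, Transcript

        g = GeneModel("H", "lncRNA", [
            Transcript("H.small", [GenomicInterval("chr1", s, s + 5, "+")
                                   for s in (0, 20, 40)]),
            Transcript("H.big", [GenomicInterval("chr1", s, s + 5, "+")
                                 for s in (100, 110, 120, 130, 140)]),
        ])
        assert pick_representative_transcript(g) == "H.big"

    def test_single_transcript_returns_itself(self):
        g = mk_gene("G", "chr1", "+", [(0, 10)])
        assert pick_representative_transcript(g) == "G.t1"

    def test_tie_broken_lexicographically(self):
        g = mk_gene("G", "chr1", "+", [(0, 10), (20, 30)], n_tx=3)
        assert pick_representative_transcript(g) == "G.t1"


def exact_ranksum_pvalue(a, b):
    """Enumerate all group assignments of the pooled sample (distinct values)
    and compute the exact two-sided Mann-Whitney p."""
    pooled = list(a) + list(b)
    n = len(a)
    ranks = stats.rankdata(pooled)

    def u_stat(idx):
        r = sum(ranks[i] for i in idx)
        return r - n * (n + 1) / 2

    obs = u_stat(range(n))
    m = len(pooled) - n
    mean_u = n * m / 2
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n):
        u = u_stat(comb)
        if abs(u - mean_u) >= abs(obs - mean_u) - 1e-9:
            count += 1
        total += 1
    return count / total


class TestLocalizationScreen:
    def test_fewer_than_three_carriers_not_tested(self):
        locs = compute_rci(expr_table([
            (f"T{i}", f"G{i}", "c1", 2.0 + i, 1.0, 1.0) for i in range(6)
        ]))
        carriers = {"T0": {"X"}, "T1": {"X"}}
        df = localization_screen(carriers, locs)
        assert len(df) == 0

    def test_wilcoxon_matches_exact_enumeration_oracle(self, rng):
        rci_r = [1.2, 2.5, 0.7, 3.1]
        rci_b = [0.1, -0.5, 0.9, -1.2, 0.3]
        rows = [(f"R{i}", f"GR{i}", "c1", 2.0 ** v, 1.0, 1.0) for i, v in enumerate(rci_r)]
        rows += [(f"B{i}", f"GB{i}", "c1", 2.0 ** v, 1.0, 1.0) for i, v in enumerate(rci_b)]
        locs = compute_rci(expr_table(rows))
        carriers = {f"R{i}": {"X"} for i in range(len(rci_r))}
        df = localization_screen(carriers, locs)
        assert len(df) == 1
        expected = exact_ranksum_pvalue(rci_r, rci_b)
        assert df.iloc[0].p_wilcoxon == pytest.approx(expected, rel=1e-6)

    def test_bh_set_contains_bonferroni_set(self, rng):
        p = rng.uniform(0, 0.2, size=40)
        q = adjust_fdr(p)
        alpha = 0.05
        bonf = p <= alpha / p.size
        bh = q <= alpha
        assert set(np.flatnonzero(bonf)) <= set(np.flatnonzero(bh))


class TestDoseResponse:
    def test_monotone_relationship_gives_rho_one(self):
        counts = [0, 1, 2, 3, 4]
        rci = [0.1, 0.5, 1.2, 2.0, 3.3]
        rho, p = dose_response(rci, counts)
        assert rho == pytest.approx(1.0)

    def test_independent_permutation_gives_small_rho(self, rng):
        counts = rng.integers(0, 4, size=500)
        rci = rng.normal(size=500)
        rho, p = dose_response(rci, counts)
        assert abs(rho) < 0.15

    def test_planted_positive_dose_effect_detected(self, rng):
        counts = rng.integers(0, 4, size=500)
        rci = rng.normal(scale=1.0, size=500) + 0.5 * counts
        rho, p = dose_response(rci, counts)
        assert rho > 0
        assert p < 0.01

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            dose_response([1.0, 1.0, 1.0], [1, 1, 1])


class TestLinearModel:
    def simulate(self, rng, n=1000, beta=(0.5, 0.001, 0.02)):
        counts = rng.integers(0, 5, size=n).astype(float)
        lengths = rng.uniform(200, 3000, size=n)
        expr = rng.uniform(1, 50, size=n)
        y = beta[0] * counts + beta[1] * lengths + beta[2] * expr + rng.normal(size=n)
        return y, counts, lengths, expr

    def test_parameter_recovery_within_ci_most_replicates(self, rng):
        beta = (0.5, 0.001, 0.02)
        hits = 0
        n_rep = 20
        for _ in range(n_rep):
            y, counts, lengths, expr = self.simulate(rng, beta=beta)
            fit = fit_localization_model(y, counts, lengths, expr)
            assert fit.kind == "ols" and fit.n_obs == 1000
            ok = True
            # pull the 95% CI from an equivalent statsmodels fit
            import statsmodels.api as sm
            X = sm.add_constant(pd.DataFrame({
                "ridl_count": counts, "transcript_length": lengths, "expression": expr,
            }))
            ci = sm.OLS(y, X).fit().conf_int(alpha=0.05)
            for term, b in zip(("ridl_count", "transcript_length", "expression"), beta):
                lo, hi = ci.loc[term]
                ok &= lo <= b <= hi
            hits += ok
        assert hits >= 15  # each replicate covers all three terms jointly (~86%)

    def test_null_term_has_small_estimate(self, rng):
        y, counts, lengths, expr = self.simulate(rng, beta=(0.0, 0.001, 0.02))
        fit = fit_localization_model(y, counts, lengths, expr)
        assert abs(fit.coefficients["ridl_count"]) < 0.1

    def test_orthogonal_covariates_have_vif_below_1_1(self, rng):
        y, counts, lengths, expr = self.simulate(rng)
        fit = fit_localization_model(y, counts, lengths, expr)
        assert all(v < 1.1 for v in fit.vifs.values())
        assert all(v >= 1.0 for v in fit.vifs.values())

    def test_rank_deficient_design_rejected(self):
        n = 20
        y = np.arange(n, dtype=float)
        const = np.ones(n)
        with pytest.raises(ValueError, match="rank-deficient|collinear"):
            fit_localization_model(y, const, const * 2, np.arange(n, dtype=float))


class TestPartialCorrelation:
    def test_matches_marginal_when_controls_independent(self, rng):
        n = 1000
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        controls = {"len": rng.normal(size=n), "expr": rng.normal(size=n)}
        rho_p, _ = partial_correlation(x, y, controls)
        rho_m = stats.spearmanr(x, y).statistic
        assert abs(rho_p - rho_m) < 0.05

    def test_confound_removed_when_outcome_driven_by_control(self, rng):
        n = 800
        length = rng.normal(size=n)
        counts = length + rng.normal(scale=0.5, size=n)  # correlated with control
        rci = 2.0 * length + rng.normal(scale=0.1, size=n)
        rho_p, p = partial_correlation(counts, rci, {"len": length, "e": rng.normal(size=n)})
        assert abs(rho_p) < 0.1

    def test_agrees_with_pingouin_oracle(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 200
        df = pd.DataFrame({
            "x": rng.normal(size=n),
            "y": rng.normal(size=n),
            "a": rng.normal(size=n),
            "b": rng.normal(size=n),
        })
        df["y"] += 0.4 * df["x"] + 0.3 * df["a"]
        rho_p, p = partial_correlation(
            df["x"], df["y"], {"a": df["a"], "b": df["b"]}
        )
        ref = pingouin.partial_corr(
            data=df, x="x", y="y", covar=["a", "b"], method="spearman"
        )
        assert rho_p == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-3)

    def test_constant_control_rejected(self):
        with pytest.raises(ValueError):
            partial_correlation([1, 2, 3, 4, 5, 6], [2, 3, 4, 5, 6, 7],
                                {"c": [1, 1, 1, 1, 1, 1]})


class TestIsoformContrast:
    def make_genes(self):
        g = mk_gene("G", "chr1", "+", [(0, 100), (200, 300)], n_tx=2)
        h = mk_gene("H", "chr1", "+", [(1000, 1100)], n_tx=2)
        return [g, h]

    def test_delta_is_mean_difference(self):
        genes = self.make_genes()
        locs = compute_rci(expr_table([
            ("G.t1", "G", "c1", 4.0, 1.0, 1.0),   # RCI 2, RIDL isoform
            ("G.t2", "G", "c1", 2.0, 1.0, 1.0),   # RCI 1
        ]))
        df = isoform_contrast(genes, locs, {"G.t1"})
        assert df.iloc[0].n_genes == 1
        assert df.iloc[0].deltas[0] == pytest.approx(1.0)

    def test_gene_with_only_ridl_isoforms_excluded(self):
        genes = self.make_genes()
        locs = compute_rci(expr_table([
            ("G.t1", "G", "c1", 4.0, 1.0, 1.0),
            ("G.t2", "G", "c1", 2.0, 1.0, 1.0),
        ]))
        df = isoform_contrast(genes, locs, {"G.t1", "G.t2"})
        assert len(df) == 0

    def test_null_generator_gives_uniformish_pvalues(self, rng):
        genes = [mk_gene(f"G{i}", "chr1", "+", [(i * 1000, i * 1000 + 100)], n_tx=2)
                 for i in range(40)]
        rows = []
        for i in range(40):
            rows.append((f"G{i}.t1", f"G{i}", "c1", 2.0 ** rng.normal(), 1.0, 1.0))
            rows.append((f"G{i}.t2", f"G{i}", "c1", 2.0 ** rng.normal(), 1.0, 1.0))
        locs = compute_rci(expr_table(rows))
        ridl_tx = {f"G{i}.t1" for i in range(40)}
        ps = []
        for _ in range(10):
            # re-randomize by regenerating RCIs
            rows = [(t, g, c, 2.0 ** rng.normal(), 1.0, 1.0)
                    for (t, g, c, *_rest) in rows]
            locs = compute_rci(expr_table(rows))
            ps.append(isoform_contrast(genes, locs, ridl_tx).iloc[0].p_ttest)
        # under the null, one-sided p should not be systematically tiny
        assert np.median(ps) > 0.1
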