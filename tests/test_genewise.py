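"""Per-gene pipeline: screen, line means, genetics, aggregates, covariates."""

import numpy as np
import pandas as pd
import pytest

from dimorph.genewise import (
    ExpressionDataset,
    LineMeanTable,
    aggregate_correlations,
    dimorphism_and_class,
    expression_covariates,
    line_means,
    per_gene_genetics,
    screen_gene,
    screen_genes,
    tissue_specificity,
    transform_dimorphism,
)
from dimorph.simulate import make_scenario, simulate_panel


def _single_probe_samples(L, R):
    recs = [
        {"line": f"L{li}", "sex": sex, "rep": str(r), "probe": ""}
        for li in range(L)
        for sex in ("M", "F")
        for r in range(1, R + 1)
    ]
    return pd.DataFrame(recs)


def _simulate_gene(rng, L=40, R=2, var_line=0.0, var_ls=0.0, sd_e=0.5, d=0.0):
    samples = _single_probe_samples(L, R)
    a = rng.normal(0, np.sqrt(var_line), L)
    c = rng.normal(0, np.sqrt(var_ls), (L, 2))
    li = samples["line"].str[1:].astype(int).values
    si = (samples["sex"] == "F").astype(int).values
    y = (
        5.0
        + np.where(si == 0, d / 2, -d / 2)
        + a[li]
        + c[li, si]
        + rng.normal(0, sd_e, len(samples))
    )
    return y, samples


class TestScreen:
    def test_single_probe_uses_two_df(self, rng):
        y, samples = _simulate_gene(rng, var_line=0.5)
        _, df_used = screen_gene(y, samples)
        assert df_used == 2

    def test_multi_probe_uses_three_df(self, rng):
        y, samples = _simulate_gene(rng, L=10, var_line=0.5)
        samples2 = pd.concat([samples, samples], ignore_index=True)
        samples2["probe"] = ["p1"] * len(samples) + ["p2"] * len(samples)
        y2 = np.concatenate([y, y + 0.3 + rng.normal(0, 0.5, len(y))])
        _, df_used = screen_gene(y2, samples2)
        assert df_used == 3

    def test_degenerate_design_flagged(self, rng):
        y, samples = _simulate_gene(rng, L=1)
        with pytest.raises(ValueError, match="unscreenable"):
            screen_gene(y, samples)

    def test_planted_variance_detected(self, rng):
        """Line variance 5x residual, 40 lines x 2 reps: essentially
        always significant at the 1% level."""
        hits = 0
        for _ in range(50):
            y, samples = _simulate_gene(rng, var_line=5 * 0.25, sd_e=0.5)
            p, _ = screen_gene(y, samples)
            hits += p < 0.01
        assert hits >= 49

    def test_null_retention_conservative(self, rng):
        """Under zero genetic variance the plain chi-square referral is
        conservative: retention stays at or below the nominal 1%."""
        n = 400
        ps = []
        for _ in range(n):
            y, samples = _simulate_gene(rng, var_line=0.0, var_ls=0.0)
            ps.append(screen_gene(y, samples)[0])
        rate = np.mean(np.array(ps) < 0.01)
        mc_sd = np.sqrt(0.01 * 0.99 / n)
        assert rate <= 0.01 + 3 * mc_sd

    def test_agrees_with_mixedlm_reml(self, rng):
        """The balanced-path variance components match statsmodels
        MixedLM REML on the same model (line + line x sex + residual)."""
        import statsmodels.formula.api as smf

        from dimorph.genewise import _balanced_suffstats

        y, samples = _simulate_gene(rng, L=30, var_line=0.4, var_ls=0.2, d=0.8)
        ssw, dfw, ssu, ssv, L, R = _balanced_suffstats(y, samples)
        sa = (ssu / (L - 1) - ssv / (L - 1)) / 2
        sc = ssv / (L - 1) - (ssw / dfw) / R
        se = ssw / dfw
        assert min(sa, sc) > 0  # interior solution for this draw
        df = pd.DataFrame({"y": y, "line": samples["line"], "sex": samples["sex"]})
        fit = smf.mixedlm(
            "y ~ sex", df, groups="line", re_formula="1",
            vc_formula={"ls": "0 + C(sex)"},
        ).fit(reml=True)
        assert float(fit.cov_re.iloc[0, 0]) == pytest.approx(sa, rel=1e-4)
        assert float(fit.vcomp[0]) == pytest.approx(sc, rel=1e-4)
        assert float(fit.scale) == pytest.approx(se, rel=1e-4)

    def test_fast_and_generic_paths_agree(self, rng):
        """The balanced sufficient-statistic path and the per-line-block
        REML give the same p-value on the same gene."""
        from dimorph.genewise import _generic_screen

        y, samples = _simulate_gene(rng, L=15, var_line=0.3, var_ls=0.1)
        p_fast, _ = screen_gene(y, samples)
        p_gen, _ = _generic_screen(y, samples)
        assert p_gen == pytest.approx(p_fast, rel=1e-3, abs=1e-6)

    def test_screen_genes_table(self, default_panel):
        dataset, _ = default_panel
        sub = ExpressionDataset(
            dataset.gene_ids[:30], dataset.samples, dataset.values[:30]
        )
        out = screen_genes(sub, alpha=0.01)
        assert set(out.columns) == {"lrt_p", "df_used", "retained"}
        assert ((out.lrt_p >= 0) & (out.lrt_p <= 1)).all()
        assert (out.retained == (out.lrt_p < 0.01)).all()


class TestLineMeans:
    def test_balanced_equals_replicate_mean(self):
        samples = _single_probe_samples(2, 2)
        values = np.array([[5.0, 5.2, 1.0, 1.4, 2.0, 2.2, 3.0, 3.2]])
        ds = ExpressionDataset(["g1"], samples, values)
        lm = line_means(ds)
        assert lm.values[0, 0, 0] == pytest.approx(5.1)  # L0 male
        assert lm.values[0, 0, 1] == pytest.approx(1.2)  # L0 female

    def test_constant_gene(self):
        samples = _single_probe_samples(3, 2)
        ds = ExpressionDataset(["g1"], samples, np.full((1, 12), 7.0))
        lm = line_means(ds)
        np.testing.assert_allclose(lm.values, 7.0)

    def test_missing_cell_stays_missing(self):
        samples = _single_probe_samples(2, 2)
        values = np.full((1, 8), 4.0)
        values[0, :2] = np.nan  # L0 male cell entirely missing
        ds = ExpressionDataset(["g1"], samples, values)
        lm = line_means(ds)
        assert np.isnan(lm.values[0, 0, 0])
        assert lm.values[0, 0, 1] == 4.0
        assert not lm.complete_genes()[0]

    def test_multiprobe_ls_mean_matches_normal_equations(self, rng):
        """Probe-adjusted LS means equal the prediction-average solution
        of the full normal equations on an unbalanced probe design."""
        L = 4
        recs = []
        vals = []
        probe_effect = {"p1": 0.0, "p2": 0.9}
        cell = {}
        for li in range(L):
            for sex in ("M", "F"):
                cell[(li, sex)] = rng.normal(5, 1)
                for probe in ("p1", "p2"):
                    n_rep = 2 if probe == "p1" else (1 if li % 2 else 2)
                    for r in range(n_rep):
                        recs.append(
                            {"line": f"L{li}", "sex": sex, "rep": str(r + 1),
                             "probe": probe}
                        )
                        vals.append(
                            cell[(li, sex)] + probe_effect[probe]
                            + (0.4 if (probe == "p2" and sex == "M") else 0.0)
                            + rng.normal(0, 0.05)
                        )
        samples = pd.DataFrame(recs)
        ds = ExpressionDataset(["g1"], samples, np.array([vals]))
        lm = line_means(ds)
        # oracle: full dummy regression, predictions averaged over probes
        X_cols, names = [], []
        for li in range(L):
            for sex in ("M", "F"):
                X_cols.append(((samples["line"] == f"L{li}")
                               & (samples["sex"] == sex)).astype(float).values)
                names.append((li, sex))
        for probe in ("p2",):
            X_cols.append((samples["probe"] == probe).astype(float).values)
            X_cols.append(((samples["probe"] == probe)
                           & (samples["sex"] == "M")).astype(float).values)
        X = np.column_stack(X_cols)
        coef, *_ = np.linalg.lstsq(X, np.array(vals), rcond=None)
        for k, (li, sex) in enumerate(names):
            # average prediction over the two probes at this cell
            pred = []
            for probe in ("p1", "p2"):
                x = np.zeros(X.shape[1])
                x[k] = 1.0
                if probe == "p2":
                    x[-2] = 1.0
                    if sex == "M":
                        x[-1] = 1.0
                pred.append(x @ coef)
            ls_oracle = np.mean(pred)
            si = 0 if sex == "M" else 1
            assert lm.values[0, li, si] == pytest.approx(ls_oracle, abs=1e-8)


class TestDimorphism:
    @pytest.mark.parametrize(
        "d_value, expected", [(1.2, "MB"), (-1.5, "FB"), (1.0, "UB"), (0.0, "UB"),
                              (-1.0, "UB")]
    )
    def test_bias_classes_with_closed_boundary(self, d_value, expected):
        lm = LineMeanTable(
            ["g"], ["L1", "L2"],
            np.array([[[d_value / 2, -d_value / 2], [d_value / 2, -d_value / 2]]]),
        )
        out = dimorphism_and_class(lm)
        assert out.loc["g", "D"] == pytest.approx(d_value)
        assert out.loc["g", "bias_class"] == expected

    def test_classes_partition_genes(self, default_summaries):
        summary, _ = default_summaries
        retained = summary[summary["retained"]]
        counts = retained["bias_class"].value_counts()
        assert counts.sum() == len(retained)
        assert set(counts.index) <= {"MB", "FB", "UB"}

    @pytest.mark.parametrize(
        "d_value, expected",
        [(0.0, -2.0), (0.99, 0.0), (-1.5, 0.17897694729317)],
    )
    def test_transform(self, d_value, expected):
        assert transform_dimorphism(d_value) == pytest.approx(expected, abs=1e-10)


class TestPerGeneGenetics:
    def _lm(self, male, female):
        vals = np.stack([np.asarray(male), np.asarray(female)], axis=-1)[None]
        return LineMeanTable(["g"], [f"L{i}" for i in range(len(male))], vals)

    def test_identical_vectors(self):
        out = per_gene_genetics(self._lm([1, 2, 3], [1, 2, 3]))
        row = out.loc["g"]
        assert row.m == row.f == row.b == 1.0
        assert row.r_mf == 1.0 and row.d == 1.0

    def test_reversed_vectors(self):
        assert per_gene_genetics(self._lm([1, 2, 3], [3, 2, 1])).loc["g", "r_mf"] == -1.0

    def test_hand_moments(self):
        out = per_gene_genetics(self._lm([0, 1, 2, 3], [0, 2, 1, 3])).loc["g"]
        assert out.m == pytest.approx(5 / 3)
        assert out.f == pytest.approx(5 / 3)
        assert out.b == pytest.approx(4 / 3)
        assert out.r_mf == pytest.approx(0.8)

    def test_too_few_lines(self):
        with pytest.raises(ValueError, match="3 lines"):
            per_gene_genetics(self._lm([1, 2], [1, 2]))

    def test_recovers_planted_parameters_at_many_lines(self):
        """Between-line moments of simulated line means converge on the
        planted (m, f, b) as lines grow (10% relative at 400 lines,
        averaged over 200 genes)."""
        rng = np.random.default_rng(42)
        L, G = 400, 200
        m, f, rmf = 0.5, 0.3, 0.6
        b = rmf * np.sqrt(m * f)
        am = rng.normal(0, np.sqrt(m), (G, L))
        af = (b / m) * am + rng.normal(0, np.sqrt(f - b**2 / m), (G, L))
        lm = LineMeanTable(
            [f"g{i}" for i in range(G)], [f"L{i}" for i in range(L)],
            np.stack([am, af], axis=-1),
        )
        out = per_gene_genetics(lm)
        assert abs(out.m.mean() - m) / m < 0.1
        assert abs(out.f.mean() - f) / f < 0.1
        assert abs(out.b.mean() - b) / b < 0.1


class TestAggregateCorrelations:
    def _brute_force(self, male, female):
        """O(n^2) double loop directly over the definitions."""
        n, L = male.shape
        cm = np.corrcoef(male)
        cf = np.corrcoef(female)
        cb = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                cb[i, j] = np.corrcoef(male[i], female[j])[0, 1]
        out = np.zeros((n, 4))
        for i in range(n):
            sw = sum(cm[i, j] + cf[i, j] for j in range(n) if j != i)
            sb = sum(cb[i, j] + cb[j, i] for j in range(n) if j != i)
            sdw = sum(cm[i, j] - cf[i, j] for j in range(n) if j != i)
            sdb = sum(cb[i, j] - cb[j, i] for j in range(n) if j != i)
            k = 2 * (n - 1)
            out[i] = [sw / k, sb / k, abs(sdw / k), abs(sdb / k)]
        return out

    def test_matches_brute_force_on_50_genes(self, rng):
        n, L = 50, 12
        male = rng.standard_normal((n, L))
        female = 0.5 * male + rng.standard_normal((n, L))
        lm = LineMeanTable(
            [f"g{i}" for i in range(n)], [f"L{i}" for i in range(L)],
            np.stack([male, female], axis=-1),
        )
        fast = aggregate_correlations(lm).to_numpy()
        brute = self._brute_force(male, female)
        np.testing.assert_allclose(fast, brute, atol=1e-10)

    def test_two_gene_hand_case(self, rng):
        # construct two genes; verify against the direct definition
        male = rng.standard_normal((2, 30))
        female = rng.standard_normal((2, 30))
        lm = LineMeanTable(
            ["g1", "g2"], [f"L{i}" for i in range(30)],
            np.stack([male, female], axis=-1),
        )
        out = aggregate_correlations(lm)
        r_mm = np.corrcoef(male[0], male[1])[0, 1]
        r_ff = np.corrcoef(female[0], female[1])[0, 1]
        assert out.loc["g1", "rw_bar"] == pytest.approx((r_mm + r_ff) / 2)

    def test_symmetric_cross_structure_zeroes_rdb(self, rng):
        """When the male and female line-mean matrices are identical the
        cross-sex correlation structure is symmetric, so |r_db| = 0."""
        male = rng.standard_normal((5, 20))
        lm = LineMeanTable(
            [f"g{i}" for i in range(5)], [f"L{i}" for i in range(20)],
            np.stack([male, male], axis=-1),
        )
        out = aggregate_correlations(lm)
        np.testing.assert_allclose(out["abs_rdb"], 0.0, atol=1e-12)
        np.testing.assert_allclose(out["abs_rdw"], 0.0, atol=1e-12)

    def test_zero_variance_gene_excluded(self, rng):
        male = rng.standard_normal((3, 10))
        female = rng.standard_normal((3, 10))
        male[2] = 1.0  # no variance in males
        lm = LineMeanTable(
            ["g1", "g2", "g3"], [f"L{i}" for i in range(10)],
            np.stack([male, female], axis=-1),
        )
        out = aggregate_correlations(lm)
        assert out.loc["g3"].isna().all()
        # remaining pair computed over n = 2
        r_mm = np.corrcoef(male[0], male[1])[0, 1]
        r_ff = np.corrcoef(female[0], female[1])[0, 1]
        assert out.loc["g1", "rw_bar"] == pytest.approx((r_mm + r_ff) / 2)


class TestExpressionCovariates:
    @pytest.mark.parametrize(
        "vec, expected", [((4, 4, 4), 0.0), ((4, 0, 0), 1.0), ((4, 2, 0), 0.75)]
    )
    def test_tau_examples(self, vec, expected):
        table = pd.DataFrame({"g1": vec}, index=["t1", "t2", "t3"])
        assert tissue_specificity(table)["g1"] == pytest.approx(expected)

    def test_tau_all_zero_missing(self):
        table = pd.DataFrame({"g1": [0.0, 0.0]}, index=["t1", "t2"])
        assert np.isnan(tissue_specificity(table)["g1"])

    def test_tau_negative_values_shifted(self):
        # log-scale input: shifting by the minimum makes values nonnegative
        table = pd.DataFrame({"g1": [-2.0, 0.0, 2.0]}, index=["t1", "t2", "t3"])
        tau = tissue_specificity(table)["g1"]
        assert tau == pytest.approx((1.0 + 0.5 + 0.0) / 2)

    def test_tau_transcripts_averaged(self):
        table = pd.DataFrame(
            {"tr1": [4, 0, 0], "tr2": [4, 4, 4]}, index=["t1", "t2", "t3"]
        )
        tau = tissue_specificity(table, gene_map={"tr1": "g", "tr2": "g"})
        assert tau["g"] == pytest.approx(0.5)

    def test_single_tissue_rejected(self):
        with pytest.raises(ValueError, match="tissues"):
            tissue_specificity(pd.DataFrame({"g1": [1.0]}, index=["t1"]))

    def test_e_bar_is_grand_mean(self):
        samples = _single_probe_samples(2, 2)
        values = np.arange(8, dtype=float)[None]
        ds = ExpressionDataset(["g1"], samples, values)
        out = expression_covariates(ds)
        assert out.loc["g1", "E_bar"] == pytest.approx(3.5)
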