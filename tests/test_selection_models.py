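"""Nested linear models, the B regression, and the BGS adjustment."""

import numpy as np
import pandas as pd
import pytest

import _oracles as oracle
from ampbalance import (
    ControlPolicy,
    assign_regions,
    fit_bgs_anova,
    fit_nested_anova,
    regress_on_b,
    resample_residuals,
)
from ampbalance.selection_models import gene_window_means
from conftest import make_gene_table


def model_toy(seed=0, n=300, effect=0.0, amp_every=4, spacing=10_000):
    """Genes over three arms, AMPs interleaved, optional injected AMP
    shift on Tajima's D (in residual-sd units)."""
    rng = np.random.default_rng(seed)
    chroms = ["2L", "2R", "3R"]
    rows = [
        (f"g{i}", chroms[i % 3], spacing * (i // 3) + 1_000, 300 + 3 * (i % 50),
         "AMP" if i % amp_every == 0 else "background", 0.0)
        for i in range(n)
    ]
    df = make_gene_table(rows)
    df["tajimas_d"] = rng.normal(0, 1, n) + effect * (df["category"] == "AMP")
    return df


class TestAssignRegions:
    def test_tiled_floor_arithmetic(self):
        df = make_gene_table([
            ("a", "2L", 150_000, 300, "background", 0.0),
            ("b", "2L", 250_000, 300, "background", 0.0),
        ])
        assert list(assign_regions(df, "tiled", width=200_000)) == ["2L:0", "2L:1"]

    def test_same_coordinate_different_chromosome(self):
        df = make_gene_table([
            ("a", "2L", 150_000, 300, "background", 0.0),
            ("b", "2R", 150_000, 300, "background", 0.0),
        ])
        labels = assign_regions(df, "tiled")
        assert labels[0] != labels[1]

    def test_amp_neighborhood_matches_candidate_rule(self):
        """Neighbourhood membership = the control candidate set + the AMP."""
        df = make_gene_table([
            ("focal", "2L", 50_000, 300, "AMP", 1.0),
            ("near_small", "2L", 30_000, 600, "background", 0.0),
            ("window_edge", "2L", 120_000, 300, "background", 0.2),
            ("near_large9", "2L", 140_000, 900, "background", 0.1),
            ("too_big", "2L", 60_000, 3_300, "background", 0.3),
            ("other_chrom", "2R", 50_000, 300, "background", 0.4),
        ])
        labels = assign_regions(df, "amp_neighborhood")
        members = set(df.loc[labels.notna(), "gene_id"])
        assert members == {"focal", "near_small", "window_edge", "near_large9"}


class TestRegressOnB:
    def windows(self, b, y):
        return pd.DataFrame({
            "chromosome": "2L",
            "start": np.arange(len(b)) * 1_000,
            "end": np.arange(1, len(b) + 1) * 1_000,
            "B": b, "silent_polymorphism": y,
        })

    def test_exact_linearity_zero_residuals(self):
        fit = regress_on_b(self.windows([0.2, 0.5, 0.8, 1.0],
                                        [0.02, 0.05, 0.08, 0.10]))
        assert np.all(np.abs(fit.residuals) < 1e-10)

    def test_three_point_closed_form(self):
        """{(0,0),(1,1),(2,2.3)}: slope 1.15, intercept -0.05."""
        fit = regress_on_b(self.windows([0, 1, 2], [0, 1, 2.3]))
        assert fit.slope == pytest.approx(1.15, abs=1e-10)
        assert fit.intercept == pytest.approx(-0.05, abs=1e-10)
        assert fit.residuals.to_numpy() == pytest.approx([0.05, -0.10, 0.05], abs=1e-10)

    def test_residuals_sum_to_zero(self, rng):
        fit = regress_on_b(self.windows(rng.uniform(0.2, 1, 50),
                                        rng.normal(0.05, 0.01, 50)))
        assert fit.residuals.sum() == pytest.approx(0.0, abs=1e-10)

    def test_constant_b_degenerate(self):
        with pytest.raises(ValueError, match="constant"):
            regress_on_b(self.windows([0.5, 0.5, 0.5], [1, 2, 3]))

    def test_slope_recovers_simulator_truth(self):
        """On a noise-only landscape the fitted slope matches the generating
        slope within 3 se."""
        from ampbalance import SimulationConfig, simulate_b_landscape
        from ampbalance.silent_sites import GeneRecord

        layout = [GeneRecord("g0", "2L", 0, 300, "+", 300)]
        w = simulate_b_landscape(
            layout, {"2L": 500_000}, slope=0.02, noise_sd=0.002, seed_or_rng=5,
        )
        fit = regress_on_b(w)
        resid_sd = fit.residuals.std(ddof=2)
        b = w["B"].to_numpy()
        se = resid_sd / np.sqrt(((b - b.mean()) ** 2).sum())
        assert fit.slope == pytest.approx(0.02, abs=3 * se)


class TestNestedAnova:
    def test_constant_response_all_f_zero(self):
        df = model_toy(n=120)
        df["tajimas_d"] = 1.0
        a = fit_nested_anova(df, "tajimas_d")
        assert np.all(a.terms["F"].to_numpy() < 1e-20)

    def test_matches_independent_lstsq_oracle(self):
        """F and df for every term match an independent normal-equations
        solve (Type II comparisons built by hand) on a fixed 50-gene toy."""
        df = model_toy(seed=3, n=50, spacing=30_000)
        region = assign_regions(df, "tiled")
        a = fit_nested_anova(df, "tajimas_d")

        y = df["tajimas_d"].to_numpy()
        chrom_d = pd.get_dummies(df["chromosome"], drop_first=True).to_numpy(float)
        length = df[["cds_length"]].to_numpy(float)
        region_d = pd.get_dummies(region, drop_first=False).to_numpy(float)
        is_amp = (df["category"] == "AMP").to_numpy(float)
        amp_d = np.column_stack([
            is_amp * (region == r).to_numpy(float)
            for r in sorted(region.unique())
            if (is_amp * (region == r).to_numpy(float)).any()
        ])

        def stack(*parts):
            parts = [p for p in parts if p.size]
            return np.column_stack(parts) if parts else None

        cases = {
            "gene_length": (stack(chrom_d, region_d, amp_d),
                            stack(chrom_d, region_d, amp_d, length)),
            "chromosome": (stack(length), stack(length, chrom_d)),
            "region": (stack(chrom_d, length), stack(chrom_d, length, region_d)),
            "AMP": (stack(chrom_d, length, region_d),
                    stack(chrom_d, length, region_d, amp_d)),
        }
        # oracle F uses the reduced/with-term RSS difference over the
        # full-model mean square, as the implementation defines Type II
        x_full = stack(chrom_d, length, region_d, amp_d)
        y_arr = np.asarray(y, float)
        xf = np.column_stack([np.ones(len(y_arr)), x_full])
        beta, *_ = np.linalg.lstsq(xf, y_arr, rcond=None)
        rss_full = float(((y_arr - xf @ beta) ** 2).sum())
        df_resid = len(y_arr) - np.linalg.matrix_rank(xf)
        mse = rss_full / df_resid
        def rss_of(x):
            xx = np.column_stack([np.ones(len(y_arr))] + ([x] if x is not None else []))
            bb, *_ = np.linalg.lstsq(xx, y_arr, rcond=None)
            return float(((y_arr - xx @ bb) ** 2).sum())

        for term, (xr, xw) in cases.items():
            _, df_num, _ = oracle.ols_f_test(y, xr, xw)
            got = a.term(term)
            # Type II: (RSS_reduced - RSS_with_term)/df over the full-model MSE
            f_expected = (rss_of(xr) - rss_of(xw)) / df_num / mse
            assert got["df"] == df_num
            assert got["F"] == pytest.approx(f_expected, abs=1e-6)
            assert int(got["df_resid"]) == df_resid

    def test_injected_amp_effect_detected(self):
        """A 1-sd AMP shift is flagged (P < 0.01) in >= 95 of 100 runs."""
        hits = sum(
            float(fit_nested_anova(model_toy(seed=s, effect=1.0),
                                   "tajimas_d").term("AMP")["P"]) < 0.01
            for s in range(100)
        )
        assert hits >= 95

    def test_null_false_positive_rate(self):
        """With no effect, P < 0.01 is rare."""
        hits = sum(
            float(fit_nested_anova(model_toy(seed=s), "tajimas_d").term("AMP")["P"]) < 0.01
            for s in range(50)
        )
        assert hits <= 4

    def test_region_permutation_leaves_chromosome_f(self):
        """Permuting region labels within a chromosome leaves the
        chromosome main-effect F unchanged (Type II: chromosome is only
        adjusted for gene length)."""
        df = model_toy(seed=5, n=90)
        f1 = float(fit_nested_anova(df, "tajimas_d").term("chromosome")["F"])
        # shift every gene one tile within its arm: region labels permute
        df2 = df.copy()
        df2["midpoint"] = df2["midpoint"] + 200_000
        f2 = float(fit_nested_anova(df2, "tajimas_d").term("chromosome")["F"])
        assert f1 == pytest.approx(f2, rel=1e-9)


def landscape_toy(seed=0, boost=0.004, noise_sd=0.0005, depression=0.3):
    """Gene table + B windows where AMP windows have low B and extra
    polymorphism, mirroring linked purifying selection plus balancing."""
    from ampbalance import simulate_b_landscape
    from ampbalance.silent_sites import GeneRecord

    rng = np.random.default_rng(seed)
    chroms = ["2L", "2R", "3R"]
    records, rows = [], []
    for i in range(120):
        chrom = chroms[i % 3]
        start = 12_000 * (i // 3) + 2_000
        cat = "AMP" if i % 6 == 0 else "background"
        records.append(GeneRecord(f"g{i}", chrom, start, start + 3_000, "+", 300, cat))
        rows.append((f"g{i}", chrom, start + 1_500, 300, cat, 0.0))
    table = make_gene_table(rows)
    balanced = {r.gene_id for r in records if r.category == "AMP"}
    windows = simulate_b_landscape(
        records, {c: 500_000 for c in chroms},
        slope=0.02, noise_sd=noise_sd, seed_or_rng=seed + 1,
        balanced_ids=balanced, boost=boost, b_depression=depression,
    )
    table["pi"] = gene_window_means(table, windows, "silent_polymorphism")
    return table, windows


class TestBgsAnalysis:
    def test_gene_window_mean_rule(self):
        """A gene spanning windows with residuals {+0.2, -0.1} scores +0.05."""
        genes = make_gene_table([("g", "2L", 1_000, 300, "AMP", 0.0)])
        genes.loc[0, ["start", "end"]] = [500, 1_500]
        w = pd.DataFrame({
            "chromosome": ["2L", "2L"], "start": [0, 1_000], "end": [1_000, 2_000],
            "resid": [0.2, -0.1],
        })
        assert gene_window_means(genes, w, "resid")[0] == pytest.approx(0.05)

    def test_zero_residuals_give_zero_deltas(self):
        table, windows = landscape_toy(boost=0.0, noise_sd=0.0, depression=0.0)
        fit = regress_on_b(windows)
        dist, summ = resample_residuals(
            fit, table, windows, "AMP",
            ControlPolicy(n_replicates=200, seed=1, window_bp=200_000),
        )
        assert np.all(np.abs(dist.deltas) < 1e-10)

    def test_boosted_amp_windows_detected_by_resampling(self):
        table, windows = landscape_toy(seed=2)
        fit = regress_on_b(windows)
        dist, summ = resample_residuals(
            fit, table, windows, "AMP",
            ControlPolicy(n_replicates=2_000, seed=3, window_bp=200_000),
        )
        assert summ.pct_positive >= 95

    def test_m1_explains_everything_amp_f_small(self):
        """Polymorphism exactly linear in B with no boost: the AMP term
        explains nothing once M1 is in the model."""
        table, windows = landscape_toy(boost=0.0, noise_sd=0.0, depression=0.0)
        a = fit_bgs_anova(table, windows, statistic="pi")
        assert float(a.term("AMP")["F"]) < 1e-6

    def test_adjustment_raises_amp_f(self):
        """With AMP windows at low B plus a boost, adjusting for M1 gives a
        larger AMP F than the unadjusted model."""
        table, windows = landscape_toy(seed=4)
        adj = fit_bgs_anova(table, windows, statistic="pi")
        unadj = fit_bgs_anova(table, windows, statistic="pi", include_m1=False)
        assert float(adj.term("AMP")["F"]) > float(unadj.term("AMP")["F"])

    def test_injected_boost_detected_in_bgs_model(self):
        hits = 0
        for s in range(20):
            table, windows = landscape_toy(seed=100 + s)
            a = fit_bgs_anova(table, windows, statistic="pi")
            hits += float(a.term("AMP")["P"]) < 0.01
        assert hits >= 19
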