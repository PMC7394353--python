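"""Regulatory classification, TE statistics, permutation and interval tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ribointerplay.config import PipelineConfig
from ribointerplay.differential import DifferentialResult
from ribointerplay.interplay import (
    classify_regulation,
    compute_te,
    log2fc_to_fold,
    mann_whitney_u,
    permutation_abundance_test,
    prediction_interval_outliers,
    regress_te_on_abundance,
    te_deviation_by_group,
)
from ribointerplay.synthetic import make_design


def _result(rows, assay="rna"):
    df = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))])
    df["se"] = 0.1
    df["mean_expression"] = 100.0
    return DifferentialResult(df, assay=assay)


class TestClassification:
    @pytest.mark.parametrize("m_lfc,m_p,r_lfc,r_p,expected", [
        (2.0, 1e-3, 1.8, 1e-3, "TC+"),
        (-2.0, 1e-3, -1.8, 1e-3, "TC-"),
        (1.5, 0.01, 0.2, 0.9, "COMP-"),
        (-1.5, 0.01, 0.2, 0.9, "COMP+"),
        (0.3, 0.9, 1.7, 0.01, "TL+"),
        (0.3, 0.9, -1.7, 0.01, "TL-"),
        (0.5, 0.9, 0.2, 0.8, "NR"),
        (2.0, 1e-3, -1.8, 1e-3, "DISCORDANT"),
        (2.0, np.nan, 1.8, 1e-3, "NOT_ASSESSED"),
        (1.5, 0.2, 1.5, 0.2, "NR"),       # large FC but not significant
        (0.9, 1e-5, 0.9, 1e-5, "NR"),     # significant p but FC below threshold
    ])
    def test_rule_instantiation(self, m_lfc, m_p, r_lfc, r_p, expected):
        mrna = _result([{"log2fc": m_lfc, "pvalue": m_p, "padj": m_p}])
        ribo = _result([{"log2fc": r_lfc, "pvalue": r_p, "padj": r_p}], "ribo")
        table = classify_regulation(mrna, ribo)
        assert table["class"].iloc[0] == expected

    def test_totality_partition(self, rng):
        n = 500
        mk = lambda: pd.DataFrame({
            "log2fc": rng.normal(0, 2, n),
            "pvalue": rng.uniform(size=n),
            "padj": np.where(rng.uniform(size=n) < 0.1, np.nan, rng.uniform(size=n)),
            "se": 0.1, "mean_expression": 50.0,
        }, index=[f"g{i}" for i in range(n)])
        table = classify_regulation(DifferentialResult(mk()),
                                    DifferentialResult(mk(), "ribo"))
        counts = table["class"].value_counts()
        assert counts.sum() == n  # every gene gets exactly one label

    def test_mismatched_universe(self):
        mrna = _result([{"log2fc": 0, "pvalue": 1, "padj": 1}])
        ribo = _result([{"log2fc": 0, "pvalue": 1, "padj": 1}] * 2, "ribo")
        with pytest.raises(ValueError, match="universe"):
            classify_regulation(mrna, ribo)


def _abundance(df, design_cols, genes):
    cols = {c: df[:, j] for j, c in enumerate(design_cols)}
    from ribointerplay.datamodel import AbundanceMatrix
    return AbundanceMatrix(pd.DataFrame(cols, index=genes), tpm_normalized=False)


class TestTE:
    def _te(self, rna_vals, ribo_vals):
        design = make_design(n_reps=1)
        genes = [f"g{i}" for i in range(len(rna_vals))]
        rna = _abundance(np.array(rna_vals)[:, None] * np.ones((1, 4)),
                         design.table.loc[design.table.assay == "rna", "sample_id"],
                         genes)
        ribo = _abundance(np.array(ribo_vals)[:, None] * np.ones((1, 4)),
                          design.table.loc[design.table.assay == "ribo", "sample_id"],
                          genes)
        return compute_te(rna, ribo, design, "TP1")

    def test_equal_abundances_zero_te(self):
        te = self._te([50.0], [50.0])
        assert te["te"].iloc[0] == 0.0

    def test_exact_log_ratio(self):
        te = self._te([100.0], [25.0])
        assert te["te"].iloc[0] == -2.0

    def test_zero_footprints_na(self):
        te = self._te([10.0, 50.0, 40.0], [0.0, 50.0, 40.0])
        assert np.isnan(te["te"].iloc[0])
        fit = regress_te_on_abundance(
            pd.concat([te, te.assign(te=te.te + 0.5, tpm_rna=te.tpm_rna * 2)]))
        assert fit.n == 4  # NA genes excluded from the regression


class TestRegression:
    def test_noiseless_line_recovered(self, rng):
        x = rng.uniform(0, 4, 50)
        tpm = 10.0 ** x - 1.0
        te = pd.DataFrame({"te": 1.0 - 1.10 * x, "tpm_rna": tpm, "tpm_ribo": 1.0,
                           "time_point": "TP1"}, index=[f"g{i}" for i in range(50)])
        fit = regress_te_on_abundance(te)
        assert fit.slope == pytest.approx(-1.10, abs=1e-9)
        assert fit.r == pytest.approx(-1.0, abs=1e-9)

    def test_constant_te_zero_slope(self, rng):
        te = pd.DataFrame({"te": 2.0, "tpm_rna": rng.uniform(10, 1000, 30),
                           "tpm_ribo": 1.0, "time_point": "TP1"},
                          index=[f"g{i}" for i in range(30)])
        assert regress_te_on_abundance(te).slope == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_x_rejected(self):
        te = pd.DataFrame({"te": [1.0, 2.0, 3.0], "tpm_rna": 100.0,
                           "tpm_ribo": 1.0, "time_point": "TP1"},
                          index=list("abc"))
        with pytest.raises(ValueError, match="degenerate"):
            regress_te_on_abundance(te)

    def test_residuals_and_r2_consistent(self, rng):
        x = rng.uniform(0, 4, 200)
        te = pd.DataFrame({"te": 1.0 - 1.1 * x + rng.normal(0, 0.8, 200),
                           "tpm_rna": 10.0 ** x - 1.0, "tpm_ribo": 1.0,
                           "time_point": "TP1"}, index=[f"g{i}" for i in range(200)])
        fit = regress_te_on_abundance(te)
        assert abs(fit.residuals.mean()) < 1e-10
        ss_res = float((fit.residuals ** 2).sum())
        ss_tot = float(((te["te"] - te["te"].mean()) ** 2).sum())
        assert fit.r ** 2 == pytest.approx(1.0 - ss_res / ss_tot, abs=1e-10)

    def test_intercept_shift_leaves_slope_and_residuals(self, rng):
        x = rng.uniform(0, 4, 100)
        base = pd.DataFrame({"te": -1.1 * x + rng.normal(0, 0.5, 100),
                             "tpm_rna": 10.0 ** x - 1.0, "tpm_ribo": 1.0,
                             "time_point": "TP1"}, index=[f"g{i}" for i in range(100)])
        f1 = regress_te_on_abundance(base)
        f2 = regress_te_on_abundance(base.assign(te=base.te + 5.0))
        assert f2.slope == pytest.approx(f1.slope, abs=1e-10)
        assert np.allclose(f1.residuals, f2.residuals, atol=1e-10)


def _brute_force_mw(x, y):
    """Exhaustive two-sided Mann-Whitney over all group relabelings."""
    nx = len(x)
    pooled = np.concatenate([x, y])
    u_obs = sum(1 for a in x for b in y if a > b) + 0.5 * sum(
        1 for a in x for b in y if a == b)
    mean_u = nx * len(y) / 2.0
    stat = abs(u_obs - mean_u)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), nx):
        xs = pooled[list(comb)]
        ys = np.delete(pooled, list(comb))
        u = sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b)
        total += 1
        if abs(u - mean_u) >= stat - 1e-12:
            count += 1
    return u_obs, count / total


class TestMannWhitney:
    def test_separated_triples_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_p_near_one(self, rng):
        x = rng.normal(size=30)
        _, p = mann_whitney_u(x, x.copy())
        assert p > 0.99

    def test_extreme_separation(self, rng):
        x = rng.normal(1.0, 0.1, 50)
        y = rng.normal(0.0, 0.1, 50)
        _, p = mann_whitney_u(x, y)
        assert p < 1e-10

    def test_agrees_with_enumeration_small_samples(self, rng):
        """All untied two-group inputs with n1+n2 <= 8 match brute force."""
        for n1, n2 in [(2, 2), (2, 3), (3, 3), (3, 4), (4, 4), (2, 6)]:
            for _ in range(5):
                vals = rng.permutation(np.arange(1.0, n1 + n2 + 1.0))
                x, y = vals[:n1], vals[n1:]
                _, p = mann_whitney_u(x, y)
                _, p_brute = _brute_force_mw(x, y)
                assert p == pytest.approx(p_brute, abs=1e-12), (x, y)


class TestPermutation:
    def test_whole_universe_p_one(self, rng):
        abund = pd.Series(rng.uniform(1, 100, 50), index=[f"g{i}" for i in range(50)])
        res = permutation_abundance_test(list(abund.index), abund, n_perm=99, seed=1)
        assert res["pvalue"] == 1.0

    def test_set_larger_than_universe_rejected(self, rng):
        abund = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            permutation_abundance_test(["a", "b", "c"], abund, n_perm=9, seed=0)

    def test_lower_upper_tails_mirror(self, rng):
        abund = pd.Series(rng.lognormal(3, 1, 400),
                          index=[f"g{i}" for i in range(400)])
        gene_set = list(abund.nsmallest(10).index)
        lo = permutation_abundance_test(gene_set, abund, n_perm=999, seed=5,
                                        tail="lower")
        hi = permutation_abundance_test(gene_set, abund, n_perm=999, seed=5,
                                        tail="upper")
        assert lo["pvalue"] < 0.05 < hi["pvalue"]

    def test_seed_reproducibility(self, rng):
        abund = pd.Series(rng.uniform(1, 100, 200),
                          index=[f"g{i}" for i in range(200)])
        s = [f"g{i}" for i in range(8)]
        a = permutation_abundance_test(s, abund, n_perm=500, seed=42)
        b = permutation_abundance_test(s, abund, n_perm=500, seed=42)
        assert a == b


class TestPredictionInterval:
    def test_constructed_outlier_flagged(self, rng):
        x = pd.Series(rng.uniform(-3, 3, 40), index=[f"g{i}" for i in range(40)])
        y = 0.7 * x + pd.Series(rng.normal(0, 0.1, 40), index=x.index)
        y.loc["g7"] += 10 * 0.1 * 10
        fit = prediction_interval_outliers(x, y)
        assert list(fit.outliers) == ["g7"]

    def test_collinear_points_no_flags(self):
        x = pd.Series([0.0, 1.0, 2.0], index=list("abc"))
        fit = prediction_interval_outliers(x, 2 * x + 1)
        assert len(fit.outliers) == 0

    def test_flag_rate_near_five_percent(self, rng):
        rates = []
        for _ in range(40):
            x = pd.Series(rng.uniform(-2, 2, 58))
            y = 0.7 * x + rng.normal(0, 0.3, 58)
            rates.append(len(prediction_interval_outliers(x, y).outliers) / 58)
        assert 0.01 <= float(np.mean(rates)) <= 0.09


class TestFoldConversion:
    @pytest.mark.parametrize("lfc,fold,direction", [
        (-4.70, 26, "down"), (-2.78, 7, "down"), (0.0, 1, "none"), (1.0, 2, "up"),
    ])
    def test_examples(self, lfc, fold, direction):
        f, d = log2fc_to_fold(lfc)
        assert round(f) == fold and d == direction

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            log2fc_to_fold(np.inf)


class TestDeviationByGroup:
    def test_bins_and_untestable_groups(self, rng):
        n = 300
        x = rng.uniform(1.1, 4, n)  # TPM 10..10^4
        genes = [f"g{i}" for i in range(n)]
        te = pd.DataFrame({"te": -1.1 * x + rng.normal(0, 0.5, n),
                           "tpm_rna": 10.0 ** x - 1.0, "tpm_ribo": 1.0,
                           "time_point": "TP4"}, index=genes)
        fit = regress_te_on_abundance(te)
        lfc = rng.choice([2.0, -2.0, 0.0], size=n, p=[0.3, 0.3, 0.4])
        classes = pd.DataFrame({
            "class": "NR", "mrna_lfc": lfc,
            "mrna_padj": np.where(lfc == 0, 0.9, 0.001),
            "ribo_lfc": 0.0, "ribo_padj": 0.9}, index=genes)
        table = te_deviation_by_group(fit, classes, PipelineConfig())
        assert set(table["bin"]) == {"low", "medium", "high"}
        assert (table["pvalue"].dropna() <= 1).all()
        tested = table[table["n_a"] >= 3]
        assert len(tested) > 0

    def test_shifted_up_group_detected(self, rng):
        n = 200
        x = rng.uniform(2.01, 3.0, n)  # all in the "medium" bin
        genes = [f"g{i}" for i in range(n)]
        up = np.arange(n) < 60
        down = (np.arange(n) >= 60) & (np.arange(n) < 120)
        resid_shift = np.where(up, 1.0, 0.0)
        te = pd.DataFrame({"te": -1.1 * x + resid_shift + rng.normal(0, 0.2, n),
                           "tpm_rna": 10.0 ** x - 1.0, "tpm_ribo": 1.0,
                           "time_point": "TP4"}, index=genes)
        fit = regress_te_on_abundance(te)
        classes = pd.DataFrame({
            "class": "NR",
            "mrna_lfc": np.where(up, 2.0, np.where(down, -2.0, 0.0)),
            "mrna_padj": np.where(up | down, 1e-4, 0.9),
            "ribo_lfc": 0.0, "ribo_padj": 0.9}, index=genes)
        table = te_deviation_by_group(fit, classes, PipelineConfig())
        row = table[(table["bin"] == "medium") & (table["group_a"] == "up")
                    & (table["group_b"] == "down")].iloc[0]
        assert row["pvalue"] < 1e-6 and row["significance"] == "**"
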