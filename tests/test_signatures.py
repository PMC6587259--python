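"""Differential expression, APPM signature, ssGSEA and survival link."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from neoprior import signatures, stats, synthetic
from neoprior.errors import DesignError, ParameterError, SignatureError


def null_matrix(n_genes=300, n_samples=10, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=[f"G{i:04d}" for i in range(n_genes)],
        columns=[f"S{i:02d}" for i in range(n_samples)],
    )


def groups_for(matrix, n1=None):
    n1 = n1 or matrix.shape[1] // 2
    return pd.Series(
        ["a"] * n1 + ["b"] * (matrix.shape[1] - n1), index=matrix.columns)


class TestDifferentialExpression:
    def test_null_p_values_uniform(self):
        m = null_matrix(2000, 10, seed=1)
        deg = signatures.differential_expression(m, groups_for(m),
                                                 method="welch")
        ks = sps.kstest(deg["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_effect_recovered(self):
        """>=80% of genes shifted by 2 sd recovered at p<0.05 (n=5 vs 5)."""
        m = null_matrix(500, 10, seed=2)
        planted = m.index[:50]
        m.loc[planted, m.columns[:5]] += 2.0
        for method in ("welch", "moderated"):
            deg = signatures.differential_expression(m, groups_for(m), method)
            recovered = (deg.loc[planted, "p"] < 0.05).mean()
            assert recovered >= 0.80, method

    def test_single_gene_welch_reduces_to_kernel(self):
        m = null_matrix(1, 12, seed=3)
        deg = signatures.differential_expression(m, groups_for(m), "welch")
        x = m.iloc[0, :6].to_numpy()
        y = m.iloc[0, 6:].to_numpy()
        t, _, p = stats.welch_t(x, y)
        assert deg["statistic"].iloc[0] == pytest.approx(t, rel=1e-10)
        assert deg["p"].iloc[0] == pytest.approx(p, rel=1e-10)

    def test_moderated_shrinks_toward_prior(self):
        m = null_matrix(400, 10, seed=4)
        welch = signatures.differential_expression(m, groups_for(m), "welch")
        mod = signatures.differential_expression(m, groups_for(m), "moderated")
        # shrinkage narrows the spread of the statistic under the null
        assert mod["statistic"].std() < welch["statistic"].std() * 1.05

    def test_small_group_rejected(self):
        m = null_matrix(10, 4)
        groups = pd.Series(["a", "a", "a", "b"], index=m.columns)
        with pytest.raises(DesignError):
            signatures.differential_expression(m, groups)


class TestSignatureDerivation:
    def test_intersection(self):
        deg = pd.DataFrame({"p": [0.01, 0.02, 0.03, 0.5]},
                           index=["A", "B", "C", "D"])
        sets = [signatures.GeneSet("appm1", "", ("B", "C", "D", "E"))]
        assert signatures.derive_appm_signature(deg, sets) == ["B", "C"]

    def test_disjoint_sets_empty(self):
        deg = pd.DataFrame({"p": [0.01]}, index=["A"])
        sets = [signatures.GeneSet("appm1", "", ("X", "Y"))]
        assert signatures.derive_appm_signature(deg, sets) == []

    def test_gmt_round_trip(self, tmp_path):
        sets = [signatures.GeneSet("s1", "desc", ("A", "B")),
                signatures.GeneSet("s2", "", ("C", "D", "E"))]
        path = tmp_path / "sets.gmt"
        signatures.write_gmt(sets, str(path))
        assert signatures.read_gmt(str(path)) == sets


class TestScoring:
    def test_constant_signature_gives_that_value(self):
        m = null_matrix(5, 4)
        m.loc[["G0000", "G0001", "G0002"], "S00"] = 7.0
        score = signatures.signature_score(m, ["G0000", "G0001", "G0002"])
        assert score["S00"] == 7.0

    def test_median_matches_hand_computation(self):
        m = pd.DataFrame([[1.0, 4.0], [2.0, 5.0], [9.0, 6.0]],
                         index=["A", "B", "C"], columns=["s1", "s2"])
        score = signatures.signature_score(m, ["A", "B", "C"])
        assert list(score) == [2.0, 5.0]

    def test_missing_genes_dropped_no_overlap_raises(self):
        m = null_matrix(5, 4)
        with pytest.raises(SignatureError):
            signatures.signature_score(m, ["ZZZ"])


class TestTertiles:
    @pytest.mark.parametrize("n,expected", [
        (9, (3, 3, 3)),
        (10, (4, 3, 3)),      # largest remainder to the top tertile
        (307, (103, 102, 102)),
    ])
    def test_allocation(self, n, expected):
        scores = pd.Series(np.arange(n, dtype=float),
                           index=[f"S{i:04d}" for i in range(n)])
        labels = signatures.stratify_tertiles(scores)
        counts = labels.value_counts()
        assert (counts["high"], counts["middle"], counts["low"]) == expected

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        scores = pd.Series(rng.normal(size=40),
                           index=[f"S{i:02d}" for i in range(40)])
        a = signatures.stratify_tertiles(scores)
        b = signatures.stratify_tertiles(np.exp(scores))
        assert (a == b).all()

    def test_high_gets_top_scores(self):
        scores = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        labels = signatures.stratify_tertiles(scores)
        assert labels["c"] == "high" and labels["a"] == "low"

    def test_too_few_samples(self):
        with pytest.raises(ParameterError):
            signatures.stratify_tertiles(pd.Series([1.0, 2.0]))


def ssgsea_oracle(expr, members, alpha):
    """Step-by-step running-sum re-implementation for one sample."""
    order = sorted(expr.index, key=lambda g: (-expr[g], g))
    n = len(order)
    rank_value = list(range(n, 0, -1))
    w_sum = sum(rank_value[i] ** alpha for i, g in enumerate(order)
                if g in members)
    running = 0.0
    es = 0.0
    for i, g in enumerate(order):
        if g in members:
            running += rank_value[i] ** alpha / w_sum
        else:
            running -= 1.0 / (n - len(members))
        es += running
    return es


class TestSsgsea:
    def _toy(self):
        rng = np.random.default_rng(6)
        return pd.DataFrame(
            {"s1": rng.permutation(10).astype(float)},
            index=[f"G{i}" for i in range(10)],
        )

    def test_matches_step_by_step_oracle(self):
        m = self._toy()
        members = ("G1", "G4", "G7")
        sets = [signatures.GeneSet("toy", "", members)]
        es = signatures.ssgsea(m, sets, normalize=False)
        raw = ssgsea_oracle(m["s1"], set(members), 0.25)
        assert es.loc["toy", "s1"] == pytest.approx(raw, rel=1e-12)

    def test_top_ranked_set_positive_bottom_negative(self):
        m = self._toy()
        expr = m["s1"]
        top = tuple(expr.sort_values(ascending=False).index[:3])
        bottom = tuple(expr.sort_values(ascending=True).index[:3])
        nes = signatures.ssgsea(
            m, [signatures.GeneSet("top", "", top),
                signatures.GeneSet("bottom", "", bottom)])
        assert nes.loc["top", "s1"] > 0
        assert nes.loc["bottom", "s1"] < 0

    def test_nes_within_unit_range(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.normal(size=(50, 6)),
                         index=[f"G{i}" for i in range(50)],
                         columns=[f"s{i}" for i in range(6)])
        sets = [signatures.GeneSet(f"set{j}", "",
                                   tuple(rng.choice(m.index, 8, replace=False)))
                for j in range(4)]
        nes = signatures.ssgsea(m, sets)
        assert (nes.to_numpy() >= -1).all() and (nes.to_numpy() <= 1).all()

    def test_small_set_skipped(self):
        m = self._toy()
        with pytest.raises(ParameterError):
            signatures.ssgsea(m, [signatures.GeneSet("tiny", "", ("G1",))])


class TestSurvivalBySignature:
    def test_planted_hazard_link_recovered(self):
        matrix, surv, _ = synthetic.simulate_expression_survival(
            31, 300, [f"G{i:05d}" for i in range(31)], effect=0.0,
            hazard_ratio=2.5, seed=8)
        scores = signatures.signature_score(matrix, list(matrix.index))
        records = [stats.SurvivalRecord(r.sample, r.time, r.event)
                   for r in surv.itertuples()]
        res = signatures.survival_by_signature(scores, records)
        assert res["logrank_p"] < 0.05
        assert res["cox"]["hazard_ratio"] < 1  # high signature protective

    def test_km_tables_present_for_both_groups(self):
        matrix, surv, _ = synthetic.simulate_expression_survival(
            10, 60, [], effect=0.0, hazard_ratio=1.0, seed=9)
        scores = signatures.signature_score(matrix, list(matrix.index))
        records = [stats.SurvivalRecord(r.sample, r.time, r.event)
                   for r in surv.itertuples()]
        res = signatures.survival_by_signature(scores, records)
        assert set(res["km"]) == {"high", "low"}
        assert (res["km"]["high"]["survival"] <= 1).all()


class TestInfiltrationAndCorrelation:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(10)
        cells = pd.DataFrame(rng.normal(size=(20, 3)),
                             index=[f"S{i:02d}" for i in range(20)],
                             columns=["CD4", "CD8", "Treg"])
        cells.iloc[10:] = cells.iloc[:10].to_numpy()
        groups = pd.Series(["high"] * 10 + ["low"] * 10, index=cells.index)
        table = compare = signatures.compare_infiltration(cells, groups)
        assert np.allclose(table["t"], 0.0)
        assert np.allclose(table["p"], 1.0)

    def test_planted_shift_flagged(self):
        rng = np.random.default_rng(11)
        cells = pd.DataFrame(rng.normal(size=(40, 4)),
                             index=[f"S{i:02d}" for i in range(40)],
                             columns=["CD4mem", "Th1", "Th2", "Treg"])
        groups = pd.Series(["high"] * 20 + ["low"] * 20, index=cells.index)
        cells.loc[groups == "high", "Th1"] += 2.0
        table = signatures.compare_infiltration(cells, groups)
        assert table.loc["Th1", "p"] < 0.05
        assert (table.drop(index="Th1")["p"] > 0.05).all()

    def test_anticorrelated_gene(self):
        scores = pd.Series(np.linspace(0, 1, 10),
                           index=[f"S{i}" for i in range(10)])
        res = signatures.correlate_signature_gene(scores, -scores)
        assert res["r"] == pytest.approx(-1.0)
        assert res["slope"] == pytest.approx(-1.0)

    def test_fit_matches_normal_equations(self):
        x = pd.Series([0.0, 1.0, 2.0, 3.0, 4.0],
                      index=[f"S{i}" for i in range(5)])
        y = pd.Series([1.1, 1.9, 3.2, 3.8, 5.1], index=x.index)
        res = signatures.correlate_signature_gene(x, y)
        X = np.vstack([x, np.ones(5)]).T
        slope, intercept = np.linalg.lstsq(X, y.to_numpy(), rcond=None)[0]
        assert res["slope"] == pytest.approx(slope, rel=1e-10)
        assert res["intercept"] == pytest.approx(intercept, rel=1e-10)
        assert (res["band_lower"] <= res["band_upper"]).all()
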