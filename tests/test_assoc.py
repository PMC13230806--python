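import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from sf_endotyper import assoc
from sf_endotyper.assoc import (
    OutcomeSpec,
    bh_adjust,
    call_replication,
    fit_protein_association,
    run_stratified,
    select_best_aptamer,
)
from sf_endotyper.assoc import test_interaction as fit_interaction


def _metadata(n, rng, **extra):
    md = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "age": rng.normal(64, 11, n),
            "sex": rng.choice(["F", "M"], n),
            "bmi": rng.normal(30, 6, n),
            "cohort": rng.choice(["C1", "C2", "C3"], n),
            "dataset": rng.choice(["Discovery", "Replication"], n),
        }
    )
    for k, v in extra.items():
        md[k] = v
    return md.set_index("sample_id", drop=False)


def _zscore(x):
    return (x - x.mean()) / x.std(ddof=1)


class TestFitAssociation:
    def test_exact_linear_effect(self):
        rng = np.random.default_rng(0)
        z = _zscore(rng.standard_normal(60))
        md = _metadata(60, rng, y=2.0 * z + 3.0)
        mat = pd.DataFrame({"apt1": z}, index=md.index)
        spec = OutcomeSpec(name="y", family="continuous", outcome="y", covariates=())
        res = fit_protein_association(mat, md, spec)
        assert res.loc[0, "effect"] == pytest.approx(2.0, abs=1e-10)
        assert res.loc[0, "direction"] == 1

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(5)
        n, p = 150, 300
        x = rng.standard_normal((n, p))
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        md = _metadata(n, rng, y=rng.standard_normal(n))
        mat = pd.DataFrame(x, index=md.index, columns=[f"a{j}" for j in range(p)])
        spec = OutcomeSpec(name="y", family="continuous", outcome="y")
        res = fit_protein_association(mat, md, spec)
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_binary_advanced_kl_with_covariates(self):
        rng = np.random.default_rng(3)
        n = 300
        kl = rng.integers(0, 5, n)
        md = _metadata(n, rng, kl_grade=kl)
        z = _zscore(1.0 * (kl >= 3) + rng.normal(0, 1, n))
        mat = pd.DataFrame({"apt1": z}, index=md.index)
        spec = OutcomeSpec(name="advanced_kl", family="binary")
        res = fit_protein_association(mat, md, spec)
        assert res.loc[0, "p"] < 1e-4
        assert res.loc[0, "effect"] > 0

    def test_ordinal_kl_grades(self):
        rng = np.random.default_rng(4)
        n = 300
        u = rng.standard_normal(n)
        kl = np.clip(np.round(2 + 1.2 * u + rng.normal(0, 1, n)), 0, 4)
        md = _metadata(n, rng, kl_grade=kl)
        mat = pd.DataFrame({"apt1": _zscore(u)}, index=md.index)
        spec = OutcomeSpec(
            name="kl", family="ordinal", outcome="kl_grade", covariates=()
        )
        res = fit_protein_association(mat, md, spec)
        assert res.loc[0, "p"] < 1e-6
        assert res.loc[0, "effect"] > 0

    def test_cohort_random_intercept(self):
        rng = np.random.default_rng(6)
        n = 200
        cohort_effect = {"C1": -1.0, "C2": 0.0, "C3": 1.0}
        md = _metadata(n, rng)
        z = _zscore(rng.standard_normal(n))
        y = 0.5 * z + md["cohort"].map(cohort_effect).to_numpy() + rng.normal(0, 1, n)
        md["y"] = y
        mat = pd.DataFrame({"apt1": z}, index=md.index)
        fixed = fit_protein_association(
            mat, md, OutcomeSpec(name="y", family="continuous", outcome="y", cohort_adjust="fixed")
        )
        random = fit_protein_association(
            mat, md, OutcomeSpec(name="y", family="continuous", outcome="y", cohort_adjust="random")
        )
        assert np.sign(fixed.loc[0, "effect"]) == np.sign(random.loc[0, "effect"]) == 1
        assert fixed.loc[0, "effect"] == pytest.approx(random.loc[0, "effect"], abs=0.1)

    def test_constant_outcome_rejected(self):
        rng = np.random.default_rng(0)
        md = _metadata(50, rng, y=np.ones(50))
        mat = pd.DataFrame({"a": _zscore(rng.standard_normal(50))}, index=md.index)
        with pytest.raises(ValueError, match="constant"):
            fit_protein_association(
                mat, md, OutcomeSpec(name="y", family="binary", outcome="y")
            )

    def test_min_n_enforced(self):
        rng = np.random.default_rng(0)
        md = _metadata(10, rng, y=rng.standard_normal(10))
        mat = pd.DataFrame({"a": rng.standard_normal(10)}, index=md.index)
        with pytest.raises(ValueError, match="min_n"):
            fit_protein_association(
                mat, md, OutcomeSpec(name="y", family="continuous", outcome="y")
            )

    def test_separation_flagged_not_dropped(self):
        rng = np.random.default_rng(1)
        n = 60
        z = _zscore(rng.standard_normal(n))
        md = _metadata(n, rng, y=(z > 0).astype(float))  # perfectly separated
        mat = pd.DataFrame({"apt1": z}, index=md.index)
        res = fit_protein_association(
            mat, md, OutcomeSpec(name="y", family="binary", outcome="y", covariates=())
        )
        assert len(res) == 1
        assert bool(res.loc[0, "flagged"])
        assert np.isnan(res.loc[0, "p"])

    def test_affine_rescaling_invariance(self):
        # standardization absorbs affine rescaling of the raw abundance
        rng = np.random.default_rng(9)
        n = 120
        raw = rng.lognormal(7, 0.4, n)
        md = _metadata(n, rng, y=np.log(raw) + rng.normal(0, 0.5, n))
        spec = OutcomeSpec(name="y", family="continuous", outcome="y", covariates=())
        res1 = fit_protein_association(
            pd.DataFrame({"a": _zscore(np.log(raw))}, index=md.index), md, spec
        )
        res2 = fit_protein_association(
            pd.DataFrame({"a": _zscore(np.log(raw * 1000.0))}, index=md.index), md, spec
        )
        assert res1.loc[0, "effect"] == pytest.approx(res2.loc[0, "effect"], rel=1e-9)


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.04, 0.05]), [0.04, 0.04, 0.05, 0.05]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_single_p(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(2)
        p = rng.random(200)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50)
    )
    @settings(max_examples=100, deadline=None)
    def test_properties(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestReplication:
    def _rec(self, padj, direction):
        return pd.DataFrame(
            {
                "aptamer_id": ["a1"],
                "effect": [float(direction)],
                "p": [padj / 2],
                "padj": [padj],
                "direction": [direction],
            }
        )

    @pytest.mark.parametrize(
        "padj_d, dir_d, padj_r, dir_r, expected",
        [
            (0.04, 1, 0.03, 1, True),
            (0.04, 1, 0.03, -1, False),
            (0.06, 1, 0.01, 1, False),
            (0.01, 1, 0.06, 1, False),
            (0.05, -1, 0.05, -1, True),  # boundary: <= 0.05 counts
            (0.06, 1, 0.06, 1, False),
            (0.04, -1, 0.03, 1, False),
            (0.051, -1, 0.049, -1, False),
        ],
    )
    def test_truth_table(self, padj_d, dir_d, padj_r, dir_r, expected):
        out = call_replication(self._rec(padj_d, dir_d), self._rec(padj_r, dir_r))
        assert bool(out.loc[0, "replicated"]) is expected

    def test_no_overlap_rejected(self):
        a = self._rec(0.01, 1)
        b = self._rec(0.01, 1).assign(aptamer_id=["other"])
        with pytest.raises(ValueError, match="overlap"):
            call_replication(a, b)


class TestInteraction:
    def test_planted_differential_slope(self):
        rng = np.random.default_rng(12)
        n = 800
        z = _zscore(rng.standard_normal(n))
        obese = (rng.random(n) < 0.5).astype(float)
        md = _metadata(n, rng, bmi=np.where(obese == 1, 35.0, 25.0))
        md["y"] = 0.5 * z + 1.0 * z * obese + rng.normal(0, 1, n)
        mat = pd.DataFrame(
            {"hit": z, "null": _zscore(rng.standard_normal(n))}, index=md.index
        )
        spec = OutcomeSpec(name="y", family="continuous", outcome="y", covariates=())
        res = fit_interaction(mat, md, spec, "obese")
        res = res.set_index("aptamer_id")
        assert res.loc["hit", "padj"] <= 0.05
        assert res.loc["hit", "interaction"] == pytest.approx(1.0, abs=0.2)
        assert res.loc["null", "p"] > 0.05

    def test_constant_modifier_rejected(self):
        rng = np.random.default_rng(0)
        md = _metadata(50, rng, y=rng.standard_normal(50), bmi=np.full(50, 40.0))
        mat = pd.DataFrame({"a": _zscore(rng.standard_normal(50))}, index=md.index)
        spec = OutcomeSpec(name="y", family="continuous", outcome="y", covariates=())
        with pytest.raises(ValueError, match="constant"):
            fit_interaction(mat, md, spec, "obese")


class TestSelectBestAptamer:
    def test_keeps_smallest_padj(self):
        df = pd.DataFrame(
            {
                "aptamer_id": ["a1", "a2"],
                "gene": ["G", "G"],
                "p": [0.005, 0.02],
                "padj": [0.01, 0.03],
            }
        )
        out = select_best_aptamer(df)
        assert list(out["aptamer_id"]) == ["a1"]

    def test_unique_genes_unchanged(self):
        df = pd.DataFrame(
            {
                "aptamer_id": ["a1", "a2"],
                "gene": ["G1", "G2"],
                "p": [0.5, 0.1],
                "padj": [0.6, 0.2],
            }
        )
        assert len(select_best_aptamer(df)) == 2

    def test_exact_tie_breaks_lexicographically(self):
        df = pd.DataFrame(
            {
                "aptamer_id": ["b9", "a1"],
                "gene": ["G", "G"],
                "p": [0.01, 0.01],
                "padj": [0.02, 0.02],
            }
        )
        out = select_best_aptamer(df)
        assert list(out["aptamer_id"]) == ["a1"]


class TestStratified:
    def test_strata_sizes(self):
        rng = np.random.default_rng(0)
        n = 200
        md = _metadata(n, rng, y=rng.standard_normal(n))
        mat = pd.DataFrame(
            rng.standard_normal((n, 3)),
            index=md.index,
            columns=["a1", "a2", "a3"],
        )
        spec = OutcomeSpec(name="y", family="continuous", outcome="y", covariates=())
        out = run_stratified(mat, md, "bmi>=30", spec)
        sizes = {k: int(v["n"].iloc[0]) for k, v in out["strata"].items()}
        assert sizes["bmi>=30"] + sizes["not(bmi>=30)"] == n

    def test_shared_effect_correlates_across_strata(self):
        rng = np.random.default_rng(8)
        n, p = 800, 40
        x = rng.standard_normal((n, p))
        beta = rng.normal(0, 0.5, p)
        y = x @ beta + rng.normal(0, 1, n)
        md = _metadata(n, rng, y=y)
        mat = pd.DataFrame(x, index=md.index, columns=[f"a{j}" for j in range(p)])
        spec = OutcomeSpec(name="y", family="continuous", outcome="y", covariates=())
        out = run_stratified(mat, md, "bmi>=30", spec)
        assert out["effect_correlation"] >= 0.6

    def test_sex_stratified_drops_sex_covariate(self):
        rng = np.random.default_rng(1)
        n = 200
        md = _metadata(n, rng, y=rng.standard_normal(n))
        mat = pd.DataFrame({"a1": rng.standard_normal(n)}, index=md.index)
        spec = OutcomeSpec(name="y", family="continuous", outcome="y")
        out = run_stratified(mat, md, "sex==F", spec)  # must not raise
        assert set(out["strata"]) == {"sex==F", "not(sex==F)"}

    def test_empty_stratum_rejected(self):
        rng = np.random.default_rng(1)
        md = _metadata(50, rng, y=rng.standard_normal(50))
        mat = pd.DataFrame({"a1": rng.standard_normal(50)}, index=md.index)
        spec = OutcomeSpec(name="y", family="continuous", outcome="y", covariates=())
        with pytest.raises(ValueError, match="empty stratum"):
            run_stratified(mat, md, "bmi>=1000", spec)
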