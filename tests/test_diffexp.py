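"""Differential expression: downsampling, filters, NB / hurdle / protein routes."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
import statsmodels.api as sm

import plaqniche as pq
from plaqniche.diffexp import (
    DesignSpec,
    DownsampleConstraints,
    _fit_nb_wald,
    bh_adjust,
    build_design,
    find_markers,
    gene_filter,
    hurdle_test,
    normalize_log1p,
    protein_nb_test,
    pseudobulk_nb_test,
)
from tests.conftest import COHORT_DESIGN


def _units(sizes_by_group):
    """Build a unit table from {group: {sample: n}}."""
    rows = []
    for g, samples in sizes_by_group.items():
        for s, n in samples.items():
            for i in range(n):
                rows.append({"unit": f"{g}_{s}_{i}", "sample": s, "group": g})
    return pd.DataFrame(rows)


class TestBalanceDownsample:
    def test_both_groups_capped_at_3000(self):
        units = _units(
            {
                "g1": {f"a{i}": 2000 for i in range(6)},
                "g2": {f"b{i}": 1500 for i in range(6)},
            }
        )
        kept = pq.balance_downsample(units, seed=1)
        sizes = kept.groupby("group").size()
        assert sizes.max() <= 3000
        assert sizes["g1"] == 3000 and sizes["g2"] == 3000

    def test_fold_cap_binds_when_smaller_group_is_small(self):
        units = _units({"g1": {f"a{i}": 1000 for i in range(8)}, "g2": {"b": 700}})
        kept = pq.balance_downsample(units, seed=2)
        sizes = kept.groupby("group").size()
        assert sizes["g1"] <= 3 * sizes["g2"]

    def test_share_cap_fixed_point(self):
        # 900/100 split converges to 100/100 under the floor(0.5 * total) trim
        units = _units({"g1": {"p": 900, "q": 100}, "g2": {"z": 300}})
        kept = pq.balance_downsample(units, seed=3)
        g1 = kept[kept["group"] == "g1"]["sample"].value_counts()
        assert g1.to_dict() == {"p": 100, "q": 100}

    def test_single_sample_group_exempt_from_share_rule(self):
        units = _units({"g1": {"only": 500}, "g2": {"x": 300, "y": 300}})
        kept = pq.balance_downsample(units, seed=4)
        assert (kept[kept["group"] == "g1"]["sample"] == "only").all()
        assert len(kept[kept["group"] == "g1"]) == 500

    def test_deterministic_given_seed(self):
        units = _units(
            {"g1": {"a": 4000, "b": 800}, "g2": {"c": 2500, "d": 2500, "e": 100}}
        )
        k1 = pq.balance_downsample(units, seed=7)
        k2 = pq.balance_downsample(units, seed=7)
        pd.testing.assert_frame_equal(k1, k2)
        k3 = pq.balance_downsample(units, seed=8)
        assert not k1["unit"].equals(k3["unit"])

    def test_empty_group_aborts(self):
        units = _units({"g1": {"a": 10}})
        with pytest.raises(ValueError):
            pq.balance_downsample(units, seed=0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        sizes1=st.lists(st.integers(1, 400), min_size=1, max_size=5),
        sizes2=st.lists(st.integers(1, 400), min_size=1, max_size=5),
        seed=st.integers(0, 2**16),
    )
    def test_constraints_always_hold(self, sizes1, sizes2, seed):
        constraints = DownsampleConstraints(max_group_size=300)
        units = _units(
            {
                "g1": {f"a{i}": n for i, n in enumerate(sizes1)},
                "g2": {f"b{i}": n for i, n in enumerate(sizes2)},
            }
        )
        kept = pq.balance_downsample(units, constraints, seed=seed)
        sizes = kept.groupby("group").size()
        assert sizes.min() >= 1
        assert sizes.max() <= 300
        assert sizes.max() <= 3.0 * sizes.min()
        for g, sub in kept.groupby("group"):
            if sub["sample"].nunique() > 1:
                assert sub["sample"].value_counts().max() <= 0.5 * len(sub)


class TestGeneFilter:
    @staticmethod
    def _counts(det1, det2, name="GENE1", n=200):
        """One gene detected in det1 / det2 fractions of two 100-unit groups."""
        v = np.zeros(n)
        v[: int(det1 * 100)] = 5
        v[100 : 100 + int(det2 * 100)] = 5
        counts = pd.DataFrame([v], index=[name], columns=[f"u{i}" for i in range(n)])
        groups = pd.Series(["g1"] * 100 + ["g2"] * 100, index=counts.columns)
        return counts, groups

    def test_all_zero_gene_excluded_everywhere(self):
        counts, groups = self._counts(0, 0)
        for mode in ("pseudobulk", "hurdle", "hd"):
            assert gene_filter(counts, groups, mode) == []

    @pytest.mark.parametrize("symbol", ["MT-CO1", "RPS6", "RPL13A", "HBB"])
    def test_prefix_exclusion(self, symbol):
        counts, groups = self._counts(0.5, 0.5, name=symbol)
        assert gene_filter(counts, groups, "pseudobulk") == []

    def test_prefix_exclusion_case_sensitive(self):
        counts, groups = self._counts(0.5, 0.5, name="Mtor")
        assert gene_filter(counts, groups, "pseudobulk") == ["Mtor"]

    def test_hurdle_rule(self):
        kept, groups = self._counts(0.02, 0.12)
        assert gene_filter(kept, groups, "hurdle") == ["GENE1"]
        dropped, _ = self._counts(0.02, 0.08)
        assert gene_filter(dropped, groups, "hurdle") == []
        one_sided, _ = self._counts(0.0, 0.5)
        assert gene_filter(one_sided, groups, "hurdle") == []

    def test_either_group_rule(self):
        counts, groups = self._counts(0.0, 0.01)
        assert gene_filter(counts, groups, "pseudobulk") == ["GENE1"]
        assert gene_filter(counts, groups, "hd") == ["GENE1"]


class TestBHAdjust:
    @staticmethod
    def _bh_oracle(p):
        """Literal step-up definition with monotonization."""
        p = np.asarray(p, dtype=float)
        n = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(n)
        prev = 1.0
        for rank_from_top in range(n, 0, -1):
            i = order[rank_from_top - 1]
            val = min(prev, p[i] * n / rank_from_top)
            adj[i] = val
            prev = val
        return adj

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for n in (1, 2, 5, 13, 20):
            for _ in range(20):
                p = rng.random(n)
                assert np.allclose(bh_adjust(p), self._bh_oracle(p))

    def test_matches_oracle_with_ties(self):
        p = np.array([0.01, 0.01, 0.4, 0.4, 0.4, 1.0])
        assert np.allclose(bh_adjust(p), self._bh_oracle(p))

    def test_nan_passthrough(self):
        adj = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(adj[1])
        assert np.allclose(adj[[0, 2]], self._bh_oracle([0.01, 0.5]))


class TestBuildDesign:
    def test_collinearity_names_aliased_column(self):
        meta = pd.DataFrame(
            {
                "group": ["a", "a", "b", "b"],
                "dup": [0.0, 0.0, 1.0, 1.0],
            },
            index=list("wxyz"),
        )
        with pytest.raises(ValueError, match="dup"):
            build_design(meta, DesignSpec(covariates=(("dup", "continuous"),)))

    def test_continuous_covariates_standardized(self):
        meta = pd.DataFrame(
            {"group": list("aabb"), "age": [60.0, 70.0, 80.0, 90.0]},
            index=list("wxyz"),
        )
        X, _, _ = build_design(meta, DesignSpec(covariates=(("age", "continuous"),)))
        assert X["age"].mean() == pytest.approx(0.0, abs=1e-12)
        assert X["age"].std(ddof=0) == pytest.approx(1.0)


class TestPseudobulkNB:
    def test_null_type_one_error_small_cohort(self, small_null_cohort):
        cohort = small_null_cohort
        counts, meta = cohort["counts"], cohort["meta"]
        donor_meta = meta.groupby("sample").first()
        genes = gene_filter(counts, meta["group"], mode="pseudobulk")
        tab = pseudobulk_nb_test(
            counts, meta["sample"], donor_meta, COHORT_DESIGN, genes=genes
        )
        frac = (tab["p"] < 0.05).mean()
        assert 0.01 < frac < 0.10
        assert tab["significant"].mean() < 0.02

    def test_planted_effect_detected(self):
        params = pq.SynthParams(
            seed=13, n_niche_genes=0, n_group_genes=20, group_lfc=2.0,
            n_genes=200, spots_per_donor=300,
        )
        cohort = pq.simulate_cohort(params, seed=13)
        counts, meta = cohort["counts"], cohort["meta"]
        tab = pseudobulk_nb_test(
            counts, meta["sample"], meta.groupby("sample").first(), COHORT_DESIGN
        )
        planted = set(cohort["truth"].group_genes)
        assert (tab.loc[sorted(planted), "significant"]).mean() >= 0.9

    def test_no_signal_gene_flat(self):
        # identical counts across donors with equal library sizes
        counts = pd.DataFrame(
            {f"d{i}": [50, 1000] for i in range(8)}, index=["flat", "filler"]
        )
        meta = pd.DataFrame({"group": ["a"] * 4 + ["b"] * 4}, index=counts.columns)
        tab = pseudobulk_nb_test(
            counts, pd.Series(counts.columns, index=counts.columns), meta, DesignSpec()
        )
        assert abs(tab.loc["flat", "lfc"]) < 1e-6
        assert tab.loc["flat", "p"] > 0.99

    def test_fewer_than_two_donors_errors(self):
        counts = pd.DataFrame({"d1": [5], "d2": [6], "d3": [7]}, index=["g"])
        meta = pd.DataFrame({"group": ["a", "b", "b"]}, index=counts.columns)
        with pytest.raises(ValueError, match="2 donors"):
            pseudobulk_nb_test(
                counts, pd.Series(counts.columns, index=counts.columns), meta,
                DesignSpec(),
            )

    def test_poisson_limit_matches_poisson_glm(self):
        # with dispersion -> infinity the NB Wald test is the Poisson Wald test
        rng = np.random.default_rng(5)
        n = 16
        X = pd.DataFrame(
            {"intercept": 1.0, "group": [0.0] * 8 + [1.0] * 8},
            index=[f"d{i}" for i in range(n)],
        )
        offset = np.log(rng.uniform(1e4, 2e4, n))
        y = rng.poisson(np.exp(offset + 0.4 * X["group"].to_numpy() - 6.0))
        lfc_nb, p_nb = _fit_nb_wald(y, X, offset, theta=np.inf, df_resid=None)
        fit = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        z = fit.params["group"] / fit.bse["group"]
        assert lfc_nb == pytest.approx(fit.params["group"] / np.log(2), rel=1e-4)
        assert p_nb == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-3)

    def test_matches_deseq2_oracle_on_fixture(self):
        # independent cross-check of the whole route against pydeseq2
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(0)
        groups = ["A"] * 6 + ["B"] * 6
        lib = rng.lognormal(np.log(5e4), 0.2, 12)
        base = rng.lognormal(0, 1, 60)
        base /= base.sum()
        lfc = np.zeros(60)
        lfc[:10] = rng.choice([-1.5, 1.5], 10)
        mu = lib[None, :] * base[:, None] * 2 ** (
            lfc[:, None] * (np.array(groups) == "B")[None, :]
        )
        theta = 20.0
        counts = pd.DataFrame(
            rng.negative_binomial(theta, theta / (theta + mu)),
            index=[f"g{i}" for i in range(60)],
            columns=[f"d{i}" for i in range(12)],
        )
        meta = pd.DataFrame({"group": groups}, index=counts.columns)
        tab = pseudobulk_nb_test(
            counts, pd.Series(counts.columns, index=counts.columns), meta, DesignSpec()
        )
        dds = DeseqDataSet(counts=counts.T, metadata=meta, design="~group", quiet=True)
        dds.deseq2()
        res = DeseqStats(
            dds, contrast=["group", "B", "A"], independent_filter=False, quiet=True
        )
        res.summary()
        ref = res.results_df.loc[tab.index]
        assert np.corrcoef(tab["lfc"], ref["log2FoldChange"])[0, 1] > 0.99
        assert np.abs(tab["lfc"] - ref["log2FoldChange"]).mean() < 0.1
        mine = set(tab.index[tab["significant"]])
        theirs = set(
            ref.index[(ref["padj"] < 0.05) & (ref["log2FoldChange"].abs() >= np.log2(1.5))]
        )
        # planted genes recovered consistently by both implementations
        overlap = len(mine & theirs) / max(len(mine | theirs), 1)
        assert overlap >= 0.8


class TestHurdle:
    @staticmethod
    def _meta(n_per_group, rng):
        n = 2 * n_per_group
        return pd.DataFrame(
            {
                "group": ["a"] * n_per_group + ["b"] * n_per_group,
                "cdr": rng.normal(0.3, 0.05, n),
            },
            index=[f"u{i}" for i in range(n)],
        )

    def test_fully_detected_gene_uses_continuous_part_only(self):
        rng = np.random.default_rng(1)
        meta = self._meta(60, rng)
        expr = pd.DataFrame(
            [rng.normal(2.0, 0.5, 120) + 0.8 * (meta["group"] == "b")],
            index=["g"], columns=meta.index,
        )
        design = DesignSpec(covariates=(("cdr", "continuous"),))
        tab = hurdle_test(expr, meta, design)
        # all-detected: discrete part contributes 0 df, test is the linear LRT
        from plaqniche.diffexp import _lrt_linear, build_design

        X, _, _ = build_design(meta, design)
        chi, df = _lrt_linear(
            expr.loc["g"].to_numpy(), X.to_numpy(), list(X.columns).index("group")
        )
        assert tab.loc["g", "p"] == pytest.approx(stats.chi2.sf(chi, df))

    def test_detection_difference_drives_significance(self):
        rng = np.random.default_rng(2)
        meta = self._meta(150, rng)
        det = np.r_[rng.random(150) < 0.8, rng.random(150) < 0.2]
        vals = rng.normal(2.0, 0.3, 300)  # equal positive means
        expr = pd.DataFrame([np.where(det, vals, 0.0)], index=["g"], columns=meta.index)
        tab = hurdle_test(expr, meta, DesignSpec())
        assert tab.loc["g", "p"] < 1e-6

    def test_null_calibration(self):
        rng = np.random.default_rng(3)
        meta = self._meta(120, rng)
        n_genes = 400
        det = rng.random((n_genes, 240)) < 0.5
        expr = pd.DataFrame(
            np.where(det, rng.normal(2, 0.5, (n_genes, 240)), 0.0),
            index=[f"g{i}" for i in range(n_genes)],
            columns=meta.index,
        )
        tab = hurdle_test(expr, meta, DesignSpec(covariates=(("cdr", "continuous"),)))
        frac = (tab["p"] < 0.05).mean()
        assert 0.02 < frac < 0.09


class TestProteinNB:
    def test_planted_effect_and_untested_protein(self):
        rng = np.random.default_rng(4)
        n = 1000  # 500 per group
        meta = pd.DataFrame(
            {"group": ["a"] * 500 + ["b"] * 500, "cdr": rng.normal(0, 1, n)},
            index=[f"u{i}" for i in range(n)],
        )
        theta = 5.0
        base = np.full(n, 20.0)
        mu_up = base * np.where(meta["group"] == "b", 3.0, 1.0)
        # a realistic panel: many stable proteins anchor the library-size offset
        panel = {
            f"P_bg{i}": rng.negative_binomial(theta, theta / (theta + base))
            for i in range(30)
        }
        panel["P_flat"] = rng.negative_binomial(theta, theta / (theta + base))
        panel["P_up"] = rng.negative_binomial(theta, theta / (theta + mu_up))
        panel["P_absent"] = np.zeros(n)
        counts = pd.DataFrame(panel, index=meta.index).T
        tab = protein_nb_test(
            counts, meta, DesignSpec(covariates=(("cdr", "continuous"),))
        )
        assert tab.loc["P_up", "significant"]
        assert not tab.loc["P_absent", "tested"]
        assert tab.loc["P_flat", "p"] > 0.01

    def test_null_type_one_error(self):
        rng = np.random.default_rng(5)
        n = 400
        meta = pd.DataFrame(
            {"group": ["a"] * 200 + ["b"] * 200}, index=[f"u{i}" for i in range(n)]
        )
        theta = 8.0
        counts = pd.DataFrame(
            rng.negative_binomial(theta, theta / (theta + 15.0), size=(150, n)),
            index=[f"P{i}" for i in range(150)],
            columns=meta.index,
        )
        tab = protein_nb_test(counts, meta, DesignSpec())
        frac = (tab["p"] < 0.05).mean()
        assert 0.01 < frac < 0.10


class TestFindMarkers:
    def test_exclusive_gene_is_top_marker(self):
        rng = np.random.default_rng(6)
        n = 200
        clusters = pd.Series(
            ["A"] * 100 + ["B"] * 100, index=[f"u{i}" for i in range(n)]
        )
        E = rng.lognormal(0, 0.2, (30, n))
        E[0, 100:] = 0.0  # gene 0 expressed only in cluster A? no: zero in B
        E[0, :100] = np.where(rng.random(100) < 0.6, 3.0, 0.0)
        expr = pd.DataFrame(E, index=[f"g{i}" for i in range(30)], columns=clusters.index)
        out = find_markers(expr, clusters)
        assert out["A"].index[0] == "g0"
        assert out["A"].iloc[0]["significant"]

    def test_low_detection_untested(self):
        rng = np.random.default_rng(7)
        clusters = pd.Series(["A"] * 50 + ["B"] * 50, index=[f"u{i}" for i in range(100)])
        v = np.zeros(100)
        v[:5] = 4.0  # 10% detection in cluster A
        expr = pd.DataFrame([v], index=["g"], columns=clusters.index)
        out = find_markers(expr, clusters)
        assert not out["A"].loc["g", "tested"]

    def test_identical_clusters_no_markers(self):
        rng = np.random.default_rng(8)
        clusters = pd.Series(["A"] * 80 + ["B"] * 80, index=[f"u{i}" for i in range(160)])
        expr = pd.DataFrame(
            rng.lognormal(0, 0.3, (50, 160)),
            index=[f"g{i}" for i in range(50)],
            columns=clusters.index,
        )
        out = find_markers(expr, clusters, only_pos=False)
        for tab in out.values():
            assert not tab["significant"].any()

    def test_prefix_excluded_from_markers(self):
        clusters = pd.Series(["A"] * 10 + ["B"] * 10, index=[f"u{i}" for i in range(20)])
        expr = pd.DataFrame(
            np.ones((2, 20)), index=["MT-ND1", "OK1"], columns=clusters.index
        )
        out = find_markers(expr, clusters)
        assert "MT-ND1" not in out["A"].index
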