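"""Alpha/beta diversity, PCoA, PERMANOVA, and the two beta-diversity
comparison procedures."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cyclevag import diversity
from cyclevag.diversity import OrdinationResult


def _dist(df):
    return diversity.euclidean_clr(df)


class TestAlpha:
    def test_single_taxon_degenerate(self):
        assert diversity.shannon([50]) == 0.0
        assert diversity.simpson([50]) == 0.0

    def test_uniform_closed_forms(self):
        assert diversity.shannon([10, 10, 10, 10]) == pytest.approx(np.log(4))
        assert diversity.simpson([10, 10, 10, 10]) == pytest.approx(0.75)

    def test_direct_formula_value(self):
        assert diversity.shannon([10, 30, 60]) == pytest.approx(0.8979, abs=5e-5)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            diversity.shannon([0, 0])
        with pytest.raises(ValueError):
            diversity.simpson([0, 0])

    def test_table_conventions(self, toy_counts):
        table = diversity.alpha_diversity_table(toy_counts)
        assert np.allclose(
            table["simpson"] + table["simpson_concentration"], 1.0
        )


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        rel = pd.DataFrame([[0.5, 0.5], [0.5, 0.5]], index=["a", "b"])
        assert diversity.bray_curtis(rel).loc["a", "b"] == 0.0

    def test_disjoint_supports_one(self):
        rel = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"])
        assert diversity.bray_curtis(rel).loc["a", "b"] == pytest.approx(1.0)

    def test_hand_evaluated_pair(self):
        rel = pd.DataFrame([[0.7, 0.3], [0.3, 0.7]], index=["a", "b"])
        assert diversity.bray_curtis(rel).loc["a", "b"] == pytest.approx(0.4)

    def test_permutation_equivariance(self, default_cohort):
        from cyclevag import composition

        rel = composition.to_relative_abundance(default_cohort["counts"].iloc[:15])
        d1 = diversity.bray_curtis(rel)
        perm = rel.sample(frac=1.0, random_state=3)
        d2 = diversity.bray_curtis(perm)
        assert np.allclose(
            d2.loc[d1.index, d1.columns].to_numpy(), d1.to_numpy(), atol=1e-12
        )


class TestPCoA:
    def test_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(12, 2))
        df = pd.DataFrame(pts, index=[f"s{i}" for i in range(12)])
        res = diversity.pcoa(_dist(df), n_axes=2)
        from scipy.spatial.distance import pdist

        assert np.allclose(
            pdist(res.samples.to_numpy()), pdist(pts), atol=1e-8
        )

    def test_duplicated_sample_identical_scores(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(6, 3))
        pts[5] = pts[0]
        df = pd.DataFrame(pts, index=[f"s{i}" for i in range(6)])
        res = diversity.pcoa(_dist(df), n_axes=2)
        assert np.allclose(
            res.samples.loc["s0"].to_numpy(), res.samples.loc["s5"].to_numpy(), atol=1e-8
        )

    def test_three_point_eigenvalues_match_direct_decomposition(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        df = pd.DataFrame(pts, index=["a", "b", "c"])
        d = _dist(df).to_numpy()
        # oracle: eigendecomposition of the double-centered Gram matrix
        J = np.eye(3) - np.ones((3, 3)) / 3
        G = -0.5 * J @ (d**2) @ J
        expected = np.sort(np.linalg.eigvalsh(G))[::-1]
        res = diversity.pcoa(_dist(df), n_axes=2)
        assert np.allclose(np.sort(res.eigenvalues)[::-1][:3], expected, atol=1e-8)

    def test_axes_ordered_by_eigenvalue(self, default_cohort):
        from cyclevag import composition

        rel = composition.to_relative_abundance(default_cohort["counts"].iloc[:40])
        res = diversity.pcoa(diversity.bray_curtis(rel))
        variances = res.samples.var(axis=0).to_numpy()
        assert (np.diff(variances) <= 1e-12).all()


class TestScreenAndAdjust:
    def _ordination(self, scores, ids):
        return OrdinationResult(
            samples=pd.DataFrame({"PCo1": scores}, index=ids),
            eigenvalues=np.array([1.0]),
        )

    def test_identical_scores_not_significant(self):
        ids = [f"s{i}" for i in range(30)]
        meta = pd.DataFrame(
            {"visit_number": 1, "var": ["a", "b", "c"] * 10}, index=ids
        )
        res = diversity.screen_covariates_per_visit(
            self._ordination(np.ones(30), ids), meta, ["var"]
        )
        assert res["p"].iloc[0] > 0.9

    def test_forced_separation_significant(self):
        ids = [f"s{i}" for i in range(60)]
        groups = ["a"] * 30 + ["b"] * 30
        scores = np.r_[np.zeros(30), np.ones(30) * 10] + np.random.default_rng(0).normal(
            0, 0.01, 60
        )
        meta = pd.DataFrame({"visit_number": 1, "var": groups}, index=ids)
        res = diversity.screen_covariates_per_visit(
            self._ordination(scores, ids), meta, ["var"]
        )
        assert res["p"].iloc[0] < 1e-6

    def test_constant_variable_reports_na(self):
        ids = [f"s{i}" for i in range(10)]
        meta = pd.DataFrame({"visit_number": 1, "var": ["a"] * 10}, index=ids)
        res = diversity.screen_covariates_per_visit(
            self._ordination(np.arange(10.0), ids), meta, ["var"]
        )
        assert np.isnan(res["p"].iloc[0])
        assert res["note"].iloc[0] != ""

    def test_adjusted_axis_orthogonal_to_covariate(self):
        rng = np.random.default_rng(2)
        ids = [f"s{i}" for i in range(50)]
        cov = rng.normal(size=50)
        scores = 2.0 * cov + rng.normal(0, 0.1, 50)
        meta = pd.DataFrame({"visit_number": 1, "Age": cov}, index=ids)
        adjusted = diversity.adjust_axes(
            self._ordination(scores, ids), meta, {"PCo1": ["Age"]}
        )
        r = adjusted.samples["PCo1"].to_numpy()
        assert abs((cov - cov.mean()) @ r) < 1e-6
        assert adjusted.samples["PCo1"].var() <= np.var(scores)
        assert adjusted.adjusted_with == {"PCo1": ["Age"]}


class TestPermanova:
    def test_maximal_separation_reaches_minimum_p(self):
        # two internally identical, mutually distinct groups; 8+8 so no
        # permutation reproduces the partition under this seed
        a = np.tile([0.0, 0.0], (8, 1))
        b = np.tile([10.0, 10.0], (8, 1))
        df = pd.DataFrame(np.vstack([a, b]), index=[f"s{i}" for i in range(16)])
        g = pd.Series(["a"] * 8 + ["b"] * 8, index=df.index)
        res = diversity.permanova(_dist(df), g, n_perm=199, seed=0)
        assert res["p"] == pytest.approx(1 / 200)

    def test_pseudo_f_matches_brute_force(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(6, 2)), index=[f"s{i}" for i in range(6)])
        g = pd.Series(["a", "a", "a", "b", "b", "b"], index=df.index)
        d = _dist(df).to_numpy()
        n, a = 6, 2
        sst = (d[np.triu_indices(n, 1)] ** 2).sum() / n
        ssw = 0.0
        for lev in ("a", "b"):
            idx = np.where(g.to_numpy() == lev)[0]
            sub = d[np.ix_(idx, idx)]
            ssw += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
        ssb = sst - ssw
        f_expected = (ssb / (a - 1)) / (ssw / (n - a))
        res = diversity.permanova(_dist(df), g, n_perm=99, seed=0)
        assert res["pseudo_F"] == pytest.approx(f_expected, rel=1e-10)
        assert res["R2"] == pytest.approx(ssb / sst, rel=1e-10)

    def test_reproducible_under_seed(self, default_cohort):
        from cyclevag import composition

        rel = composition.to_relative_abundance(default_cohort["counts"].iloc[:30])
        d = diversity.bray_curtis(rel)
        g = pd.Series(
            default_cohort["metadata"].loc[d.index, "visit_number"] <= 2, index=d.index
        ).map({True: "early", False: "late"})
        r1 = diversity.permanova(d, g, n_perm=199, seed=9)
        r2 = diversity.permanova(d, g, n_perm=199, seed=9)
        assert r1 == r2

    def test_p_decreases_with_effect_size(self):
        rng = np.random.default_rng(7)
        mean_p = []
        for shift in (0.0, 0.75, 1.5):
            ps = []
            for _ in range(60):
                x = rng.normal(size=(20, 3))
                x[10:] += shift
                df = pd.DataFrame(x, index=[f"s{i}" for i in range(20)])
                g = pd.Series(["a"] * 10 + ["b"] * 10, index=df.index)
                ps.append(diversity.permanova(_dist(df), g, n_perm=99,
                                              seed=int(rng.integers(2**31)))["p"])
            mean_p.append(np.mean(ps))
        assert mean_p[0] > mean_p[1] > mean_p[2]

    def test_single_level_rejected(self):
        df = pd.DataFrame(np.eye(3), index=list("abc"))
        g = pd.Series(["x", "x", "x"], index=df.index)
        with pytest.raises(ValueError, match="2 levels"):
            diversity.permanova(_dist(df), g)


class TestFriedman:
    def _design(self, n_women):
        ids = [f"W{w}_{v}" for w in range(n_women) for v in range(1, 5)]
        return pd.DataFrame(
            {
                "woman": [s.split("_")[0] for s in ids],
                "visit_number": [int(s.split("_")[1]) for s in ids],
            },
            index=ids,
        )

    def test_constant_values_p_one(self):
        design = self._design(10)
        alpha = pd.Series(1.0, index=design.index)
        assert diversity.friedman_alpha(alpha, design) == 1.0

    def test_monotone_trend_detected(self):
        design = self._design(20)
        alpha = pd.Series(design["visit_number"].astype(float), index=design.index)
        alpha += np.random.default_rng(0).normal(0, 1e-6, len(alpha))
        assert diversity.friedman_alpha(alpha, design) < 1e-4

    def test_null_p_uniform(self):
        rng = np.random.default_rng(3)
        design = self._design(15)
        ps = []
        for _ in range(400):
            alpha = pd.Series(rng.normal(size=len(design)), index=design.index)
            ps.append(diversity.friedman_alpha(alpha, design))
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestPerPhaseBeta:
    def _cohort(self, n_women, rng, phase_scale=None):
        ids = [f"W{w}_{v}" for w in range(n_women) for v in range(1, 5)]
        design = pd.DataFrame(
            {
                "woman": [s.split("_")[0] for s in ids],
                "visit_number": [int(s.split("_")[1]) for s in ids],
            },
            index=ids,
        )
        scale = np.ones(len(ids))
        if phase_scale:
            scale = np.array([phase_scale[int(s.split("_")[1])] for s in ids])
        X = rng.normal(size=(len(ids), 8)) * scale[:, None]
        return pd.DataFrame(X, index=ids), design

    def test_identical_samples_all_null(self):
        ids = [f"W{w}_{v}" for w in range(6) for v in range(1, 5)]
        design = pd.DataFrame(
            {
                "woman": [s.split("_")[0] for s in ids],
                "visit_number": [int(s.split("_")[1]) for s in ids],
            },
            index=ids,
        )
        df = pd.DataFrame(np.ones((len(ids), 4)), index=ids)
        res = diversity.per_phase_beta(_dist(df), design)
        assert (res.summaries["summary"] == 0).all()
        assert (res.tests["p_wilcoxon"] == 1.0).all()

    def test_bonferroni_is_sixfold(self):
        rng = np.random.default_rng(0)
        df, design = self._cohort(12, rng)
        res = diversity.per_phase_beta(_dist(df), design)
        assert res.n_comparisons == 6
        assert np.allclose(
            res.tests["p_wilcoxon_bonf"],
            np.minimum(1.0, res.tests["p_wilcoxon"] * 6),
        )

    def test_inflated_phase_detected(self):
        # follicular dispersion doubled: its summary is greatest and the
        # follicular-vs-ovulatory contrast is significant
        rng = np.random.default_rng(5)
        df, design = self._cohort(60, rng, phase_scale={1: 2.0, 2: 1.0, 3: 1.0, 4: 1.0})
        res = diversity.per_phase_beta(_dist(df), design)
        by_phase = res.summaries.groupby("visit_number")["summary"].mean()
        assert by_phase.idxmax() == 1
        row = res.tests.set_index("comparison").loc["follicular_vs_ovulatory"]
        assert row["p_wilcoxon"] < 0.05


class TestSelfVsRandom:
    def _identical_within_woman(self, n_women=14):
        ids = [f"W{w}_{v}" for w in range(n_women) for v in range(1, 5)]
        design = pd.DataFrame(
            {
                "woman": [s.split("_")[0] for s in ids],
                "visit_number": [int(s.split("_")[1]) for s in ids],
            },
            index=ids,
        )
        rng = np.random.default_rng(1)
        base = rng.normal(size=(n_women, 5)) * 5
        X = np.array([base[int(s.split("_")[0][1:])] for s in ids])
        return pd.DataFrame(X, index=ids), design

    def test_forced_separation(self):
        df, design = self._identical_within_woman()
        res = diversity.self_vs_random(_dist(df), design, n_random=5, seed=0)
        self_vals = res.summaries.loc[res.summaries["replicate"] == 0, "summary"]
        rand_vals = res.summaries.loc[res.summaries["replicate"] > 0, "summary"]
        assert (self_vals == 0).all()
        assert (rand_vals > 0).all()
        assert (res.tests["p_wilcoxon"] < 1e-4).all()

    def test_self_summaries_invariant_to_seed(self, default_cohort):
        from cyclevag import composition

        rel = composition.to_relative_abundance(default_cohort["counts"])
        clr = composition.clr_transform(rel)
        adj = composition.residualize(clr, default_cohort["metadata"], 2)
        d = diversity.euclidean_clr(adj)
        design = default_cohort["metadata"][["woman", "visit_number"]]
        r1 = diversity.self_vs_random(d, design, n_random=2, seed=1)
        r2 = diversity.self_vs_random(d, design, n_random=2, seed=99)
        s1 = r1.summaries.loc[r1.summaries["replicate"] == 0, "summary"].to_numpy()
        s2 = r2.summaries.loc[r2.summaries["replicate"] == 0, "summary"].to_numpy()
        assert np.array_equal(s1, s2)

    def test_bonferroni_over_replicates(self):
        df, design = self._identical_within_woman(10)
        res = diversity.self_vs_random(_dist(df), design, n_random=4, seed=2)
        assert res.n_comparisons == 4
        assert np.allclose(
            res.tests["p_wilcoxon_bonf"],
            np.minimum(1.0, res.tests["p_wilcoxon"] * 4),
        )
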