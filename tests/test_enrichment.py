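"""Quasi-binomial IRLS fits and the per-category enrichment tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from goglm.enrichment import (
    DegenerateCategoryError,
    FitError,
    fit_quasibinomial,
    local_pcu_test,
    run_enrichment,
)
from goglm.enrichment import test_category as category_test
from goglm.enrichment import test_category_uncorrected as category_test_uncorrected
from goglm.ontology import AnnotationMap, GoDag, GoTerm, propagate
from goglm.significance import LengthSpec


def _two_by_two(a, b, c, d):
    """y = row indicator (category), x = column indicator (DE)."""
    x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    return y, np.column_stack([np.ones_like(x), x])


class TestFitQuasibinomial:
    @pytest.mark.parametrize("mean", [0.1, 0.25, 0.5, 0.8])
    def test_intercept_only_closed_form(self, mean):
        n = 200
        y = np.zeros(n)
        y[: int(mean * n)] = 1.0
        fit = fit_quasibinomial(y, np.ones((n, 1)))
        assert fit.converged
        assert fit.beta[0] == pytest.approx(np.log(mean / (1 - mean)), abs=1e-6)

    @pytest.mark.parametrize("cells", [(30, 10, 15, 45), (12, 8, 20, 40), (5, 25, 7, 63)])
    def test_saturated_two_by_two_closed_form(self, cells):
        a, b, c, d = cells
        y, X = _two_by_two(a, b, c, d)
        fit = fit_quasibinomial(y, X)
        n = a + b + c + d
        assert fit.beta[1] == pytest.approx(np.log(a * d / (b * c)), abs=1e-6)
        # ungrouped binary data with cell-wise fitted means: Pearson X^2 = n
        assert fit.dispersion == pytest.approx(n / (n - 2), rel=1e-6)
        # model-based variance of the log odds ratio
        expected_var = fit.dispersion * (1 / a + 1 / b + 1 / c + 1 / d)
        assert fit.cov[1, 1] == pytest.approx(expected_var, rel=1e-6)

    def test_matches_statsmodels_quasibinomial(self):
        rng = np.random.default_rng(42)
        n = 400
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.exponential(size=n)])
        eta = -1.0 + 0.8 * X[:, 1] - 0.4 * X[:, 2]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        ours = fit_quasibinomial(y, X)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit(scale="X2")
        np.testing.assert_allclose(ours.beta, ref.params, atol=1e-6)
        np.testing.assert_allclose(ours.dispersion, ref.scale, rtol=1e-6)
        np.testing.assert_allclose(ours.cov, ref.cov_params(), rtol=1e-5)

    def test_zero_variance_column_dropped(self):
        rng = np.random.default_rng(0)
        n = 100
        X = np.column_stack([np.ones(n), rng.normal(size=n), np.full(n, 7.0)])
        y = (rng.random(n) < 0.4).astype(float)
        fit = fit_quasibinomial(y, X)
        assert not fit.kept[2]
        assert np.isnan(fit.beta[2])
        assert fit.df_resid == n - 2

    def test_rank_deficient_rejected(self):
        n = 50
        x = np.linspace(0, 1, n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        y = (x > 0.5).astype(float)
        with pytest.raises(FitError):
            fit_quasibinomial(y, X)

    def test_non_binary_rejected(self):
        with pytest.raises(FitError):
            fit_quasibinomial(np.array([0.0, 0.5, 1.0]), np.ones((3, 1)))

    def test_too_few_observations(self):
        X = np.array([[1.0, 0.5, 2.0], [1.0, 1.5, 3.0]])
        with pytest.raises(FitError):
            fit_quasibinomial(np.array([0.0, 1.0]), X)

    def test_separation_flagged(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = x.copy()
        fit = fit_quasibinomial(y, np.column_stack([np.ones_like(x), x]))
        assert not fit.converged
        assert fit.note == "separation"


def _universe(n, lengths, gene_prefix="g"):
    return pd.DataFrame(
        {"gene_id": [f"{gene_prefix}{i}" for i in range(n)], "length": lengths}
    )


class TestCategoryTests:
    def test_binary_s_equals_log_odds_ratio(self):
        a, b, c, d = 30, 10, 15, 45
        n = a + b + c + d
        uni = _universe(n, np.ones(n))
        s = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
        members = set(uni["gene_id"][: a + b])
        res = category_test_uncorrected(uni, members, s)
        assert res.beta1 == pytest.approx(np.log(a * d / (b * c)), abs=1e-6)

    def test_constant_length_reduces_to_uncorrected(self):
        rng = np.random.default_rng(3)
        n = 300
        uni = _universe(n, np.full(n, 850.0))
        s = rng.exponential(size=n)
        members = set(uni["gene_id"][rng.random(n) < 0.3])
        full = category_test(uni, members, s, LengthSpec("log"))
        reduced = category_test_uncorrected(uni, members, s)
        assert full.beta1 == pytest.approx(reduced.beta1, abs=1e-8)
        assert full.se1 == pytest.approx(reduced.se1, abs=1e-8)
        assert full.p_enrich == pytest.approx(reduced.p_enrich, abs=1e-8)

    def test_degenerate_membership_raises(self):
        uni = _universe(10, np.ones(10))
        s = np.arange(10.0)
        with pytest.raises(DegenerateCategoryError):
            category_test(uni, set(uni["gene_id"]), s)
        with pytest.raises(DegenerateCategoryError):
            category_test(uni, set(), s)

    def test_zero_variance_significance_flagged(self):
        uni = _universe(20, np.exp(np.linspace(3, 8, 20)))
        res = category_test(uni, {"g0", "g1"}, np.zeros(20))
        assert not res.converged
        assert "zero-variance" in res.note
        assert np.isnan(res.p_enrich)

    def test_wald_comparable_to_chisquare_on_2x2(self):
        a, b, c, d = 30, 10, 15, 45
        n = a + b + c + d
        uni = _universe(n, np.ones(n))
        s = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
        members = set(uni["gene_id"][: a + b])
        res = category_test_uncorrected(uni, members, s)
        chi2_stat = stats.chi2_contingency([[a, b], [c, d]], correction=False)[0]
        # Wald and Pearson statistics agree to first order; the Wald test of
        # the log odds ratio is slightly conservative at strong effects
        assert abs(res.wald_stat) == pytest.approx(np.sqrt(chi2_stat), rel=0.15)
        assert res.p_two_sided < 1e-4

    def test_null_calibration_small(self):
        """Membership independent of (s, l): one-sided p roughly uniform."""
        rng = np.random.default_rng(11)
        n, reps = 800, 200
        pvals = []
        for _ in range(reps):
            uni = _universe(n, np.exp(rng.normal(6, 0.7, n)))
            s = rng.exponential(size=n)
            members = set(uni["gene_id"][rng.permutation(n)[:120]])
            pvals.append(category_test(uni, members, s).p_enrich)
        frac = np.mean(np.array(pvals) < 0.05)
        # 3-sigma binomial band around 0.05
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)


class TestRunEnrichment:
    def _setup(self, seed=5, n=400, n_terms=6):
        rng = np.random.default_rng(seed)
        uni = _universe(n, np.exp(rng.normal(6, 0.7, n)))
        s = rng.exponential(size=n)
        terms = {}
        for t in range(n_terms):
            terms[f"T{t}"] = set(uni["gene_id"][rng.random(n) < 0.2])
        return uni, s, terms

    def test_ranks_follow_pvalues(self):
        uni, s, terms = self._setup()
        out = run_enrichment(uni, terms, terms.keys(), s, LengthSpec("log"))
        ranked = out.dropna(subset=["rank"]).sort_values("rank")
        assert ranked["p_enrich"].is_monotonic_increasing
        assert ranked["rank"].tolist() == list(range(1, len(ranked) + 1))

    def test_empty_terms_rejected(self):
        uni, s, terms = self._setup()
        with pytest.raises(ValueError):
            run_enrichment(uni, terms, [], s)

    def test_rank_order_invariant_to_affine_s(self):
        uni, s, terms = self._setup(seed=8)
        a = run_enrichment(uni, terms, terms.keys(), s, LengthSpec("log"))
        b = run_enrichment(uni, terms, terms.keys(), 2.5 * s + 7.0, LengthSpec("log"))
        merged = a.merge(b, on="term_id", suffixes=("_a", "_b"))
        assert (merged["rank_a"] == merged["rank_b"]).all()

    def test_unknown_mode_rejected(self):
        uni, s, terms = self._setup()
        with pytest.raises(ValueError):
            run_enrichment(uni, terms, terms.keys(), s, mode="sideways")

    def test_degenerate_category_reported_unranked(self):
        uni, s, terms = self._setup()
        terms["ALL"] = set(uni["gene_id"])
        out = run_enrichment(uni, terms, terms.keys(), s, LengthSpec("log"))
        row = out[out["term_id"] == "ALL"].iloc[0]
        assert pd.isna(row["rank"])
        assert "degenerate" in row["note"]


def _pcu_fixture():
    """Root with two parents; the tested term is a child of both."""
    terms = {
        "GO:1": GoTerm("GO:1", "root", "BP", set()),
        "GO:2": GoTerm("GO:2", "p1", "BP", {"GO:1"}),
        "GO:3": GoTerm("GO:3", "p2", "BP", {"GO:1"}),
        "GO:4": GoTerm("GO:4", "child", "BP", {"GO:2", "GO:3"}),
    }
    return GoDag(terms=terms, roots={"GO:1"})


class TestLocalPcu:
    def test_local_signal_beats_diluted_global(self):
        rng = np.random.default_rng(21)
        dag = _pcu_fixture()
        genes = [f"g{i}" for i in range(800)]
        members = set(genes[:20])          # term genes, inside the parents
        p1_extra = set(genes[20:110])      # parent-1 background
        p2_extra = set(genes[110:200])     # parent-2 background
        rootonly = set(genes[200:])        # outside the parent union
        direct = {
            "GO:4": members,
            "GO:2": p1_extra,
            "GO:3": p2_extra,
            "GO:1": rootonly,
        }
        ann = propagate(dag, AnnotationMap(direct=direct))
        uni = pd.DataFrame(
            {"gene_id": genes, "length": np.exp(rng.normal(6, 0.5, len(genes)))}
        )
        s = rng.normal(0, 1, len(genes))
        idx = {g: i for i, g in enumerate(genes)}
        # members stand out inside the parent union, but the bulk of the
        # universe outside the union carries the same elevated scores, so
        # the global contrast is diluted
        for g in members | rootonly:
            s[idx[g]] += 1.2
        local = local_pcu_test(dag, ann, "GO:4", uni, s, LengthSpec("log"))
        glob = category_test(uni, ann.propagated["GO:4"], s, LengthSpec("log"))
        assert local.n_universe == 200
        assert local.p_enrich < glob.p_enrich

    def test_single_parent_equals_restricted_global(self, chain_dag, chain_annotation):
        rng = np.random.default_rng(2)
        genes = ["g1", "g2"] + [f"x{i}" for i in range(48)]
        direct = dict(chain_annotation.direct)
        direct["GO:0000002"] = {"g2", *genes[2:30]}
        ann = propagate(chain_dag, AnnotationMap(direct=direct))
        uni = pd.DataFrame(
            {"gene_id": genes, "length": np.exp(rng.normal(6, 0.5, 50))}
        )
        s = rng.exponential(size=50)
        local = local_pcu_test(chain_dag, ann, "GO:0000003", uni, s)
        parent_genes = ann.propagated["GO:0000002"]
        mask = uni["gene_id"].isin(parent_genes).to_numpy()
        manual = category_test(
            uni[mask].reset_index(drop=True),
            ann.propagated["GO:0000003"],
            s[mask],
        )
        assert local.beta1 == pytest.approx(manual.beta1, abs=1e-10)
        assert local.p_enrich == pytest.approx(manual.p_enrich, abs=1e-10)

    def test_root_is_skipped(self, chain_dag, chain_annotation):
        uni = pd.DataFrame({"gene_id": ["g1", "g2"], "length": [100.0, 200.0]})
        res = local_pcu_test(
            chain_dag, chain_annotation, "GO:0000001", uni, np.array([1.0, 2.0])
        )
        assert "skipped" in res.note
        assert np.isnan(res.p_enrich)

    def test_saturating_term_flagged(self, chain_dag, chain_annotation):
        # leaf's genes equal mid's genes -> local universe == member set
        direct = {"GO:0000003": {"g1", "g2"}, "GO:0000002": set()}
        ann = propagate(chain_dag, AnnotationMap(direct=direct))
        uni = pd.DataFrame({"gene_id": ["g1", "g2"], "length": [100.0, 200.0]})
        res = local_pcu_test(
            chain_dag, ann, "GO:0000003", uni, np.array([1.0, 2.0])
        )
        assert "degenerate" in res.note
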