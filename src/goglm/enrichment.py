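"""Logistic-regression GO enrichment with length-bias correction.

For each GO category, membership y_i (1 if gene i belongs to the
category) is regressed on the gene's DE significance s_i:

    logit P(y_i = 1) = b0 + b1 * s_i                (uncorrected)
    logit P(y_i = 1) = b0 + b1 * s_i + b2 * g(l_i)  (length-corrected)

where g(l) is the gene length or its log.  A positive b1 means genes
with stronger DE evidence have higher odds of category membership; the
length covariate removes the confounding that arises because RNA-Seq DE
tests are more powerful for long transcripts while category membership
is itself correlated with length.

Fits use a quasi-binomial model: the binomial likelihood is maximised by
iteratively reweighted least squares (IRLS), and the Pearson dispersion
estimate phi = X^2_Pearson / (n - p) absorbs global over- or
under-dispersion.  Two coefficient covariances are computed: the
model-based phi * (X'WX)^-1 and a sandwich (robust) estimator.  Wald
inference uses the sandwich covariance by default because a single
scalar dispersion cannot absorb misfit that is concentrated along a
covariate — exactly the situation when category membership has a sharp
length boundary — whereas the two agree when the model is well
specified.  Wald statistics b1/se1 are referred to a Student t
distribution with n - p degrees of freedom, the usual convention when
the dispersion is estimated.  The reported enrichment p-value is
one-sided (upper tail, b1 > 0); the two-sided p is also returned.

A parent-child-union (PCU) local test is provided: the regression for a
term is refit on the sub-universe of genes annotated to the union of the
term's direct parents, so a term is only called enriched if it is
enriched *relative to its parents*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ontology import AnnotationMap, GoDag, direct_parents
from .significance import LengthSpec

logger = logging.getLogger(__name__)

MAX_ITER = 25
DEVIANCE_RTOL = 1e-8
SEPARATION_BETA = 15.0
SEPARATION_SE = 1e3


class FitError(ValueError):
    """The design matrix cannot support the requested fit."""


class DegenerateCategoryError(ValueError):
    """Membership vector is constant (all genes in or out of the category)."""


@dataclass
class GlmFit:
    """Result of a quasi-binomial IRLS fit.

    ``beta``, ``cov`` and ``cov_robust`` are indexed by the columns of
    the original design matrix; entries for dropped zero-variance
    columns are NaN.  ``cov`` is the quasi-likelihood (model-based)
    covariance phi * (X'WX)^-1; ``cov_robust`` is the sandwich estimator
    (X'WX)^-1 (X' diag((y-mu)^2) X) (X'WX)^-1, which agrees with ``cov``
    under a correctly specified mean model but stays valid when the
    misfit varies with a covariate (a single scalar dispersion cannot
    absorb that).  ``df_resid`` is n minus the number of columns fitted.
    """

    beta: np.ndarray
    cov: np.ndarray
    cov_robust: np.ndarray
    dispersion: float
    converged: bool
    n_iter: int
    n_obs: int
    df_resid: int
    kept: np.ndarray  # boolean mask over original columns
    note: str = ""

    def se(self, robust: bool = False) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_robust if robust else self.cov))


@dataclass
class EnrichmentResult:
    """Per-category regression output."""

    term_id: str | None
    n_category: int
    n_universe: int
    median_length_bp: float
    beta1: float
    se1: float
    wald_stat: float
    p_enrich: float
    p_two_sided: float
    dispersion: float
    converged: bool
    rank: int | None = None
    note: str = ""


def _binomial_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
    return -2.0 * float(np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)))


def fit_quasibinomial(
    y: np.ndarray,
    X: np.ndarray,
    max_iter: int = MAX_ITER,
    tol: float = DEVIANCE_RTOL,
) -> GlmFit:
    """Fit a binary-response logistic regression by IRLS with quasi-binomial
    dispersion.

    Non-intercept columns with zero variance are dropped with a logged
    note (the first column is treated as the intercept and always kept).
    A rank-deficient design after that cleaning raises :class:`FitError`.
    Apparent separation (|beta| > 15 or an SE > 1e3) marks the fit
    non-converged rather than failing.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape
    if y.shape[0] != n:
        raise FitError("y and X have incompatible shapes")
    if not np.isin(y, (0.0, 1.0)).all():
        raise FitError("y must be binary 0/1")

    kept = np.ones(k, dtype=bool)
    for j in range(1, k):
        if np.ptp(X[:, j]) == 0.0:
            kept[j] = False
    if (~kept).any():
        logger.info("dropped %d zero-variance design column(s)", int((~kept).sum()))
    Xk = X[:, kept]
    p = Xk.shape[1]
    if n <= p:
        raise FitError(f"n={n} observations cannot support {p} coefficients")
    if np.linalg.matrix_rank(Xk) < p:
        raise FitError("design matrix is rank deficient after cleaning")

    # IRLS with the standard mu = (y + 1/2) / 2 start.
    mu = (y + 0.5) / 2.0
    eta = np.log(mu / (1.0 - mu))
    deviance = _binomial_deviance(y, mu)
    beta_k = np.zeros(p)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        sw = np.sqrt(w)
        beta_k, *_ = np.linalg.lstsq(Xk * sw[:, None], z * sw, rcond=None)
        eta = Xk @ beta_k
        mu = 1.0 / (1.0 + np.exp(-eta))
        new_dev = _binomial_deviance(y, mu)
        if abs(new_dev - deviance) / (abs(new_dev) + 0.1) < tol:
            deviance = new_dev
            converged = True
            break
        deviance = new_dev

    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    resid = y - mu
    pearson = float(np.sum(resid**2 / w))
    df_resid = n - p
    dispersion = pearson / df_resid
    xtwx = Xk.T @ (Xk * w[:, None])
    bread = np.linalg.inv(xtwx)
    cov_k = dispersion * bread
    meat = Xk.T @ (Xk * (resid**2)[:, None])
    cov_robust_k = bread @ meat @ bread

    note = ""
    if np.abs(beta_k).max() > SEPARATION_BETA or np.sqrt(
        np.diag(cov_k)
    ).max() > SEPARATION_SE:
        converged = False
        note = "separation"

    beta = np.full(k, np.nan)
    beta[kept] = beta_k
    cov = np.full((k, k), np.nan)
    cov[np.ix_(kept, kept)] = cov_k
    cov_robust = np.full((k, k), np.nan)
    cov_robust[np.ix_(kept, kept)] = cov_robust_k
    return GlmFit(
        beta=beta,
        cov=cov,
        cov_robust=cov_robust,
        dispersion=dispersion,
        converged=converged,
        n_iter=n_iter,
        n_obs=n,
        df_resid=df_resid,
        kept=kept,
        note=note,
    )


def _wald_result(
    term_id: str | None,
    fit: GlmFit,
    y: np.ndarray,
    lengths: np.ndarray,
    note: str = "",
    wald_cov: str = "robust",
) -> EnrichmentResult:
    if wald_cov not in ("robust", "model"):
        raise ValueError("wald_cov must be 'robust' or 'model'")
    covmat = fit.cov_robust if wald_cov == "robust" else fit.cov
    beta1 = float(fit.beta[1])
    se1 = float(np.sqrt(covmat[1, 1]))
    wald = beta1 / se1
    p_one = float(stats.t.sf(wald, fit.df_resid))
    p_two = float(2.0 * stats.t.sf(abs(wald), fit.df_resid))
    members = y.astype(bool)
    return EnrichmentResult(
        term_id=term_id,
        n_category=int(y.sum()),
        n_universe=int(y.size),
        median_length_bp=float(np.median(lengths[members])),
        beta1=beta1,
        se1=se1,
        wald_stat=wald,
        p_enrich=p_one,
        p_two_sided=p_two,
        dispersion=fit.dispersion,
        converged=fit.converged,
        note=note or fit.note,
    )


def _flagged_result(
    term_id: str | None, y: np.ndarray, lengths: np.ndarray, note: str
) -> EnrichmentResult:
    members = y.astype(bool)
    med = float(np.median(lengths[members])) if members.any() else float("nan")
    return EnrichmentResult(
        term_id=term_id,
        n_category=int(y.sum()),
        n_universe=int(y.size),
        median_length_bp=med,
        beta1=float("nan"),
        se1=float("nan"),
        wald_stat=float("nan"),
        p_enrich=float("nan"),
        p_two_sided=float("nan"),
        dispersion=float("nan"),
        converged=False,
        note=note,
    )


def _membership(universe: pd.DataFrame, members) -> np.ndarray:
    return universe["gene_id"].isin(set(members)).to_numpy()


def test_category(
    universe: pd.DataFrame,
    members,
    s: np.ndarray,
    length_spec: LengthSpec | None = None,
    term_id: str | None = None,
    wald_cov: str = "robust",
) -> EnrichmentResult:
    """Length-corrected enrichment test for one category.

    ``universe`` is a DataFrame with columns ``gene_id`` and ``length``
    (one row per gene, aligned with ``s``); ``members`` is the set of
    gene ids annotated to the category.
    """
    length_spec = length_spec or LengthSpec()
    s = np.asarray(s, dtype=float)
    lengths = universe["length"].to_numpy(dtype=float)
    y = _membership(universe, members).astype(float)
    if y.sum() == 0 or y.sum() == y.size:
        raise DegenerateCategoryError(
            "category membership is constant over the universe"
        )
    if np.ptp(s) == 0.0:
        return _flagged_result(term_id, y, lengths, "zero-variance significance")
    X = np.column_stack([np.ones_like(s), s, length_spec.apply(lengths)])
    fit = fit_quasibinomial(y, X)
    return _wald_result(term_id, fit, y, lengths, wald_cov=wald_cov)


def test_category_uncorrected(
    universe: pd.DataFrame,
    members,
    s: np.ndarray,
    term_id: str | None = None,
    wald_cov: str = "robust",
) -> EnrichmentResult:
    """Enrichment test without the length covariate (design [1, s])."""
    s = np.asarray(s, dtype=float)
    lengths = universe["length"].to_numpy(dtype=float)
    y = _membership(universe, members).astype(float)
    if y.sum() == 0 or y.sum() == y.size:
        raise DegenerateCategoryError(
            "category membership is constant over the universe"
        )
    if np.ptp(s) == 0.0:
        return _flagged_result(term_id, y, lengths, "zero-variance significance")
    X = np.column_stack([np.ones_like(s), s])
    fit = fit_quasibinomial(y, X)
    return _wald_result(term_id, fit, y, lengths, wald_cov=wald_cov)


def local_pcu_test(
    dag: GoDag,
    ann: AnnotationMap,
    term: str,
    universe: pd.DataFrame,
    s: np.ndarray,
    length_spec: LengthSpec | None = None,
    wald_cov: str = "robust",
) -> EnrichmentResult:
    """Parent-child-union local enrichment test for one term.

    The regression is fit on the genes of ``universe`` annotated
    (after propagation) to the union of the term's direct parents, so the
    test asks whether the term is enriched relative to its parents rather
    than to the whole universe.  Namespace roots have no parents and
    return a skipped marker.
    """
    if ann.propagated is None:
        raise ValueError("annotations must be propagated for the local test")
    s = np.asarray(s, dtype=float)
    lengths = universe["length"].to_numpy(dtype=float)
    parents = direct_parents(dag, term)
    members = ann.propagated.get(term, set())
    y_global = _membership(universe, members).astype(float)
    if not parents:
        return _flagged_result(term, y_global, lengths, "skipped: namespace root")

    parent_union: set[str] = set()
    for p in parents:
        parent_union |= ann.propagated.get(p, set())
    local_mask = _membership(universe, parent_union)
    local_universe = universe.loc[local_mask].reset_index(drop=True)
    local_members = members & parent_union
    if local_mask.sum() == 0 or len(local_members) >= int(local_mask.sum()):
        return _flagged_result(
            term, y_global, lengths, "degenerate: term saturates its parent union"
        )
    result = test_category(
        local_universe, local_members, s[local_mask], length_spec,
        term_id=term, wald_cov=wald_cov,
    )
    return result


def run_enrichment(
    universe: pd.DataFrame,
    ann,
    terms,
    s: np.ndarray,
    length_spec: LengthSpec | None = None,
    mode: str = "global",
    dag: GoDag | None = None,
    include_nonconverged: bool = False,
    wald_cov: str = "robust",
) -> pd.DataFrame:
    """Test every term and return a ranked category table.

    ``ann`` is an :class:`AnnotationMap` (propagated) or a plain mapping
    ``term_id -> gene-id set``.  ``mode`` is ``global`` (length-corrected),
    ``uncorrected`` (no length covariate) or ``local`` (parent-child
    union; requires ``dag`` and an AnnotationMap).  Ranks are assigned by
    ascending one-sided enrichment p; ties break by |Wald statistic|
    descending, then term id.  Non-converged or degenerate categories are
    reported but excluded from ranking unless ``include_nonconverged``.
    """
    terms = sorted(terms)
    if not terms:
        raise ValueError("no terms to test")
    if mode not in ("global", "uncorrected", "local"):
        raise ValueError(f"unknown mode {mode!r}")

    if isinstance(ann, AnnotationMap):
        if ann.propagated is None:
            raise ValueError("AnnotationMap must be propagated")
        term_genes = ann.propagated
    else:
        term_genes = ann

    rows = []
    lengths = universe["length"].to_numpy(dtype=float)
    for term in terms:
        try:
            if mode == "local":
                if dag is None or not isinstance(ann, AnnotationMap):
                    raise ValueError("local mode requires a GoDag and AnnotationMap")
                res = local_pcu_test(
                    dag, ann, term, universe, s, length_spec, wald_cov=wald_cov
                )
            elif mode == "global":
                res = test_category(
                    universe, term_genes.get(term, set()), s, length_spec, term,
                    wald_cov=wald_cov,
                )
            else:
                res = test_category_uncorrected(
                    universe, term_genes.get(term, set()), s, term,
                    wald_cov=wald_cov,
                )
        except DegenerateCategoryError as exc:
            y = _membership(universe, term_genes.get(term, set())).astype(float)
            res = _flagged_result(term, y, lengths, f"degenerate: {exc}")
        rows.append(res)

    df = pd.DataFrame(
        {
            "term_id": [r.term_id for r in rows],
            "n_category": [r.n_category for r in rows],
            "n_universe": [r.n_universe for r in rows],
            "median_length": [r.median_length_bp for r in rows],
            "beta1": [r.beta1 for r in rows],
            "se1": [r.se1 for r in rows],
            "wald_stat": [r.wald_stat for r in rows],
            "p_enrich": [r.p_enrich for r in rows],
            "p_two_sided": [r.p_two_sided for r in rows],
            "dispersion": [r.dispersion for r in rows],
            "converged": [r.converged for r in rows],
            "note": [r.note for r in rows],
        }
    )
    rankable = (df["converged"] | include_nonconverged) & df["p_enrich"].notna()
    order = df.loc[rankable].sort_values(
        by=["p_enrich", "wald_stat", "term_id"],
        ascending=[True, False, True],
        key=lambda col: col.abs() if col.name == "wald_stat" else col,
    )
    df["rank"] = pd.Series(pd.NA, index=df.index, dtype="Int64")
    df.loc[order.index, "rank"] = np.arange(1, len(order) + 1)
    return df.sort_values(
        by=["rank", "term_id"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
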