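"""Contingency-table enrichment baselines: Fisher and length-weighted
Wallenius tests.

The classical enrichment test dichotomizes DE results and cross-
classifies genes by category membership and DE call in a 2x2 table; the
one-sided Fisher exact test is the upper tail of the central
hypergeometric distribution.  To compensate for length bias, the
GOseq-style approach estimates the probability of being called DE as a
monotone function of transcript length (the probability weighting
function, PWF) and replaces the central hypergeometric null by the
Wallenius noncentral hypergeometric distribution, whose odds parameter is
the ratio of mean PWF weights inside versus outside the category.  With a
constant PWF the odds are 1 and the Wallenius test reduces exactly to
Fisher's exact test.

The Wallenius tail here is computed by exact dynamic programming over the
sequential biased-urn draws (probabilities accumulated draw by draw), not
by an asymptotic approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.isotonic import IsotonicRegression


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 cross-classification: rows in/out of category, columns DE/non-DE."""

    n11: int  # category & DE
    n12: int  # category & non-DE
    n21: int  # non-category & DE
    n22: int  # non-category & non-DE

    def __post_init__(self) -> None:
        cells = (self.n11, self.n12, self.n21, self.n22)
        if any(c < 0 for c in cells):
            raise ValueError("contingency cells must be nonnegative")
        if sum(cells) == 0:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.n11 + self.n12 + self.n21 + self.n22

    @property
    def n_category(self) -> int:
        return self.n11 + self.n12

    @property
    def n_de(self) -> int:
        return self.n11 + self.n21

    def margins(self) -> dict[str, int]:
        return {
            "row_category": self.n_category,
            "row_noncategory": self.n21 + self.n22,
            "col_de": self.n_de,
            "col_nonde": self.n12 + self.n22,
            "total": self.total,
        }


def build_contingency(de_flags, members, universe) -> ContingencyTable:
    """Cross-classify ``universe`` genes by membership and DE call.

    ``universe`` is a sequence of gene ids aligned with ``de_flags``;
    ``members`` is the category's gene-id set (must lie in the universe).
    """
    genes = list(universe)
    if not genes:
        raise ValueError("empty gene universe")
    de = np.asarray(de_flags).astype(bool)
    if de.shape[0] != len(genes):
        raise ValueError("de_flags and universe have different lengths")
    members = set(members)
    extra = members - set(genes)
    if extra:
        raise ValueError(f"{len(extra)} member genes are not in the universe")
    in_cat = np.array([g in members for g in genes])
    return ContingencyTable(
        n11=int(np.sum(in_cat & de)),
        n12=int(np.sum(in_cat & ~de)),
        n21=int(np.sum(~in_cat & de)),
        n22=int(np.sum(~in_cat & ~de)),
    )


def fisher_test(t: ContingencyTable) -> tuple[float, float]:
    """One-sided Fisher exact test for enrichment.

    Returns ``(odds_ratio, p)`` with p = P(X >= n11) under the central
    hypergeometric distribution with the table's margins.  The sample
    odds ratio (n11*n22)/(n12*n21) is reported, +inf when the denominator
    is zero; it equals exp(beta1) of the saturated logistic fit on the
    same table.
    """
    if t.n12 * t.n21 == 0:
        odds_ratio = float("inf") if t.n11 * t.n22 > 0 else float("nan")
    else:
        odds_ratio = (t.n11 * t.n22) / (t.n12 * t.n21)
    p = float(stats.hypergeom.sf(t.n11 - 1, t.total, t.n_category, t.n_de))
    return odds_ratio, min(p, 1.0)


@dataclass
class PWF:
    """Monotone probability weighting function, normalized to mean 1.

    Piecewise-linear interpolation between bin centres of an isotonic fit
    of P(DE | length); constant extrapolation beyond the outermost bins.
    """

    bin_lengths: np.ndarray
    bin_weights: np.ndarray  # already scaled to mean 1 over the fit universe

    def __call__(self, lengths) -> np.ndarray:
        lengths = np.asarray(lengths, dtype=float)
        if self.bin_lengths.size == 1:
            return np.full(lengths.shape, self.bin_weights[0])
        return np.interp(lengths, self.bin_lengths, self.bin_weights)


def estimate_pwf(de_flags, lengths, n_bins: int = 20) -> PWF:
    """Estimate P(DE | length) as a monotone nondecreasing weight function.

    Genes are sorted by length into equal-count bins; the per-bin DE
    proportion is smoothed by isotonic regression against the bin mean
    length, interpolated linearly between bin centres, floored at a small
    positive value, and normalized to mean weight 1 over the input genes.
    Degenerate input (a single DE class, or all lengths equal) yields a
    constant PWF of 1.
    """
    de = np.asarray(de_flags).astype(float)
    lengths = np.asarray(lengths, dtype=float)
    if de.shape != lengths.shape:
        raise ValueError("de_flags and lengths have different shapes")
    if lengths.size < 2:
        raise ValueError("need at least two genes to estimate a PWF")

    if de.min() == de.max():
        warnings.warn(
            "all genes share one DE class; returning a constant PWF",
            stacklevel=2,
        )
        return PWF(np.array([np.median(lengths)]), np.array([1.0]))
    if np.ptp(lengths) == 0.0:
        return PWF(np.array([lengths[0]]), np.array([1.0]))

    order = np.argsort(lengths, kind="mergesort")
    n_bins = int(min(n_bins, max(1, np.unique(lengths).size)))
    splits = np.array_split(order, n_bins)
    centres = np.array([lengths[idx].mean() for idx in splits])
    props = np.array([de[idx].mean() for idx in splits])
    sizes = np.array([idx.size for idx in splits], dtype=float)

    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted = iso.fit_transform(centres, props, sample_weight=sizes)
    floor = max(fitted.max() * 1e-6, 1e-12)
    fitted = np.clip(fitted, floor, None)

    pwf = PWF(centres, fitted)
    scale = pwf(lengths).mean()
    return PWF(centres, fitted / scale)


def wallenius_pmf(m1: int, m2: int, n: int, odds: float) -> np.ndarray:
    """Exact Wallenius noncentral hypergeometric pmf by sequential DP.

    An urn holds ``m1`` weighted (category) and ``m2`` unweighted balls;
    ``n`` balls are drawn without replacement, each draw picking a
    weighted ball with probability proportional to ``odds`` times the
    remaining weighted count.  Returns P(X = x) for x = 0..n (entries
    outside the support are 0).
    """
    if min(m1, m2, n) < 0 or n > m1 + m2:
        raise ValueError("invalid urn configuration")
    if odds <= 0 or not np.isfinite(odds):
        raise ValueError("odds must be positive and finite")
    prob = np.zeros(n + 1)
    prob[0] = 1.0
    for k in range(n):
        x = np.arange(k + 1, dtype=float)
        w_white = np.clip(odds * (m1 - x), 0.0, None)
        w_black = np.clip(m2 - (k - x), 0.0, None)
        denom = w_white + w_black
        p_white = np.where(denom > 0, w_white / denom, 0.0)
        new = np.zeros(n + 1)
        new[: k + 1] = prob[: k + 1] * (1.0 - p_white)
        new[1 : k + 2] += prob[: k + 1] * p_white
        prob = new
    return prob


def wallenius_test(
    t: ContingencyTable, pwf: PWF, member_lengths, nonmember_lengths
) -> float:
    """One-sided length-corrected enrichment p-value.

    The Wallenius odds parameter is the ratio of the mean PWF weight of
    category genes to that of non-category genes; the p-value is the
    upper tail P(X >= n11) of the Wallenius distribution with the table's
    margins.  Degenerate margins (no DE genes or an empty category side)
    return p = 1.
    """
    member_lengths = np.asarray(member_lengths, dtype=float)
    nonmember_lengths = np.asarray(nonmember_lengths, dtype=float)
    if member_lengths.size != t.n_category or nonmember_lengths.size != (
        t.total - t.n_category
    ):
        raise ValueError("length vectors do not match the table margins")
    if t.n_de == 0 or t.n_category == 0 or t.n_category == t.total:
        return 1.0
    odds = float(pwf(member_lengths).mean() / pwf(nonmember_lengths).mean())
    pmf = wallenius_pmf(t.n_category, t.total - t.n_category, t.n_de, odds)
    p = float(pmf[t.n11 :].sum())
    return min(max(p, 0.0), 1.0)
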