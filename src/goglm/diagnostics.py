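"""Length-bias diagnostics for enrichment analyses.

These utilities quantify how strongly category membership is tied to
gene length (the precondition for length bias), how the enrichment
ranking tracks category length before and after correction, how uniform
null enrichment p-values are, how two rankings overlap at the top, and
how sensitive a contingency-table test is to the DE-call cut-off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .baselines import build_contingency, fisher_test
from .significance import dichotomize


@dataclass
class RankLengthProfile:
    """Categories binned by mean gene length, with mean enrichment rank.

    A negative Spearman trend (longer categories get better, i.e. lower,
    ranks) is the signature of uncorrected length bias.
    """

    table: pd.DataFrame  # columns: bin, mean_length, mean_rank, n_categories
    spearman_rho: float
    spearman_p: float


def length_category_association(members, universe_lengths) -> tuple[float, float]:
    """Welch two-sample t-test of log gene length inside vs outside a category.

    ``members`` is a boolean mask over the universe.  Returns
    ``(t_stat, two_sided_p)``.
    """
    members = np.asarray(members).astype(bool)
    lengths = np.asarray(universe_lengths, dtype=float)
    if lengths.min() <= 0:
        raise ValueError("lengths must be positive")
    x_in = np.log(lengths[members])
    x_out = np.log(lengths[~members])
    if x_in.size < 2 or x_out.size < 2:
        raise ValueError("need at least two genes in and out of the category")
    if np.ptp(x_in) == 0 and np.ptp(x_out) == 0 and x_in[0] == x_out[0]:
        return 0.0, 1.0
    res = stats.ttest_ind(x_in, x_out, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def association_prevalence(
    term_genes: dict[str, set],
    universe: pd.DataFrame,
    min_size: int = 10,
    alpha: float = 0.05,
) -> float:
    """Proportion of categories whose membership is length-associated.

    Runs the Welch test for every category with at least ``min_size``
    genes in the universe and returns the fraction significant at
    ``alpha``.  Categories with zero length variance in either group are
    untestable and counted as non-significant.
    """
    gene_ids = universe["gene_id"].to_numpy()
    lengths = universe["length"].to_numpy(dtype=float)
    tested = 0
    significant = 0
    for term, genes in term_genes.items():
        mask = np.isin(gene_ids, list(genes))
        size = int(mask.sum())
        if size < min_size or size > len(gene_ids) - 2:
            continue
        tested += 1
        x_in = np.log(lengths[mask])
        x_out = np.log(lengths[~mask])
        if np.ptp(x_in) == 0 or np.ptp(x_out) == 0:
            continue  # untestable: counted in the denominator only
        _, p = length_category_association(mask, lengths)
        if p < alpha:
            significant += 1
    if tested == 0:
        raise ValueError("no category passes the size filter")
    return significant / tested


def rank_length_profile(
    results: pd.DataFrame,
    lengths_by_category: dict[str, float] | None = None,
    n_bins: int = 300,
) -> RankLengthProfile:
    """Mean enrichment rank per category-length bin.

    ``results`` is a ranked enrichment table (``term_id``, ``rank`` and,
    unless ``lengths_by_category`` overrides it, ``median_length``).
    Categories are sorted by mean gene length and split into ``n_bins``
    equal-count bins; the Spearman correlation of bin mean length vs bin
    mean rank summarizes the trend.
    """
    df = results.dropna(subset=["rank"]).copy()
    if lengths_by_category is not None:
        df["median_length"] = df["term_id"].map(lengths_by_category)
    if len(df) < n_bins:
        warnings.warn(
            f"only {len(df)} ranked categories; reducing bins from {n_bins}",
            stacklevel=2,
        )
        n_bins = len(df)
    df = df.sort_values("median_length", kind="mergesort")
    splits = np.array_split(np.arange(len(df)), n_bins)
    rows = [
        {
            "bin": b,
            "mean_length": float(df["median_length"].to_numpy()[idx].mean()),
            "mean_rank": float(df["rank"].to_numpy(dtype=float)[idx].mean()),
            "n_categories": int(idx.size),
        }
        for b, idx in enumerate(splits)
    ]
    table = pd.DataFrame(rows)
    if len(table) > 1 and table["mean_rank"].nunique() > 1:
        rho, p = stats.spearmanr(table["mean_length"], table["mean_rank"])
    else:
        rho, p = 0.0, 1.0
    return RankLengthProfile(table=table, spearman_rho=float(rho), spearman_p=float(p))


def pvalue_uniformity(
    p_values, alpha_grid=(0.01, 0.05, 0.10)
) -> tuple[dict[float, float], float]:
    """Fractions of p-values below each alpha, plus the KS statistic vs U(0,1)."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    fractions = {float(a): float(np.mean(p < a)) for a in alpha_grid}
    ks = float(stats.kstest(p, "uniform").statistic)
    return fractions, ks


def ranking_overlap(rank_a, rank_b, k_grid) -> pd.DataFrame:
    """Top-k overlap proportions between two rankings of the same terms.

    ``rank_a``/``rank_b`` map term id -> rank (dict or Series).  Returns a
    DataFrame with columns ``k`` and ``overlap`` where overlap is
    |top-k(a) & top-k(b)| / k.  The measure is symmetric in its arguments.
    """
    a = pd.Series(rank_a).dropna()
    b = pd.Series(rank_b).dropna()
    if set(a.index) != set(b.index):
        raise ValueError("rankings cover different term sets")
    m = len(a)
    rows = []
    for k in k_grid:
        if k > m:
            warnings.warn(f"k={k} exceeds {m} terms; truncated", stacklevel=2)
            k = m
        top_a = set(a.nsmallest(k).index)
        top_b = set(b.nsmallest(k).index)
        rows.append({"k": k, "overlap": len(top_a & top_b) / k})
    return pd.DataFrame(rows)


def cutoff_sensitivity(
    records: pd.DataFrame,
    members,
    cutoff_grid,
    adjust: str = "none",
) -> pd.DataFrame:
    """Fisher enrichment p as a function of the DE-call p-value cut-off.

    For each cut-off the DE calls are re-dichotomized, the 2x2 table is
    rebuilt, and the one-sided Fisher p recorded.  Cut-offs that produce
    an empty (or exhaustive) DE set are flagged and reported with p = 1.
    """
    rows = []
    universe = records["gene_id"].tolist()
    for cutoff in cutoff_grid:
        if not (0.0 < cutoff <= 1.0):
            raise ValueError("cutoffs must lie in (0, 1]")
        if cutoff == 1.0:
            flags = np.ones(len(records), dtype=int)
        else:
            flags = dichotomize(records, cutoff, adjust=adjust)
        n_de = int(flags.sum())
        degenerate = n_de == 0 or n_de == len(flags)
        if degenerate:
            p = 1.0
        else:
            table = build_contingency(flags, members, universe)
            _, p = fisher_test(table)
        rows.append(
            {"cutoff": cutoff, "p_fisher": p, "n_de": n_de, "degenerate": degenerate}
        )
    return pd.DataFrame(rows)
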