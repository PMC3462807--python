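"""Per-gene differential-expression significance measures.

The enrichment regressions model GO-category membership as a function of
how significant each gene's differential-expression (DE) test was.  The
DE evidence can enter as a continuous score or be dichotomized at a
p-value cut-off; this module computes those measures and the length
covariate transform.

Available measures of DE significance for a p-value ``p``:

``neg_p``          -p (untransformed scale)
``neg_log_p``      -ln p
``double_log_p``   ln(-ln p) — the "d-log" transform; the inner log keeps
                   attention on the order of magnitude of p, the outer log
                   down-weighs extremely small p-values
``log_fc``         the supplied log2 fold change
``binary``         1 if p (optionally BH-adjusted) < cutoff, else 0

p-values are clamped to ``[eps, 1 - eps]`` before any log transform so
that p = 0 or p = 1 never produces an infinite score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MEASURES = ("neg_p", "neg_log_p", "double_log_p", "log_fc", "binary")
LENGTH_TRANSFORMS = ("log", "identity")


class ValidationError(ValueError):
    """A DE table row violates its contract (p out of range, length <= 0)."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene's DE result.

    ``length`` is the gene length in base pairs, defined as the median
    length of the gene's mature transcripts.
    """

    gene_id: str
    length: float
    p_value: float
    log_fc: float | None = None


@dataclass
class SignificanceSpec:
    """How to turn DE results into the regression predictor s_i."""

    measure: str = "double_log_p"
    binary_cutoff: float = 0.05
    binary_adjust: str = "none"  # {"none", "BH"}
    eps: float = 1e-15

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}; one of {MEASURES}")
        if not (0.0 < self.eps < 0.5):
            raise ValueError(f"eps must be in (0, 0.5), got {self.eps}")
        if not (0.0 < self.binary_cutoff < 1.0):
            raise ValueError("binary_cutoff must be in (0, 1)")
        if self.binary_adjust not in ("none", "BH"):
            raise ValueError("binary_adjust must be 'none' or 'BH'")


@dataclass
class LengthSpec:
    """How gene length enters the regression design."""

    transform: str = "log"

    def __post_init__(self) -> None:
        if self.transform not in LENGTH_TRANSFORMS:
            raise ValueError(
                f"unknown length transform {self.transform!r}; "
                f"one of {LENGTH_TRANSFORMS}"
            )

    def apply(self, lengths: np.ndarray) -> np.ndarray:
        lengths = np.asarray(lengths, dtype=float)
        if self.transform == "log":
            return np.log(lengths)
        return lengths


def load_de_table(
    path: str | Path,
    gene_col: str = "gene_id",
    p_col: str = "pvalue",
    length_col: str = "length",
    logfc_col: str = "logfc",
) -> pd.DataFrame:
    """Load a per-gene DE result table (TSV with a header row).

    Returns a DataFrame with columns ``gene_id``, ``length``, ``pvalue``
    and, when present in the input, ``logfc``.  Rows with missing length
    or p-value are dropped with a logged count; out-of-range values raise
    :class:`ValidationError` naming the offending gene.
    """
    df = pd.read_csv(path, sep="\t")
    for col in (gene_col, p_col, length_col):
        if col not in df.columns:
            raise ValidationError(f"DE table {path} lacks required column {col!r}")
    out = pd.DataFrame(
        {
            "gene_id": df[gene_col].astype(str),
            "length": pd.to_numeric(df[length_col], errors="coerce"),
            "pvalue": pd.to_numeric(df[p_col], errors="coerce"),
        }
    )
    if logfc_col in df.columns:
        out["logfc"] = pd.to_numeric(df[logfc_col], errors="coerce")

    missing = out["length"].isna() | out["pvalue"].isna()
    if missing.any():
        logger.info("dropped %d genes with missing length or p-value", missing.sum())
        out = out.loc[~missing].reset_index(drop=True)

    bad_p = (out["pvalue"] < 0) | (out["pvalue"] > 1)
    if bad_p.any():
        gene = out.loc[bad_p, "gene_id"].iloc[0]
        raise ValidationError(f"gene {gene}: p-value outside [0, 1]")
    bad_len = out["length"] <= 0
    if bad_len.any():
        gene = out.loc[bad_len, "gene_id"].iloc[0]
        raise ValidationError(f"gene {gene}: non-positive length")
    return out.reset_index(drop=True)


def _pvalues(records) -> np.ndarray:
    if isinstance(records, pd.DataFrame):
        return records["pvalue"].to_numpy(dtype=float)
    return np.asarray(records, dtype=float)


def compute_significance(records, spec: SignificanceSpec) -> np.ndarray:
    """Compute the significance vector s (one real per gene).

    ``records`` may be a DE-table DataFrame or, for the pure p-value
    measures, a bare array of p-values.
    """
    if spec.measure == "log_fc":
        if not isinstance(records, pd.DataFrame) or "logfc" not in records.columns:
            raise ValidationError("log_fc measure requested but no logfc column")
        return records["logfc"].to_numpy(dtype=float)

    p = _pvalues(records)
    if spec.measure == "neg_p":
        return -p
    if spec.measure == "binary":
        return dichotomize(p, spec.binary_cutoff, adjust=spec.binary_adjust).astype(
            float
        )
    p = np.clip(p, spec.eps, 1.0 - spec.eps)
    if spec.measure == "neg_log_p":
        return -np.log(p)
    # double_log_p
    return np.log(-np.log(p))


def dichotomize(records, cutoff: float, adjust: str = "none") -> np.ndarray:
    """0/1 DE call per gene at a p-value ``cutoff``.

    With ``adjust='BH'`` the Benjamini-Hochberg FDR adjustment is applied
    over the supplied gene universe before thresholding.
    """
    if not (0.0 < cutoff < 1.0):
        raise ValueError("cutoff must be in (0, 1)")
    p = _pvalues(records)
    if adjust == "BH":
        p = multipletests(p, method="fdr_bh")[1]
    elif adjust != "none":
        raise ValueError("adjust must be 'none' or 'BH'")
    return (p < cutoff).astype(int)
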