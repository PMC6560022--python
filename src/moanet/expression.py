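"""Probe-level expression to per-gene signed fold changes.

The deregulation filter used throughout the pipeline is a plain fold-change
criterion: a gene counts as deregulated when the magnitude of its signed
fold change between treated and control group means reaches a threshold
(1.2 by default, inclusive). The signed convention encodes the ratio
``r = treated_mean / control_mean`` as ``r`` when ``r >= 1`` and ``-1/r``
otherwise, so magnitude is symmetric in direction.

An optional Welch t-test on log intensities can be attached (off by
default); the core selection rule remains the fold-change criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ExpressionMatrix",
    "ProbeSummarizer",
    "FoldChangeSelector",
    "summarize_probes",
    "compute_fold_changes",
    "select_deregulated",
]

GROUPS = ("treated", "control")


@dataclass
class ExpressionMatrix:
    """Positive intensity table (probes x samples) with group labels.

    values
        DataFrame of positive intensities, rows = probes (or genes after
        summarization), columns = samples.
    groups
        Series mapping sample -> 'treated' or 'control'; both non-empty.
    annotation
        Series mapping probe -> gene identifier; probes absent from it are
        unannotated. ``None`` marks an already gene-level matrix.
    """

    values: pd.DataFrame
    groups: pd.Series
    annotation: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("intensities must be strictly positive")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        labels = set(self.groups.loc[list(self.values.columns)])
        if not labels <= set(GROUPS):
            raise ValueError(f"group labels must be in {GROUPS}")
        for grp in GROUPS:
            if not (self.groups.loc[list(self.values.columns)] == grp).any():
                raise ValueError(f"group {grp!r} has no samples")

    def samples_in(self, group: str) -> list[str]:
        g = self.groups.loc[list(self.values.columns)]
        return list(g.index[g == group])


class ProbeSummarizer(BaseEstimator, TransformerMixin):
    """Collapse probes to genes by the arithmetic mean of probe intensities.

    Unannotated probes are dropped; group labels are preserved. Stateless —
    ``fit`` only validates.
    """

    def fit(self, X: ExpressionMatrix, y=None):
        if X.annotation is None or X.annotation.empty:
            raise ValueError("no probe carries a gene annotation")
        if not set(X.annotation.index) & set(X.values.index):
            raise ValueError("no probe carries a gene annotation")
        return self

    def transform(self, X: ExpressionMatrix) -> ExpressionMatrix:
        self.fit(X)
        ann = X.annotation.loc[X.annotation.index.intersection(X.values.index)]
        vals = X.values.loc[ann.index]
        gene_vals = vals.groupby(ann).mean().sort_index()
        return ExpressionMatrix(values=gene_vals, groups=X.groups, annotation=None)


class FoldChangeSelector(BaseEstimator):
    """Signed fold changes per gene plus the deregulated-gene selection.

    Parameters
    ----------
    threshold : float, default 1.2
        Fold-change magnitude a gene must reach to count as deregulated.
    strict : bool, default False
        Use a strict ``>`` comparison instead of the inclusive ``>=``.
    welch_alpha : float or None, default None
        When set, additionally require a Welch t-test on log intensities
        (treated vs control) with p below this level.

    Attributes
    ----------
    fold_changes_ : DataFrame indexed by gene with columns ``treated_mean``,
        ``control_mean``, ``signed_fc`` (and ``p_value`` when testing).
    deregulated_ : DataFrame of selected genes with ``signed_fc`` and
        ``direction`` ('up'/'down'), index = gene.
    """

    def __init__(self, threshold: float = 1.2, strict: bool = False, welch_alpha: float | None = None):
        self.threshold = threshold
        self.strict = strict
        self.welch_alpha = welch_alpha

    def fit(self, X: ExpressionMatrix, y=None):
        if self.threshold < 1:
            raise ValueError("threshold must be >= 1")
        if X.annotation is not None:
            X = ProbeSummarizer().fit_transform(X)
        table = compute_fold_changes(X, welch_test=self.welch_alpha is not None)
        self.fold_changes_ = table
        self.deregulated_ = select_deregulated(
            table, threshold=self.threshold, strict=self.strict, alpha=self.welch_alpha
        )
        return self

    def transform(self, X: ExpressionMatrix) -> ExpressionMatrix:
        """Restrict a gene-level matrix to the selected deregulated genes."""
        if X.annotation is not None:
            X = ProbeSummarizer().fit_transform(X)
        keep = X.values.index.intersection(self.deregulated_.index)
        return ExpressionMatrix(values=X.values.loc[keep], groups=X.groups, annotation=None)


def summarize_probes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Gene-level matrix: per-sample arithmetic mean over each gene's probes."""
    return ProbeSummarizer().fit_transform(matrix)


def compute_fold_changes(gene_matrix: ExpressionMatrix, welch_test: bool = False) -> pd.DataFrame:
    """Signed fold change per gene between treated and control group means.

    Returns a DataFrame indexed by gene with ``treated_mean``,
    ``control_mean`` and ``signed_fc``; with ``welch_test`` a two-sided
    Welch t-test p-value on log intensities is added.
    """
    t_cols = gene_matrix.samples_in("treated")
    c_cols = gene_matrix.samples_in("control")
    t_mean = gene_matrix.values[t_cols].mean(axis=1)
    c_mean = gene_matrix.values[c_cols].mean(axis=1)
    if (t_mean <= 0).any() or (c_mean <= 0).any():
        raise ValueError("group means must be strictly positive")
    ratio = t_mean / c_mean
    signed = np.where(ratio >= 1, ratio, -1.0 / ratio)
    out = pd.DataFrame(
        {"treated_mean": t_mean, "control_mean": c_mean, "signed_fc": signed},
        index=gene_matrix.values.index,
    )
    out.index.name = "gene"
    if welch_test:
        logv = np.log(gene_matrix.values)
        res = stats.ttest_ind(logv[t_cols], logv[c_cols], axis=1, equal_var=False)
        out["p_value"] = res.pvalue
    return out


def select_deregulated(
    table: pd.DataFrame,
    threshold: float = 1.2,
    strict: bool = False,
    alpha: float | None = None,
) -> pd.DataFrame:
    """Genes whose fold-change magnitude meets the threshold, with direction.

    The comparison is inclusive (``>=``) unless ``strict``. When ``alpha``
    is given the table must carry a ``p_value`` column and genes must also
    pass ``p < alpha``.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    mag = table["signed_fc"].abs()
    mask = mag > threshold if strict else mag >= threshold
    if alpha is not None:
        if "p_value" not in table.columns:
            raise ValueError("alpha given but table has no p_value column")
        mask &= table["p_value"] < alpha
    sel = table.loc[mask, ["signed_fc"]].copy()
    sel["direction"] = np.where(sel["signed_fc"] > 0, "up", "down")
    return sel.sort_index()
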