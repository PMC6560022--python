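"""Downstream longitudinal analyses: change correlations, tertile
stratification, and the association between early biomarker change and
subsequent eGFR decline.

The eGFR-decline model reuses the package's REML/MMRM engine: response is
the eGFR change from baseline at the post-baseline visits, with treatment
and visit as factors, the biomarker change and its visit interaction as
covariates, adjusted for baseline age, sex, systolic and diastolic blood
pressure, BMI, HbA1c, eGFR, albuminuria (log UACR) and the albuminuria
change to the first post-baseline visit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mmrm import REMLResult, reml_fit

__all__ = [
    "CorrelationResult",
    "TertileAssociation",
    "correlate_changes",
    "stratify_tertiles",
    "associate_egfr_decline",
    "plot_contrasts",
]

NAMED_BANDS = (
    ("reduction_ge_30pct", -np.inf, -30.0),
    ("reduction_0_30pct", -30.0, 0.0),
    ("increase", 0.0, np.inf),
)


@dataclass
class CorrelationResult:
    """Pairwise Pearson correlations with a p < ``alpha`` significance flag.

    Undefined correlations (constant input, fewer than 3 complete pairs)
    are reported as missing (NaN / flag False), never as a number.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    alpha: float


@dataclass
class TertileAssociation:
    """Grouped least-squares-mean eGFR change plus the continuous p value."""

    groups: pd.DataFrame  # index group label; n, lsmean, ci_low, ci_high
    p_continuous: float
    coef_continuous: float
    fit: REMLResult
    grouping: str


def _per_subject_values(data: pd.DataFrame, marker: str, week: int) -> pd.Series:
    d = data[(data["biomarker"] == marker) & (data["visit_week"] == week)]
    return d.set_index("subject")["value"]


def correlate_changes(
    data: pd.DataFrame,
    markers: list[str],
    at_week: int = 52,
    mode: str = "change",
    alpha: float = 0.001,
) -> CorrelationResult:
    """Pairwise Pearson correlations between markers at ``at_week``.

    mode='change' correlates percentage changes from baseline,
    100*(value/baseline - 1); mode='achieved' correlates the attained
    values. Complete pairs only; the diagonal is 1.
    """
    if mode not in ("change", "achieved"):
        raise ValueError("mode must be 'change' or 'achieved'")
    series = {}
    for m in markers:
        at = _per_subject_values(data, m, at_week)
        if at.empty:
            raise ValueError(f"marker {m!r} not measured at week {at_week}")
        if mode == "change":
            base = _per_subject_values(data, m, 0)
            if base.empty:
                raise ValueError(f"marker {m!r} not measured at week 0")
            common = at.index.intersection(base.index)
            series[m] = 100.0 * (at.loc[common] / base.loc[common] - 1.0)
        else:
            series[m] = at
    n = len(markers)
    r = pd.DataFrame(np.eye(n), index=markers, columns=markers)
    p = pd.DataFrame(np.zeros((n, n)), index=markers, columns=markers)
    for i, a in enumerate(markers):
        for j, b in enumerate(markers):
            if j <= i:
                continue
            pair = pd.concat([series[a], series[b]], axis=1, join="inner").dropna()
            x, y = pair.iloc[:, 0], pair.iloc[:, 1]
            if len(pair) < 3 or x.nunique() < 2 or y.nunique() < 2:
                rv, pv = np.nan, np.nan
            else:
                rv, pv = stats.pearsonr(x, y)
            r.iloc[i, j] = r.iloc[j, i] = rv
            p.iloc[i, j] = p.iloc[j, i] = pv
    sig = (p < alpha) & p.notna()
    np.fill_diagonal(sig.values, False)
    return CorrelationResult(r=r, p=p, significant=sig, alpha=alpha)


def stratify_tertiles(changes: pd.Series) -> pd.Series:
    """Rank-based split into three groups of sizes differing by at most 1.

    Ties are broken by stable subject-ID order; when the size is not a
    multiple of 3 the extra subjects go to the lower tertiles first.
    Returns labels 1 (lowest) to 3, indexed like the input.
    """
    vals = changes.dropna()
    n = len(vals)
    if n < 3:
        raise ValueError("need at least 3 non-missing values")
    order = vals.iloc[np.lexsort((vals.index.astype(str), vals.to_numpy()))]
    q, rem = divmod(n, 3)
    sizes = [q + (1 if i < rem else 0) for i in range(3)]
    labels = np.repeat([1, 2, 3], sizes)
    return pd.Series(labels, index=order.index, name="tertile").reindex(changes.dropna().index)


def _band_labels(changes: pd.Series) -> pd.Series:
    out = pd.Series(index=changes.index, dtype=object)
    for name, lo, hi in NAMED_BANDS:
        out[(changes > lo) & (changes <= hi)] = name
    out[changes > NAMED_BANDS[-1][1]] = NAMED_BANDS[-1][0]
    return out


def associate_egfr_decline(
    data: pd.DataFrame,
    biomarker_change: pd.Series,
    covariates: pd.DataFrame,
    grouping: str = "continuous",
    egfr_marker: str = "eGFR",
    uacr_marker: str = "UACR",
    change_week: int = 52,
    alpha: float = 0.05,
) -> TertileAssociation:
    """Association between early biomarker change and eGFR decline.

    ``biomarker_change`` is the per-subject change from baseline to
    ``change_week`` (any scale chosen by the caller; percentage change for
    the named bands). The response is the eGFR change from baseline at each
    post-baseline visit, modelled by REML with unstructured within-subject
    covariance. The continuous coefficient (biomarker change averaged over
    its visit interactions) is always reported; with grouping='tertiles' or
    'named_bands' the change enters as a factor instead and per-group
    least-squares means with 95% CIs are returned.
    """
    if grouping not in ("continuous", "tertiles", "named_bands"):
        raise ValueError("grouping must be continuous, tertiles or named_bands")
    egfr = data[data["biomarker"] == egfr_marker]
    if egfr.empty:
        raise ValueError(f"no {egfr_marker!r} records")
    wide = egfr.pivot_table(index="subject", columns="visit_week", values="value", aggfunc="first")
    if 0 not in wide.columns:
        raise ValueError("eGFR baseline (week 0) required")
    post = [w for w in sorted(wide.columns) if w != 0]
    if len(post) < 2:
        raise ValueError("need eGFR at >=2 post-baseline visits")
    change = wide[post].sub(wide[0], axis=0)

    arm = data[["subject", "arm"]].drop_duplicates().set_index("subject")["arm"]
    # albuminuria change from baseline to the first post-baseline visit (log scale)
    uacr = data[data["biomarker"] == uacr_marker]
    uw = uacr.pivot_table(index="subject", columns="visit_week", values="value", aggfunc="first")
    uacr_change = (
        np.log(uw[change_week] / uw[0])
        if {0, change_week} <= set(uw.columns)
        else pd.Series(0.0, index=wide.index)
    )

    adj_cols = ["age", "female", "sbp", "dbp", "bmi", "hba1c", "egfr"]
    subj = wide.index
    keep = (
        biomarker_change.reindex(subj).notna()
        & covariates.reindex(subj)[adj_cols].notna().all(axis=1)
        & uacr_change.reindex(subj).notna()
    )
    subj = subj[keep]
    if len(subj) < 10:
        raise ValueError("too few subjects with complete data")

    long = (
        change.loc[subj]
        .stack()
        .rename("egfr_change")
        .reset_index()
        .rename(columns={"level_1": "visit_week"})
    )
    long = long.dropna(subset=["egfr_change"])
    arms = sorted(arm.loc[subj].unique())
    ref = "control" if "control" in arms else arms[0]
    s = long["subject"]
    bmch = biomarker_change.reindex(s).to_numpy()

    def base_design(extra_cols):
        cols = ["Intercept"]
        cols += [f"arm[{a}]" for a in arms if a != ref]
        cols += [f"visit[{v}]" for v in post[1:]]
        cols += extra_cols
        cols += adj_cols + ["log_uacr", "uacr_change"]
        X = np.zeros((len(long), len(cols)))
        ix = {c: i for i, c in enumerate(cols)}
        X[:, 0] = 1.0
        armvals = arm.reindex(s).to_numpy()
        for a in arms:
            if a != ref:
                X[:, ix[f"arm[{a}]"]] = armvals == a
        for v in post[1:]:
            X[:, ix[f"visit[{v}]"]] = (long["visit_week"] == v).to_numpy(float)
        cv = covariates.reindex(s)
        for c in adj_cols:
            X[:, ix[c]] = cv[c].to_numpy(float)
        X[:, ix["log_uacr"]] = np.log(cv["uacr"].to_numpy(float))
        X[:, ix["uacr_change"]] = uacr_change.reindex(s).to_numpy(float)
        return X, cols, ix

    # continuous model (always fitted: provides the coefficient p value)
    extra = ["bm_change"] + [f"bm_change:visit[{v}]" for v in post[1:]]
    X, cols, ix = base_design(extra)
    X[:, ix["bm_change"]] = bmch
    for v in post[1:]:
        X[:, ix[f"bm_change:visit[{v}]"]] = bmch * (long["visit_week"] == v).to_numpy(float)
    visit_pos = long["visit_week"].map({w: i for i, w in enumerate(post)}).to_numpy()
    fit_c = reml_fit(long["egfr_change"].to_numpy(), X, s.to_numpy(), visit_pos,
                     len(post), colnames=cols, visits=post)
    cvec = np.zeros(len(cols))
    cvec[ix["bm_change"]] = 1.0
    for v in post[1:]:
        cvec[ix[f"bm_change:visit[{v}]"]] = 1.0 / len(post)
    coef, _, p_cont, _ = fit_c.wald(cvec)

    if grouping == "continuous":
        groups = pd.DataFrame(columns=["n", "lsmean", "ci_low", "ci_high"])
        return TertileAssociation(groups=groups, p_continuous=p_cont,
                                  coef_continuous=coef, fit=fit_c, grouping=grouping)

    if grouping == "tertiles":
        lab = stratify_tertiles(biomarker_change.loc[subj])
        levels = [1, 2, 3]
    else:
        lab = _band_labels(biomarker_change.loc[subj])
        levels = [b[0] for b in NAMED_BANDS if (lab == b[0]).any()]
    glab = lab.reindex(s)
    extra = [f"group[{g}]" for g in levels[1:]]
    Xg, colsg, ixg = base_design(extra)
    for g in levels[1:]:
        Xg[:, ixg[f"group[{g}]"]] = (glab == g).to_numpy(float)
    fit_g = reml_fit(long["egfr_change"].to_numpy(), Xg, s.to_numpy(), visit_pos,
                     len(post), colnames=colsg, visits=post)

    # least-squares means: covariates at their subject-level means, visits
    # and arms averaged (arms by observed subject proportions)
    arm_props = arm.loc[subj].value_counts(normalize=True)
    cv_subj = covariates.reindex(subj)
    means = {c: float(cv_subj[c].mean()) for c in adj_cols}
    means["log_uacr"] = float(np.log(cv_subj["uacr"]).mean())
    means["uacr_change"] = float(uacr_change.reindex(subj).mean())
    rows = []
    for g in levels:
        row = np.zeros(len(colsg))
        row[ixg["Intercept"]] = 1.0
        for a in arms:
            if a != ref:
                row[ixg[f"arm[{a}]"]] = float(arm_props.get(a, 0.0))
        for v in post[1:]:
            row[ixg[f"visit[{v}]"]] = 1.0 / len(post)
        if g != levels[0]:
            row[ixg[f"group[{g}]"]] = 1.0
        for c, m in means.items():
            row[ixg[c]] = m
        est, se, _, df = fit_g.wald(row)
        z = stats.t.ppf(1 - alpha / 2, df)
        rows.append({"group": g, "n": int((lab == g).sum()), "lsmean": est,
                     "ci_low": est - z * se, "ci_high": est + z * se})
    groups = pd.DataFrame(rows).set_index("group")
    return TertileAssociation(groups=groups, p_continuous=p_cont,
                              coef_continuous=coef, fit=fit_g, grouping=grouping)


def plot_contrasts(results: dict, path: str) -> None:
    """Forest plot of per-marker percentage-difference contrasts."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    markers = list(results)
    est = [results[m].estimate for m in markers]
    lo = [results[m].ci_low for m in markers]
    hi = [results[m].ci_high for m in markers]
    ypos = np.arange(len(markers))[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.5 * len(markers) + 1.5))
    ax.errorbar(est, ypos, xerr=[np.array(est) - np.array(lo), np.array(hi) - np.array(est)],
                fmt="o", color="k", capsize=3)
    ax.axvline(0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(ypos, markers)
    ax.set_xlabel("percentage difference vs reference arm (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
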