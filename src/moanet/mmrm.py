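"""Mixed-model repeated measures (MMRM) for longitudinal biomarkers.

Marginal linear model for the post-baseline visits of a two-or-more-arm
trial: fixed effects for treatment, visit, treatment-by-visit interaction
and the baseline response value, with an unstructured within-subject
variance-covariance matrix shared across subjects. Estimation is by
restricted maximum likelihood (REML); the covariance is parameterised
through its Cholesky factor (log-diagonal) so it stays positive definite,
and the fixed effects are profiled out. Subjects with partially missing
visits contribute all available visits (valid under missing-at-random).

Responses are modelled on the natural-log scale by default, in which case
the between-arm contrast delta back-transforms to a percentage difference
100*(exp(delta) - 1); with ``log_transform=False`` the response is the raw
percentage change from baseline and the contrast is already a percentage.
Inference uses Wald statistics against a t reference with Satterthwaite
degrees of freedom (computed from the REML information matrix), the
standard small-sample correction for repeated-measures marginal models;
the plain normal reference slightly undercovers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator

__all__ = ["MMRM", "REMLResult", "ContrastResult", "reml_fit", "fit_mmrm", "estimate_contrast"]


@dataclass
class REMLResult:
    """Low-level REML fit: fixed effects, their covariance, and the
    estimated within-subject covariance matrix over visits."""

    beta: pd.Series
    cov_beta: pd.DataFrame
    sigma: np.ndarray
    visits: list
    converged: bool
    n_iter: int
    m2_restricted_loglik: float
    n_subjects: int
    n_obs: int
    cov_beta_derivs: list | None = None  # d(cov_beta)/d(theta_i) at the optimum
    theta_cov: np.ndarray | None = None  # asymptotic covariance of theta_hat

    @property
    def correlation(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.sigma))
        return self.sigma / np.outer(d, d)

    def satterthwaite_df(self, c: np.ndarray) -> float:
        """Satterthwaite degrees of freedom for the contrast c'beta:
        df = 2 (c'Phi c)^2 / Var(c'Phi c), with the variance obtained by
        the delta method from the REML information matrix."""
        if self.cov_beta_derivs is None or self.theta_cov is None:
            return np.inf
        var_c = float(c @ self.cov_beta.to_numpy() @ c)
        g = np.array([float(c @ d @ c) for d in self.cov_beta_derivs])
        denom = float(g @ self.theta_cov @ g)
        if denom <= 0 or not np.isfinite(denom):
            return np.inf
        df = 2.0 * var_c**2 / denom
        return max(df, 3.0)

    def wald(self, c: np.ndarray) -> tuple[float, float, float, float]:
        """Estimate, SE, two-sided p (t reference, Satterthwaite df), df."""
        est = float(c @ self.beta.to_numpy())
        se = float(np.sqrt(c @ self.cov_beta.to_numpy() @ c))
        df = self.satterthwaite_df(c)
        p = 2.0 * stats.t.sf(abs(est) / se, df) if se > 0 else np.nan
        return est, se, p, df


@dataclass
class ContrastResult:
    """Between-arm percentage-difference contrast from an MMRM fit."""

    arm_a: str
    arm_b: str
    estimate: float  # percentage difference, arm_a vs arm_b
    ci_low: float
    ci_high: float
    p_value: float
    delta: float  # contrast on the model scale
    per_visit: dict = field(default_factory=dict)  # visit -> (est, lo, hi, p)


def _theta_to_chol(theta: np.ndarray, k: int) -> np.ndarray:
    L = np.zeros((k, k))
    L[np.tril_indices(k)] = theta
    L[np.diag_indices(k)] = np.exp(np.diag(L))
    return L


def _chol_to_theta(L: np.ndarray) -> np.ndarray:
    M = np.array(L, dtype=float)
    M[np.diag_indices(len(M))] = np.log(np.diag(M))
    return M[np.tril_indices(len(M))]


def _pattern_blocks(y, X, subject, visit_pos, n_visits):
    """Group subjects by their visit-availability pattern for vectorised
    likelihood evaluation."""
    order = np.lexsort((visit_pos, subject))
    y, X, subject, visit_pos = y[order], X[order], subject[order], visit_pos[order]
    blocks = {}
    start = 0
    for i in range(1, len(subject) + 1):
        if i == len(subject) or subject[i] != subject[start]:
            pat = tuple(visit_pos[start:i])
            ys, Xs = blocks.setdefault(pat, ([], []))
            ys.append(y[start:i])
            Xs.append(X[start:i])
            start = i
    return {
        pat: (np.stack(ys), np.stack(Xs)) for pat, (ys, Xs) in blocks.items()
    }


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    subject: np.ndarray,
    visit_pos: np.ndarray,
    n_visits: int,
    colnames: list[str] | None = None,
    visits: list | None = None,
    maxiter: int = 300,
) -> REMLResult:
    """REML fit of a marginal linear model with unstructured covariance.

    ``visit_pos`` gives each observation's index into the ordered visit
    vector (length ``n_visits``); each subject may contribute any non-empty
    subset of visits, at most once each.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    p = X.shape[1]
    blocks = _pattern_blocks(y, X, np.asarray(subject), np.asarray(visit_pos, int), n_visits)
    n_subj = sum(ys.shape[0] for ys, _ in blocks.values())

    # start values from OLS residual covariance (pairwise complete)
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    S0 = np.eye(n_visits) * max(resid.var(), 1e-6)
    rmat = np.full((n_subj, n_visits), np.nan)
    row = 0
    pos = 0
    for pat, (ys, Xs) in blocks.items():
        n_s = ys.shape[0]
        r = ys - Xs @ beta0
        for j, v in enumerate(pat):
            rmat[row : row + n_s, v] = r[:, j]
        row += n_s
    mask = ~np.isnan(rmat)
    for a in range(n_visits):
        for b in range(a + 1):
            m = mask[:, a] & mask[:, b]
            if m.sum() > 2:
                S0[a, b] = S0[b, a] = np.cov(rmat[m, a], rmat[m, b])[0, 1] if a != b else rmat[m, a].var()
    w, V = np.linalg.eigh(S0)
    S0 = (V * np.clip(w, 1e-6 * max(w.max(), 1e-6), None)) @ V.T
    theta0 = _chol_to_theta(np.linalg.cholesky(S0))

    def neg2_reml(theta):
        L = _theta_to_chol(theta, n_visits)
        Sigma = L @ L.T
        XtViX = np.zeros((p, p))
        XtViy = np.zeros(p)
        ytViy = 0.0
        logdet = 0.0
        for pat, (ys, Xs) in blocks.items():
            S = Sigma[np.ix_(pat, pat)]
            try:
                c = linalg.cho_factor(S, lower=True)
            except linalg.LinAlgError:
                return np.inf
            Sinv = linalg.cho_solve(c, np.eye(len(pat)))
            logdet += ys.shape[0] * 2.0 * np.sum(np.log(np.diag(c[0])))
            XtViX += np.einsum("ski,kl,slj->ij", Xs, Sinv, Xs, optimize=True)
            XtViy += np.einsum("ski,kl,sl->i", Xs, Sinv, ys, optimize=True)
            ytViy += float(np.einsum("sk,kl,sl->", ys, Sinv, ys, optimize=True))
        try:
            cx = linalg.cho_factor(XtViX)
        except linalg.LinAlgError:
            return np.inf
        beta = linalg.cho_solve(cx, XtViy)
        quad = ytViy - float(beta @ XtViy)
        logdet_x = 2.0 * np.sum(np.log(np.diag(cx[0])))
        val = logdet + logdet_x + quad
        return val if np.isfinite(val) else np.inf

    res = optimize.minimize(neg2_reml, theta0, method="Nelder-Mead",
                            options={"maxiter": maxiter * len(theta0), "xatol": 1e-8, "fatol": 1e-10})
    theta = res.x

    def moments(th):
        L = _theta_to_chol(th, n_visits)
        Sigma = L @ L.T
        XtViX = np.zeros((p, p))
        XtViy = np.zeros(p)
        for pat, (ys, Xs) in blocks.items():
            Sinv = np.linalg.inv(Sigma[np.ix_(pat, pat)])
            XtViX += np.einsum("ski,kl,slj->ij", Xs, Sinv, Xs, optimize=True)
            XtViy += np.einsum("ski,kl,sl->i", Xs, Sinv, ys, optimize=True)
        return Sigma, np.linalg.inv(XtViX), XtViy

    Sigma, cov_beta, XtViy = moments(theta)
    beta = cov_beta @ XtViy

    # Satterthwaite ingredients: d(cov_beta)/d(theta) and Var(theta_hat)
    # from the numerically differentiated REML criterion
    q = len(theta)
    steps = 1e-4 * np.maximum(1.0, np.abs(theta))
    cov_beta_derivs = []
    for i in range(q):
        e = np.zeros(q)
        e[i] = steps[i]
        cov_beta_derivs.append(
            (moments(theta + e)[1] - moments(theta - e)[1]) / (2 * steps[i])
        )
    hess = np.zeros((q, q))
    f0 = neg2_reml(theta)
    for i in range(q):
        ei = np.zeros(q); ei[i] = steps[i]
        for j in range(i, q):
            ej = np.zeros(q); ej[j] = steps[j]
            if i == j:
                hess[i, i] = (neg2_reml(theta + ei) - 2 * f0 + neg2_reml(theta - ei)) / steps[i] ** 2
            else:
                hess[i, j] = hess[j, i] = (
                    neg2_reml(theta + ei + ej) - neg2_reml(theta + ei - ej)
                    - neg2_reml(theta - ei + ej) + neg2_reml(theta - ei - ej)
                ) / (4 * steps[i] * steps[j])
    try:
        theta_cov = 2.0 * np.linalg.pinv(hess)
    except np.linalg.LinAlgError:
        theta_cov = None
    names = colnames if colnames is not None else [f"x{i}" for i in range(p)]
    converged = bool(res.success) and np.isfinite(res.fun)
    if not converged:
        warnings.warn("MMRM REML optimisation did not converge", RuntimeWarning)
    return REMLResult(
        beta=pd.Series(beta, index=names),
        cov_beta=pd.DataFrame(cov_beta, index=names, columns=names),
        sigma=Sigma,
        visits=list(visits) if visits is not None else list(range(n_visits)),
        converged=converged,
        n_iter=int(res.nit),
        m2_restricted_loglik=float(res.fun),
        n_subjects=n_subj,
        n_obs=len(y),
        cov_beta_derivs=cov_beta_derivs,
        theta_cov=theta_cov,
    )


class MMRM(BaseEstimator):
    """MMRM for one biomarker of a long-format trial dataset.

    Parameters
    ----------
    biomarker : str or None
        Biomarker to analyse; None requires the data to hold a single one.
    log_transform : bool, default True
        Model the natural log of the value (the convention for skewed
        biomarkers); otherwise the response is the raw percentage change
        from baseline.
    include_baseline : bool, default True
        Adjust for the baseline response value as a covariate.
    reference_arm : str or None
        Reference level for the treatment factor; defaults to ``'control'``
        when present, else the lexicographically first arm.

    Attributes (after ``fit``)
    --------------------------
    result_ : REMLResult; params_ / cov_params_ : fixed effects;
    sigma_ / corr_ : within-subject covariance / correlation over the
    post-baseline visits; converged_ : bool.
    """

    def __init__(
        self,
        biomarker: str | None = None,
        log_transform: bool = True,
        include_baseline: bool = True,
        reference_arm: str | None = None,
    ):
        self.biomarker = biomarker
        self.log_transform = log_transform
        self.include_baseline = include_baseline
        self.reference_arm = reference_arm

    # -- design helpers -----------------------------------------------------
    def _design_row(self, arm, visit, baseline_value) -> np.ndarray:
        row = np.zeros(len(self.colnames_))
        ix = {c: i for i, c in enumerate(self.colnames_)}
        row[ix["Intercept"]] = 1.0
        if arm != self.reference_arm_:
            row[ix[f"arm[{arm}]"]] = 1.0
        if visit != self.visits_[0]:
            row[ix[f"visit[{visit}]"]] = 1.0
            if arm != self.reference_arm_:
                row[ix[f"arm[{arm}]:visit[{visit}]"]] = 1.0
        if self.include_baseline:
            row[ix["baseline"]] = baseline_value
        return row

    def fit(self, data: pd.DataFrame, covariates: pd.DataFrame | None = None):
        df = data.copy()
        if self.biomarker is not None:
            df = df[df["biomarker"] == self.biomarker]
            if df.empty:
                raise ValueError(f"biomarker {self.biomarker!r} not found")
        elif df["biomarker"].nunique() > 1:
            raise ValueError("multiple biomarkers present; set `biomarker`")

        wide = df.pivot_table(index=["subject", "arm"], columns="visit_week",
                              values="value", aggfunc="first")
        weeks = sorted(wide.columns)
        if 0 not in weeks:
            raise ValueError("week 0 (baseline) is required")
        post = [w for w in weeks if w != 0]
        if len(post) < 2:
            raise ValueError("need at least two post-baseline visits")
        has_base = wide[0].notna()
        if (~has_base).any():
            warnings.warn(f"dropping {(~has_base).sum()} subject(s) without baseline")
            wide = wide[has_base]

        arms = sorted(df["arm"].unique())
        ref = self.reference_arm
        if ref is None:
            ref = "control" if "control" in arms else arms[0]
        if ref not in arms:
            raise ValueError(f"reference arm {ref!r} not present")
        self.reference_arm_ = ref
        self.arms_ = arms
        self.visits_ = post

        long = (
            wide[post]
            .stack()
            .rename("value")
            .reset_index()
            .rename(columns={"level_2": "visit_week"})
        )
        base = wide[0]
        long["baseline_raw"] = base.loc[
            pd.MultiIndex.from_frame(long[["subject", "arm"]])
        ].to_numpy()
        counts = long.groupby(["arm", "visit_week"])["subject"].nunique()
        for arm in arms:
            for w in post:
                if counts.get((arm, w), 0) < 2:
                    raise ValueError(f"visit {w} has <2 subjects in arm {arm!r}")
        if self.log_transform:
            y = np.log(long["value"].to_numpy())
            basecov = np.log(long["baseline_raw"].to_numpy())
        else:
            y = 100.0 * (long["value"].to_numpy() / long["baseline_raw"].to_numpy() - 1.0)
            basecov = long["baseline_raw"].to_numpy()

        cols = ["Intercept"]
        cols += [f"arm[{a}]" for a in arms if a != ref]
        cols += [f"visit[{v}]" for v in post[1:]]
        cols += [f"arm[{a}]:visit[{v}]" for a in arms if a != ref for v in post[1:]]
        if self.include_baseline:
            cols.append("baseline")
        self.colnames_ = cols
        X = np.zeros((len(long), len(cols)))
        ix = {c: i for i, c in enumerate(cols)}
        X[:, ix["Intercept"]] = 1.0
        for a in arms:
            if a != ref:
                X[:, ix[f"arm[{a}]"]] = (long["arm"] == a).to_numpy(float)
        for v in post[1:]:
            X[:, ix[f"visit[{v}]"]] = (long["visit_week"] == v).to_numpy(float)
            for a in arms:
                if a != ref:
                    X[:, ix[f"arm[{a}]:visit[{v}]"]] = (
                        (long["arm"] == a) & (long["visit_week"] == v)
                    ).to_numpy(float)
        if self.include_baseline:
            X[:, ix["baseline"]] = basecov

        visit_pos = long["visit_week"].map({w: i for i, w in enumerate(post)}).to_numpy()
        self.result_ = reml_fit(
            y, X, long["subject"].to_numpy(), visit_pos, len(post),
            colnames=cols, visits=post,
        )
        self.params_ = self.result_.beta
        self.cov_params_ = self.result_.cov_beta
        self.sigma_ = self.result_.sigma
        self.corr_ = self.result_.correlation
        self.converged_ = self.result_.converged
        return self

    def _arm_contrast(self, arm_a: str, arm_b: str, visit=None) -> np.ndarray:
        for a in (arm_a, arm_b):
            if a not in self.arms_:
                raise ValueError(f"unknown arm {a!r}")
        vs = [visit] if visit is not None else self.visits_
        rows = [
            self._design_row(arm_a, v, 0.0) - self._design_row(arm_b, v, 0.0) for v in vs
        ]
        return np.mean(rows, axis=0)

    def contrast(self, arm_a: str, arm_b: str, alpha: float = 0.05) -> ContrastResult:
        """Percentage difference of arm_a vs arm_b averaged over the
        post-baseline visits (plus per-visit contrasts)."""

        def to_pct(d):
            return 100.0 * (np.exp(d) - 1.0) if self.log_transform else d

        c = self._arm_contrast(arm_a, arm_b)
        est, se, p, df = self.result_.wald(c)
        z = stats.t.ppf(1 - alpha / 2, df)
        per_visit = {}
        for v in self.visits_:
            cv = self._arm_contrast(arm_a, arm_b, visit=v)
            e, s, pv, dfv = self.result_.wald(cv)
            zv = stats.t.ppf(1 - alpha / 2, dfv)
            per_visit[v] = (to_pct(e), to_pct(e - zv * s), to_pct(e + zv * s), pv)
        return ContrastResult(
            arm_a=arm_a,
            arm_b=arm_b,
            estimate=to_pct(est),
            ci_low=to_pct(est - z * se),
            ci_high=to_pct(est + z * se),
            p_value=p,
            delta=est,
            per_visit=per_visit,
        )


def fit_mmrm(
    data: pd.DataFrame,
    biomarker: str | None = None,
    log_transform: bool = True,
    **kwargs,
) -> MMRM:
    """Fit an :class:`MMRM` to one biomarker; thin functional wrapper."""
    return MMRM(biomarker=biomarker, log_transform=log_transform, **kwargs).fit(data)


def estimate_contrast(fit: MMRM, arm_a: str, arm_b: str, alpha: float = 0.05) -> ContrastResult:
    """Between-arm percentage-difference contrast from a fitted MMRM."""
    return fit.contrast(arm_a, arm_b, alpha=alpha)
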