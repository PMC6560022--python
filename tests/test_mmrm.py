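"""MMRM: REML engine, contrasts, parameter recovery, external oracle."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from moanet import MMRM, SimulationConfig, estimate_contrast, fit_mmrm, generate_trial

from .conftest import trial_frame


def matched_pair_data(mult, n=30, weeks=(0, 52, 104), seed=0):
    """Treated subjects are exact multiplicative copies of control subjects
    at the post-baseline visits (identical baselines)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        base = np.exp(rng.normal(np.log(10), 0.4, len(weeks)))
        for arm, m in (("control", 1.0), ("active", mult)):
            for j, w in enumerate(weeks):
                rows.append((f"{arm[0]}{i:03d}", arm, w, "B", base[j] * (m if w > 0 else 1.0)))
    return trial_frame(rows)


class TestBackTransform:
    def test_exact_minus_25_percent(self):
        """A noise-free multiplicative effect of 0.75 must back-transform to
        exactly -25.0% (up to optimizer tolerance)."""
        fit = fit_mmrm(matched_pair_data(0.75), "B")
        c = fit.contrast("active", "control")
        assert c.estimate == pytest.approx(-25.0, abs=1e-6)
        assert c.delta == pytest.approx(np.log(0.75), abs=1e-8)
        for est, lo, hi, _ in c.per_visit.values():
            assert est == pytest.approx(-25.0, abs=1e-6)
            assert lo <= est <= hi

    def test_null_effect_is_exactly_zero(self):
        fit = fit_mmrm(matched_pair_data(1.0), "B")
        c = estimate_contrast(fit, "active", "control")
        assert c.estimate == pytest.approx(0.0, abs=1e-6)

    def test_arm_relabelling_reciprocal(self):
        fit = fit_mmrm(matched_pair_data(0.75), "B")
        fwd = fit.contrast("active", "control")
        rev = fit.contrast("control", "active")
        assert rev.delta == pytest.approx(-fwd.delta, abs=1e-10)
        expected = 100.0 * (1.0 / (1.0 + fwd.estimate / 100.0) - 1.0)
        assert rev.estimate == pytest.approx(expected, abs=1e-6)


class TestPreconditions:
    def test_single_post_baseline_visit_rejected(self):
        cfg = SimulationConfig(visit_weeks=(0, 52), n_subjects_per_arm=20, seed=1)
        rec, _, _ = generate_trial(cfg)
        with pytest.raises(ValueError, match="post-baseline"):
            fit_mmrm(rec, "BM1")

    def test_unknown_arm_rejected(self):
        fit = fit_mmrm(matched_pair_data(0.9), "B")
        with pytest.raises(ValueError, match="unknown arm"):
            fit.contrast("active", "placebo")

    def test_sparse_visit_rejected(self):
        rows = matched_pair_data(1.0, n=5)
        rows = rows[~((rows.arm == "active") & (rows.visit_week == 104) & (rows.subject != "a000"))]
        with pytest.raises(ValueError, match="<2 subjects"):
            fit_mmrm(rows, "B")


class TestRecovery:
    def test_null_effect_unbiased(self):
        """Treatment and interaction effects center on 0 under the null
        (mean over replicates within 3 Monte-Carlo SEs)."""
        deltas, inters = [], []
        for s in range(80):
            cfg = SimulationConfig(n_subjects_per_arm=50, planted_effects={}, seed=2000 + s)
            rec, _, _ = generate_trial(cfg)
            fit = fit_mmrm(rec, "BM1")
            deltas.append(fit.params_["arm[active]"])
            inters.append(fit.params_["arm[active]:visit[104]"])
        for vals in (deltas, inters):
            vals = np.array(vals)
            assert abs(vals.mean()) < 3 * vals.std(ddof=1) / np.sqrt(len(vals))

    def test_within_subject_correlation_recovery(self):
        """Marginal model (no baseline covariate) recovers the planted
        correlation 0.5 within +-0.1 at n=500; the default model's
        baseline conditioning shrinks it to rho/(1+rho)."""
        cfg = SimulationConfig(n_subjects_per_arm=500, within_subject_corr=0.5,
                               planted_effects={}, seed=123)
        rec, _, _ = generate_trial(cfg)
        marg = MMRM(biomarker="BM1", include_baseline=False).fit(rec)
        assert marg.corr_[0, 1] == pytest.approx(0.5, abs=0.1)
        cond = MMRM(biomarker="BM1").fit(rec)
        assert cond.corr_[0, 1] == pytest.approx(0.5 / 1.5, abs=0.1)

    def test_missing_visits_still_fit(self):
        cfg = SimulationConfig(n_subjects_per_arm=80, dropout_rate=0.3, seed=7)
        rec, _, _ = generate_trial(cfg)
        fit = fit_mmrm(rec, "BM1")
        assert fit.converged_
        c = fit.contrast("active", "control")
        assert c.ci_low <= c.estimate <= c.ci_high

    def test_covariance_positive_definite(self):
        fit = fit_mmrm(matched_pair_data(0.8, n=40), "B")
        w = np.linalg.eigvalsh(fit.sigma_)
        assert (w > 0).all()
        assert np.allclose(fit.sigma_, fit.sigma_.T)


class TestExternalOracle:
    def test_matches_nlme_gls_reml(self, tmp_path):
        """Fixed effects agree with R nlme::gls (unstructured covariance via
        corSymm + varIdent, REML) to optimizer tolerance."""
        assert shutil.which("Rscript"), "Rscript expected on PATH"
        cfg = SimulationConfig(n_subjects_per_arm=25, seed=42)
        rec, _, _ = generate_trial(cfg)
        fit = fit_mmrm(rec, "BM1")

        d = rec[rec.biomarker == "BM1"].pivot_table(
            index=["subject", "arm"], columns="visit_week", values="value")
        long = d[[52, 104]].stack().rename("value").reset_index()
        long.columns = ["subject", "arm", "visit_week", "value"]
        long["y"] = np.log(long["value"])
        long["base"] = np.log(
            d[0].loc[pd.MultiIndex.from_frame(long[["subject", "arm"]])].to_numpy())
        long["vidx"] = (long["visit_week"] == 104).astype(int) + 1
        csv = tmp_path / "d.csv"
        long.to_csv(csv, index=False)
        script = tmp_path / "gls.R"
        script.write_text(f"""
suppressMessages(library(nlme))
d <- read.csv("{csv}")
d$arm <- relevel(factor(d$arm), ref="control")
d$visit <- factor(d$visit_week)
m <- gls(y ~ arm + visit + arm:visit + base, data=d,
         correlation=corSymm(form=~vidx|subject),
         weights=varIdent(form=~1|visit), method="REML")
co <- coef(m)
for (n in names(co)) cat(n, co[[n]], "\\n")
""")
        out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True, check=True)
        r_coef = {}
        for line in out.stdout.strip().splitlines():
            name, val = line.split()
            r_coef[name] = float(val)
        mapping = {
            "Intercept": "(Intercept)",
            "arm[active]": "armactive",
            "visit[104]": "visit104",
            "arm[active]:visit[104]": "armactive:visit104",
            "baseline": "base",
        }
        for mine, theirs in mapping.items():
            assert fit.params_[mine] == pytest.approx(r_coef[theirs], abs=1e-4)
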