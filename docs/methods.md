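# Methods

## Overview

`moanet` implements an in-silico biomarker-discovery pipeline for a chronic
disease treated with a drug whose mechanism of action (MoA) is partly known
from literature and partly observed in an in-vitro transcriptomics
experiment. The motivating application is diabetic kidney disease (DKD)
under SGLT2 inhibition, but nothing in the code is specific to that system:
gene identifiers are opaque strings and the interactome is caller-supplied.

The pipeline has two halves:

1. **Network half.** A disease molecular model and a drug-MoA molecular
   model are built as induced subgraphs of a protein–protein interaction
   network; their overlap (the *interference signature*) and its network
   neighbourhood yield prioritized biomarker candidates.
2. **Trial half.** Candidate biomarkers measured longitudinally in a
   randomized trial are analysed with a mixed-model repeated-measures
   (MMRM) framework: between-arm percentage-difference contrasts, change
   correlations, tertile stratification, and the association between early
   biomarker change and subsequent eGFR decline.

Every stage can run on synthetic data with planted truth, which is how the
test suite validates the statistics.

## Molecular models

A *molecular model* is a gene set `S` mapped onto the interactome `G`
together with the induced edge set `E(G[S])`. A member is retained only if
it has at least one induced interaction with another member; "connected"
therefore means *non-isolated* (degree ≥ 1), not single-component — models
may consist of several components. This is deliberate: literature-derived
gene sets routinely decompose into a few linked clusters, and requiring a
single component would discard biologically meaningful satellites.

The drug-MoA model starts from a literature-derived core and is extended by
one pass of the deregulation rule: a non-core gene `g` is added iff

* `|signed_fc(g)| ≥ τ` (default τ = 1.2, inclusive), and
* `g` is adjacent in the interactome to at least one *core* gene that is
  itself deregulated.

Adjacency to other added genes does not recruit (no transitive closure);
the extension is a single induced-subgraph recomputation, so the result is
independent of iteration order. Genes absent from the interactome are
dropped with a logged warning, not an error, because identifier namespaces
never match perfectly.

The interference signature of models A and B is `nodes(A) ∩ nodes(B)` with
`edges(A) ∩ edges(B)`; since both are induced on the same interactome this
equals the induced edge set on the shared nodes. Candidate ranking takes a
prognostic gene set (from the literature-evidence filter below) and tiers
it by shortest-path distance to the signature measured *on the full
interactome* (distance 0 = in signature; 1..`proximity_max` = proximal,
default 1). Proximity is measured on the interactome rather than within a
model because its purpose is to recruit genes *outside* the signature. The
output ordering (tier, distance, descending evidence count, gene ID) is a
deterministic total order.

### Literature-evidence filter

A publication supports a gene iff it (a) carries the required disease term
as a *major* topic, (b) carries all required terms (e.g. "biological
markers" and "prognosis", matched case-insensitively after whitespace
normalisation), (c) has at least one allowed study context (human, animal
model, or clinical trial) and (d) is not a high-throughput omics-profiling
study. Matching is exact string matching on a supplied annotation table; no
ontology-tree expansion is attempted, so synonymous terms must already be
normalised upstream.

## Fold-change filter

Probe-level intensities are collapsed to genes by the per-sample arithmetic
mean of each gene's probes (unannotated probes dropped). The signed fold
change encodes the ratio of arithmetic group means `r = treated/control` as
`r` if `r ≥ 1` else `−1/r`, so magnitude is direction-symmetric and the
selection rule `|signed_fc| ≥ τ` treats up- and down-regulation alike. The
comparison is inclusive by default (a gene at exactly 1.2 passes) with a
`strict` option. Fold changes are computed on the linear scale; no
significance testing is attached by default, because minor-but-significant
effects are exactly what the magnitude criterion exists to exclude, but a
Welch t-test on log intensities can be switched on (`welch_alpha`).

## MMRM

For one biomarker, the response at the post-baseline visits is modelled as

    y_iv = β0 + β_arm + β_visit + β_arm×visit + γ·baseline_i + ε_iv,
    (ε_i,v1 … ε_i,vk) ~ N(0, Σ)   with Σ unstructured (k×k),

with `y = log(value)` by default (skewed biomarkers act multiplicatively);
with `log_transform=False` the response is the raw percentage change from
baseline (intended for markers analysed on their natural scale). Subjects
with partially missing visits contribute all available visits, which is
valid under missing-at-random.

Estimation is restricted maximum likelihood. Σ is parameterised by its
Cholesky factor with log-diagonal, guaranteeing positive definiteness; the
fixed effects are profiled out, so the optimizer (Nelder–Mead, which is
robust for the ≤ 6 covariance parameters of 2–3 visits) works on
`k(k+1)/2` parameters only. Subjects are grouped by visit-availability
pattern so each likelihood evaluation is a handful of vectorised einsums.
Start values come from the pairwise-complete OLS residual covariance,
eigenvalue-clipped to positive definiteness. Non-convergence sets a flag
and raises a warning — never silently ignored.

The between-arm contrast δ is the arm difference averaged over the
post-baseline visits (per-visit contrasts are also emitted). For
log-responses the percentage difference is `100·(exp(δ) − 1)`, with CI
bounds transformed the same way, so relabelling arms maps `p%` to
`100·(1/(1+p/100) − 1)%` automatically.

**Inference.** Wald statistics are referred to a t distribution with
Satterthwaite degrees of freedom, `df = 2(c'Φc)² / Var(c'Φc)`, where
`Φ = (X'V⁻¹X)⁻¹` and the variance comes from the delta method with the
numerically differentiated REML information matrix. Simulation showed the
plain normal reference slightly undercovers at a few hundred subjects
(empirical pivot SD ≈ 1.02), the familiar small-sample behaviour that
Satterthwaite/Kenward–Roger corrections address in standard MMRM software;
the t reference restores ~95% empirical coverage. The fixed effects agree
with R `nlme::gls` (corSymm + varIdent, REML) to ~1e-5 on test data.

One derivable consequence of the baseline covariate worth knowing: if the
marginal correlation between two post-baseline visits is ρ (shared subject
intercept), the *conditional* correlation after adjusting for the baseline
value is ρ(1−ρ)σ² / ((1−ρ²)σ²) = ρ/(1+ρ). Parameter-recovery tests of Σ
therefore either fit without the baseline covariate (recovering ρ) or
compare against ρ/(1+ρ).

### eGFR-decline association

The second MMRM models eGFR change from baseline at the post-baseline
visits with treatment and visit as factors, the week-52 biomarker change
and its visit interaction as covariates, adjusted for baseline age, sex,
systolic/diastolic BP, BMI, HbA1c, eGFR, log UACR and the UACR log-change
to week 52. The unstructured covariance is reused. The continuous analysis
reports the biomarker-change coefficient averaged over its visit
interactions; grouped analyses (rank tertiles, or named percentage-change
bands: reduction ≥ 30%, reduction 0–30%, any increase) report per-group
least-squares means of eGFR change — design rows with covariates at their
sample means, visits equally weighted, arms weighted by observed
proportions — with t-based 95% CIs.

### Other trial statistics

Pearson correlations between percentage changes (or achieved levels) use
complete pairs and flag significance at p < 0.001; undefined correlations
(constant vectors, < 3 pairs) are reported as missing. Tertile
stratification is rank-based with stable subject-ID tie-breaks; when n is
not divisible by 3 the extra subjects go to the *lower* tertiles first, so
294 values always split 98/98/98 and 10 split 4/3/3. No multiplicity
adjustment is applied across biomarkers by default, matching the unadjusted
two-sided p < 0.05 convention of the motivating analysis.

## Synthetic data generator

The generator defines the package's reference study conditions:

| parameter | default | rationale |
|---|---|---|
| interactome | preferential attachment, 500 genes, m = 3 | real interactomes are heavy-tailed; topology otherwise unconstrained |
| expression design | 4 replicates/arm, 2 probes/gene | typical small in-vitro microarray design |
| baseline intensity | log-normal, median 100, log-SD 1 | plausible array intensity scale |
| planted \|FC\| | uniform [1.5, 3], random sign | clearly above the 1.2 selection threshold |
| expression noise | log-normal, sd 0.05 (log scale) | low technical noise of replicate arrays |
| trial arms | control / active, 100 subjects/arm | mid-size phase-2/3 biomarker substudy |
| visits | weeks 0, 52, 104 | annual sampling with baseline |
| planted effect | ×0.75 in active arm at both post-baseline visits | a 25% reduction, typical of a strong biomarker response |
| biomarker noise | total log-SD 0.4, within-subject corr 0.5 | moderate biological variability with subject tracking |
| covariates | age 56±9, 42% female, SBP 134±13, DBP 81±8, BMI 30.6±5, HbA1c 63±9 mmol/mol, eGFR 90±18, UACR log-normal median 3.7 mg/mmol | typical type-2-diabetes trial population |
| eGFR drift | −2 ml·min⁻¹·(1.73 m)⁻² per year, residual SD 5 | early-DKD decline rate |
| dropout | off by default; optional MAR loss of the last visit | matches available-data likelihood analysis |

A single seed is propagated through `numpy.random.SeedSequence.spawn`, so
every generator is a pure function of (config, seed) and planted truth is
always returned, never hidden. eGFR and UACR longitudinal series are
emitted alongside the biomarkers because the eGFR-decline model needs them;
a config knob plants a linear dependence of eGFR decline on the first
biomarker's log-change (0 by default = null).

What the generator does *not* emulate: probe sequence effects, array
spatial artefacts, detection limits, informative missingness, visit-time
jitter, or assay batch effects. Passing tests therefore demonstrate the
statistical machinery is correct under the stated model, not that real
microarray or plasma-assay data satisfy that model.

The deterministic benchmark scenario (`make_benchmark_scenario`) is a
hand-constructed synthetic graph whose pipeline output has a known shape —
78 drug-literature genes of which 74 interlink, 11 deregulated core genes,
31 qualifying extensions (105-node MoA model), a 44-node interference
signature and 10 in-signature prognostic candidates plus 3 proximal ones —
used as a structural regression fixture for the full pipeline.

## Numerical choices and degenerate inputs

* Fold-change ratio exactly 1 encodes as +1.0; swapping group labels flips
  all signs except at that boundary.
* REML optimisation tolerances: `xatol 1e-8`, `fatol 1e-10`; the noise-free
  matched-pair construction reproduces a planted ×0.75 effect as −25.0% to
  ≤ 1e-6.
* Satterthwaite df is clamped below at 3 and falls back to the normal
  reference if the delta-method variance is non-positive.
* Empty gene sets error in extraction; empty interference signatures and
  empty candidate lists are valid results.
* Tertiles require ≥ 3 non-missing values; MMRM requires ≥ 2 post-baseline
  visits and ≥ 2 subjects per arm-visit cell.

## Repository shape

Fit/transform-shaped stages (probe summarisation, fold-change selection,
the MMRM) are scikit-learn-style estimators (`fit`, fitted `_` attributes,
`get_params`/`set_params`) with thin functional wrappers; the graph stage
and the generators are plain functions, since set algebra and simulation
have no estimator semantics. The CLI is a thin `click` layer over the
library.

## Known limitations

* Node importance is unweighted: no centrality or edge-confidence
  weighting enters extraction, interference or ranking.
* The evidence filter is string matching on a supplied table; it cannot
  expand ontology hierarchies or resolve synonyms.
* MMRM inference is asymptotic (t/Satterthwaite); very small trials
  (tens of subjects) would warrant Kenward–Roger covariance inflation.
* The percentage-change response mode (`log_transform=False`) is
  heteroscedastic by construction; its contrast is reported untransformed.
* Simulated trials are two-arm by default; multi-arm designs work but the
  CLI reports one contrast pair at a time.
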