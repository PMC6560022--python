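"""Synthetic data generators with known planted truth.

Every downstream stage of the pipeline (fold-change filtering, molecular
model construction, network interference, MMRM trial statistics) is testable
against data generated here: a scale-free interactome, planted disease/drug
gene sets with controlled overlap, two-arm expression data with planted
multiplicative fold changes, and three-visit longitudinal trial data with
planted arm-by-visit multiplicative effects and subject-level correlation.

All generators are pure functions of (config, seed): a single global seed is
propagated to sub-generators through independent derived streams
(`numpy.random.SeedSequence.spawn`), so each generator is individually
reproducible and adding one generator call never perturbs another's stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "generate_interactome",
    "generate_gene_sets",
    "generate_expression",
    "generate_trial",
    "make_benchmark_scenario",
    "BenchmarkScenario",
]

#: default multiplicative treatment effect per post-baseline week (active arm)
_DEFAULT_EFFECTS = {"active": {52: 0.75, 104: 0.75}}


@dataclass
class SimulationConfig:
    """Bundle of simulation parameters; validated on construction.

    The defaults are the package's reference study conditions: a 500-gene
    scale-free interactome, 4 expression replicates per arm with log-normal
    noise (sd 0.05 on the natural-log scale) and planted fold-change
    magnitudes in [1.5, 3], and a two-arm trial with 100 subjects per arm
    measured at weeks 0, 52 and 104 with a planted multiplicative effect of
    0.75 (a 25% reduction) in the active arm.
    """

    interactome_size: int = 500
    attachment: int = 3
    disease_set_size: int = 60
    drug_set_size: int = 30
    planted_overlap: int = 10
    n_de_genes: int = 25
    fc_low: float = 1.5
    fc_high: float = 3.0
    noise_sd: float = 0.05
    n_replicates: int = 4
    probes_per_gene: int = 2
    n_subjects_per_arm: int = 100
    visit_weeks: tuple[int, ...] = (0, 52, 104)
    arms: tuple[str, ...] = ("control", "active")
    planted_effects: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {a: dict(v) for a, v in _DEFAULT_EFFECTS.items()}
    )
    within_subject_corr: float = 0.5
    trial_log_sd: float = 0.4
    biomarkers: tuple[str, ...] = ("BM1",)
    dropout_rate: float = 0.0
    egfr_slope_per_log_change: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.interactome_size < 2:
            raise ValueError("interactome_size must be >= 2")
        if not 1 <= self.attachment < self.interactome_size:
            raise ValueError("attachment must satisfy 1 <= attachment < interactome_size")
        for name in ("disease_set_size", "drug_set_size", "planted_overlap", "n_de_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.planted_overlap > min(self.disease_set_size, self.drug_set_size):
            raise ValueError("planted_overlap exceeds a set size")
        total = self.disease_set_size + self.drug_set_size - self.planted_overlap
        if total > self.interactome_size:
            raise ValueError("gene sets do not fit in the interactome")
        if self.n_de_genes > self.interactome_size:
            raise ValueError("n_de_genes exceeds interactome size")
        if self.fc_low < 1 or self.fc_high < self.fc_low:
            raise ValueError("need 1 <= fc_low <= fc_high")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_replicates < 1 or self.probes_per_gene < 1:
            raise ValueError("n_replicates and probes_per_gene must be positive")
        if not 0 <= self.within_subject_corr < 1:
            raise ValueError("within_subject_corr must lie in [0, 1)")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if len(self.arms) < 2:
            raise ValueError("need at least two arms")
        if 0 not in self.visit_weeks or len(self.visit_weeks) < 2:
            raise ValueError("visit_weeks must include week 0 and one post-baseline visit")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted_effects"] = {a: dict(v) for a, v in self.planted_effects.items()}
        return d


@dataclass
class PlantedTruth:
    """Ground truth recorded by the generators; never hidden state."""

    disease_genes: frozenset = frozenset()
    drug_literature_genes: frozenset = frozenset()
    de_genes: dict = field(default_factory=dict)  # gene -> signed fold change
    trial_effects: dict = field(default_factory=dict)  # (arm, week) -> multiplicative effect


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _gene_id(i: int) -> str:
    return f"G{i:05d}"


def generate_interactome(n: int, attachment: int, seed: int = 0) -> nx.Graph:
    """Scale-free interactome by preferential attachment.

    Returns an undirected simple connected graph on ``n`` gene nodes
    (labelled ``G00000`` ...) with ``attachment`` edges added per new node,
    hence ``attachment * (n - attachment)`` edges in total.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 1 <= attachment < n:
        raise ValueError("attachment must satisfy 1 <= attachment < n")
    g = nx.barabasi_albert_graph(n, attachment, seed=int(seed))
    return nx.relabel_nodes(g, {i: _gene_id(i) for i in g.nodes})


def generate_gene_sets(network: nx.Graph, config: SimulationConfig) -> PlantedTruth:
    """Sample disease and drug-literature gene sets with a planted overlap.

    Sets are drawn without replacement from the network's nodes, sharing
    exactly ``config.planted_overlap`` genes.
    """
    rng = _streams(config.seed, 4)[0]
    nodes = sorted(network.nodes)
    o = config.planted_overlap
    d_only = config.disease_set_size - o
    g_only = config.drug_set_size - o
    total = o + d_only + g_only
    if total > len(nodes):
        raise ValueError("gene sets do not fit in the network")
    picked = rng.choice(nodes, size=total, replace=False)
    shared = picked[:o]
    disease = frozenset(shared) | frozenset(picked[o : o + d_only])
    drug = frozenset(shared) | frozenset(picked[o + d_only :])
    effects = {
        (arm, w): float(config.planted_effects.get(arm, {}).get(w, 1.0))
        for arm in config.arms
        for w in config.visit_weeks
        if w != 0
    }
    return PlantedTruth(disease_genes=disease, drug_literature_genes=drug, trial_effects=effects)


def generate_expression(
    network: nx.Graph, truth: PlantedTruth, config: SimulationConfig
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Two-arm probe-level expression data with planted fold changes.

    Control-arm gene means are log-normal around 100; for each planted
    deregulated gene the treated mean is the control mean times the planted
    fold-change ratio. Each gene carries ``probes_per_gene`` probes with
    probe-specific affinity multipliers, and observations get multiplicative
    log-normal noise with standard deviation ``noise_sd`` on the log scale.
    Returns the matrix and the truth updated with ``de_genes``.
    """
    if config.noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = _streams(config.seed, 4)[1]
    genes = sorted(network.nodes)
    if config.n_de_genes > len(genes):
        raise ValueError("n_de_genes exceeds the number of genes")
    de = rng.choice(genes, size=config.n_de_genes, replace=False)
    mag = rng.uniform(config.fc_low, config.fc_high, size=config.n_de_genes)
    sign = rng.choice([-1.0, 1.0], size=config.n_de_genes)
    de_genes = {g: float(s * m) for g, s, m in zip(de, sign, mag)}

    base = 100.0 * np.exp(rng.normal(0.0, 1.0, size=len(genes)))
    ratio = np.ones(len(genes))
    idx = {g: i for i, g in enumerate(genes)}
    for g, sfc in de_genes.items():
        ratio[idx[g]] = sfc if sfc > 0 else -1.0 / sfc

    k = config.probes_per_gene
    affinity = np.exp(rng.normal(0.0, 0.3, size=(len(genes), k)))
    samples = [f"treated_{i + 1}" for i in range(config.n_replicates)] + [
        f"control_{i + 1}" for i in range(config.n_replicates)
    ]
    treated_mean = (base * ratio)[:, None] * affinity  # genes x probes
    control_mean = base[:, None] * affinity
    mean = np.concatenate(
        [
            np.repeat(treated_mean[:, :, None], config.n_replicates, axis=2),
            np.repeat(control_mean[:, :, None], config.n_replicates, axis=2),
        ],
        axis=2,
    )  # genes x probes x samples
    noise = np.exp(rng.normal(0.0, config.noise_sd, size=mean.shape)) if config.noise_sd > 0 else 1.0
    values = (mean * noise).reshape(len(genes) * k, len(samples))
    probes = [f"{g}_p{j + 1}" for g in genes for j in range(k)]
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=probes, columns=samples),
        groups=pd.Series(
            ["treated"] * config.n_replicates + ["control"] * config.n_replicates, index=samples
        ),
        annotation=pd.Series({p: p.rsplit("_p", 1)[0] for p in probes}),
    )
    out = PlantedTruth(
        disease_genes=truth.disease_genes,
        drug_literature_genes=truth.drug_literature_genes,
        de_genes=de_genes,
        trial_effects=dict(truth.trial_effects),
    )
    return matrix, out


# baseline covariate distributions of a typical type-2-diabetes trial population
_COVARIATE_SPECS = {
    "age": (56.0, 9.0),
    "sbp": (134.0, 13.0),
    "dbp": (81.0, 8.0),
    "bmi": (30.6, 5.0),
    "hba1c": (63.0, 9.0),
    "egfr": (90.0, 18.0),
}


def generate_trial(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Long-format longitudinal trial data with planted arm-by-visit effects.

    Biomarker values are log-normal with a subject-level random intercept
    inducing ``within_subject_corr`` between a subject's visits (total log-SD
    ``trial_log_sd``); post-baseline arm means are multiplied by
    ``planted_effects``. eGFR and UACR longitudinal series are emitted
    alongside the biomarkers (eGFR on its natural scale with a mild decline;
    its dependence on the first biomarker's week-52 log-change is controlled
    by ``egfr_slope_per_log_change``, 0 by default). Baseline covariates are
    drawn from fixed plausible distributions. Returns ``(records, covariates,
    truth)``.
    """
    if not 0 <= config.within_subject_corr < 1:
        raise ValueError("within_subject_corr must lie in [0, 1)")
    rng = _streams(config.seed, 4)[2]
    weeks = sorted(config.visit_weeks)
    post = [w for w in weeks if w != 0]
    n_arm = config.n_subjects_per_arm
    n_tot = n_arm * len(config.arms)
    subjects = [f"S{i + 1:04d}" for i in range(n_tot)]
    arm_of = np.repeat(list(config.arms), n_arm)

    cov = {"subject": subjects, "arm": arm_of}
    for name, (mu, sd) in _COVARIATE_SPECS.items():
        cov[name] = np.round(rng.normal(mu, sd, n_tot), 1)
    cov["female"] = (rng.random(n_tot) < 0.42).astype(int)
    cov["uacr"] = np.round(np.exp(rng.normal(np.log(3.7), 0.8, n_tot)), 2)
    covariates = pd.DataFrame(cov).set_index("subject")
    covariates["egfr"] = covariates["egfr"].clip(lower=20.0)

    rho, s_tot = config.within_subject_corr, config.trial_log_sd
    tau = s_tot * np.sqrt(rho)
    sig = s_tot * np.sqrt(1.0 - rho)
    effects = {
        (arm, w): float(config.planted_effects.get(arm, {}).get(w, 1.0))
        for arm in config.arms
        for w in post
    }

    frames = []
    first_log_change = np.zeros(n_tot)
    for bi, marker in enumerate(config.biomarkers):
        b = rng.normal(0.0, tau, n_tot)
        eps = rng.normal(0.0, sig, (n_tot, len(weeks)))
        logeff = np.zeros((n_tot, len(weeks)))
        for j, w in enumerate(weeks):
            if w != 0:
                logeff[:, j] = np.log([effects[(a, w)] for a in arm_of])
        logy = np.log(10.0) + b[:, None] + logeff + eps
        if bi == 0:
            j52 = weeks.index(post[0])
            first_log_change = logy[:, j52] - logy[:, weeks.index(0)]
        frames.append(
            pd.DataFrame(
                {
                    "subject": np.repeat(subjects, len(weeks)),
                    "arm": np.repeat(arm_of, len(weeks)),
                    "visit_week": np.tile(weeks, n_tot),
                    "biomarker": marker,
                    "value": np.exp(logy).ravel(),
                }
            )
        )

    # renal series: eGFR with a mild decline (and optional planted dependence
    # on the first biomarker's week-52 log-change), UACR roughly stable
    egfr0 = covariates["egfr"].to_numpy()
    egfr_vals = np.empty((n_tot, len(weeks)))
    for j, w in enumerate(weeks):
        if w == 0:
            egfr_vals[:, j] = egfr0
        else:
            drift = -2.0 * w / 52.0
            dep = config.egfr_slope_per_log_change * first_log_change * (w / post[0])
            egfr_vals[:, j] = egfr0 + drift + dep + rng.normal(0.0, 5.0, n_tot)
    uacr0 = covariates["uacr"].to_numpy()
    uacr_vals = np.exp(
        np.log(uacr0)[:, None] + np.where(np.array(weeks) == 0, 0.0, 1.0) * rng.normal(0.0, 0.3, (n_tot, len(weeks)))
    )
    for name, vals in (("eGFR", egfr_vals), ("UACR", uacr_vals)):
        frames.append(
            pd.DataFrame(
                {
                    "subject": np.repeat(subjects, len(weeks)),
                    "arm": np.repeat(arm_of, len(weeks)),
                    "visit_week": np.tile(weeks, n_tot),
                    "biomarker": name,
                    "value": vals.ravel(),
                }
            )
        )

    records = pd.concat(frames, ignore_index=True)
    if config.dropout_rate > 0 and len(post) > 1:
        # monotone missing-at-random dropout: affected subjects lose the last visit
        lost = np.array(subjects)[rng.random(n_tot) < config.dropout_rate]
        records = records[
            ~(records["subject"].isin(lost) & (records["visit_week"] == weeks[-1]))
        ].reset_index(drop=True)

    truth = PlantedTruth(trial_effects=effects)
    return records, covariates, truth


# ---------------------------------------------------------------------------
# deterministic benchmark scenario (synthetic)
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkScenario:
    """Synthetic benchmark with a fully known structure.

    A hand-constructed interactome and inputs whose pipeline output has a
    fixed shape: a drug-literature set of 78 genes of which 74 are mutually
    linked (the MoA core), 11 deregulated core genes, 31 qualifying extension
    genes (final MoA model: 105 nodes), a 44-node interference signature with
    the disease model, 10 prognostic candidates inside the signature and 3 at
    network distance 1.
    """

    network: nx.Graph
    drug_literature_genes: frozenset
    disease_genes: frozenset
    expression: ExpressionMatrix
    annotations: pd.DataFrame
    planted_fc: dict


def make_benchmark_scenario() -> BenchmarkScenario:
    """Build the deterministic synthetic benchmark scenario."""
    g = nx.Graph()
    core = [f"D{i:02d}" for i in range(1, 75)]  # D01..D74 chained
    g.add_edges_from(zip(core, core[1:]))
    isolates = [f"D{i:02d}" for i in range(75, 79)]  # in the set, no in-set links
    fillers = [f"F{i:02d}" for i in range(1, 5)]
    g.add_edges_from(zip(isolates, fillers))

    dereg_core = [f"D{i:02d}" for i in range(1, 22, 2)]  # 11 odd-numbered core genes
    extensions = [f"E{i:02d}" for i in range(1, 32)]  # each hangs off a deregulated core gene
    for k, e in enumerate(extensions):
        g.add_edge(e, dereg_core[k % len(dereg_core)])

    disease_only = [f"X{i:02d}" for i in range(1, 21)]
    g.add_edges_from(zip(disease_only, disease_only[1:]))

    proximal = ["P01", "P02", "P03"]  # distance 1 from the signature
    g.add_edge("P01", "D02")
    g.add_edge("P02", "E05")
    g.add_edge("P03", "D30")

    drug_set = frozenset(core + isolates)
    disease_set = frozenset(
        [f"D{i:02d}" for i in range(1, 31)] + [f"E{i:02d}" for i in range(1, 15)] + disease_only
    )

    # planted fold changes: the 11 core genes and 31 extensions pass |FC| >= 1.2;
    # X05 and F02 also pass but do not qualify for extension (not linked to a
    # deregulated core gene); everything else sits at FC 1.0
    fc: dict[str, float] = {}
    for i, gene in enumerate(dereg_core):
        fc[gene] = 1.5 + 0.1 * i if i % 2 == 0 else -(1.4 + 0.1 * i)
    for i, gene in enumerate(extensions):
        fc[gene] = 1.25 + 0.05 * (i % 10) if i % 2 == 0 else -(1.2 + 0.05 * (i % 10))
    fc["X05"] = 2.0
    fc["F02"] = -1.6

    genes = sorted(g.nodes)
    control = np.full(len(genes), 100.0)
    ratios = np.array([abs(fc.get(x, 1.0)) if fc.get(x, 1.0) > 0 else 1.0 / abs(fc.get(x, 1.0)) for x in genes])
    values = pd.DataFrame(
        {
            "treated_1": control * ratios,
            "treated_2": control * ratios,
            "control_1": control,
            "control_2": control,
        },
        index=[f"{x}_p1" for x in genes],
    )
    expr = ExpressionMatrix(
        values=values,
        groups=pd.Series(
            {"treated_1": "treated", "treated_2": "treated", "control_1": "control", "control_2": "control"}
        ),
        annotation=pd.Series({f"{x}_p1": x for x in genes}),
    )

    # literature-evidence table: 10 signature genes and the 3 proximal genes carry
    # qualifying publications; D09/D10/D75 rows exercise the exclusion rules
    prognostic_ok = [f"D{i:02d}" for i in range(1, 9)] + ["E01", "E02"]
    rows = []
    pub = 1000
    qual = dict(
        major_terms="diabetic nephropathies",
        terms="biological markers;prognosis",
        study_flags="human",
    )
    for i, gene in enumerate(prognostic_ok + proximal):
        for _ in range(3 if gene == "D01" else 2 if gene == "D02" else 1):
            pub += 1
            rows.append({"gene": gene, "publication_id": f"PMID{pub}", **qual})
    pub += 1
    rows.append(
        {
            "gene": "D09",
            "publication_id": f"PMID{pub}",
            "major_terms": "diabetic nephropathies",
            "terms": "biological markers;prognosis",
            "study_flags": "human;omics_profiling",  # excluded: omics profiling study
        }
    )
    pub += 1
    rows.append(
        {
            "gene": "D10",
            "publication_id": f"PMID{pub}",
            "major_terms": "diabetic nephropathies",
            "terms": "biological markers",  # missing the prognosis term
            "study_flags": "human",
        }
    )
    pub += 1
    rows.append({"gene": "D75", "publication_id": f"PMID{pub}", **qual})  # outside the signature
    annotations = pd.DataFrame(rows)

    return BenchmarkScenario(
        network=g,
        drug_literature_genes=drug_set,
        disease_genes=disease_set,
        expression=expr,
        annotations=annotations,
        planted_fc=fc,
    )
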