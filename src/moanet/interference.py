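"""Network interference between molecular models and candidate ranking.

The interference signature of two molecular models is their shared node set
together with the shared protein-protein interactions; since both models
are induced on the same interactome, the shared edges equal the
interactome-induced edge set on the shared nodes. Biomarker candidates are
prognostic genes inside the signature, or in close network proximity to it
(shortest-path distance up to ``proximity_max`` on the full interactome,
default 1: a direct neighbour).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .models import MolecularModel

__all__ = [
    "InterferenceSignature",
    "compute_interference",
    "filter_prognostic_evidence",
    "rank_candidates",
]

logger = logging.getLogger(__name__)

DEFAULT_MAJOR = "diabetic nephropathies"
DEFAULT_TERMS = ("biological markers", "prognosis")
DEFAULT_CONTEXTS = ("human", "animal_model", "clinical_trial")
DEFAULT_EXCLUDE = ("omics_profiling",)

_TIER_ORDER = {"in_signature": 0, "proximal": 1}


@dataclass(frozen=True)
class InterferenceSignature:
    """Shared nodes and shared edges of two molecular models."""

    shared_nodes: frozenset
    shared_edges: frozenset


def compute_interference(model_a: MolecularModel, model_b: MolecularModel) -> InterferenceSignature:
    """Shared node set and shared edge set of two models (symmetric)."""
    return InterferenceSignature(
        shared_nodes=model_a.nodes & model_b.nodes,
        shared_edges=model_a.edges & model_b.edges,
    )


def _norm_term(s: str) -> str:
    return re.sub(r"\s+", " ", str(s).strip()).casefold()


def _split(cell) -> set[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return set()
    if isinstance(cell, str):
        parts = cell.split(";")
    else:
        parts = list(cell)
    return {_norm_term(p) for p in parts if _norm_term(p)}


def filter_prognostic_evidence(
    table: pd.DataFrame,
    required_major: str = DEFAULT_MAJOR,
    required_terms: Iterable[str] = DEFAULT_TERMS,
    allowed_contexts: Iterable[str] = DEFAULT_CONTEXTS,
    exclude_flags: Iterable[str] = DEFAULT_EXCLUDE,
) -> dict[str, int]:
    """Count qualifying publications per gene.

    A publication counts for a gene iff it carries ``required_major`` as a
    major-topic term, carries every term in ``required_terms`` (major or
    plain), carries at least one ``allowed_contexts`` study flag, and none
    of ``exclude_flags``. Term matching is case-insensitive after
    whitespace normalisation. Genes with count >= 1 are prognostic.
    """
    req_major = _norm_term(required_major)
    req_terms = {_norm_term(t) for t in required_terms}
    allowed = {_norm_term(t) for t in allowed_contexts}
    excluded = {_norm_term(t) for t in exclude_flags}
    counts: dict[str, set[str]] = {}
    for row in table.itertuples(index=False):
        pub = str(row.publication_id)
        if not pub:
            continue
        major = _split(getattr(row, "major_terms", None))
        terms = _split(getattr(row, "terms", None)) | major
        flags = _split(getattr(row, "study_flags", None))
        if req_major not in major:
            continue
        if not req_terms <= terms:
            continue
        if allowed and not (flags & allowed):
            continue
        if flags & excluded:
            continue
        counts.setdefault(str(row.gene), set()).add(pub)
    return {g: len(p) for g, p in counts.items()}


def rank_candidates(
    signature: InterferenceSignature,
    network: nx.Graph,
    prognostic: Mapping[str, int] | Iterable[str],
    proximity_max: int = 1,
) -> pd.DataFrame:
    """Ordered candidate list from signature membership and proximity.

    ``prognostic`` is either a gene set or a gene -> evidence-count mapping
    (as returned by :func:`filter_prognostic_evidence`). Candidates are
    prognostic genes at shortest-path distance 0 (tier ``in_signature``) up
    to ``proximity_max`` (tier ``proximal``) from the signature, ordered by
    (tier, distance, descending evidence count, gene identifier).
    """
    if proximity_max < 0:
        raise ValueError("proximity_max must be >= 0")
    evidence = dict(prognostic) if isinstance(prognostic, Mapping) else {g: 0 for g in prognostic}
    unknown = set(evidence) - set(network.nodes)
    if unknown:
        logger.warning("dropping %d prognostic gene(s) absent from the network", len(unknown))
        evidence = {g: c for g, c in evidence.items() if g not in unknown}
    sources = [n for n in signature.shared_nodes if n in network]
    if sources:
        dist = nx.multi_source_dijkstra_path_length(
            network, sources, cutoff=proximity_max, weight=None
        )
    else:
        dist = {}
    rows = [
        {
            "gene": g,
            "tier": "in_signature" if dist[g] == 0 else "proximal",
            "distance": int(dist[g]),
            "evidence_count": int(evidence[g]),
        }
        for g in evidence
        if g in dist
    ]
    out = pd.DataFrame(rows, columns=["gene", "tier", "distance", "evidence_count"])
    if len(out):
        out = out.sort_values(
            by=["tier", "distance", "evidence_count", "gene"],
            ascending=[True, True, False, True],
            key=lambda col: col.map(_TIER_ORDER) if col.name == "tier" else col,
        ).reset_index(drop=True)
    return out
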