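"""Readers and writers for the pipeline's plain-text formats.

Interactomes travel as 2-column TSV edge lists (or SIF), gene sets as
1-column text, expression data as TSV matrices plus a probe-annotation TSV,
trial data as long CSV plus a covariates CSV, molecular models and
interference signatures as JSON, candidate lists and contrasts as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .interference import InterferenceSignature
from .models import MolecularModel, _norm_edge

__all__ = [
    "write_interactome", "read_interactome",
    "write_gene_set", "read_gene_set",
    "write_expression", "read_expression",
    "write_fold_changes", "read_fold_changes",
    "write_trial", "read_trial",
    "write_model", "read_model",
    "write_signature", "read_signature",
    "write_candidates",
]

_EDGE_HEADER = ("gene_a", "gene_b")


def write_interactome(network: nx.Graph, path: str | Path) -> None:
    """Edge list TSV: lexicographically ordered endpoints, sorted lines."""
    edges = sorted(_norm_edge(u, v) for u, v in network.edges)
    with open(path, "w") as fh:
        fh.write("\t".join(_EDGE_HEADER) + "\n")
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")


def read_interactome(path: str | Path) -> nx.Graph:
    """Read a 2-column TSV edge list or a 3-column SIF file."""
    path = Path(path)
    g = nx.Graph()
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t" if "\t" in line else None)
            if not parts or not parts[0]:
                continue
            if i == 0 and tuple(parts[:2]) == _EDGE_HEADER:
                continue
            if path.suffix.lower() == ".sif" and len(parts) >= 3:
                u, v = parts[0], parts[2]
            else:
                u, v = parts[0], parts[1]
            if u != v:
                g.add_edge(u, v)
    return g


def write_gene_set(genes, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_gene_set(path: str | Path) -> frozenset:
    return frozenset(x.strip() for x in Path(path).read_text().splitlines() if x.strip())


def write_expression(matrix: ExpressionMatrix, values_path, annotation_path) -> None:
    out = matrix.values.copy()
    out.index.name = "probe"
    out.to_csv(values_path, sep="\t")
    if matrix.annotation is not None:
        ann = matrix.annotation.rename("gene")
        ann.index.name = "probe"
        ann.to_csv(annotation_path, sep="\t")


def read_expression(values_path, annotation_path=None) -> ExpressionMatrix:
    """Read an expression TSV; sample group = part before the last '_'."""
    vals = pd.read_csv(values_path, sep="\t", index_col=0)
    groups = pd.Series({c: c.rsplit("_", 1)[0] for c in vals.columns})
    ann = None
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep="\t", index_col=0)["gene"]
    return ExpressionMatrix(values=vals, groups=groups, annotation=ann)


def write_fold_changes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_fold_changes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_trial(records: pd.DataFrame, covariates: pd.DataFrame, records_path, covariates_path) -> None:
    records.to_csv(records_path, index=False)
    covariates.to_csv(covariates_path)


def read_trial(records_path, covariates_path=None):
    records = pd.read_csv(records_path)
    covariates = pd.read_csv(covariates_path, index_col=0) if covariates_path else None
    return records, covariates


def write_model(model: MolecularModel, path) -> None:
    payload = {
        "nodes": {
            n: {k: (None if v is None or (isinstance(v, float) and np.isnan(v)) else v)
                for k, v in d.items()}
            for n, d in sorted(model.graph.nodes(data=True))
        },
        "edges": [list(e) for e in sorted(model.edges)],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_model(path) -> MolecularModel:
    payload = json.loads(Path(path).read_text())
    g = nx.Graph()
    for n, attrs in payload["nodes"].items():
        g.add_node(n, **attrs)
    g.add_edges_from(payload["edges"])
    return MolecularModel(graph=g)


def write_signature(sig: InterferenceSignature, path) -> None:
    payload = {
        "shared_nodes": sorted(sig.shared_nodes),
        "shared_edges": [list(e) for e in sorted(sig.shared_edges)],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_signature(path) -> InterferenceSignature:
    payload = json.loads(Path(path).read_text())
    return InterferenceSignature(
        shared_nodes=frozenset(payload["shared_nodes"]),
        shared_edges=frozenset(tuple(e) for e in payload["shared_edges"]),
    )


def write_candidates(candidates: pd.DataFrame, path) -> None:
    candidates.to_csv(path, index=False)
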