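"""Molecular models as induced subgraphs of an interactome.

A molecular model is a gene set mapped onto the interactome together with
its induced interactions. A gene belongs to the extracted model only if it
shares at least one interaction with another member of the set (isolated
genes are dropped); the model may consist of several connected components.
A drug mechanism-of-action (MoA) core model can then be extended by
deregulated genes linked to deregulated core members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = ["MolecularModel", "extract_connected_submodel", "extend_moa_model"]

logger = logging.getLogger(__name__)


def _norm_edge(u, v) -> tuple:
    return (u, v) if u <= v else (v, u)


@dataclass
class MolecularModel:
    """Gene set with its interactome-induced edges and per-node attributes.

    ``graph`` holds node attributes ``source`` ('literature', 'expression'
    or 'both'), ``deregulated`` (bool) and ``signed_fc`` (float or None).
    """

    graph: nx.Graph

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.graph.nodes)

    @property
    def edges(self) -> frozenset:
        return frozenset(_norm_edge(u, v) for u, v in self.graph.edges)

    def node_attrs(self) -> pd.DataFrame:
        rows = [
            {
                "gene": n,
                "source": d.get("source"),
                "deregulated": bool(d.get("deregulated", False)),
                "signed_fc": d.get("signed_fc"),
            }
            for n, d in self.graph.nodes(data=True)
        ]
        cols = ["gene", "source", "deregulated", "signed_fc"]
        return pd.DataFrame(rows, columns=cols).set_index("gene").sort_index()

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def extract_connected_submodel(
    network: nx.Graph, genes: Iterable[str], source: str = "literature"
) -> MolecularModel:
    """Extract the induced model of ``genes``, dropping isolated members.

    Genes absent from the network are dropped with a warning. A member is
    kept only when it shares at least one induced interaction with another
    member; multiple connected components are allowed.
    """
    genes = set(genes)
    if not genes:
        raise ValueError("empty input gene set")
    unknown = genes - set(network.nodes)
    if unknown:
        logger.warning("dropping %d gene(s) absent from the network: %s",
                       len(unknown), sorted(unknown)[:10])
    known = genes - unknown
    sub = network.subgraph(known).copy()
    sub.remove_nodes_from([n for n, d in sub.degree if d == 0])
    nx.set_node_attributes(sub, source, "source")
    nx.set_node_attributes(sub, False, "deregulated")
    nx.set_node_attributes(sub, None, "signed_fc")
    return MolecularModel(graph=sub)


def extend_moa_model(
    core: MolecularModel,
    network: nx.Graph,
    deregulated: Mapping[str, float] | pd.DataFrame,
    threshold: float = 1.2,
) -> MolecularModel:
    """Extend a MoA core model with qualifying deregulated genes.

    Core members found in ``deregulated`` (gene -> signed fold change, or a
    DataFrame with a ``signed_fc`` column) with magnitude >= ``threshold``
    are marked deregulated. Every non-core gene whose fold-change magnitude
    reaches the threshold and which is adjacent in the network to at least
    one deregulated *core* gene is added (source='expression'); adjacency to
    other added genes does not qualify (single pass, no transitive closure).
    Edges are recomputed as the induced edge set on the final node set.
    """
    if isinstance(deregulated, pd.DataFrame):
        deregulated = deregulated["signed_fc"].to_dict()
    passing = {g: fc for g, fc in deregulated.items() if abs(fc) >= threshold}
    unknown = set(passing) - set(network.nodes)
    if unknown:
        logger.warning("dropping %d deregulated gene(s) absent from the network", len(unknown))
        passing = {g: fc for g, fc in passing.items() if g not in unknown}

    core_nodes = core.nodes
    dereg_core = {g for g in passing if g in core_nodes}
    extension = {
        g
        for g in passing
        if g not in core_nodes and any(nb in dereg_core for nb in network.neighbors(g))
    }

    final = network.subgraph(core_nodes | extension).copy()
    for n in final.nodes:
        if n in extension:
            final.nodes[n]["source"] = "expression"
        else:
            src = core.graph.nodes[n].get("source", "literature")
            final.nodes[n]["source"] = "both" if (n in dereg_core and src == "literature") else src
        is_dereg = n in passing and (n in dereg_core or n in extension)
        final.nodes[n]["deregulated"] = is_dereg
        final.nodes[n]["signed_fc"] = float(passing[n]) if is_dereg else None
    return MolecularModel(graph=final)
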