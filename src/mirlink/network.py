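"""Bipartite miRNA->target regulatory network assembly and export.

Nodes are miRNAs and genes from the reciprocal-pair tables (isolated
features never enter); a directed edge miRNA -> gene records the stages
supporting the pair and the best (smallest) screen p of that miRNA against
the matching directional mRNA list. Multi-stage support is an edge
attribute rather than parallel edges, which keeps SIF output one line per
interaction. Exports: SIF (``mirna represses gene``), GraphML with typed
attributes, and a flat edge-list TSV — all with deterministic lexicographic
ordering so repeated exports are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .containers import ParameterError, write_table

logger = logging.getLogger("mirlink")

__all__ = ["build_network", "export"]

EXPORT_FORMATS = ("sif", "graphml", "edge-tsv")


def build_network(
    pairs: pd.DataFrame,
    screens: pd.DataFrame | None = None,
    top_mirnas: int | None = None,
) -> nx.DiGraph:
    """Union of per-stage reciprocal pairs as a directed bipartite graph.

    ``top_mirnas`` restricts the graph to the N highest-ranked miRNAs,
    ranked by smallest screen p, then by number of reciprocal pairs, then
    lexicographically — a transparent stand-in for "top identified miRNAs"
    selections whose ranking statistic is otherwise unstated.

    ``pairs`` is a reciprocal-pair table (any mix of stages). Node
    attributes: ``kind`` (mirna/gene) and one ``call_<stage>`` per stage the
    node was DE in. Edge attributes: ``stages`` (sorted, '+'-joined),
    ``n_stages``, and ``screen_p`` — the minimum screen p for that miRNA
    against the gene's direction over the supporting stages, when a screen
    row exists (pairs without a matching screen are tolerated; the attribute
    stays empty).
    """
    g = nx.DiGraph()
    if not len(pairs):
        return g
    screen_p: dict[tuple[str, str, str], float] = {}
    if screens is not None and len(screens):
        for _, row in screens.iterrows():
            key = (row["mirna_id"], row["stage"], row["mrna_list_direction"])
            p = float(row["p_two_tailed"])
            if key not in screen_p or p < screen_p[key]:
                screen_p[key] = p

    if top_mirnas is not None:
        best_p = {}
        for (m, _, _), p in screen_p.items():
            best_p[m] = min(p, best_p.get(m, 1.0))
        n_pairs = pairs.groupby("mirna_id").size()
        ranked = sorted(
            set(pairs["mirna_id"]),
            key=lambda m: (best_p.get(m, 1.0), -int(n_pairs.get(m, 0)), m),
        )
        keep = set(ranked[:top_mirnas])
        pairs = pairs[pairs["mirna_id"].isin(keep)]

    for _, row in pairs.sort_values(["mirna_id", "gene_id", "stage"]).iterrows():
        m, gene, st = row["mirna_id"], row["gene_id"], row["stage"]
        if not g.has_node(m):
            g.add_node(m, kind="mirna")
        if not g.has_node(gene):
            g.add_node(gene, kind="gene")
        g.nodes[m][f"call_{st}"] = row["mirna_call"]
        g.nodes[gene][f"call_{st}"] = row["gene_call"]
        if g.has_edge(m, gene):
            attrs = g.edges[m, gene]
            attrs["_stages"].add(st)
        else:
            g.add_edge(m, gene, _stages={st})
        p = screen_p.get((m, st, row["gene_call"]))
        if p is not None:
            prev = g.edges[m, gene].get("screen_p")
            if prev is None or p < prev:
                g.edges[m, gene]["screen_p"] = p

    for _, _, attrs in g.edges(data=True):
        stages = sorted(attrs.pop("_stages"))
        attrs["stages"] = "+".join(stages)
        attrs["n_stages"] = len(stages)
    return g


def _ordered_copy(g: nx.DiGraph) -> nx.DiGraph:
    out = nx.DiGraph()
    for node in sorted(g.nodes):
        out.add_node(node, **g.nodes[node])
    for u, v in sorted(g.edges):
        out.add_edge(u, v, **g.edges[u, v])
    return out


def export(network: nx.DiGraph, path: str | Path, format: str) -> Path:
    """Write the network in one of ``sif``, ``graphml`` or ``edge-tsv``."""
    if format not in EXPORT_FORMATS:
        raise ParameterError(f"unknown export format {format!r}; choose from {EXPORT_FORMATS}")
    path = Path(path)
    ordered = _ordered_copy(network)
    if format == "sif":
        with open(path, "w") as fh:
            for u, v in ordered.edges:
                fh.write(f"{u}\trepresses\t{v}\n")
    elif format == "graphml":
        nx.write_graphml(ordered, path, named_key_ids=True)
    else:
        rows = []
        for u, v, attrs in ordered.edges(data=True):
            rows.append(
                {
                    "mirna_id": u,
                    "gene_id": v,
                    "stages": attrs.get("stages", ""),
                    "n_stages": attrs.get("n_stages", 0),
                    "screen_p": attrs.get("screen_p", float("nan")),
                }
            )
        write_table(
            pd.DataFrame(rows, columns=["mirna_id", "gene_id", "stages", "n_stages", "screen_p"]),
            path,
        )
    return path
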