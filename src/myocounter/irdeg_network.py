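"""irDEG classification and shortest-path pruning of a regulatory graph.

An immunotherapy-related DEG (irDEG) is a gene called significantly in the
same direction in both irMyositis-vs-dermatomyositis comparisons, while being
non-significant or oppositely regulated in each dermatomyositis-vs-control
comparison.  irDEGs plus the checkpoint-inhibitor target genes (CD274, PDCD1,
CTLA4) seed the extraction of all co-minimal shortest paths from a directed
regulatory interaction graph; the pruned network is the union of nodes and
edges lying on any such path.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .multiple_testing import DecisionMatrix
from .linmodel import ContrastFit

ICI_TARGETS = ("CD274", "PDCD1", "CTLA4")
EDGE_MODES = ("positive", "negative", "unspecified")

_UP_COMPARISONS = ("irMyositis-Mi2", "irMyositis-TIF1g")
_DM_COMPARISONS = ("Mi2-NDC", "TIF1g-NDC")


def classify_irdegs(
    d: DecisionMatrix, cf: ContrastFit, corrected_expression: pd.DataFrame
) -> pd.DataFrame:
    """Select irDEGs and report their significant fold-changes.

    One row per irDEG: average corrected expression across all samples, then
    the six comparison log2 fold-changes, zeroed where the decision is 0.
    """
    needed = set(_UP_COMPARISONS) | set(_DM_COMPARISONS)
    missing = sorted(needed - set(d.decisions.columns))
    if missing:
        raise ValidationError(f"decision matrix lacks comparisons: {missing}")
    dec = d.decisions
    s_im = dec["irMyositis-Mi2"]
    s_it = dec["irMyositis-TIF1g"]
    same_direction = (s_im != 0) & (s_im == s_it)
    dm_ok = pd.Series(True, index=dec.index)
    for comparison in _DM_COMPARISONS:
        dm_ok &= dec[comparison] * s_im <= 0
    chosen = sorted(dec.index[same_direction & dm_ok])

    avg_expr = corrected_expression.mean(axis=1)
    rows = []
    for gene in chosen:
        row = {"gene": gene, "average_expression": float(avg_expr.get(gene, np.nan))}
        for comparison in cf.log2fc.columns:
            fc = float(cf.log2fc.at[gene, comparison])
            row[comparison] = fc if dec.at[gene, comparison] != 0 else 0.0
        rows.append(row)
    return pd.DataFrame(rows, columns=["gene", "average_expression", *cf.log2fc.columns])


def load_regulatory_graph(edges: str | Path | pd.DataFrame, nodes: str | Path | pd.DataFrame) -> nx.MultiDiGraph:
    """Build the directed regulatory multigraph from flat node/edge tables.

    Edge columns: source, target, mode, pathway_id; node columns: gene,
    compartments (semicolon-joined).  Unknown modes are mapped to
    ``unspecified`` with a warning; duplicated identical edge rows collapse;
    an edge naming an undeclared node is an error.
    """
    if not isinstance(edges, pd.DataFrame):
        edges = pd.read_csv(edges, sep="\t", dtype=str)
    if not isinstance(nodes, pd.DataFrame):
        nodes = pd.read_csv(nodes, sep="\t", dtype=str)
    for col in ("source", "target", "mode", "pathway_id"):
        if col not in edges.columns:
            raise ValidationError(f"edge table lacks column {col!r}")
    if "gene" not in nodes.columns:
        raise ValidationError("node table lacks column 'gene'")

    graph = nx.MultiDiGraph()
    for _, row in nodes.iterrows():
        compartments = frozenset(
            c for c in str(row.get("compartments", "") or "").split(";") if c
        )
        graph.add_node(row["gene"], compartments=compartments)
    declared = set(graph.nodes)
    unknown_modes = set()
    seen = set()
    for _, row in edges.iterrows():
        src, dst, mode, pathway = row["source"], row["target"], row["mode"], row["pathway_id"]
        for endpoint in (src, dst):
            if endpoint not in declared:
                raise ValidationError(f"edge references undeclared node {endpoint!r}")
        if mode not in EDGE_MODES:
            unknown_modes.add(mode)
            mode = "unspecified"
        key = (src, dst, mode, pathway)
        if key in seen:
            continue
        seen.add(key)
        graph.add_edge(src, dst, mode=mode, pathway_id=pathway)
    if unknown_modes:
        warnings.warn(f"unknown regulation modes mapped to 'unspecified': {sorted(unknown_modes)}")
    return graph


def build_seed_set(
    irdeg_genes: Iterable[str],
    graph: nx.MultiDiGraph,
    extra: Sequence[str] = ICI_TARGETS,
) -> tuple[list[str], list[str]]:
    """Seeds = (irDEGs union checkpoint targets) intersected with the graph;
    also returns the genes absent from the graph."""
    requested = sorted(dict.fromkeys([*irdeg_genes, *extra]))
    seeds = [g for g in requested if g in graph]
    absent = [g for g in requested if g not in graph]
    if not seeds:
        raise ValidationError("no requested seed gene is present in the graph")
    return seeds, absent


@dataclass
class PrunedNetwork:
    graph: nx.MultiDiGraph
    seeds: list[str]
    isolated_seeds: list[str]


def apsp_prune(g: nx.MultiDiGraph, seeds: Sequence[str], directed: bool = False) -> PrunedNetwork:
    """Union of ALL co-minimal shortest paths (unit edge weights) between seed
    pairs.

    With ``directed=False`` (default) traversal ignores edge direction and
    unordered pairs are considered; with ``directed=True`` every ordered pair
    is traversed along edge directions.  Seeds unreachable from every other
    seed are reported as isolated.  Edge attributes are preserved: every
    parallel edge between a retained adjacent node pair (in the traversed
    orientation) is kept.
    """
    seeds = sorted(dict.fromkeys(seeds))
    missing = [s for s in seeds if s not in g]
    if missing:
        raise ValidationError(f"seeds absent from graph (run build_seed_set first): {missing}")
    if len(seeds) < 2:
        raise ValidationError("need >= 2 seeds in the graph")
    simple = nx.DiGraph(g) if directed else nx.Graph(g)
    kept_nodes: set[str] = set()
    kept_pairs: set[tuple[str, str]] = set()
    connected: set[str] = set()
    pairs = (
        itertools.permutations(seeds, 2) if directed else itertools.combinations(seeds, 2)
    )
    for a, b in pairs:
        try:
            paths = list(nx.all_shortest_paths(simple, a, b))
        except nx.NetworkXNoPath:
            continue
        connected.update((a, b))
        for path in paths:
            kept_nodes.update(path)
            for u, v in zip(path, path[1:]):
                kept_pairs.add((u, v))

    pruned = nx.MultiDiGraph()
    for node in kept_nodes:
        pruned.add_node(node, **g.nodes[node])
    for u, v in kept_pairs:
        orientations = [(u, v)] if directed else [(u, v), (v, u)]
        for src, dst in orientations:
            if g.has_edge(src, dst):
                for _, data in g.get_edge_data(src, dst).items():
                    pruned.add_edge(src, dst, **data)
    isolated = [s for s in seeds if s not in connected]
    return PrunedNetwork(graph=pruned, seeds=list(seeds), isolated_seeds=isolated)


def annotate_network(
    p: PrunedNetwork,
    d: DecisionMatrix,
    corrected_expression: pd.DataFrame,
    panel_genes: Iterable[str],
) -> pd.DataFrame:
    """Per-node annotation table: the six decisions (where available), average
    corrected expression and its quartile within the panel-wide distribution,
    and in-panel / filtered-out flags."""
    panel = set(panel_genes)
    analyzed = set(d.decisions.index)
    avg = corrected_expression.mean(axis=1)
    quartiles = avg.quantile([0.25, 0.5, 0.75])
    rows = []
    for node in sorted(p.graph.nodes):
        in_panel = node in panel
        row: dict = {
            "gene": node,
            "in_panel": in_panel,
            "filtered_out": in_panel and node not in analyzed,
            "is_seed": node in p.seeds,
        }
        if node in analyzed:
            for comparison in d.decisions.columns:
                row[comparison] = int(d.decisions.at[node, comparison])
        else:
            for comparison in d.decisions.columns:
                row[comparison] = pd.NA
        if node in avg.index:
            expr = float(avg[node])
            row["average_expression"] = expr
            row["expression_quartile"] = int(1 + (expr > quartiles).sum())
        else:
            row["average_expression"] = np.nan
            row["expression_quartile"] = pd.NA
        rows.append(row)
    return pd.DataFrame(rows)
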