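"""Decoration, layout and export of the pruned term network.

Nodes are colored by MeSH tree category — red for Disease (tree letter C),
green for Chemicals and Drugs (tree letter D), blue for everything else —
and positioned with the Fruchterman-Reingold force-directed algorithm.
The package does not bundle the MeSH tree; it reads either the NLM ASCII
descriptor export (``MH =`` / ``MN =`` records) or a simple two-column TSV
``descriptor<TAB>tree;tree``, and ships only a small synthetic toy map for
tests.  Exact layout geometry is not a reproduction target: force layouts
are non-unique, so only determinism under a fixed seed is promised.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "load_category_map",
    "categorize",
    "decorate",
    "layout",
    "export_graphml",
    "import_graphml",
    "export_edgelist_tsv",
    "export_png",
]

DISPLAY_CLASSES = ("disease", "chemical-drug", "other")
NODE_COLORS = {"disease": "#d62728", "chemical-drug": "#2ca02c", "other": "#1f77b4"}

DEFAULT_LAYOUT_SEED = 20160101  # documented fixed default


def load_category_map(path) -> dict[str, tuple[str, ...]]:
    """Descriptor -> MeSH tree numbers, from NLM ASCII or TSV.

    NLM ASCII records are blocks of ``KEY = value`` lines; ``MH`` carries
    the Main Heading and each ``MN`` one tree number.  The TSV dialect is
    ``descriptor<TAB>tree;tree;...`` with ``#`` comments.
    """
    text = Path(path).read_text(encoding="utf-8")
    if "*NEWRECORD" in text:
        return _parse_nlm_ascii(text)
    mapping: dict[str, tuple[str, ...]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}: line {lineno}: expected 2 tab-separated fields")
        trees = tuple(t.strip() for t in parts[1].split(";") if t.strip())
        mapping[parts[0].strip()] = trees
    return mapping


def _parse_nlm_ascii(text: str) -> dict[str, tuple[str, ...]]:
    mapping: dict[str, tuple[str, ...]] = {}
    heading: str | None = None
    trees: list[str] = []
    for line in text.splitlines() + ["*NEWRECORD"]:
        line = line.strip()
        if line == "*NEWRECORD":
            if heading:
                mapping[heading] = tuple(trees)
            heading, trees = None, []
        elif "=" in line:
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "MH":
                heading = value
            elif key == "MN":
                trees.append(value)
    return mapping


def categorize(descriptor: str, category_map: Mapping[str, Sequence[str]]) -> str:
    """Display class by tree-letter priority: any C tree -> disease, else
    any D tree -> chemical-drug, else (including unmapped) -> other."""
    trees = category_map.get(descriptor, ())
    if any(t.startswith("C") for t in trees):
        return "disease"
    if any(t.startswith("D") for t in trees):
        return "chemical-drug"
    return "other"


def decorate(
    graph: nx.Graph,
    final_counts: Mapping[str, int] | None = None,
    category_map: Mapping[str, Sequence[str]] | None = None,
) -> nx.Graph:
    """Attach label, display class and final-period count to every node
    (in place; also returned)."""
    category_map = category_map or {}
    final_counts = final_counts or {}
    for node in graph.nodes:
        graph.nodes[node]["label"] = str(node)
        graph.nodes[node]["category"] = categorize(str(node), category_map)
        graph.nodes[node]["count_tn"] = int(final_counts.get(node, 0))
    return graph


def layout(graph: nx.Graph, seed: int = DEFAULT_LAYOUT_SEED) -> dict:
    """Fruchterman-Reingold coordinates, deterministic for a fixed seed.

    Disconnected components are laid out independently and tiled side by
    side along x so they never overlap.  A single node sits at the origin
    of its tile.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    pos: dict = {}
    offset = 0.0
    components = sorted(nx.connected_components(graph), key=lambda c: sorted(map(str, c)))
    for component in components:
        sub = graph.subgraph(component)
        if sub.number_of_nodes() == 1:
            local = {next(iter(component)): np.zeros(2)}
        else:
            local = nx.spring_layout(sub, seed=seed, center=(0.0, 0.0))
        span = 2.0  # spring_layout scales to [-1, 1]
        for node, xy in local.items():
            pos[node] = np.asarray([xy[0] + offset, xy[1]], dtype=float)
        offset += span + 0.5
    return pos


def export_graphml(graph: nx.Graph, pos: Mapping | None, path) -> None:
    """GraphML with node attributes (label, category, count_tn, x, y) and
    edge attributes (weight, similarity); re-import reproduces the graph."""
    out = graph.copy()
    if pos is not None:
        for node, xy in pos.items():
            out.nodes[node]["x"] = float(xy[0])
            out.nodes[node]["y"] = float(xy[1])
    nx.write_graphml(out, path, infer_numeric_types=True)


def import_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def export_edgelist_tsv(graph: nx.Graph, path) -> None:
    """One header plus one ``term_i<TAB>term_j<TAB>similarity`` line per edge."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["term_i", "term_j", "similarity"])
        for u, v, data in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            writer.writerow([u, v, f"{data.get('similarity', ''):.10g}"])


def export_png(graph: nx.Graph, pos: Mapping, path, dpi: int = 150) -> None:
    """Static snapshot of the categorized network."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 8))
    colors = [
        NODE_COLORS.get(graph.nodes[n].get("category", "other"), NODE_COLORS["other"])
        for n in graph.nodes
    ]
    nx.draw_networkx_edges(graph, pos, ax=ax, alpha=0.4)
    nx.draw_networkx_nodes(graph, pos, ax=ax, node_color=colors, node_size=120)
    nx.draw_networkx_labels(graph, pos, ax=ax, font_size=6)
    ax.set_axis_off()
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
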