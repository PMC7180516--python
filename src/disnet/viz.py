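"""Demographic glyph encoding and graph export/rendering.

Each disease node is drawn as a rectangle whose width scales with the number
of female patients and height with the number of male patients; node colour
mixes red/green/blue in proportion to the fractions of patients aged <30,
30-59 and >=60. Edges are gray arrows with thickness monotone in the relative
risk. The same attributes are exported to GraphML and cytoscape.js JSON so
the network can be styled in external viewers.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import matplotlib
import networkx as nx
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.patches import FancyArrowPatch, Rectangle  # noqa: E402

log = logging.getLogger(__name__)

__all__ = [
    "NodeGlyph",
    "EdgeGlyph",
    "encode_glyphs",
    "export_cytoscape",
    "export_graphml",
    "render_static",
]


@dataclass(frozen=True)
class NodeGlyph:
    code: str
    width: float
    height: float
    color: tuple  # (r, g, b) each in 0..255


@dataclass(frozen=True)
class EdgeGlyph:
    source: str
    target: str
    thickness: float


def _scale(count: int, max_count: int, lo: float, rng: float,
           law: str) -> float:
    if max_count <= 0 or count <= 0:
        return lo
    frac = count / max_count
    if law == "sqrt":
        frac = math.sqrt(frac)
    elif law != "linear":
        raise ValueError(f"unknown size scale {law!r}")
    return lo + rng * frac


def encode_glyphs(G: nx.DiGraph, size_scale: str = "sqrt",
                  w_min: float = 6.0, w_range: float = 34.0,
                  thickness_min: float = 0.3, thickness_range: float = 3.0):
    """Compute node and edge glyphs from the network's demographic and RR
    attributes. Square-root size scaling by default (so glyph area tracks
    patient count); ``size_scale="linear"`` for direct proportionality.
    Returns ``(node_glyphs, edge_glyphs)`` keyed lists.
    """
    max_f = max((G.nodes[v]["n_female"] for v in G.nodes), default=0)
    max_m = max((G.nodes[v]["n_male"] for v in G.nodes), default=0)
    nodes = []
    for v in sorted(G.nodes):
        d = G.nodes[v]
        total = d["n_female"] + d["n_male"]
        if total == 0:
            log.warning("node %s has no patients; gray minimum glyph", v)
            nodes.append(NodeGlyph(v, w_min, w_min, (128, 128, 128)))
            continue
        fr = (d["frac_under30"], d["frac_30_59"], d["frac_60plus"])
        color = tuple(int(round(255 * f)) for f in fr)
        nodes.append(NodeGlyph(
            v,
            _scale(d["n_female"], max_f, w_min, w_range, size_scale),
            _scale(d["n_male"], max_m, w_min, w_range, size_scale),
            color,
        ))
    max_rr = max((d["rr"] for _, _, d in G.edges(data=True)), default=1.0)
    edges = [
        EdgeGlyph(u, v, thickness_min + thickness_range * d["rr"] / max_rr)
        for u, v, d in sorted(G.edges(data=True))
    ]
    return nodes, edges


def _attach(G: nx.DiGraph, node_glyphs, edge_glyphs) -> nx.DiGraph:
    H = G.copy()
    for g in node_glyphs:
        r, gg, b = g.color
        H.nodes[g.code].update(
            glyph_width=float(g.width), glyph_height=float(g.height),
            glyph_color=f"#{r:02x}{gg:02x}{b:02x}",
        )
    for e in edge_glyphs:
        H.edges[e.source, e.target]["glyph_thickness"] = float(e.thickness)
    return H


def export_graphml(G: nx.DiGraph, node_glyphs, edge_glyphs, path) -> None:
    """GraphML with all demographic, statistical and glyph attributes."""
    nx.write_graphml(_attach(G, node_glyphs, edge_glyphs), path)


def export_cytoscape(G: nx.DiGraph, node_glyphs, edge_glyphs, path) -> None:
    """cytoscape.js JSON with the same attributes as the GraphML export."""
    if G.number_of_nodes() == 0:
        raise ValueError("cannot export an empty network")
    data = nx.cytoscape_data(_attach(G, node_glyphs, edge_glyphs))
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)


def layout_positions(G: nx.DiGraph, seed: int) -> dict:
    """Seeded force-directed (Fruchterman-Reingold) node positions; the same
    seed always yields identical coordinates."""
    return nx.spring_layout(G, seed=seed)


def render_static(G: nx.DiGraph, node_glyphs, edge_glyphs, path,
                  layout_seed: int = 0) -> dict:
    """Render the network as a static figure (format from the file suffix).

    Rectangular glyphs with the demographic size/colour encoding, gray arrows
    with RR-scaled thickness, on a seeded force-directed layout. Returns the
    layout positions used. Output is deterministic for a fixed seed.
    """
    pos = layout_positions(G, layout_seed)
    glyphs = {g.code: g for g in node_glyphs}
    fig, ax = plt.subplots(figsize=(10, 10))
    ax.set_axis_off()
    # pixel-ish glyph units mapped into the unit layout box
    unit = 1.0 / 420.0
    for e in edge_glyphs:
        ax.add_patch(FancyArrowPatch(
            pos[e.source], pos[e.target], arrowstyle="-|>",
            mutation_scale=8, linewidth=e.thickness, color="0.55",
            shrinkA=4, shrinkB=4, zorder=1,
        ))
    for code, g in sorted(glyphs.items()):
        x, y = pos[code]
        w, h = g.width * unit, g.height * unit
        ax.add_patch(Rectangle(
            (x - w / 2, y - h / 2), w, h,
            facecolor=tuple(c / 255 for c in g.color),
            edgecolor="black", linewidth=0.4, zorder=2,
        ))
        ax.annotate(code, (x, y), fontsize=5, ha="center", va="center",
                    zorder=3)
    ax.autoscale_view()
    ax.set_xlim(-1.15, 1.15)
    ax.set_ylim(-1.15, 1.15)
    with matplotlib.rc_context({"svg.hashsalt": "disnet"}):
        fig.savefig(path, metadata=_no_date_metadata(path))
    plt.close(fig)
    return pos


def _no_date_metadata(path) -> dict | None:
    # keep repeated renders byte-identical
    p = str(path).lower()
    if p.endswith(".svg"):
        return {"Date": None}
    if p.endswith(".png"):
        return None
    return None
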