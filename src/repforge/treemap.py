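"""Clonal tree-maps: V -> V-J -> V-J-CDR3 nested-rectangle layout and SVG export.

The whole canvas is first divided among V genes, each V rectangle among its
V-J combinations, and each V-J rectangle among its CDR3 sequences, with
every rectangle's area proportional to the copy-weighted frequency it
represents — so each leaf rectangle is one distinct CDR3 nucleotide
sequence and an expanded clone is immediately visible as a large block.
Within every level, larger rectangles are placed toward the bottom-right
and smaller ones toward the top-left. Leaves are rounded and coloured from
a seeded random palette, so output is reproducible bit-for-bit.

Layout geometry: recursive weighted binary partition. The sibling list
(sorted by descending frequency) is split at the half-weight point, the
parent rectangle is cut across its longer axis in exact weight proportion,
and the heavier half (holding the larger siblings) takes the bottom/right
part. This fills the parent exactly, never overlaps, and keeps aspect
ratios moderate.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotate import Clonotype

__all__ = ["TreemapNode", "build_hierarchy", "layout", "render_svg", "treemap_svg"]

Rect = tuple[float, float, float, float]  # x, y, width, height


@dataclass
class TreemapNode:
    level: str  # "root" | "V" | "VJ" | "VJCDR3"
    label: str
    frequency: float
    children: list["TreemapNode"] = field(default_factory=list)
    rect: Rect | None = None
    color: tuple[int, int, int] | None = None

    def leaves(self) -> list["TreemapNode"]:
        if not self.children:
            return [self]
        out: list[TreemapNode] = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out


def build_hierarchy(clonotypes: list[Clonotype]) -> TreemapNode:
    """Three-level copy-weighted hierarchy; children sorted by descending frequency."""
    if not clonotypes:
        raise ValueError("empty repertoire")
    total = sum(ct.total_copies for ct in clonotypes)
    by_v: dict[str, dict[str, list[Clonotype]]] = {}
    for ct in clonotypes:
        by_v.setdefault(ct.v_gene, {}).setdefault(ct.j_gene, []).append(ct)

    root = TreemapNode(level="root", label="", frequency=1.0)
    for v_gene in sorted(by_v):
        v_node = TreemapNode(level="V", label=v_gene, frequency=0.0)
        for j_gene in sorted(by_v[v_gene]):
            vj = TreemapNode(level="VJ", label=f"{v_gene}|{j_gene}", frequency=0.0)
            for ct in sorted(by_v[v_gene][j_gene], key=lambda c: c.cdr3_nt):
                leaf = TreemapNode(
                    level="VJCDR3",
                    label=f"{v_gene}|{j_gene}|{ct.cdr3_nt}",
                    frequency=ct.total_copies / total,
                )
                vj.children.append(leaf)
                vj.frequency += leaf.frequency
            vj.children.sort(key=lambda n: (-n.frequency, n.label))
            v_node.children.append(vj)
            v_node.frequency += vj.frequency
        v_node.children.sort(key=lambda n: (-n.frequency, n.label))
        root.children.append(v_node)
    root.children.sort(key=lambda n: (-n.frequency, n.label))
    return root


def _partition(nodes: list[TreemapNode], rect: Rect) -> None:
    """Recursively place ``nodes`` (descending weight) inside ``rect``."""
    x, y, w, h = rect
    if len(nodes) == 1:
        node = nodes[0]
        node.rect = (x, y, w, h)
        if node.children:
            _partition(node.children, node.rect)
        return
    total = sum(n.frequency for n in nodes)
    acc, k = 0.0, 0
    for n in nodes:
        acc += n.frequency
        k += 1
        if 2 * acc >= total:
            break
    k = min(k, len(nodes) - 1)
    heavy, light = nodes[:k], nodes[k:]
    f_heavy = sum(n.frequency for n in heavy) / total if total else 0.5
    if w >= h:  # cut vertically; heavier (larger) group to the right
        wh = w * f_heavy
        _partition(heavy, (x + (w - wh), y, wh, h))
        _partition(light, (x, y, w - wh, h))
    else:  # cut horizontally; heavier group to the bottom
        hh = h * f_heavy
        _partition(heavy, (x, y + (h - hh), w, hh))
        _partition(light, (x, y, w, h - hh))


def layout(
    root: TreemapNode, width: float = 1000.0, height: float = 600.0, seed: int = 0
) -> TreemapNode:
    """Assign rectangles (area proportional to frequency) and seeded leaf colours."""
    if width <= 0 or height <= 0:
        raise ValueError("canvas dimensions must be positive")
    root.rect = (0.0, 0.0, float(width), float(height))
    if root.children:
        _partition(root.children, root.rect)
    rng = np.random.default_rng(seed)
    prev_hue = -1.0
    for leaf in root.leaves():
        hue = float(rng.random())
        for _ in range(10):  # keep neighbouring leaves distinguishable
            if abs(hue - prev_hue) >= 0.08:
                break
            hue = float(rng.random())
        prev_hue = hue
        r, g, b = colorsys.hls_to_rgb(hue, 0.62, 0.65)
        leaf.color = (int(round(r * 255)), int(round(g * 255)), int(round(b * 255)))
    return root


def render_svg(
    root: TreemapNode, path: str | Path, corner_radius: float = 4.0
) -> None:
    """Write the laid-out tree as SVG 1.1: one rounded rectangle per leaf,
    plus V- and V-J-level border outlines. Byte-deterministic."""
    if root.rect is None:
        raise ValueError("layout() must be applied before rendering")
    _, _, w, h = root.rect
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{w:.1f}" height="{h:.1f}" viewBox="0 0 {w:.1f} {h:.1f}">\n'
    ]
    for leaf in root.leaves():
        x, y, lw, lh = leaf.rect
        r, g, b = leaf.color if leaf.color else (200, 200, 200)
        parts.append(
            f'<rect class="leaf" x="{x:.4f}" y="{y:.4f}" width="{lw:.4f}" '
            f'height="{lh:.4f}" rx="{corner_radius:.2f}" '
            f'fill="#{r:02x}{g:02x}{b:02x}" stroke="white" stroke-width="0.8"/>\n'
        )
    for node in root.children:  # V-level borders over their V-J borders
        for vj in node.children:
            x, y, lw, lh = vj.rect
            parts.append(
                f'<rect x="{x:.4f}" y="{y:.4f}" width="{lw:.4f}" height="{lh:.4f}" '
                f'fill="none" stroke="#666666" stroke-width="1.0"/>\n'
            )
        x, y, lw, lh = node.rect
        parts.append(
            f'<rect x="{x:.4f}" y="{y:.4f}" width="{lw:.4f}" height="{lh:.4f}" '
            f'fill="none" stroke="#000000" stroke-width="1.6"/>\n'
        )
    parts.append("</svg>\n")
    Path(path).write_text("".join(parts))


def treemap_svg(
    clonotypes: list[Clonotype],
    path: str | Path,
    width: float = 1000.0,
    height: float = 600.0,
    seed: int = 0,
    corner_radius: float = 4.0,
) -> TreemapNode:
    """Convenience: hierarchy + layout + SVG in one call; returns the root."""
    root = layout(build_hierarchy(clonotypes), width, height, seed)
    render_svg(root, path, corner_radius)
    return root
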