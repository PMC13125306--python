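"""Clone phylogeny reconstruction under the irreversibility assumption.

Shared events imply common ancestry: the root carries the intersection of all
clone event sets, each clone's parent is the largest event set strictly
contained in it (synthesizing internal ancestors for partial overlaps).
Branch lengths follow bk = scale * log2(|Z_child| - |Z_parent|) with a pixel
floor for differences <= 1, and node diameters follow dl = sqrt(p) where p is
the percentage of epithelial units assigned to the clone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CloneEventSet

__all__ = [
    "CloneTree",
    "build_tree",
    "branch_length",
    "node_diameter",
    "to_newick",
    "clone_composition",
    "harmonize_events",
    "collapsed_parent_map",
    "render_svg",
]

ROOT_ID = "P"


@dataclass
class CloneNode:
    node_id: str
    events: frozenset
    children: list = field(default_factory=list)
    parent: str | None = None
    branch_length: float = 0.0
    observed: bool = True
    members: list = field(default_factory=list)
    composition: dict | None = None
    diameter: float = 0.0


@dataclass
class CloneTree:
    nodes: dict  # node id -> CloneNode
    root: str
    violations: list = field(default_factory=list)
    merged: list = field(default_factory=list)  # (kept, merged-away) id pairs

    def children(self, node_id: str) -> list:
        return list(self.nodes[node_id].children)

    def parent_of(self, node_id: str):
        return self.nodes[node_id].parent

    def edges(self) -> list:
        return [(n.parent, n.node_id, n.branch_length)
                for n in self.nodes.values() if n.parent is not None]

    def validate(self) -> None:
        for n in self.nodes.values():
            if n.parent is not None:
                parent = self.nodes[n.parent]
                if not parent.events < n.events and parent.events != n.events:
                    raise AssertionError(
                        f"edge {n.parent}->{n.node_id} violates strict containment"
                    )


def branch_length(z_descendant: int, z_parent: int, scale: float = 10.0,
                  floor_px: float = 2.0) -> float:
    """bk = scale * log2(z_descendant - z_parent); differences of 0 or 1
    (where the log is 0 or undefined) fall back to the pixel floor."""
    if z_descendant < z_parent:
        raise ValueError(
            f"descendant has fewer events ({z_descendant}) than parent ({z_parent}); "
            "irreversibility violated upstream"
        )
    diff = z_descendant - z_parent
    if diff <= 1:
        return float(floor_px)
    return float(scale * math.log2(diff))


def node_diameter(p_percent: float) -> float:
    """dl = sqrt(p), p the percentage (0..100) of epithelial units in the clone."""
    if not 0 <= p_percent <= 100:
        raise ValueError(f"percentage must be within [0, 100], got {p_percent}")
    return math.sqrt(p_percent)


def _region_key(event):
    """Region identity of an event key, direction stripped."""
    if isinstance(event, tuple) and len(event) == 4:
        return event[:3], event[3]
    return event, None


def _strip_conflicts(clones: list):
    """Detect regions appearing with both directions anywhere in the input
    (CNV reversion); report them and build the tree on the rest."""
    seen: dict = {}
    for c in clones:
        for e in c.event_set():
            region, direction = _region_key(e)
            if direction is None:
                continue
            seen.setdefault(region, set()).add(direction)
    conflicted = {r for r, dirs in seen.items() if len(dirs) > 1}
    if not conflicted:
        return clones, []
    violations = sorted(str(r) for r in conflicted)
    warnings.warn(
        f"irreversibility violation: regions {violations} carry both directions; "
        "tree built on the non-conflicting subset"
    )
    cleaned = []
    for c in clones:
        kept = [e for e in c.events if _region_key(e)[0] not in conflicted]
        cleaned.append(CloneEventSet(clone_id=c.clone_id, events=kept, members=c.members,
                                     support=c.support, histology=c.histology))
    return cleaned, violations


def build_tree(clones, scale: float = 10.0, floor_px: float = 2.0) -> CloneTree:
    """Reconstruct the rooted clone tree from event sets.

    The root ``P`` carries the intersection of all clone event sets; each
    node's parent is the largest strict subset among candidate nodes
    (observed clones plus synthesized pairwise-intersection ancestors).
    Identical event sets are merged with a warning.
    """
    clones = list(clones)
    if not clones:
        raise ValueError("at least one clone is required")
    clones, violations = _strip_conflicts(clones)

    # merge clones with identical event sets
    merged_pairs = []
    by_set: dict = {}
    for c in sorted(clones, key=lambda c: str(c.clone_id)):
        key = c.event_set()
        if key in by_set:
            keeper = by_set[key]
            warnings.warn(
                f"clones {keeper.clone_id!r} and {c.clone_id!r} have identical "
                "event sets; merged"
            )
            keeper.members = list(keeper.members) + list(c.members)
            merged_pairs.append((keeper.clone_id, c.clone_id))
        else:
            by_set[key] = CloneEventSet(
                clone_id=str(c.clone_id), events=list(c.events),
                members=list(c.members), support=dict(c.support),
                histology=dict(c.histology),
            )
    clones = list(by_set.values())

    root_events = frozenset.intersection(*[c.event_set() for c in clones])
    candidate_sets = {root_events}
    for c in clones:
        candidate_sets.add(c.event_set())
    for i, a in enumerate(clones):
        for b in clones[i + 1:]:
            candidate_sets.add(a.event_set() & b.event_set())

    observed = {c.event_set(): c for c in clones}
    nodes: dict = {}
    set_to_id: dict = {}
    synth = 0
    for s in sorted(candidate_sets, key=lambda s: (len(s), sorted(map(str, s)))):
        if s in observed:
            # a clone whose set equals the intersection coincides with the
            # common ancestor P and becomes the root itself
            nid = observed[s].clone_id
        elif s == root_events:
            nid = ROOT_ID
        else:
            synth += 1
            nid = f"N{synth}"
        set_to_id[s] = nid
        clone = observed.get(s)
        nodes[nid] = CloneNode(
            node_id=nid, events=s, observed=s in observed,
            members=list(clone.members) if clone else [],
            composition=dict(clone.histology) if clone and clone.histology else None,
        )
    root_id = set_to_id[root_events]

    ordered = sorted(set_to_id.items(), key=lambda kv: (len(kv[0]), sorted(map(str, kv[0]))))
    for s, nid in ordered:
        if nid == root_id:
            continue
        best = None
        for t, tid in ordered:
            if t < s and (best is None or len(t) > len(best)):
                best = t
        parent_id = set_to_id[best]
        node = nodes[nid]
        node.parent = parent_id
        node.branch_length = branch_length(len(s), len(best), scale=scale, floor_px=floor_px)
        nodes[parent_id].children.append(nid)

    tree = CloneTree(nodes=nodes, root=root_id, violations=violations, merged=merged_pairs)
    tree.validate()
    return tree


def assign_diameters(tree: CloneTree, total_units: int | None = None) -> None:
    """Set node diameters from member counts: dl = sqrt(percentage)."""
    if total_units is None:
        total_units = sum(len(n.members) for n in tree.nodes.values())
    for n in tree.nodes.values():
        p = 100.0 * len(n.members) / total_units if total_units else 0.0
        n.diameter = node_diameter(p)


def clone_composition(assignments, histology) -> dict:
    """Per-clone DCIS/IDC fractions among labelled members; NA excluded from
    the denominator. Clones with zero labelled members report ``None``."""
    assignments = pd.Series(assignments)
    histology = pd.Series(histology)
    out = {}
    for clone in sorted(assignments.dropna().unique()):
        members = assignments.index[assignments == clone]
        labels = histology.reindex(members).dropna()
        labels = labels[labels.isin(["DCIS", "IDC"])]
        if len(labels) == 0:
            out[str(clone)] = None
        else:
            counts = labels.value_counts()
            out[str(clone)] = {
                "DCIS": float(counts.get("DCIS", 0)) / len(labels),
                "IDC": float(counts.get("IDC", 0)) / len(labels),
            }
    return out


def _newick_label(name: str) -> str:
    if any(ch in name for ch in " (),:;[]'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(tree: CloneTree) -> str:
    """Newick string with branch lengths bk and clone ids as node labels."""

    def rec(nid: str) -> str:
        node = tree.nodes[nid]
        label = _newick_label(node.node_id)
        if not node.children:
            if node.parent is None:
                return label
            return f"{label}:{node.branch_length:.6g}"
        inner = ",".join(rec(c) for c in sorted(node.children))
        if node.parent is None:
            return f"({inner}){label}"
        return f"({inner}){label}:{node.branch_length:.6g}"

    return rec(tree.root) + ";"


def collapsed_parent_map(tree: CloneTree) -> dict:
    """Map each observed clone to its nearest observed (or root) ancestor —
    the topology with synthesized pass-through nodes collapsed."""
    out = {}
    for nid, node in tree.nodes.items():
        if not node.observed and nid != tree.root:
            continue
        p = node.parent
        while p is not None and not tree.nodes[p].observed and p != tree.root:
            p = tree.nodes[p].parent
        out[nid] = p
    return out


def harmonize_events(clone_sets: dict, min_reciprocal_overlap: float = 0.5) -> dict:
    """Unify near-identical events across clones.

    Consensus boundaries jitter by a couple of genes between clones, which
    would break the set-inclusion logic; events with the same chromosome and
    direction whose gene spans reciprocally overlap by
    >= ``min_reciprocal_overlap`` are merged into one shared key (the span of
    the first-seen representative). Returns new ``{clone_id: CloneEventSet}``.
    """
    classes: list = []  # representative tuples (chrom, start, end, direction)

    def find_class(ev):
        chrom, start, end, direction = ev
        for rep in classes:
            if rep[0] == chrom and rep[3] == direction:
                inter = min(end, rep[2]) - max(start, rep[1]) + 1
                if inter > 0:
                    frac = min(inter / (end - start + 1), inter / (rep[2] - rep[1] + 1))
                    if frac >= min_reciprocal_overlap:
                        return rep
        classes.append(ev)
        return ev

    out = {}
    for clone_id in sorted(clone_sets):
        c = clone_sets[clone_id]
        new_events, new_support = [], {}
        for ev in sorted(c.events):
            rep = find_class(tuple(ev))
            if rep not in new_events:
                new_events.append(rep)
                new_support[rep] = c.support.get(ev, float("nan"))
        out[clone_id] = CloneEventSet(
            clone_id=c.clone_id, events=new_events, members=list(c.members),
            support=new_support, histology=dict(c.histology),
        )
    return out


def render_svg(tree: CloneTree, path: str) -> None:
    """Minimal SVG rendering: nodes as circles sized by dl with DCIS/IDC pie
    wedges, edges as lines whose length is bk."""
    # simple layered layout: depth -> x, leaves spread on y
    depth = {}

    def set_depth(nid, d):
        depth[nid] = d
        for c in tree.nodes[nid].children:
            set_depth(c, d + tree.nodes[c].branch_length)

    set_depth(tree.root, 0.0)
    leaves = [nid for nid, n in tree.nodes.items() if not n.children]
    ypos = {nid: 40.0 + 60.0 * i for i, nid in enumerate(sorted(leaves))}

    def set_y(nid):
        node = tree.nodes[nid]
        if not node.children:
            return ypos[nid]
        ys = [set_y(c) for c in node.children]
        ypos[nid] = sum(ys) / len(ys)
        return ypos[nid]

    set_y(tree.root)
    scale_x = 3.0
    parts = ['<svg xmlns="http://www.w3.org/2000/svg" width="800" height="%d">'
             % (60 * max(len(leaves), 1) + 60)]
    for parent, child, _ in tree.edges():
        x1, y1 = 40 + scale_x * depth[parent], ypos[parent]
        x2, y2 = 40 + scale_x * depth[child], ypos[child]
        parts.append(
            f'<path d="M{x1:.1f},{y1:.1f} L{x1:.1f},{y2:.1f} L{x2:.1f},{y2:.1f}" '
            'fill="none" stroke="black"/>'
        )
    for nid, node in tree.nodes.items():
        x, y = 40 + scale_x * depth[nid], ypos[nid]
        r = max(node.diameter / 2.0, 3.0)
        comp = node.composition or {}
        dcis = comp.get("DCIS", 0.0)
        if 0 < dcis < 1:
            angle = 2 * math.pi * dcis
            x2 = x + r * math.sin(angle)
            y2 = y - r * math.cos(angle)
            large = 1 if dcis > 0.5 else 0
            parts.append(
                f'<circle cx="{x:.1f}" cy="{y:.1f}" r="{r:.1f}" fill="chartreuse" '
                'stroke="black"/>'
            )
            parts.append(
                f'<path d="M{x:.1f},{y:.1f} L{x:.1f},{y - r:.1f} '
                f'A{r:.1f},{r:.1f} 0 {large} 1 {x2:.1f},{y2:.1f} Z" fill="dodgerblue"/>'
            )
        else:
            fill = "dodgerblue" if dcis >= 1 else ("chartreuse" if comp else "black")
            parts.append(
                f'<circle cx="{x:.1f}" cy="{y:.1f}" r="{r:.1f}" fill="{fill}" '
                'stroke="black"/>'
            )
        parts.append(f'<text x="{x + r + 3:.1f}" y="{y + 4:.1f}" '
                     f'font-size="12">{node.node_id}</text>')
    parts.append("</svg>")
    with open(path, "w") as fh:
        fh.write("\n".join(parts) + "\n")
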