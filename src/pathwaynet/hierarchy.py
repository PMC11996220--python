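"""Pathway hierarchies and the binary connectivity masks derived from them.

A pathway knowledgebase of the Reactome kind supplies two files: a GMT
gene-set file (``pathway_id<TAB>description<TAB>gene1<TAB>gene2...``) and a
two-column relations table of directed ``parent<TAB>child`` pathway pairs.
Together they define a DAG whose leaves carry gene annotations.  This module
layers that DAG into a fixed number of levels and emits the stack of 0/1
matrices that constrain a sparse subnetwork: genes connect only to the
level-1 pathways they (or any deeper descendant pathway) are annotated to,
and level-*l* pathways connect only to their level-*(l+1)* parents.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PathwayHierarchy",
    "MaskStack",
    "HierarchyError",
    "load_hierarchy",
    "assign_levels",
    "build_masks",
    "mask_stats",
]


class HierarchyError(ValueError):
    """Malformed or structurally invalid pathway resource."""


@dataclass
class PathwayHierarchy:
    """A gene-annotated pathway DAG.

    Attributes
    ----------
    pathways : dict
        Mapping pathway id -> display name.
    gene_membership : dict
        Mapping pathway id -> set of gene symbols annotated to it.
    parent_child : set
        Directed (parent, child) pathway pairs.
    """

    pathways: dict[str, str]
    gene_membership: dict[str, set[str]]
    parent_child: set[tuple[str, str]]

    @property
    def roots(self) -> set[str]:
        """Pathways that appear as a parent but never as a child.

        Isolated pathways (no relations at all) are deliberately *not*
        roots: with an empty relations table every pathway is unreachable
        and collapses to the gene-adjacent level.
        """
        parents = {p for p, _ in self.parent_child}
        children = {c for _, c in self.parent_child}
        return parents - children

    def n_edges(self) -> int:
        return len(self.parent_child)

    def descendant_closure(self, pathway: str) -> set[str]:
        """All pathways reachable from ``pathway`` via parent->child edges,
        including itself."""
        children: dict[str, list[str]] = {}
        for p, c in self.parent_child:
            children.setdefault(p, []).append(c)
        seen = {pathway}
        queue = deque([pathway])
        while queue:
            node = queue.popleft()
            for c in children.get(node, ()):
                if c not in seen:
                    seen.add(c)
                    queue.append(c)
        return seen

    def save_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for pid in sorted(self.pathways):
                genes = sorted(self.gene_membership.get(pid, ()))
                if not genes:
                    continue  # GMT lines need >=3 fields; gene-less pathways live in the relations file
                fh.write("\t".join([pid, self.pathways[pid], *genes]) + "\n")

    def save_relations(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for p, c in sorted(self.parent_child):
                fh.write(f"{p}\t{c}\n")

    def validate(self) -> None:
        for p, c in self.parent_child:
            if p == c:
                raise HierarchyError(f"self-loop on pathway {p!r}")
            for q in (p, c):
                if q not in self.pathways:
                    raise HierarchyError(f"relation references unknown pathway {q!r}")
        g = nx.DiGraph(list(self.parent_child))
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise HierarchyError(f"cycle detected in pathway relations: {cycle}")
        for pw, genes in self.gene_membership.items():
            for gsym in genes:
                if not isinstance(gsym, str) or not gsym:
                    raise HierarchyError(f"empty gene symbol in pathway {pw!r}")


@dataclass
class MaskStack:
    """Ordered binary connectivity matrices for one sparse subnetwork.

    ``masks[0]`` is genes x level-1 pathways; ``masks[l]`` (l >= 1) is
    level-l x level-(l+1) pathways.  Entries are 0/1 floats so the arrays
    double as frozen layer weights.
    """

    gene_order: list[str]
    level_orders: list[list[str]]
    masks: list[np.ndarray]
    dropped_pathways: dict[int, list[str]] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return len(self.level_orders)

    @property
    def n_genes(self) -> int:
        return len(self.gene_order)

    def nonzeros(self) -> list[int]:
        return [int(m.sum()) for m in self.masks]

    def total_connections(self) -> int:
        return int(sum(self.nonzeros()))

    def validate(self) -> None:
        if len(self.masks) != self.depth:
            raise HierarchyError("mask count does not match level count")
        prev = self.n_genes
        for lvl, (order, m) in enumerate(zip(self.level_orders, self.masks), start=1):
            if m.shape != (prev, len(order)):
                raise HierarchyError(f"mask {lvl} has shape {m.shape}, expected {(prev, len(order))}")
            if not np.isin(m, (0.0, 1.0)).all():
                raise HierarchyError(f"mask {lvl} has entries outside {{0,1}}")
            if (m.sum(axis=0) == 0).any():
                raise HierarchyError(f"level-{lvl} node with no incoming connection")
            prev = len(order)

    # --- persistence ----------------------------------------------------
    def to_edge_list(self) -> pd.DataFrame:
        """Sparse edge-list view: columns (level, row_id, col_id)."""
        rows = []
        row_names = [self.gene_order] + self.level_orders[:-1]
        for lvl, (rnames, cnames, m) in enumerate(
            zip(row_names, self.level_orders, self.masks), start=1
        ):
            i, j = np.nonzero(m)
            for a, b in zip(i, j):
                rows.append((lvl, rnames[a], cnames[b]))
        return pd.DataFrame(rows, columns=["level", "row_id", "col_id"])

    def save_edge_list(self, path: str | Path) -> None:
        self.to_edge_list().to_csv(path, sep="\t", index=False)

    def save_dense(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        row_names = [self.gene_order] + self.level_orders[:-1]
        for lvl, (rnames, cnames, m) in enumerate(
            zip(row_names, self.level_orders, self.masks), start=1
        ):
            pd.DataFrame(m, index=rnames, columns=cnames).to_csv(
                directory / f"mask_level{lvl}.tsv", sep="\t"
            )

    @classmethod
    def from_edge_list(
        cls,
        edges: pd.DataFrame,
        gene_order: list[str],
        level_orders: list[list[str]],
    ) -> "MaskStack":
        masks = []
        row_names = [gene_order] + level_orders[:-1]
        for lvl, (rnames, cnames) in enumerate(zip(row_names, level_orders), start=1):
            m = np.zeros((len(rnames), len(cnames)))
            sub = edges[edges["level"] == lvl]
            ridx = {n: i for i, n in enumerate(rnames)}
            cidx = {n: i for i, n in enumerate(cnames)}
            for _, r in sub.iterrows():
                m[ridx[r["row_id"]], cidx[r["col_id"]]] = 1.0
            masks.append(m)
        return cls(gene_order=list(gene_order), level_orders=[list(o) for o in level_orders], masks=masks)


def load_hierarchy(gmt_path: str | Path, relations_path: str | Path) -> PathwayHierarchy:
    """Parse a GMT gene-set file plus a parent/child relations TSV.

    Pathways referenced only in the relations table are retained with empty
    gene membership.  Raises :class:`HierarchyError` on malformed GMT lines
    (fewer than 3 tab-separated fields) or on a cyclic relation graph.
    """
    pathways: dict[str, str] = {}
    membership: dict[str, set[str]] = {}
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise HierarchyError(
                    f"{gmt_path}: line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            pid, desc, *genes = fields
            pid = pid.strip()
            pathways[pid] = desc.strip()
            membership[pid] = {g.strip() for g in genes if g.strip()}

    relations: set[tuple[str, str]] = set()
    with open(relations_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise HierarchyError(
                    f"{relations_path}: line {lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            parent, child = fields[0].strip(), fields[1].strip()
            relations.add((parent, child))
            for q in (parent, child):
                if q not in pathways:
                    pathways[q] = q
                    membership[q] = set()

    h = PathwayHierarchy(pathways=pathways, gene_membership=membership, parent_child=relations)
    h.validate()
    return h


def assign_levels(
    h: PathwayHierarchy, depth: int = 3
) -> tuple[dict[str, int], list[str]]:
    """Layer the pathway DAG into ``depth`` levels by distance from a root.

    ``level = depth - min(distance_to_nearest_root, depth - 1)``: pathways
    adjacent to a root occupy the top level and anything deeper than the cut
    collapses onto level 1 (the gene-adjacent, most specific layer).

    Returns ``(levels, unreachable)`` where ``unreachable`` lists pathways
    with no path from any root; those are assigned level 1 and a warning is
    emitted.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    children: dict[str, list[str]] = {}
    for p, c in h.parent_child:
        children.setdefault(p, []).append(c)
    dist: dict[str, int] = {r: 0 for r in h.roots}
    queue = deque(h.roots)
    while queue:
        node = queue.popleft()
        for c in children.get(node, ()):
            if c not in dist:
                dist[c] = dist[node] + 1
                queue.append(c)
    levels: dict[str, int] = {}
    unreachable: list[str] = []
    for pw in h.pathways:
        if pw in dist:
            levels[pw] = depth - min(dist[pw], depth - 1)
        else:
            levels[pw] = 1
            unreachable.append(pw)
    if unreachable:
        warnings.warn(
            f"{len(unreachable)} pathway(s) unreachable from any root were assigned level 1",
            stacklevel=2,
        )
    return levels, sorted(unreachable)


def build_masks(
    h: PathwayHierarchy,
    gene_list: list[str],
    depth: int = 3,
    case_fold: bool = False,
) -> MaskStack:
    """Construct the layered 0/1 connectivity matrices for ``gene_list``.

    A gene connects to a level-1 pathway if it is annotated to that pathway
    or to any pathway in its descendant closure (membership up-propagation).
    Level-1 pathways left with zero connected genes are dropped, as are
    higher-level pathways left without any incoming connection after the
    drop cascades upward.  Genes with no annotation anywhere keep an
    all-zero row so the input axis matches ``gene_list``.
    """
    genes = [g.strip() for g in gene_list]
    if case_fold:
        genes = [g.upper() for g in genes]
    if not genes:
        raise HierarchyError("gene_list is empty")
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise HierarchyError(f"duplicate genes in gene_list: {dupes[:5]}")

    def norm(g: str) -> str:
        g = g.strip()
        return g.upper() if case_fold else g

    levels, _ = assign_levels(h, depth)
    by_level: dict[int, list[str]] = {l: [] for l in range(1, depth + 1)}
    for pw in sorted(h.pathways):
        by_level[levels[pw]].append(pw)

    gene_idx = {g: i for i, g in enumerate(genes)}

    # level-1 columns: up-propagated memberships over the descendant closure
    closure_genes: dict[str, set[str]] = {}
    for pw in by_level[1]:
        pooled: set[str] = set()
        for q in h.descendant_closure(pw):
            pooled.update(norm(g) for g in h.gene_membership.get(q, ()))
        closure_genes[pw] = pooled & set(genes)

    level1 = [pw for pw in by_level[1] if closure_genes[pw]]
    dropped = {1: [pw for pw in by_level[1] if not closure_genes[pw]]}
    if not level1:
        raise HierarchyError("empty constraint: no gene in gene_list is annotated to any pathway")

    orders: list[list[str]] = [level1]
    for lvl in range(2, depth + 1):
        lower = set(orders[-1])
        keep = [
            pw
            for pw in by_level[lvl]
            if any((pw, c) in h.parent_child and c in lower for c in h.pathways)
        ]
        dropped[lvl] = [pw for pw in by_level[lvl] if pw not in keep]
        if not keep:
            raise HierarchyError(f"no pathways remain at level {lvl}")
        orders.append(keep)

    masks: list[np.ndarray] = []
    m0 = np.zeros((len(genes), len(level1)))
    for j, pw in enumerate(level1):
        for g in closure_genes[pw]:
            m0[gene_idx[g], j] = 1.0
    masks.append(m0)
    for lvl in range(2, depth + 1):
        lower, upper = orders[lvl - 2], orders[lvl - 1]
        m = np.zeros((len(lower), len(upper)))
        for i, c in enumerate(lower):
            for j, p in enumerate(upper):
                if (p, c) in h.parent_child:
                    m[i, j] = 1.0
        masks.append(m)

    stack = MaskStack(gene_order=genes, level_orders=orders, masks=masks, dropped_pathways=dropped)
    stack.validate()
    return stack


def mask_stats(stack: MaskStack) -> pd.DataFrame:
    """Per-level node and connection counts plus a totals row."""
    rows = [("genes", stack.n_genes, np.nan)]
    for lvl, (order, nnz) in enumerate(zip(stack.level_orders, stack.nonzeros()), start=1):
        rows.append((f"level_{lvl}", len(order), nnz))
    rows.append(("total", sum(len(o) for o in stack.level_orders), stack.total_connections()))
    return pd.DataFrame(rows, columns=["layer", "nodes", "connections"])
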