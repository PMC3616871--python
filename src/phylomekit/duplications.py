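"""Gene-tree/species-tree reconciliation, duplication dating and rates.

Two views of duplications coexist here.  :func:`reconcile_lca` is the
classical LCA-mapping reconciliation used as the gene-tree-parsimony cost in
supertree searches.  :func:`date_duplications` instead consumes
species-overlap event labels (see :mod:`phylomekit.orthology`) and assigns
each duplication to the species-tree branch ("lineage") ending at the LCA of
the species below it.  Because every homologous gene carries its own tree, a
phylome reports the same evolutionary event many times; redundant reports are
merged before per-lineage duplication rates (duplications per gene) are
computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode

from .treecore import make_species_getter, write_newick

__all__ = [
    "EventRecord",
    "LineageRates",
    "reconcile_lca",
    "date_duplications",
    "merge_redundant_events",
    "lineage_duplication_rates",
    "annotate_species_tree_with_rates",
]


@dataclass
class EventRecord:
    """One duplication (or speciation) event reported by one gene tree."""

    tree_id: str
    node_id: object
    event_type: str
    side1: frozenset
    side2: frozenset
    lineage: str | None = None
    group: int | None = None

    @property
    def leaves(self) -> frozenset:
        return self.side1 | self.side2

    def sides(self) -> frozenset:
        return frozenset({self.side1, self.side2})


class _SpeciesIndex:
    """Parent pointers / depths over a species tree for fast LCA queries."""

    def __init__(self, species_tree: TreeNode):
        self.tree = species_tree
        self.parent: dict[str, str | None] = {}
        self.depth: dict[str, int] = {}
        self.names: set[str] = set()
        for node in species_tree.preorder(include_self=True):
            if node.name is None:
                raise ValueError("species tree has unnamed nodes")
            self.names.add(node.name)
            if node.parent is None:
                self.parent[node.name] = None
                self.depth[node.name] = 0
            else:
                self.parent[node.name] = node.parent.name
                self.depth[node.name] = self.depth[node.parent.name] + 1
        self.tips = {t.name for t in species_tree.tips()}

    def lca(self, a: str, b: str) -> str:
        da, db = self.depth[a], self.depth[b]
        while da > db:
            a = self.parent[a]
            da -= 1
        while db > da:
            b = self.parent[b]
            db -= 1
        while a != b:
            a, b = self.parent[a], self.parent[b]
        return a

    def lca_many(self, names: Iterable[str]) -> str:
        it = iter(names)
        acc = next(it)
        for n in it:
            acc = self.lca(acc, n)
        return acc


def _ensure_named_internals(species_tree: TreeNode) -> TreeNode:
    """Name unnamed internal nodes N1.. (preorder) on a copy if needed."""
    if all(n.name for n in species_tree.preorder(include_self=True)):
        return species_tree
    tree = species_tree.copy()
    i = 0
    for node in tree.preorder(include_self=True):
        if not node.name:
            i += 1
            node.name = f"N{i}"
    return tree


def reconcile_lca(
    gene_tree: TreeNode,
    species_tree: TreeNode,
    species_map: Mapping[str, str] | None = None,
) -> tuple[dict, int]:
    """Standard LCA reconciliation.

    Maps every gene-tree node to the species-tree LCA of its descendant
    species; a gene node is a duplication iff its mapping equals the mapping
    of at least one of its children.  Returns ``(mapping, duplication_count)``
    where the mapping keys are gene-tree nodes (leaves map to species tips).
    """
    species_tree = _ensure_named_internals(species_tree)
    idx = _SpeciesIndex(species_tree)
    getter = make_species_getter(species_map)
    unknown = set()
    mapping: dict = {}
    dup_count = 0
    for node in gene_tree.postorder(include_self=True):
        if not node.children:
            sp = getter(node.name)
            if sp not in idx.tips:
                unknown.add(sp)
                continue
            mapping[id(node)] = sp
        else:
            child_maps = [mapping.get(id(c)) for c in node.children]
            if any(m is None for m in child_maps):
                continue
            m = idx.lca_many(child_maps)
            mapping[id(node)] = m
            if any(cm == m for cm in child_maps):
                dup_count += 1
    if unknown:
        raise ValueError(f"species not in species tree: {sorted(unknown)}")
    return {id_: name for id_, name in mapping.items()}, dup_count


def date_duplications(
    labeled_trees: Mapping[str, TreeNode],
    species_tree: TreeNode,
    species_map: Mapping[str, str] | None = None,
) -> list[EventRecord]:
    """Date species-overlap duplication nodes onto species-tree lineages.

    ``labeled_trees`` maps tree ids to gene trees annotated by
    :func:`phylomekit.orthology.label_events_species_overlap`.  Each
    duplication node is assigned the branch ending at the species-tree LCA of
    the union of species below it; speciation nodes are not dated.
    """
    species_tree = _ensure_named_internals(species_tree)
    idx = _SpeciesIndex(species_tree)
    getter = make_species_getter(species_map)
    events: list[EventRecord] = []
    for tree_id, tree in labeled_trees.items():
        for node in tree.non_tips(include_self=True):
            if getattr(node, "event", None) != "duplication":
                continue
            sides = [
                frozenset(t.name for t in c.tips(include_self=True))
                for c in node.children
            ]
            species = {getter(l) for s in sides for l in s}
            unknown = species - idx.names
            if unknown:
                raise ValueError(f"species not in species tree: {sorted(unknown)}")
            lineage = idx.lca_many(species)
            events.append(
                EventRecord(
                    tree_id=tree_id,
                    node_id=getattr(node, "node_id", id(node)),
                    event_type="duplication",
                    side1=sides[0],
                    side2=frozenset().union(*sides[1:]),
                    lineage=lineage,
                )
            )
    return events


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        p = self.parent.setdefault(x, x)
        if p != x:
            self.parent[x] = p = self.find(p)
        return p

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def merge_redundant_events(
    events: list[EventRecord],
    tree_universes: Mapping[str, frozenset] | None = None,
    rule: str = "restricted-exact",
) -> list[EventRecord]:
    """Group redundant duplication reports and keep one representative each.

    Two events from different trees are redundant when their unordered pairs
    of descendant leaf-id sets are identical after restricting both to the
    intersection of the two trees' leaf universes with all four restricted
    sides non-empty (``rule="restricted-exact"``), or identical verbatim
    (``rule="exact"``).  Groups are connected components of this relation;
    the representative is the event with the largest leaf set (ties by tree
    id).  Returned events carry ``group`` ids; the input list is annotated in
    place as well.
    """
    if rule not in {"exact", "restricted-exact"}:
        raise ValueError("rule must be 'exact' or 'restricted-exact'")
    if tree_universes is None:
        tree_universes = {}
        for ev in events:
            tree_universes.setdefault(ev.tree_id, frozenset())
        tree_universes = {
            t: frozenset().union(*(e.leaves for e in events if e.tree_id == t))
            for t in tree_universes
        }
    uf = _UnionFind()
    for i in range(len(events)):
        uf.find(i)
    by_leaf: dict[str, list[int]] = {}
    for i, ev in enumerate(events):
        for leaf in ev.leaves:
            by_leaf.setdefault(leaf, []).append(i)
    pairs = set()
    for bucket in by_leaf.values():
        for ai in range(len(bucket)):
            for bi in range(ai + 1, len(bucket)):
                pairs.add((bucket[ai], bucket[bi]))
    for i, j in pairs:
        a, b = events[i], events[j]
        if a.tree_id == b.tree_id:
            continue
        if rule == "exact":
            if a.sides() == b.sides():
                uf.union(i, j)
            continue
        common = tree_universes[a.tree_id] & tree_universes[b.tree_id]
        ra = frozenset({a.side1 & common, a.side2 & common})
        rb = frozenset({b.side1 & common, b.side2 & common})
        if frozenset() in ra or frozenset() in rb:
            continue
        if ra == rb:
            uf.union(i, j)
    roots: dict = {}
    for i in range(len(events)):
        roots.setdefault(uf.find(i), []).append(i)
    merged: list[EventRecord] = []
    for gid, members in enumerate(sorted(roots.values(), key=min)):
        for i in members:
            events[i].group = gid
        rep = max(
            (events[i] for i in members),
            key=lambda e: (len(e.leaves), e.tree_id),
        )
        merged.append(rep)
    return merged


@dataclass
class LineageRates:
    """Per-lineage duplication counts and rates (duplications per gene)."""

    table: pd.DataFrame
    fraction_trees_with_duplication: float
    fraction_trees_with_merged_duplication: float
    total_merged_duplications: int

    def rate(self, branch_id: str) -> float:
        row = self.table.loc[self.table.branch_id == branch_id]
        if row.empty:
            raise KeyError(branch_id)
        return float(row.rate.iloc[0])


def lineage_duplication_rates(
    merged_events: list[EventRecord],
    phylome_trees: Mapping[str, TreeNode],
    species_tree: TreeNode,
    species_map: Mapping[str, str] | None = None,
    denominator: str = "observable",
    raw_events: list[EventRecord] | None = None,
) -> LineageRates:
    """Duplications per gene for every species-tree branch.

    A tree is *informative* for branch ``b`` when its species span could have
    witnessed a duplication dated to ``b``: it contains at least one species
    from the clade below ``b`` and one outside it (for terminal branches, at
    least one sequence of that species).  ``denominator="all"`` divides by the
    total tree count instead.  Branches with zero informative trees get a NaN
    rate and are flagged undefined.
    """
    if denominator not in {"observable", "all"}:
        raise ValueError("denominator must be 'observable' or 'all'")
    species_tree = _ensure_named_internals(species_tree)
    getter = make_species_getter(species_map)
    clades: dict[str, frozenset] = {}
    parents: dict[str, str] = {}
    for node in species_tree.preorder(include_self=True):
        clades[node.name] = frozenset(t.name for t in node.tips(include_self=True))
        if node.parent is not None:
            parents[node.name] = node.parent.name
    all_species = clades[species_tree.name]
    tree_species = {
        tid: {getter(t.name) for t in tree.tips()}
        for tid, tree in phylome_trees.items()
    }
    counts: dict[str, int] = {b: 0 for b in clades}
    for ev in merged_events:
        if ev.lineage is None:
            raise ValueError("events must be dated before rate computation")
        counts[ev.lineage] += 1
    rows = []
    n_trees = len(phylome_trees)
    for branch, clade in clades.items():
        if denominator == "all":
            informative = n_trees
        elif len(clade) == 1:
            informative = sum(1 for sp in tree_species.values() if clade & sp)
        else:
            outside = all_species - clade
            informative = sum(
                1
                for sp in tree_species.values()
                if (clade & sp) and (outside & sp or not outside)
            )
        rate = counts[branch] / informative if informative > 0 else np.nan
        rows.append(
            {
                "branch_id": branch,
                "parent_id": parents.get(branch, ""),
                "n_species_below": len(clade),
                "duplications": counts[branch],
                "informative_genes": informative,
                "rate": rate,
                "undefined": informative == 0,
            }
        )
    table = pd.DataFrame(rows)
    trees_with_dup: set[str] = set()
    source = raw_events if raw_events is not None else merged_events
    for ev in source:
        trees_with_dup.add(ev.tree_id)
    merged_trees = {ev.tree_id for ev in merged_events}
    return LineageRates(
        table=table,
        fraction_trees_with_duplication=(
            len(trees_with_dup) / n_trees if n_trees else 0.0
        ),
        fraction_trees_with_merged_duplication=(
            len(merged_trees) / n_trees if n_trees else 0.0
        ),
        total_merged_duplications=len(merged_events),
    )


def annotate_species_tree_with_rates(
    species_tree: TreeNode, rates: LineageRates
) -> str:
    """Newick with per-branch duplication rates as internal-node labels."""
    tree = _ensure_named_internals(species_tree).copy()
    lookup = dict(zip(rates.table.branch_id, rates.table.rate))
    for node in tree.preorder(include_self=True):
        r = lookup.get(node.name)
        if r is None or np.isnan(r):
            continue
        label = f"{node.name}|{r:.4f}"
        node.name = label
    return write_newick(tree)


def events_to_frame(events: list[EventRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tree_id": [e.tree_id for e in events],
            "node_id": [str(e.node_id) for e in events],
            "event": [e.event_type for e in events],
            "side1": [",".join(sorted(e.side1)) for e in events],
            "side2": [",".join(sorted(e.side2)) for e in events],
            "lineage": [e.lineage or "" for e in events],
            "group": [e.group if e.group is not None else -1 for e in events],
        }
    )
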