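"""Species-overlap event labeling, ortholog cataloguing, and speciation-only
subtree decomposition.

An internal node of a rooted gene tree is labeled a *duplication* when the
species sets of its two child subtrees overlap (Jaccard overlap score above a
threshold, 0 by default: any shared species), and a *speciation* otherwise.
Two leaves are orthologs iff their most recent common ancestor is a
speciation node; the relation type (one-to-one / one-to-many / many-to-many)
follows from how many sequences of each species the two sides of that node
contribute.  Multi-copy trees are decomposed at every duplication node into
all implied speciation-only, single-labeled species topologies — the form
consumed by split-fit supertree scoring.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping

from skbio import TreeNode

from .treecore import make_species_getter, resolve_polytomies

logger = logging.getLogger(__name__)

__all__ = [
    "OrthologPair",
    "label_events_species_overlap",
    "infer_orthologs",
    "decompose_speciation_subtrees",
]


@dataclass(frozen=True)
class OrthologPair:
    """One classified leaf pair; ``relation`` is 'one-to-one', 'one-to-many',
    'many-to-many' (orthologs) or 'paralog'."""

    a: str
    b: str
    relation: str
    mediating_node: str


def label_events_species_overlap(
    tree: TreeNode,
    overlap_threshold: float = 0.0,
    species_map: Mapping[str, str] | None = None,
) -> TreeNode:
    """Label every internal node duplication/speciation by species overlap.

    Returns an annotated copy: each internal node carries ``node_id`` (stable
    preorder id), ``event`` and ``overlap_score``
    (|intersection| / |union| of the child species sets).  Polytomies are
    resolved deterministically (left-to-right) first and the resolution is
    logged.
    """
    if any(len(n.children) > 2 for n in tree.non_tips(include_self=True)):
        logger.info("resolving polytomies left-to-right before event labeling")
        tree = resolve_polytomies(tree)
    else:
        tree = tree.copy()
    getter = make_species_getter(species_map)
    species_below: dict = {}
    for node in tree.postorder(include_self=True):
        if not node.children:
            species_below[id(node)] = {getter(node.name)}
        else:
            species_below[id(node)] = set().union(
                *(species_below[id(c)] for c in node.children)
            )
    for i, node in enumerate(tree.preorder(include_self=True)):
        if not node.children:
            continue
        node.node_id = f"n{i}"
        sets = [species_below[id(c)] for c in node.children]
        inter = set.intersection(*sets)
        union = set.union(*sets)
        score = len(inter) / len(union)
        node.overlap_score = score
        node.event = "duplication" if score > overlap_threshold else "speciation"
    return tree


def _require_labeled(tree: TreeNode) -> None:
    for node in tree.non_tips(include_self=True):
        if getattr(node, "event", None) is None:
            raise ValueError(
                "tree is not event-labeled; run label_events_species_overlap first"
            )


def infer_orthologs(
    labeled_tree: TreeNode,
    seed_only: bool = False,
    seed_id: str | None = None,
    include_paralogs: bool = False,
    species_map: Mapping[str, str] | None = None,
) -> list[OrthologPair]:
    """Classify every unordered leaf pair through its MRCA's event label.

    Orthologs (speciation MRCA) get a relation from the per-species sequence
    counts each side of the mediating node contributes: 1 vs 1 one-to-one,
    1 vs >1 one-to-many, >1 vs >1 many-to-many.  ``seed_only`` keeps pairs
    involving ``seed_id``; ``include_paralogs`` also emits duplication-
    mediated pairs with relation 'paralog'.
    """
    _require_labeled(labeled_tree)
    if seed_only and seed_id is None:
        raise ValueError("seed_only requires seed_id")
    getter = make_species_getter(species_map)
    pairs: list[OrthologPair] = []
    # walk internal nodes: pairs with this MRCA are cross-child pairs
    for node in labeled_tree.non_tips(include_self=True):
        kids = node.children
        leaf_sets = [list(c.tips(include_self=True)) for c in kids]
        for (i, la), (j, lb) in itertools.combinations(enumerate(leaf_sets), 2):
            for ta in la:
                for tb in lb:
                    a, b = sorted((ta.name, tb.name))
                    if seed_only and seed_id not in (a, b):
                        continue
                    if node.event == "speciation":
                        # sequences of each partner's species on its own side
                        na = sum(
                            1 for t in la if getter(t.name) == getter(ta.name)
                        )
                        nb = sum(
                            1 for t in lb if getter(t.name) == getter(tb.name)
                        )
                        if na == 1 and nb == 1:
                            rel = "one-to-one"
                        elif na > 1 and nb > 1:
                            rel = "many-to-many"
                        else:
                            rel = "one-to-many"
                    elif include_paralogs:
                        rel = "paralog"
                    else:
                        continue
                    pairs.append(
                        OrthologPair(a=a, b=b, relation=rel,
                                     mediating_node=getattr(node, "node_id", ""))
                    )
    return pairs


def _species_subtree(
    node: TreeNode, getter, keep: set | None
) -> list[TreeNode]:
    """All implied speciation-only subtrees below ``node`` (TreeKO-style).

    Returns species-relabeled subtrees; at a duplication the child lists are
    concatenated, at a speciation they are combined (cartesian product).
    """
    if not node.children:
        leaf = TreeNode(name=getter(node.name), length=node.length)
        leaf._members = {node.name}
        return [leaf]
    child_lists = [_species_subtree(c, getter, keep) for c in node.children]
    if getattr(node, "event", "speciation") == "duplication":
        return [t for lst in child_lists for t in lst]
    out = []
    for combo in itertools.product(*child_lists):
        if len(combo) == 1:
            t = combo[0]
            out.append(t)
            continue
        parent = TreeNode(length=node.length)
        members = set()
        copies = []
        for sub in combo:
            c = sub.copy()
            c._members = sub._members
            copies.append(c)
            members |= sub._members
        parent.extend(copies)
        parent._members = members
        out.append(parent)
    return out


def decompose_speciation_subtrees(
    labeled_tree: TreeNode,
    seed_containing_only: bool = False,
    seed_id: str | None = None,
    deduplicate: bool = False,
    species_map: Mapping[str, str] | None = None,
) -> list[TreeNode]:
    """Split a labeled gene tree into speciation-only species topologies.

    The tree is cut at every duplication node; every implied subtree whose
    internal nodes are all speciations is returned, relabeled by species
    codes (single-labeled when the overlap threshold is 0).  With
    ``seed_containing_only`` only subtrees containing the seed leaf survive;
    duplicate topologies are retained unless ``deduplicate`` is set, because
    downstream support counting weights by occurrence.
    """
    _require_labeled(labeled_tree)
    if seed_containing_only and seed_id is None:
        raise ValueError("seed_containing_only requires seed_id")
    getter = make_species_getter(species_map)
    subtrees = _species_subtree(labeled_tree, getter, None)
    if seed_containing_only:
        subtrees = [t for t in subtrees if seed_id in t._members]
    out = []
    seen = set()
    for t in subtrees:
        t = t.copy()
        # suppress unary chains introduced by pruning losses upstream
        for node in list(t.postorder(include_self=False)):
            if len(node.children) == 1:
                child = node.children[0]
                if node.length and child.length is not None:
                    child.length += node.length
                parent = node.parent
                parent.remove(node)
                parent.append(child)
        while len(t.children) == 1:
            t = t.children[0]
            t.parent = None
        if deduplicate:
            key = frozenset(
                (frozenset(x.name for x in n.tips(include_self=True)))
                for n in t.traverse(include_self=True)
            )
            if key in seen:
                continue
            seen.add(key)
        out.append(t)
    return out
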