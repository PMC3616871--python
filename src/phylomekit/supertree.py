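"""Species supertrees from gene-tree collections, and gene-tree support.

Two optimality criteria are implemented.  *Split fit* (SFIT) scores a
candidate species tree by the mean fraction of bipartitions it shares with
each single-labeled source topology after restricting both to their common
taxa — the input of choice is the speciation-only decomposition of the
phylome's gene trees.  *Gene-tree duplication parsimony* scores a candidate
by the total number of duplications implied when every (multi-copy) gene
tree is LCA-reconciled against it, and seeks the candidate minimizing that
count.  The search is hill climbing over rooted species topologies with NNI
moves, escalating to one SPR sweep when NNI stalls, from a greedy
taxon-addition start plus random starts.

Per-bipartition gene-tree support — the percentage of gene trees whose
induced topology contains a given species-tree split, among the trees
eligible to show it — is computed for any fixed species tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .treecore import bipartitions, leaf_names, write_newick

__all__ = [
    "SupertreeResult",
    "sfit_score",
    "gtp_duplication_cost",
    "search_supertree",
    "exhaustive_supertree",
    "enumerate_rooted_topologies",
    "bipartition_support",
]


@dataclass
class SupertreeResult:
    tree: TreeNode
    criterion: str
    score: float
    trace: list[tuple[int, str, float]] = field(default_factory=list)

    @property
    def newick(self) -> str:
        return write_newick(self.tree)


# ---------------------------------------------------------------------------
# criteria


def sfit_score(
    candidate: TreeNode,
    gene_topologies: Sequence[TreeNode],
    denominator: str = "max",
    min_shared_species: int = 4,
) -> float:
    """Mean split fit of the candidate against single-labeled topologies.

    Per source tree: both trees are restricted to their shared species; the
    fit is |shared non-trivial splits| / max(splits(source), splits(candidate))
    (``denominator="source"`` divides by the source's splits instead).
    Source trees sharing fewer than ``min_shared_species`` species — or
    having no non-trivial split after restriction — are skipped; an empty
    eligible set is an error.
    """
    scorer = _SfitScorer(gene_topologies, denominator, min_shared_species)
    return scorer.score(candidate)


def _restrict_splits(splits, taxa: frozenset) -> frozenset:
    """Induced non-trivial splits after restricting to a taxon subset."""
    from .treecore import _canon_split

    out = set()
    for a, b in splits:
        ra, rb = frozenset(a & taxa), frozenset(b & taxa)
        if len(ra) >= 2 and len(rb) >= 2:
            out.add(_canon_split(ra, rb))
    return frozenset(out)


class _SfitScorer:
    """Preprocessed split-fit scoring: source splits are computed once and
    grouped by taxon set so repeated candidate evaluations are cheap."""

    def __init__(
        self,
        gene_topologies: Sequence[TreeNode],
        denominator: str = "max",
        min_shared_species: int = 4,
    ):
        if denominator not in {"max", "source"}:
            raise ValueError("denominator must be 'max' or 'source'")
        self.denominator = denominator
        self.min_shared = min_shared_species
        self.n_sources = len(gene_topologies)
        self.n_skipped_small = 0
        # taxa -> {source splitset -> multiplicity}
        self.groups: dict[frozenset, dict[frozenset, int]] = {}
        for t in gene_topologies:
            taxa = frozenset(leaf_names(t))
            splits = frozenset(bipartitions(t))
            bucket = self.groups.setdefault(taxa, {})
            bucket[splits] = bucket.get(splits, 0) + 1

    def score(self, candidate: TreeNode) -> float:
        cand_taxa = frozenset(leaf_names(candidate))
        cand_splits = bipartitions(candidate)
        total = 0.0
        n = 0
        for taxa, bucket in self.groups.items():
            shared = taxa & cand_taxa
            if len(shared) < self.min_shared:
                continue
            cand_r = _restrict_splits(cand_splits, shared)
            for src_splits, mult in bucket.items():
                src_r = (
                    _restrict_splits(src_splits, shared)
                    if shared != taxa
                    else src_splits
                )
                denom = (
                    max(len(src_r), len(cand_r))
                    if self.denominator == "max"
                    else len(src_r)
                )
                if denom == 0:
                    continue
                total += mult * len(src_r & cand_r) / denom
                n += mult
        if n == 0:
            raise ValueError(
                "no gene topology shares enough species with the candidate"
            )
        return total / n


class _GtpScorer:
    """Preprocessed gene-tree-parsimony scoring.

    Gene trees are flattened once into postorder integer programs; each
    candidate evaluation builds a small LCA table over the candidate's nodes
    and replays the programs with integer lookups only.
    """

    def __init__(
        self,
        gene_trees: Sequence[TreeNode],
        species_map: Mapping[str, str] | None = None,
    ):
        from .treecore import make_species_getter

        getter = make_species_getter(species_map)
        species = set()
        for gt in gene_trees:
            species.update(getter(l) for l in leaf_names(gt))
        self.species = sorted(species)
        sp_index = {s: i for i, s in enumerate(self.species)}
        self.programs: list[list[tuple[int, int]]] = []
        for gt in gene_trees:
            ops: list[tuple[int, int]] = []
            pos: dict[int, int] = {}
            for node in gt.postorder(include_self=True):
                if not node.children:
                    ops.append((-1, sp_index[getter(node.name)]))
                else:
                    kids = [pos[id(c)] for c in node.children]
                    acc = kids[0]
                    for k in kids[1:]:
                        ops.append((acc, k))
                        acc = len(ops) - 1
                pos[id(node)] = len(ops) - 1
            self.programs.append(ops)

    def score(self, candidate: TreeNode) -> int:
        nodes = list(candidate.postorder(include_self=True))
        nid = {id(n): i for i, n in enumerate(nodes)}
        parent = [nid[id(n.parent)] if n.parent is not None else -1 for n in nodes]
        depth = [0] * len(nodes)
        for i in reversed(range(len(nodes) - 1)):
            depth[i] = depth[parent[i]] + 1
        tip_of: dict[str, int] = {
            n.name: nid[id(n)] for n in nodes if not n.children
        }
        try:
            sp_node = [tip_of[s] for s in self.species]
        except KeyError as exc:
            raise ValueError(f"species {exc} not in candidate tree") from None
        N = len(nodes)
        lca = [[0] * N for _ in range(N)]
        for a in range(N):
            lca[a][a] = a
            for b in range(a + 1, N):
                x, y = a, b
                while depth[x] > depth[y]:
                    x = parent[x]
                while depth[y] > depth[x]:
                    y = parent[y]
                while x != y:
                    x, y = parent[x], parent[y]
                lca[a][b] = lca[b][a] = x
        total = 0
        for ops in self.programs:
            vals = [0] * len(ops)
            for i, (a, b) in enumerate(ops):
                if a == -1:
                    vals[i] = sp_node[b]
                else:
                    va, vb = vals[a], vals[b]
                    m = lca[va][vb]
                    vals[i] = m
                    if m == va or m == vb:
                        total += 1
        return total


def gtp_duplication_cost(
    candidate: TreeNode,
    gene_trees: Sequence[TreeNode],
    species_map: Mapping[str, str] | None = None,
) -> int:
    """Total LCA-reconciliation duplication count over the collection."""
    return _GtpScorer(gene_trees, species_map=species_map).score(candidate)


# ---------------------------------------------------------------------------
# topology proposals


def _join(a: TreeNode, b: TreeNode) -> TreeNode:
    root = TreeNode()
    root.extend([a, b])
    return root


def _insert_child(parent: TreeNode, idx: int, child: TreeNode) -> None:
    """Attach ``child`` under ``parent`` at position ``idx``."""
    parent.append(child)
    parent.children.insert(idx, parent.children.pop())


def enumerate_rooted_topologies(species: Sequence[str]) -> Iterable[TreeNode]:
    """All rooted binary topologies over the given species (lazily).

    (2n-3)!! trees; practical up to ~7 species (10395 trees at n=6).
    """
    species = sorted(species)

    def build(tree: TreeNode, remaining: list[str]):
        if not remaining:
            yield tree.copy()
            return
        nxt, rest = remaining[0], remaining[1:]
        # insert on every edge, plus above the root
        for node in list(tree.traverse(include_self=False)):
            parent = node.parent
            idx = parent.children.index(node)
            parent.remove(node)
            joint = TreeNode()
            joint.extend([node, TreeNode(name=nxt)])
            _insert_child(parent, idx, joint)
            yield from build(tree, rest)
            parent.remove(joint)
            joint.remove(node)
            _insert_child(parent, idx, node)
        new_root = _join(tree, TreeNode(name=nxt))
        yield from build(new_root, rest)
        new_root.remove(tree)
        tree.parent = None

    if len(species) == 1:
        yield TreeNode(name=species[0])
        return
    start = _join(TreeNode(name=species[0]), TreeNode(name=species[1]))
    yield from build(start, list(species[2:]))


def _random_topology(species: Sequence[str], rng: np.random.Generator) -> TreeNode:
    order = list(species)
    rng.shuffle(order)
    tree = _join(TreeNode(name=order[0]), TreeNode(name=order[1]))
    for name in order[2:]:
        edges = list(tree.traverse(include_self=False))
        choice = int(rng.integers(len(edges) + 1))
        if choice == len(edges):
            tree = _join(tree, TreeNode(name=name))
            continue
        node = edges[choice]
        parent = node.parent
        idx = parent.children.index(node)
        parent.remove(node)
        joint = TreeNode()
        joint.extend([node, TreeNode(name=name)])
        _insert_child(parent, idx, joint)
    return tree


def _nni_neighbors(tree: TreeNode) -> Iterable[tuple[str, TreeNode]]:
    """The two NNI rearrangements around every internal (non-root) edge."""
    nodes = [
        n for n in tree.preorder(include_self=False) if n.children
    ]
    for ni, node in enumerate(nodes):
        parent = node.parent
        siblings = [s for s in parent.children if s is not node]
        if len(siblings) != 1:
            continue
        sib = siblings[0]
        for ci in range(len(node.children)):
            t = tree.copy()
            t_nodes = [
                n for n in t.preorder(include_self=False) if n.children
            ]
            tn = t_nodes[ni]
            tp = tn.parent
            tsib = [s for s in tp.children if s is not tn][0]
            tchild = tn.children[ci]
            tn.remove(tchild)
            tp.remove(tsib)
            tn.append(tsib)
            tp.append(tchild)
            yield f"nni:{ni}.{ci}", t


def _spr_neighbors(tree: TreeNode) -> Iterable[tuple[str, TreeNode]]:
    """Prune every non-root clade and regraft it on every other edge
    (including above the root)."""
    all_nodes = list(tree.preorder(include_self=False))
    for pi in range(len(all_nodes)):
        prune = all_nodes[pi]
        prune_leaves = _clade_key(prune)
        in_pruned = set(id(n) for n in prune.traverse(include_self=True))
        for gi in range(len(all_nodes) + 1):
            if gi < len(all_nodes):
                graft = all_nodes[gi]
                if id(graft) in in_pruned or graft is prune.parent:
                    continue
                if graft.parent is prune.parent and len(prune.parent.children) == 2:
                    continue  # regraft onto sibling edge: original topology
                target_names = _clade_key(graft) - prune_leaves
                if not target_names:
                    continue
            t = tree.copy()
            nodes_t = list(t.preorder(include_self=False))
            prune_t = nodes_t[pi]
            parent = prune_t.parent
            parent.remove(prune_t)
            # suppress the unary node left behind
            if len(parent.children) == 1:
                only = parent.children[0]
                if parent.parent is None:
                    t = only
                    only.parent = None
                else:
                    gp = parent.parent
                    idx = gp.children.index(parent)
                    gp.remove(parent)
                    _insert_child(gp, idx, only)
            if gi == len(all_nodes):
                t = _join(t, prune_t)
                yield f"spr:{pi}.root", t
                continue
            target = None
            for cand in t.preorder(include_self=False):
                if _clade_key(cand) == target_names:
                    target = cand
                    break
            if target is None:
                continue
            tp = target.parent
            idx = tp.children.index(target)
            tp.remove(target)
            joint = TreeNode()
            joint.extend([target, prune_t])
            _insert_child(tp, idx, joint)
            yield f"spr:{pi}.{gi}", t


def _clade_key(node: TreeNode) -> frozenset:
    return frozenset(t.name for t in node.tips(include_self=True))


def _topology_key(tree: TreeNode) -> frozenset:
    return frozenset(
        _clade_key(n) for n in tree.traverse(include_self=True)
    )


def _greedy_start(
    species: Sequence[str], score_fn, maximize: bool
) -> TreeNode:
    """Stepwise taxon addition: each species inserted at its best position."""
    species = sorted(species)
    best = None
    sign = 1.0 if maximize else -1.0
    tree = _join(TreeNode(name=species[0]), TreeNode(name=species[1]))
    for name in species[2:]:
        candidates = []
        edges = list(tree.traverse(include_self=False))
        for choice in range(len(edges) + 1):
            t = tree.copy()
            edges_t = list(t.traverse(include_self=False))
            if choice == len(edges):
                t = _join(t, TreeNode(name=name))
            else:
                node = edges_t[choice]
                parent = node.parent
                idx = parent.children.index(node)
                parent.remove(node)
                joint = TreeNode()
                joint.extend([node, TreeNode(name=name)])
                _insert_child(parent, idx, joint)
            try:
                s = score_fn(t)
            except ValueError:
                s = -np.inf * sign
            candidates.append((sign * s, write_newick(t), t))
        candidates.sort(key=lambda c: (-c[0], c[1]))
        tree = candidates[0][2]
    return tree


def search_supertree(
    gene_trees: Sequence[TreeNode],
    criterion: str = "duplication_parsimony",
    n_starts: int = 20,
    seed: int = 0,
    species_map: Mapping[str, str] | None = None,
    gene_topologies: Sequence[TreeNode] | None = None,
    n_kicks: int = 5,
) -> SupertreeResult:
    """Hill-climbing supertree search under SFIT or duplication parsimony.

    ``criterion="sfit"`` scores against ``gene_topologies`` (single-labeled,
    e.g. speciation-only decompositions; defaults to ``gene_trees`` if they
    are already species-labeled).  ``criterion="duplication_parsimony"``
    reconciles the raw gene trees.  NNI first-improvement (deterministic
    preorder edge ordering), one SPR sweep when NNI stalls, ``n_starts``
    random starts plus a greedy taxon-addition start, then ``n_kicks``
    double-NNI perturbation restarts from the incumbent; deterministic given
    ``seed``.
    """
    from .treecore import make_species_getter

    if criterion == "sfit":
        sources = list(gene_topologies if gene_topologies is not None else gene_trees)
        species = sorted(set().union(*(leaf_names(t) for t in sources)))
        scorer = _SfitScorer(sources)

        def score_fn(t: TreeNode) -> float:
            return scorer.score(t)

        maximize = True
    elif criterion == "duplication_parsimony":
        gscorer = _GtpScorer(gene_trees, species_map=species_map)
        species = gscorer.species

        def score_fn(t: TreeNode) -> float:
            return -float(gscorer.score(t))

        maximize = True  # internally negated cost
    else:
        raise ValueError("criterion must be 'sfit' or 'duplication_parsimony'")
    if len(species) < 4:
        raise ValueError("supertree search needs at least 4 species")

    cache: dict[frozenset, float] = {}

    def cached_score(t: TreeNode) -> float:
        key = _topology_key(t)
        s = cache.get(key)
        if s is None:
            s = score_fn(t)
            cache[key] = s
        return s

    trace: list[tuple[int, str, float]] = []
    step = 0

    def climb(tree: TreeNode, tag: str) -> tuple[TreeNode, float]:
        nonlocal step
        score = cached_score(tree)
        trace.append((step, tag, _signed(score, criterion)))
        step += 1
        improved = True
        while improved:
            improved = False
            for move, cand in _nni_neighbors(tree):
                s = cached_score(cand)
                if s > score + 1e-12:
                    tree, score = cand, s
                    trace.append((step, move, _signed(s, criterion)))
                    step += 1
                    improved = True
                    break
            if not improved:
                for move, cand in _spr_neighbors(tree):
                    s = cached_score(cand)
                    if s > score + 1e-12:
                        tree, score = cand, s
                        trace.append((step, move, _signed(s, criterion)))
                        step += 1
                        improved = True
                        break
        return tree, score

    rng = np.random.default_rng(seed)
    starts = [_greedy_start(species, score_fn, maximize)]
    starts += [_random_topology(species, rng) for _ in range(n_starts)]

    best_tree, best_score = None, -np.inf
    for si, start in enumerate(starts):
        tree, score = climb(start, f"start:{si}")
        if score > best_score or (
            score == best_score
            and best_tree is not None
            and write_newick(tree) < write_newick(best_tree)
        ):
            best_tree, best_score = tree, score
    # perturbation restarts: random double-NNI kicks from the incumbent
    for ki in range(n_kicks):
        kicked = best_tree.copy()
        for _ in range(2):
            neigh = list(_nni_neighbors(kicked))
            if not neigh:
                break
            kicked = neigh[int(rng.integers(len(neigh)))][1]
        tree, score = climb(kicked, f"kick:{ki}")
        if score > best_score:
            best_tree, best_score = tree, score
    return SupertreeResult(
        tree=best_tree,
        criterion=criterion,
        score=_signed(best_score, criterion),
        trace=trace,
    )


def _signed(score: float, criterion: str) -> float:
    return -score if criterion == "duplication_parsimony" else score


def exhaustive_supertree(
    gene_trees: Sequence[TreeNode],
    criterion: str = "duplication_parsimony",
    species_map: Mapping[str, str] | None = None,
    gene_topologies: Sequence[TreeNode] | None = None,
) -> SupertreeResult:
    """Exact optimum by enumerating every rooted topology (small n only)."""
    from .treecore import make_species_getter

    if criterion == "sfit":
        sources = list(gene_topologies if gene_topologies is not None else gene_trees)
        species = sorted(set().union(*(leaf_names(t) for t in sources)))

        def score_fn(t):
            return sfit_score(t, sources)

        better = lambda a, b: a > b
    else:
        getter = make_species_getter(species_map)
        species = sorted(
            {getter(l) for gt in gene_trees for l in leaf_names(gt)}
        )

        def score_fn(t):
            return gtp_duplication_cost(t, gene_trees, species_map=species_map)

        better = lambda a, b: a < b
    best, best_score = None, None
    for t in enumerate_rooted_topologies(species):
        s = score_fn(t)
        if best is None or better(s, best_score):
            best, best_score = t, s
    return SupertreeResult(tree=best, criterion=criterion, score=best_score)


# ---------------------------------------------------------------------------
# gene-tree support


def bipartition_support(
    species_tree: TreeNode,
    gene_topologies: Sequence[TreeNode],
    strict: bool = False,
) -> pd.DataFrame:
    """Percent of gene trees supporting each species-tree bipartition.

    A gene topology is *eligible* for split A|B when restricting the split to
    the tree's species leaves >= 2 species on both sides (``strict=True``
    instead requires every species present); it *supports* the split when the
    restricted split occurs among its own non-trivial splits.  Splits with no
    eligible tree get NaN support.
    """
    from .treecore import _canon_split

    rows = []
    species = set(leaf_names(species_tree))
    src_info = []
    for t in gene_topologies:
        taxa = set(leaf_names(t))
        extra = taxa - species
        splits = bipartitions(t, restrict_to=taxa - extra) if extra else bipartitions(t)
        src_info.append((taxa & species, splits))
    for a, b in sorted(bipartitions(species_tree), key=lambda s: sorted(s[0])):
        eligible = supporting = 0
        for taxa, splits in src_info:
            ra, rb = frozenset(a & taxa), frozenset(b & taxa)
            if strict:
                if ra != a or rb != b:
                    continue
            elif len(ra) < 2 or len(rb) < 2:
                continue
            eligible += 1
            if _canon_split(ra, rb) in splits:
                supporting += 1
        pct = 100.0 * supporting / eligible if eligible else np.nan
        rows.append(
            {
                "side1": ",".join(sorted(a)),
                "side2": ",".join(sorted(b)),
                "supporting": supporting,
                "eligible": eligible,
                "support_pct": round(pct, 1) if eligible else np.nan,
            }
        )
    return pd.DataFrame(rows)
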