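"""Core tree model shared by every other module.

Trees are :class:`skbio.TreeNode` objects throughout the package.  Leaves of
gene trees are named ``<sequence_id>_<species_code>`` by default (species code
after the *last* underscore); an explicit sequence-id -> species mapping can be
supplied instead wherever a species assignment is needed.

This module adds the operations the rest of the pipeline relies on: validated
Newick parsing, outgroup/midpoint rooting, non-trivial bipartition extraction,
pruning to a taxon subset, and the Robinson-Foulds distance.
"""

from __future__ import annotations

import io
from typing import Callable, Iterable, Mapping

from skbio import TreeNode

__all__ = [
    "TreeError",
    "NewickParseError",
    "LeafNamingError",
    "parse_newick",
    "write_newick",
    "species_of_label",
    "make_species_getter",
    "leaf_names",
    "leaf_species",
    "root_tree",
    "midpoint_root",
    "outgroup_root",
    "bipartitions",
    "prune_to_taxa",
    "rf_distance",
    "resolve_polytomies",
    "is_binary",
    "read_species_map",
]


class TreeError(ValueError):
    """Invalid tree or invalid operation on a tree."""


class NewickParseError(TreeError):
    """Malformed Newick input."""


class LeafNamingError(TreeError):
    """Leaf labels that cannot be mapped to a species."""


SpeciesGetter = Callable[[str], str]


def species_of_label(label: str) -> str:
    """Extract the species code from a ``SEQID_SPECIES`` leaf label."""
    if "_" not in label:
        raise LeafNamingError(
            f"leaf label {label!r} has no '_species' suffix; "
            "supply an explicit species map"
        )
    return label.rsplit("_", 1)[1]


def sequence_id_of_label(label: str) -> str:
    """The sequence identifier part of a leaf label (the label itself)."""
    return label


def make_species_getter(
    species_map: Mapping[str, str] | None = None,
) -> SpeciesGetter:
    """Return a label -> species function.

    With no mapping the default ``SEQID_SPECIES`` suffix convention is used;
    with a mapping, labels are looked up and misses raise
    :class:`LeafNamingError`.
    """
    if species_map is None:
        return species_of_label

    def getter(label: str) -> str:
        try:
            return species_map[label]
        except KeyError:
            raise LeafNamingError(f"leaf {label!r} missing from species map") from None

    return getter


def read_species_map(path) -> dict[str, str]:
    """Read a two-column TSV (sequence_id, species_code) into a dict."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            mapping[parts[0]] = parts[1]
    return mapping


def parse_newick(
    text: str,
    species_map: Mapping[str, str] | None = None,
    validate_species: bool = False,
) -> TreeNode:
    """Parse one Newick string into a tree.

    Underscores in unquoted labels are kept verbatim (no space conversion).
    Duplicate leaf labels raise :class:`TreeError`; with
    ``validate_species=True`` every leaf must resolve to a species under the
    naming convention (or the supplied map), otherwise a
    :class:`LeafNamingError` lists the offenders.
    """
    try:
        tree = TreeNode.read(io.StringIO(text), convert_underscores=False)
    except Exception as exc:  # skbio raises NewickFormatError
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    names = [tip.name for tip in tree.tips()]
    if any(n is None for n in names):
        raise NewickParseError("unlabeled leaf in Newick input")
    seen: set[str] = set()
    dups = {n for n in names if n in seen or seen.add(n)}  # type: ignore[func-returns-value]
    if dups:
        raise TreeError(f"duplicate leaf labels: {sorted(dups)}")
    if validate_species:
        getter = make_species_getter(species_map)
        bad = []
        for n in names:
            try:
                getter(n)
            except LeafNamingError:
                bad.append(n)
        if bad:
            raise LeafNamingError(f"leaves without species assignment: {sorted(bad)}")
    return tree


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to a single-line Newick string."""
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def leaf_names(tree: TreeNode) -> list[str]:
    return [tip.name for tip in tree.tips()]


def leaf_species(
    tree: TreeNode, species_map: Mapping[str, str] | None = None
) -> set[str]:
    getter = make_species_getter(species_map)
    return {getter(tip.name) for tip in tree.tips()}


def _total_length(tree: TreeNode) -> float:
    return sum(n.length or 0.0 for n in tree.traverse(include_self=False))


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Requires at least one positive branch length; otherwise the midpoint is
    undefined and outgroup rooting must be used instead.
    """
    if _total_length(tree) <= 0.0:
        raise TreeError(
            "midpoint rooting undefined: tree has no positive branch lengths; "
            "use outgroup rooting"
        )
    tips = list(tree.tips())
    if len(tips) == 2:
        # skbio's midpoint rooting degenerates on a single edge
        half = _total_length(tree) / 2.0
        a, b = tips
        out = TreeNode()
        out.extend([TreeNode(name=a.name, length=half), TreeNode(name=b.name, length=half)])
        return out
    return tree.root_at_midpoint(branch_attrs=[])


def outgroup_root(
    tree: TreeNode,
    outgroup_species: Iterable[str],
    species_map: Mapping[str, str] | None = None,
) -> TreeNode:
    """Root on the edge above the smallest clade holding all outgroup leaves.

    ``outgroup_species`` are species codes; every leaf of those species that is
    present counts as an outgroup leaf.  Rooting is placed at the middle of the
    chosen edge.
    """
    wanted = set(outgroup_species)
    getter = make_species_getter(species_map)
    og = {tip.name for tip in tree.tips() if getter(tip.name) in wanted}
    if not og:
        raise TreeError(f"no outgroup species {sorted(wanted)} present in tree")
    all_leaves = set(leaf_names(tree))
    if og == all_leaves:
        raise TreeError("outgroup covers every leaf; cannot root")
    # Every edge splits the unrooted tree into clade(node) vs the rest; pick
    # the edge whose og-containing side is smallest.
    best = None
    best_size = len(all_leaves) + 1
    best_flip = False
    for node in tree.traverse(include_self=False):
        side = {t.name for t in node.tips()} if node.children else {node.name}
        if og <= side and len(side) < best_size:
            best, best_size, best_flip = node, len(side), False
        comp = all_leaves - side
        if og <= comp and len(comp) < best_size:
            best, best_size, best_flip = node, len(comp), True
    assert best is not None
    if best.parent.is_root() and len(best.parent.children) == 2 and not best_flip:
        # already rooted on that edge
        return tree.copy()
    rooted = tree.root_at(best, above=True, branch_attrs=[])
    return rooted


def root_tree(
    tree: TreeNode,
    outgroup_species: Iterable[str] | None = None,
    species_map: Mapping[str, str] | None = None,
) -> TreeNode:
    """Root by outgroup when given, else by midpoint."""
    if outgroup_species:
        return outgroup_root(tree, outgroup_species, species_map)
    return midpoint_root(tree)


Bipartition = tuple[frozenset, frozenset]


def _canon_split(a: frozenset, b: frozenset) -> Bipartition:
    return (a, b) if tuple(sorted(a)) <= tuple(sorted(b)) else (b, a)


def bipartitions(
    tree: TreeNode,
    restrict_to: Iterable[str] | None = None,
    include_trivial: bool = False,
) -> set[Bipartition]:
    """Non-trivial splits of the unrooted topology.

    With ``restrict_to`` the tree is first pruned to that leaf subset; fewer
    than four remaining leaves yield an empty set.
    """
    if restrict_to is not None:
        keep = set(restrict_to)
        present = keep & set(leaf_names(tree))
        if len(present) < (2 if include_trivial else 4):
            return set()
        tree = prune_to_taxa(tree, present)
    all_leaves = frozenset(leaf_names(tree))
    out: set[Bipartition] = set()
    minimum = 1 if include_trivial else 2
    for node in tree.traverse(include_self=False):
        if not node.children:
            if include_trivial:
                side = frozenset([node.name])
                comp = all_leaves - side
                if len(comp) >= 1:
                    out.add(_canon_split(side, comp))
            continue
        side = frozenset(t.name for t in node.tips())
        comp = all_leaves - side
        if len(side) >= minimum and len(comp) >= minimum:
            out.add(_canon_split(side, comp))
    return out


def prune_to_taxa(tree: TreeNode, keep: Iterable[str]) -> TreeNode:
    """Prune to a leaf subset, suppressing unary nodes (lengths summed)."""
    keep = set(keep)
    if not keep:
        raise TreeError("cannot prune to an empty leaf set")
    have = set(leaf_names(tree))
    unknown = keep - have
    if unknown:
        raise TreeError(f"unknown leaves in keep set: {sorted(unknown)}")
    if keep == have:
        return tree.copy()
    return tree.shear(keep)


def rf_distance(t1: TreeNode, t2: TreeNode) -> int:
    """Robinson-Foulds distance: size of the symmetric difference of the
    non-trivial bipartition sets.  Requires identical leaf sets."""
    l1, l2 = set(leaf_names(t1)), set(leaf_names(t2))
    if l1 != l2:
        raise TreeError(
            f"leaf sets differ; symmetric difference: {sorted(l1 ^ l2)}"
        )
    return len(bipartitions(t1) ^ bipartitions(t2))


def is_binary(tree: TreeNode) -> bool:
    """True when every internal node has exactly two children (rooted sense)."""
    return all(
        len(n.children) == 2 for n in tree.non_tips(include_self=True)
    )


def resolve_polytomies(tree: TreeNode) -> TreeNode:
    """Resolve every polytomy deterministically (left-to-right ladder).

    Children beyond the first are folded into a caterpillar with zero-length
    introduced branches, preserving input child order.
    """
    t = tree.copy()
    for node in list(t.non_tips(include_self=True)):
        while len(node.children) > 2:
            a = node.children[-2]
            b = node.children[-1]
            node.remove(a)
            node.remove(b)
            joint = TreeNode(length=0.0)
            joint.append(a)
            joint.append(b)
            node.append(joint)
    return t
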