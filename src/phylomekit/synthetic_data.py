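"""Synthetic phylome generator with planted ground truth.

Emulates the data regime of a transcriptome-based phylome: a dated species
tree, gene families evolving along it under a gene birth-death process
(duplications and losses per gene lineage), transcriptome-style incomplete
sampling of gene copies, optional gene-tree reconstruction error (one random
NNI), and protein alignments evolved under empirical replacement models.
Every stochastic output is reproducible from ``(config, seed)`` and every
planted duplication is recorded with its true species-tree lineage, so all
downstream stages can be validated against ground truth.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from dendropy.model import birthdeath
from skbio import TreeNode

from .duplications import EventRecord
from .likelihood import SubstModel, load_model
from .seqio import AMINO_ACIDS
from .treecore import parse_newick

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "simulate_species_tree",
    "simulate_gene_family",
    "simulate_alignment",
    "simulate_phylome",
]

_MAX_RETRIES = 100


@dataclass
class SimulationConfig:
    """Parameters of the phylome simulation.

    Rates are per lineage per unit of species-tree branch length (time);
    ``sampling_prob`` models transcriptome incompleteness (probability that a
    surviving gene copy was assembled and annotated); ``topology_error_p`` is
    the probability that a simulated gene tree receives one random NNI
    perturbation, standing in for reconstruction error.
    """

    n_species: int = 8
    birth_rate: float = 1.0
    death_rate: float = 0.2
    n_families: int = 200
    dup_rate: float = 0.3
    loss_rate: float = 0.1
    sampling_prob: float = 1.0
    topology_error_p: float = 0.0
    aln_length: int = 300
    model: str = "LG"
    alpha: float = 1.0
    p_inv: float = 0.0
    seed: int = 0
    seed_species: str | None = None

    def __post_init__(self):
        for name in ("birth_rate", "death_rate", "dup_rate", "loss_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("sampling_prob", "topology_error_p"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_species < 2:
            raise ValueError("need at least two species")


@dataclass
class TruthSet:
    """Planted ground truth of one simulated phylome."""

    species_tree: TreeNode
    gene_trees: dict[str, TreeNode]
    events: list[EventRecord]
    seed_ids: dict[str, str]  # family id -> seed sequence id
    perturbed: set[str] = field(default_factory=set)
    n_resimulated: int = 0

    def lineage_duplication_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for ev in self.events:
            counts[ev.lineage] = counts.get(ev.lineage, 0) + 1
        return counts


def _species_rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, 0xA5]))


def simulate_species_tree(config: SimulationConfig) -> TreeNode:
    """Rooted ultrametric birth-death tree conditioned on ``n_species`` tips.

    Uses the general-sampling-approach conditioning so no branch has length
    zero.  Tips are renamed ``S1..Sn`` and internal nodes ``N1..`` in preorder;
    branch lengths are in time units.
    """
    rng = _pyrandom.Random(int(_species_rng(config).integers(2**31)))
    last = None
    for _ in range(_MAX_RETRIES):
        try:
            dtree = birthdeath.birth_death_tree(
                birth_rate=config.birth_rate,
                death_rate=config.death_rate,
                num_extant_tips=config.n_species,
                gsa_ntax=config.n_species + 2,
                rng=rng,
                repeat_until_success=False,
            )
            break
        except Exception as exc:  # total extinction
            last = exc
    else:
        raise RuntimeError(
            f"species-tree simulation failed after {_MAX_RETRIES} attempts "
            f"(death rate too close to or above birth rate?): {last}"
        )
    newick = dtree.as_string(schema="newick", suppress_rooting=True)
    tree = parse_newick(newick.strip())
    tip_i = internal_i = 0
    for node in tree.preorder(include_self=True):
        if node.children:
            internal_i += 1
            node.name = f"N{internal_i}"
        else:
            tip_i += 1
            node.name = f"S{tip_i}"
    assert tip_i == config.n_species
    return tree


class _FamilySimulator:
    """Gene birth-death along a fixed species tree for one family."""

    def __init__(self, species_tree: TreeNode, config: SimulationConfig,
                 family_id: str, rng: np.random.Generator):
        self.sp = species_tree
        self.cfg = config
        self.fam = family_id
        self.rng = rng
        self.events: list[EventRecord] = []
        self.copy_counter = 0

    def run(self) -> TreeNode | None:
        root = self._evolve(self.sp, None)
        if root is None:
            return None
        # keep only events whose node survived into the final tree with both
        # sides non-empty (others are invisible to any downstream method)
        kept = []
        surviving = {id(n) for n in root.traverse(include_self=True)}
        for ev in self.events:
            if ev.node_id in surviving:
                node = next(n for n in root.traverse(include_self=True)
                            if id(n) == ev.node_id)
                sides = [frozenset(t.name for t in c.tips(include_self=True))
                         for c in node.children]
                if len(sides) == 2 and all(sides):
                    kept.append(EventRecord(
                        tree_id=self.fam, node_id=ev.node_id,
                        event_type="duplication",
                        side1=sides[0], side2=sides[1], lineage=ev.lineage,
                    ))
        self.events = kept
        return root

    def _evolve(self, sp_node: TreeNode, time_left: float | None) -> TreeNode | None:
        """One gene lineage entering the branch above ``sp_node`` with
        ``time_left`` remaining (None = top of the species-tree root branch).

        The returned subtree root's ``length`` is the time consumed on this
        species-tree branch before the subtree's first event; losses return
        None and unary survivors are suppressed with lengths summed.
        """
        cfg = self.cfg
        if time_left is None:
            time_left = sp_node.length or 0.0
        total = cfg.dup_rate + cfg.loss_rate
        elapsed = 0.0
        while total > 0 and time_left > 0:
            wait = self.rng.exponential(1.0 / total)
            if wait >= time_left:
                elapsed += time_left
                time_left = 0.0
                break
            elapsed += wait
            time_left -= wait
            if self.rng.random() < cfg.dup_rate / total:
                left = self._evolve(sp_node, time_left)
                right = self._evolve(sp_node, time_left)
                if left is None and right is None:
                    return None
                if left is None or right is None:
                    survivor = left if right is None else right
                    survivor.length += elapsed
                    return survivor
                node = TreeNode(length=elapsed)
                node.extend([left, right])
                self.events.append(EventRecord(
                    tree_id=self.fam, node_id=id(node),
                    event_type="duplication",
                    side1=frozenset(), side2=frozenset(),
                    lineage=sp_node.name,
                ))
                return node
            return None  # loss
        else:
            elapsed += time_left
        # reached the bottom of the branch
        if not sp_node.children:
            if self.rng.random() >= cfg.sampling_prob:
                return None
            self.copy_counter += 1
            name = f"{self.fam}g{self.copy_counter}_{sp_node.name}"
            return TreeNode(name=name, length=elapsed)
        kids = [self._evolve(c, None) for c in sp_node.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            kids[0].length += elapsed
            return kids[0]
        node = TreeNode(length=elapsed)
        node.extend(kids)
        return node


def _random_nni(tree: TreeNode, rng: np.random.Generator) -> bool:
    """Apply one uniformly chosen NNI on an internal edge; False if none."""
    edges = [
        n for n in tree.traverse(include_self=False)
        if n.children and n.parent is not None and
        (n.parent.parent is not None or len(n.parent.children) > 1)
    ]
    cand = []
    for n in edges:
        siblings = [s for s in n.parent.children if s is not n]
        if siblings:
            cand.append((n, siblings))
    if not cand:
        return False
    n, siblings = cand[int(rng.integers(len(cand)))]
    sib = siblings[int(rng.integers(len(siblings)))]
    child = n.children[int(rng.integers(len(n.children)))]
    parent = n.parent
    n.remove(child)
    parent.remove(sib)
    n.append(sib)
    parent.append(child)
    return True


def simulate_gene_family(
    species_tree: TreeNode,
    config: SimulationConfig,
    family_id: str = "F1",
    rng: np.random.Generator | None = None,
) -> tuple[TreeNode, list[EventRecord], bool]:
    """Simulate one gene family; resimulates until the tree has >= 3 sampled
    leaves and contains a copy of the seed species.

    Returns ``(gene_tree, planted_events, was_perturbed, n_retries)``; the
    retry count is the number of attempts discarded before a usable family
    emerged.  The tree's leaves
    are named ``<family>g<k>_<species>`` and carry branch lengths in the
    species tree's time units.  The seed copy is chosen uniformly among the
    seed species' surviving copies and exposed through the caller
    (:func:`simulate_phylome` records it).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    seed_sp = config.seed_species or next(species_tree.tips()).name
    for attempt in range(_MAX_RETRIES):
        sim = _FamilySimulator(species_tree, config, family_id, rng)
        tree = sim.run()
        if tree is None or tree.count(tips=True) < 3:
            continue
        if not any(t.name.endswith(f"_{seed_sp}") for t in tree.tips()):
            continue
        perturbed = False
        if config.topology_error_p > 0 and rng.random() < config.topology_error_p:
            perturbed = _random_nni(tree, rng)
        return tree, sim.events, perturbed, attempt
    raise RuntimeError(
        f"family simulation failed {_MAX_RETRIES} times; "
        "lower loss_rate or raise sampling_prob"
    )


def simulate_alignment(
    tree: TreeNode,
    length: int,
    model: SubstModel | str = "LG",
    alpha: float | None = 1.0,
    p_inv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Evolve a gapless protein alignment down ``tree``.

    The root sequence is drawn from the model's stationary frequencies and
    evolved with transition probabilities :math:`e^{Qt r}` where the per-site
    rate :math:`r` is 0 with probability ``p_inv`` and otherwise a continuous
    Gamma(alpha, 1/alpha) draw (uniform rates when ``alpha`` is None).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if isinstance(model, str):
        model = load_model(model)
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError("alignment simulation requires branch lengths")
    rates = np.ones(length)
    if alpha is not None and np.isfinite(alpha):
        rates = rng.gamma(alpha, 1.0 / alpha, size=length)
    if p_inv > 0:
        rates[rng.random(length) < p_inv] = 0.0
    seqs: dict[str, str] = {}
    root_states = rng.choice(20, size=length, p=model.freqs)

    def walk(node: TreeNode, states: np.ndarray) -> None:
        for child in node.children:
            new = states.copy()
            t = child.length
            if t > 0:
                for r in np.unique(rates):
                    mask = rates == r
                    if r == 0 or not mask.any():
                        continue
                    P = model.transition_matrix(t * r)
                    cum = P.cumsum(axis=1)
                    u = rng.random(int(mask.sum()))
                    sub = states[mask]
                    new[mask] = np.minimum(
                        (u[:, None] > cum[sub]).sum(axis=1), 19
                    )
            if child.children:
                walk(child, new)
            else:
                seqs[child.name] = "".join(AMINO_ACIDS[s] for s in new)
        return None

    if tree.children:
        walk(tree, root_states)
    else:
        seqs[tree.name] = "".join(AMINO_ACIDS[s] for s in root_states)
    return seqs


def simulate_phylome(config: SimulationConfig):
    """Simulate a full phylome: species tree, gene trees, and ground truth.

    Returns ``(phylome, truth)`` where the phylome maps each family's seed
    sequence id to its gene tree (see :class:`phylomekit.phylome.Phylome`).
    """
    from .phylome import Phylome

    species_tree = simulate_species_tree(config)
    seed_sp = config.seed_species or next(species_tree.tips()).name
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xFA]))
    trees: dict[str, TreeNode] = {}
    truth_trees: dict[str, TreeNode] = {}
    events: list[EventRecord] = []
    seed_ids: dict[str, str] = {}
    perturbed: set[str] = set()
    n_resim = 0
    for i in range(1, config.n_families + 1):
        fam = f"F{i:04d}"
        tree, fam_events, was_perturbed, retries = simulate_gene_family(
            species_tree, config, family_id=fam, rng=rng
        )
        n_resim += retries
        seed_copies = sorted(
            t.name for t in tree.tips() if t.name.endswith(f"_{seed_sp}")
        )
        seed_id = seed_copies[int(rng.integers(len(seed_copies)))]
        seed_ids[fam] = seed_id
        trees[seed_id] = tree
        truth_trees[fam] = tree
        events.extend(fam_events)
        if was_perturbed:
            perturbed.add(fam)
    truth = TruthSet(
        species_tree=species_tree,
        gene_trees=truth_trees,
        events=events,
        seed_ids=seed_ids,
        perturbed=perturbed,
        n_resimulated=n_resim,
    )
    phylome = Phylome(
        trees=trees,
        provenance={sid: "primary" for sid in trees},
        name="simulated",
    )
    return phylome, truth
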