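"""Topology hypothesis testing from per-site log-likelihoods.

Given a matrix of per-site log-likelihoods (rows = candidate topologies,
columns = alignment sites), implements the RELL bootstrap (resampling
estimated log-likelihoods, no re-optimization), the Kishino–Hasegawa and
Shimodaira–Hasegawa tests, and the Approximately Unbiased (AU) test.  The AU
test fits the multiscale bootstrap proportions BP(r) at scales r to
``1 - Phi(d*sqrt(r) + c/sqrt(r))`` by weighted least squares and reports
``p = 1 - Phi(d - c)``, with the signed distance ``d`` and curvature ``c`` of
the region boundary.

Constraint topologies — a single resolved split (a focal taxon joined to a
named sister group) on an otherwise unresolved star — can be built and then
resolved by constrained neighbor joining before likelihood scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import norm
from skbio import DistanceMatrix, TreeNode

from .likelihood import nj_tree

__all__ = [
    "TopoTestResult",
    "build_constrained_topologies",
    "resolve_polytomies_nj",
    "rell_bootstrap",
    "topology_tests",
    "DEFAULT_AU_SCALES",
]

DEFAULT_AU_SCALES = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))


def build_constrained_topologies(
    species: Sequence[str],
    focal_clade_assignments: Sequence[tuple[str, Sequence[str]]],
) -> list[TreeNode]:
    """Constraint trees with a single resolved split each.

    Each assignment ``(focal, group)`` places the focal taxon as sister to
    the named group; everything else stays in a root polytomy.  An
    assignment that groups the focal taxon with every other species carries
    no information and is rejected.
    """
    species = list(species)
    out = []
    for focal, group in focal_clade_assignments:
        if focal not in species:
            raise ValueError(f"focal taxon {focal!r} not among species")
        group = list(group)
        unknown = set(group) - set(species)
        if unknown:
            raise ValueError(f"unknown group members: {sorted(unknown)}")
        rest = [s for s in species if s != focal and s not in group]
        if not rest:
            raise ValueError(
                f"assignment for {focal!r} groups it with every other taxon; "
                "uninformative constraint"
            )
        root = TreeNode()
        for s in rest:
            root.append(TreeNode(name=s))
        clade = TreeNode()
        clade.append(TreeNode(name=focal))
        if len(group) == 1:
            clade.append(TreeNode(name=group[0]))
        else:
            g = TreeNode()
            for s in group:
                g.append(TreeNode(name=s))
            clade.append(g)
        root.append(clade)
        out.append(root)
    return out


def resolve_polytomies_nj(
    tree: TreeNode, distances: DistanceMatrix
) -> TreeNode:
    """Resolve every polytomy by neighbor joining on its child clades.

    Distances between child clades are average pairwise leaf distances; the
    NJ topology over the clades replaces the polytomy (branch lengths of
    introduced nodes left unset).  The constraint's resolved groupings are
    preserved.
    """
    tree = tree.copy()
    ids = list(distances.ids)
    pos = {name: i for i, name in enumerate(ids)}
    data = distances.data

    def clade_leaves(node: TreeNode) -> list[str]:
        return [t.name for t in node.tips(include_self=True)]

    for node in list(tree.postorder(include_self=True)):
        while len(node.children) > 2:
            kids = list(node.children)
            k = len(kids)
            d = np.zeros((k, k))
            for i in range(k):
                li = [pos[x] for x in clade_leaves(kids[i])]
                for j in range(i + 1, k):
                    lj = [pos[x] for x in clade_leaves(kids[j])]
                    d[i, j] = d[j, i] = float(
                        np.mean([data[a, b] for a in li for b in lj])
                    )
            # NJ join criterion on the clade distance matrix: pick the pair
            # minimizing the Q statistic and join it, then iterate
            tot = d.sum(axis=1)
            best, best_q = None, np.inf
            for i in range(k):
                for j in range(i + 1, k):
                    q = (k - 2) * d[i, j] - tot[i] - tot[j]
                    if q < best_q - 1e-12:
                        best_q, best = q, (i, j)
            i, j = best
            a, b = kids[i], kids[j]
            node.remove(a)
            node.remove(b)
            joint = TreeNode()
            joint.extend([a, b])
            node.append(joint)
    return tree


def rell_bootstrap(
    sitelnl: np.ndarray,
    n_rep: int,
    seed: int | np.random.Generator = 0,
    scale: float = 1.0,
) -> np.ndarray:
    """RELL replicate totals: resample columns with replacement and sum.

    Returns an ``(n_rep, n_topologies)`` array.  ``scale`` multiplies the
    resample size (multiscale bootstrap); totals are raw sums over the
    resampled columns (not rescaled).
    """
    sitelnl = np.asarray(sitelnl, dtype=float)
    if sitelnl.ndim != 2 or sitelnl.size == 0:
        raise ValueError("site lnL matrix must be non-empty and 2-D")
    if n_rep < 1:
        raise ValueError("need at least one replicate")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    ntopo, nsites = sitelnl.shape
    m = max(1, int(round(scale * nsites)))
    out = np.empty((n_rep, ntopo))
    # chunk to bound memory at large n_rep * m
    chunk = max(1, int(5e7 // max(m, 1)))
    for lo in range(0, n_rep, chunk):
        hi = min(n_rep, lo + chunk)
        idx = rng.integers(0, nsites, size=(hi - lo, m))
        out[lo:hi] = sitelnl[:, idx].sum(axis=2).T
    return out


@dataclass
class TopoTestResult:
    """Per-topology test summary plus AU fitting diagnostics."""

    table: pd.DataFrame
    bp: dict[int, dict[float, float]] = field(default_factory=dict)
    au_params: dict[int, tuple[float, float]] = field(default_factory=dict)
    flags: dict[int, str] = field(default_factory=dict)

    def p_values(self, kind: str) -> np.ndarray:
        return self.table[kind].to_numpy()


def _fit_au(scales: np.ndarray, bp: np.ndarray, n_rep: int):
    """Weighted LS fit of BP(r) = 1 - Phi(d*sqrt(r) + c/sqrt(r)).

    Returns (d, c) or None when fewer than two scales are informative.
    """
    ok = (bp > 0.0) & (bp < 1.0)
    if ok.sum() < 2:
        return None
    r = scales[ok]
    p = bp[ok]
    z = norm.ppf(1.0 - p)  # = d*sqrt(r) + c/sqrt(r)
    X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)

    def resid(params):
        d, c = params
        pred = 1.0 - norm.cdf(d * np.sqrt(r) + c / np.sqrt(r))
        var = np.maximum(p * (1.0 - p), 1e-10) / n_rep
        return (p - pred) / np.sqrt(var)

    sol = least_squares(resid, beta, method="lm", xtol=1e-14, ftol=1e-14)
    return float(sol.x[0]), float(sol.x[1])


def topology_tests(
    sitelnl: np.ndarray,
    n_rep: int = 10_000,
    au_scales: Sequence[float] = DEFAULT_AU_SCALES,
    seed: int = 0,
) -> TopoTestResult:
    """KH, SH and AU tests for every topology in a site-lnL matrix.

    KH (against the ML topology, replicate-mean centering): p is the
    proportion of centered replicate score differences at least as large as
    the observed one.  SH centers every topology at its own replicate mean
    and compares against the max; it is conservative, so SH p >= KH p.
    AU: per scale r, ``round(r*S)`` sites are resampled ``n_rep`` times; the
    proportion of replicates in which a topology is the best fits the
    multiscale model; p = 1 - Phi(d - c).  Degenerate topologies (BP 0 or 1
    at every scale) get p = 0 / p = 1 and a flag.  Per-scale seed streams
    keep results stable when scales are added or removed.
    """
    sitelnl = np.asarray(sitelnl, dtype=float)
    if sitelnl.ndim != 2 or sitelnl.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two topologies")
    ntopo, nsites = sitelnl.shape
    totals = sitelnl.sum(axis=1)
    best = int(np.argmax(totals))
    delta = totals[best] - totals

    root_ss = np.random.SeedSequence(abs(int(seed)))
    kh_sh_rng = np.random.default_rng(root_ss.spawn(1)[0])
    reps = rell_bootstrap(sitelnl, n_rep, seed=kh_sh_rng)  # (B, ntopo)
    centered = reps - reps.mean(axis=0, keepdims=True)
    kh = np.empty(ntopo)
    sh = np.empty(ntopo)
    for i in range(ntopo):
        d_kh = centered[:, best] - centered[:, i]
        kh[i] = float(np.mean(d_kh >= delta[i]))
        d_sh = centered.max(axis=1) - centered[:, i]
        sh[i] = float(np.mean(d_sh >= delta[i]))

    scales = np.asarray(sorted(au_scales), dtype=float)
    bp = np.zeros((len(scales), ntopo))
    scale_seeds = root_ss.spawn(len(scales) + 1)[1:]
    for si, r in enumerate(scales):
        rng = np.random.default_rng(scale_seeds[si])
        rep = rell_bootstrap(sitelnl, n_rep, seed=rng, scale=float(r))
        winners = np.argmax(rep, axis=1)
        for i in range(ntopo):
            bp[si, i] = np.mean(winners == i)

    au = np.full(ntopo, np.nan)
    au_params: dict[int, tuple[float, float]] = {}
    flags: dict[int, str] = {}
    bp_out: dict[int, dict[float, float]] = {}
    for i in range(ntopo):
        bp_out[i] = {float(r): float(bp[si, i]) for si, r in enumerate(scales)}
        if np.all(bp[:, i] == 0.0):
            au[i] = 0.0
            flags[i] = "degenerate:never-best"
            continue
        if np.all(bp[:, i] == 1.0):
            au[i] = 1.0
            flags[i] = "degenerate:always-best"
            continue
        fit = _fit_au(scales, bp[:, i], n_rep)
        if fit is None:
            flags[i] = "au-unavailable:<2 informative scales"
            continue
        d, c = fit
        au_params[i] = (d, c)
        au[i] = float(1.0 - norm.cdf(d - c))
    table = pd.DataFrame(
        {
            "topology": np.arange(ntopo),
            "lnL": totals,
            "delta_lnL": delta,
            "kh_p": kh,
            "sh_p": sh,
            "au_p": au,
        }
    )
    return TopoTestResult(table=table, bp=bp_out, au_params=au_params, flags=flags)


def write_result_table(result: TopoTestResult, path) -> None:
    tab = result.table.copy()
    tab["flags"] = [result.flags.get(i, "") for i in tab["topology"]]
    tab.to_csv(path, sep="\t", index=False)
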