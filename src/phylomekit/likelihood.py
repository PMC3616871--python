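"""Phylogenetic likelihood engine for protein alignments.

Implements the standard machinery used during phylome tree building:
empirical amino-acid replacement models (JTT, WAG, MtREV, LG, Blosum62,
DCMut) plus a Poisson model, discrete-gamma (mean-of-bin categories) and
invariant-sites rate heterogeneity, Felsenstein pruning likelihoods with
per-site export, neighbor-joining topology estimation, coordinate-wise
branch-length optimization, and AIC model selection.

The rate matrix :math:`Q` is built from symmetric exchangeabilities
:math:`s_{ij}` and stationary frequencies :math:`\\pi_j`
(:math:`q_{ij}=s_{ij}\\pi_j`) and normalized to one expected substitution
per site at stationarity; branch lengths are therefore expected
substitutions per site.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc, logsumexp
from scipy.stats import gamma as gamma_dist
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .seqio import AMINO_ACIDS, MISSING_CODE, check_rectangular, encode_alignment

EMPIRICAL_MODELS = ("JTT", "WAG", "MtREV", "LG", "Blosum62", "DCMut")
ALL_MODELS = EMPIRICAL_MODELS + ("Poisson",)

__all__ = [
    "SubstModel",
    "load_model",
    "gamma_category_rates",
    "nj_tree",
    "p_distance_matrix",
    "poisson_distance_matrix",
    "site_log_likelihoods",
    "total_log_likelihood",
    "optimize_branch_lengths",
    "select_model_aic",
    "write_site_lnl_matrix",
    "read_site_lnl_matrix",
    "EMPIRICAL_MODELS",
    "ALL_MODELS",
]


def _load_exchangeabilities(name: str) -> tuple[np.ndarray, np.ndarray]:
    """Read a lower-triangular exchangeability file shipped with the package."""
    ref = importlib.resources.files("phylomekit") / "data" / f"{name}.dat"
    rows: list[list[float]] = []
    order = None
    with ref.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.isalpha():
                order = line
                continue
            rows.append([float(x) for x in line.split()])
    freqs = np.array(rows.pop(), dtype=float)
    if order is None or order != AMINO_ACIDS:
        raise ValueError(f"model file {name} not in {AMINO_ACIDS} residue order")
    S = np.zeros((20, 20))
    for i, row in enumerate(rows, start=1):
        S[i, : len(row)] = row
    S = S + S.T
    return S, freqs / freqs.sum()


@dataclass(frozen=True, eq=False)
class SubstModel:
    """An amino-acid substitution model with among-site rate heterogeneity.

    ``alpha=None`` means uniform rates (equivalently a single category);
    ``p_inv`` is the proportion of invariant sites.
    """

    name: str
    exchangeabilities: np.ndarray
    freqs: np.ndarray
    alpha: float | None = None
    ncat: int = 4
    p_inv: float = 0.0
    _eig: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.alpha is not None and not (self.alpha > 0):
            raise ValueError("gamma shape alpha must be > 0")
        if not (0.0 <= self.p_inv < 1.0):
            raise ValueError("p_inv must be in [0, 1)")
        object.__setattr__(self, "_eig", self._decompose())

    def _decompose(self):
        S, pi = self.exchangeabilities, self.freqs
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -float(np.dot(pi, np.diag(Q)))
        Q = Q / scale
        # reversible Q: symmetrize with pi^1/2 for a stable eigendecomposition
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        w, V = np.linalg.eigh((B + B.T) / 2.0)
        left = V.T * sq[None, :]        # V^T D
        right = (V.T / sq[None, :]).T   # D^-1 V
        return w, right, left, Q

    @property
    def Q(self) -> np.ndarray:
        """Normalized instantaneous rate matrix (rows sum to zero)."""
        return self._eig[3]

    def transition_matrix(self, t: float) -> np.ndarray:
        """:math:`P(t)=e^{Qt}` for branch length ``t`` (subst./site)."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        w, right, left, _ = self._eig
        P = (right * np.exp(w * t)[None, :]) @ left
        return np.clip(P, 0.0, None)

    def category_rates(self) -> np.ndarray:
        if self.alpha is None or math.isinf(self.alpha):
            return np.ones(1)
        return gamma_category_rates(self.alpha, self.ncat)

    def with_rates(self, alpha: float | None = None, p_inv: float | None = None) -> "SubstModel":
        kw = {}
        if alpha is not None:
            kw["alpha"] = alpha
        if p_inv is not None:
            kw["p_inv"] = p_inv
        return replace(self, _eig=None, **kw)


def load_model(
    name: str, alpha: float | None = None, ncat: int = 4, p_inv: float = 0.0
) -> SubstModel:
    """Load a shipped empirical model (or the Poisson model) by name."""
    if name == "Poisson":
        S = np.ones((20, 20))
        np.fill_diagonal(S, 0.0)
        freqs = np.full(20, 1 / 20)
    elif name in EMPIRICAL_MODELS:
        S, freqs = _load_exchangeabilities(name)
    else:
        raise ValueError(f"unknown model {name!r}; choose from {ALL_MODELS}")
    return SubstModel(name, S, freqs, alpha=alpha, ncat=ncat, p_inv=p_inv)


def gamma_category_rates(alpha: float, k: int = 4) -> np.ndarray:
    """Mean-of-bin discrete gamma category rates (mean exactly 1)."""
    if k < 1:
        raise ValueError("need at least one category")
    bounds = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1.0 / alpha)
    upper = gammainc(alpha + 1.0, bounds[1:] * alpha)
    lower = gammainc(alpha + 1.0, bounds[:-1] * alpha)
    rates = k * (upper - lower)
    return rates / rates.mean()


# ---------------------------------------------------------------------------
# distances and neighbor joining


def _pairwise_counts(codes: np.ndarray):
    n = codes.shape[0]
    diff = np.zeros((n, n))
    comp = np.zeros((n, n))
    valid = codes != MISSING_CODE
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            c = int(both.sum())
            d = int((codes[i][both] != codes[j][both]).sum())
            comp[i, j] = comp[j, i] = c
            diff[i, j] = diff[j, i] = d
    return diff, comp


def p_distance_matrix(aln: Mapping[str, str]) -> DistanceMatrix:
    """Observed proportion of differing sites (gaps pairwise-deleted)."""
    names, codes = encode_alignment(aln)
    diff, comp = _pairwise_counts(codes)
    with np.errstate(invalid="ignore"):
        p = np.where(comp > 0, diff / np.maximum(comp, 1), 0.0)
    np.fill_diagonal(p, 0.0)
    return DistanceMatrix(p, ids=names)


def poisson_distance_matrix(aln: Mapping[str, str]) -> DistanceMatrix:
    """Poisson-model-corrected distance ``-(19/20) ln(1 - (20/19) p)``.

    Saturated pairs (p >= 19/20) are clamped just below saturation.
    """
    pm = p_distance_matrix(aln)
    p = np.minimum(pm.data, 19 / 20 - 1e-9)
    d = -(19 / 20) * np.log1p(-(20 / 19) * p)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=list(pm.ids))


def nj_tree(distances: DistanceMatrix) -> TreeNode:
    """Neighbor joining; negative branch lengths are clamped to zero."""
    arr = distances.data
    if not np.allclose(arr, arr.T, atol=1e-9):
        raise ValueError("distance matrix is not symmetric (tolerance 1e-9)")
    if distances.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tree = _skbio_nj(distances)
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# pruning engine


class PruningEngine:
    """Felsenstein pruning over one alignment/topology pair.

    Compresses columns to unique patterns and exposes the total and per-site
    log-likelihood as a function of branch lengths and rate parameters, which
    is what the optimizers cycle over.
    """

    def __init__(self, aln: Mapping[str, str], tree: TreeNode):
        names, codes = encode_alignment(aln)
        row = {n: i for i, n in enumerate(names)}
        tips = {t.name for t in tree.tips()}
        if tips != set(names):
            missing = tips ^ set(names)
            raise ValueError(f"tree/alignment leaf mismatch: {sorted(missing)}")
        self.tree = tree.copy()
        self.nodes = list(self.tree.postorder(include_self=True))
        self.node_index = {id(n): i for i, n in enumerate(self.nodes)}
        self.leaf_rows = {
            self.node_index[id(n)]: row[n.name] for n in self.tree.tips()
        }
        patterns, inverse, counts = np.unique(
            codes.T, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = patterns  # (npat, ntaxa)
        self.pattern_of_site = inverse
        self.weights = counts.astype(float)
        self.codes_rows = codes
        # invariant-site compatibility: the set of states consistent with all
        # non-missing residues in the pattern (0 or 1 states, or all 20)
        npat = patterns.shape[0]
        self.const_lik = np.zeros(npat)
        self._const_state = np.full(npat, -1)
        for p in range(npat):
            obs = set(int(c) for c in patterns[p] if c != MISSING_CODE)
            if len(obs) == 0:
                self.const_lik[p] = 1.0
            elif len(obs) == 1:
                self._const_state[p] = obs.pop()

    def branch_lengths(self) -> np.ndarray:
        return np.array(
            [n.length if n.length is not None else 0.0 for n in self.nodes[:-1]]
        )

    def set_branch_lengths(self, bl: Sequence[float]) -> None:
        for n, t in zip(self.nodes[:-1], bl):
            n.length = float(t)

    def _per_pattern_loglik(self, model: SubstModel) -> np.ndarray:
        rates = model.category_rates()
        k = len(rates)
        bl = self.branch_lengths()
        npat = self.patterns.shape[0]
        logliks = np.empty((k, npat))
        pi = model.freqs
        for ci, r in enumerate(rates):
            partial = [None] * len(self.nodes)
            scaler = np.zeros(npat)
            for i, node in enumerate(self.nodes):
                if not node.children:
                    lv = np.zeros((npat, 20))
                    col = self.patterns[:, self.leaf_rows[i]]
                    miss = col == MISSING_CODE
                    lv[miss, :] = 1.0
                    obs = ~miss
                    lv[np.nonzero(obs)[0], col[obs].astype(int)] = 1.0
                    partial[i] = lv
                    continue
                acc = np.ones((npat, 20))
                for child in node.children:
                    j = self.node_index[id(child)]
                    P = model.transition_matrix(r * bl[j])
                    acc *= partial[j] @ P.T
                mx = acc.max(axis=1)
                mx[mx == 0.0] = 1.0
                acc /= mx[:, None]
                scaler += np.log(mx)
                partial[i] = acc
            root_l = partial[-1] @ pi
            logliks[ci] = np.log(np.maximum(root_l, 1e-300)) + scaler
        log_mix = logsumexp(logliks - math.log(k), axis=0)
        p_inv = model.p_inv
        if p_inv > 0.0:
            const = np.where(
                self._const_state >= 0,
                pi[np.maximum(self._const_state, 0)],
                self.const_lik,
            )
            with np.errstate(divide="ignore"):
                log_const = np.log(const * p_inv)
            log_mix = np.logaddexp(log_const, math.log1p(-p_inv) + log_mix)
        return log_mix

    def site_log_likelihoods(self, model: SubstModel) -> np.ndarray:
        return self._per_pattern_loglik(model)[self.pattern_of_site]

    def total_log_likelihood(self, model: SubstModel) -> float:
        return float(self._per_pattern_loglik(model) @ self.weights)


def site_log_likelihoods(
    aln: Mapping[str, str], tree: TreeNode, model: SubstModel
) -> np.ndarray:
    """Per-column natural-log likelihoods under the pruning algorithm."""
    return PruningEngine(aln, tree).site_log_likelihoods(model)


def total_log_likelihood(
    aln: Mapping[str, str], tree: TreeNode, model: SubstModel
) -> float:
    return PruningEngine(aln, tree).total_log_likelihood(model)


_MAX_BL = 20.0


def optimize_branch_lengths(
    tree: TreeNode,
    aln: Mapping[str, str],
    model: SubstModel,
    tol: float = 1e-6,
    max_cycles: int = 100,
) -> TreeNode:
    """Coordinate-wise Brent optimization of every branch length.

    Cycles over branches until the total log-likelihood improves by less than
    ``tol``; non-convergence after ``max_cycles`` returns the current state.
    """
    engine = PruningEngine(aln, tree)
    _optimize_lengths_inplace(engine, model, tol=tol, max_cycles=max_cycles)
    return engine.tree


def _optimize_lengths_inplace(
    engine: PruningEngine,
    model: SubstModel,
    tol: float = 1e-6,
    max_cycles: int = 100,
    xatol: float = 1e-8,
) -> float:
    last = engine.total_log_likelihood(model)
    for _ in range(max_cycles):
        for node in engine.nodes[:-1]:
            def neg(t: float, node=node) -> float:
                node.length = float(t)
                return -engine.total_log_likelihood(model)

            res = minimize_scalar(
                neg, bounds=(0.0, _MAX_BL), method="bounded",
                options={"xatol": xatol},
            )
            node.length = float(res.x)
        now = engine.total_log_likelihood(model)
        if now - last < tol:
            return now
        last = now
    return last


def _optimize_rate_params(
    engine: PruningEngine, model: SubstModel, est_alpha: bool, est_pinv: bool
) -> SubstModel:
    if est_alpha:
        def neg_a(loga: float) -> float:
            return -engine.total_log_likelihood(
                model.with_rates(alpha=math.exp(loga))
            )

        res = minimize_scalar(
            neg_a, bounds=(math.log(0.02), math.log(100.0)), method="bounded",
            options={"xatol": 1e-4},
        )
        model = model.with_rates(alpha=math.exp(res.x))
    if est_pinv:
        def neg_p(p: float) -> float:
            return -engine.total_log_likelihood(model.with_rates(p_inv=p))

        res = minimize_scalar(
            neg_p, bounds=(0.0, 0.99), method="bounded", options={"xatol": 1e-4}
        )
        model = model.with_rates(p_inv=float(res.x))
    return model


def fit_model(
    aln: Mapping[str, str],
    topology: TreeNode,
    model: SubstModel,
    estimate_alpha: bool = True,
    estimate_pinv: bool = True,
    outer_rounds: int = 2,
    bl_cycles: int = 3,
    tol: float = 1e-4,
) -> tuple[SubstModel, TreeNode, float]:
    """Alternate branch-length and rate-parameter optimization.

    Returns the fitted model (alpha, p_inv updated), the tree with optimized
    lengths, and the final log-likelihood.
    """
    engine = PruningEngine(aln, topology)
    lnl = -np.inf
    for _ in range(outer_rounds):
        lnl = _optimize_lengths_inplace(
            engine, model, tol=tol, max_cycles=bl_cycles, xatol=1e-4
        )
        model = _optimize_rate_params(engine, model, estimate_alpha, estimate_pinv)
    lnl = engine.total_log_likelihood(model)
    return model, engine.tree, lnl


def select_model_aic(
    aln: Mapping[str, str],
    topology: TreeNode,
    candidate_models: Iterable[str | SubstModel] = EMPIRICAL_MODELS,
):
    """AIC model selection on a fixed topology.

    Each candidate gets its branch lengths, gamma shape and invariant fraction
    optimized; ``AIC = 2(branches + 2) - 2 lnL``.  Returns the winning fitted
    model and a table sorted by candidate order (ties broken by name order).
    """
    import pandas as pd

    candidates = list(candidate_models)
    if not candidates:
        raise ValueError("no candidate models given")
    rows = []
    fitted = {}
    n_branches = sum(1 for _ in topology.traverse(include_self=False))
    for cand in candidates:
        model = load_model(cand, alpha=1.0) if isinstance(cand, str) else cand
        model, tree, lnl = fit_model(aln, topology, model)
        k = n_branches + 2  # alpha and p_inv
        rows.append(
            {
                "model": model.name,
                "lnL": lnl,
                "params": k,
                "AIC": 2 * k - 2 * lnl,
                "alpha": model.alpha,
                "p_inv": model.p_inv,
            }
        )
        fitted[model.name] = (model, tree)
    table = pd.DataFrame(rows)
    best_name = table.sort_values(["AIC", "model"]).iloc[0]["model"]
    return fitted[best_name][0], table


# ---------------------------------------------------------------------------
# site-likelihood matrix I/O


def write_site_lnl_matrix(matrix: np.ndarray, path, names: Sequence[str] | None = None) -> None:
    """Plain per-site lnL matrix: header "ntopologies nsites", one row per
    topology (optionally name-prefixed, the RAxML-style dialect)."""
    matrix = np.asarray(matrix, dtype=float)
    with open(path, "w") as fh:
        fh.write(f" {matrix.shape[0]} {matrix.shape[1]}\n")
        for i, row in enumerate(matrix):
            prefix = f"{names[i]}\t" if names is not None else ""
            fh.write(prefix + " ".join(f"{v:.8f}" for v in row) + "\n")


def read_site_lnl_matrix(path) -> tuple[np.ndarray, list[str]]:
    """Read the plain matrix format or the RAxML per-site lnL dialect.

    Rows may start with a topology name token; names default to ``tr<i>``.
    """
    rows, names = [], []
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("expected 'ntopologies nsites' header")
        ntopo, nsites = int(header[0]), int(header[1])
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            try:
                float(parts[0])
                name = f"tr{len(rows) + 1}"
                vals = parts
            except ValueError:
                name = parts[0]
                vals = parts[1:]
            row = [float(x) for x in vals]
            if len(row) != nsites:
                raise ValueError(
                    f"row {name} has {len(row)} values, expected {nsites}"
                )
            rows.append(row)
            names.append(name)
    if len(rows) != ntopo:
        raise ValueError(f"expected {ntopo} rows, found {len(rows)}")
    return np.array(rows), names
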