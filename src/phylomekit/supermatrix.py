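"""Partitioned supermatrix construction and compositional-bias analysis.

Strictly single-copy orthologous families (exactly one sequence per required
species, all cross-species pairs one-to-one) are selected from labeled
phylome trees, trimmed column-wise (gap-score and optional entropy filters),
assigned a best-fit replacement model per family, and concatenated into a
model-partitioned supermatrix.  Amino-acid composition heterogeneity across
species — a classical source of tree artifacts — is summarized by PCA of
per-species residue frequency vectors plus per-species chi-square
homogeneity statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .seqio import AMINO_ACIDS, check_rectangular
from .treecore import make_species_getter

__all__ = [
    "Partition",
    "CompositionProfile",
    "select_one_to_one_families",
    "trim_alignment",
    "concatenate",
    "composition_pca",
    "write_partition_file",
]


@dataclass(frozen=True)
class Partition:
    """One model block of the supermatrix; 1-based inclusive columns."""

    name: str
    model: str
    start: int
    end: int
    families: tuple[str, ...]

    @property
    def n_columns(self) -> int:
        return self.end - self.start + 1


def select_one_to_one_families(
    labeled_trees: Mapping[str, TreeNode],
    required_species: Iterable[str],
    species_map: Mapping[str, str] | None = None,
) -> list[str]:
    """Families with strict one-to-one orthology across all required species.

    A family qualifies iff its tree contains exactly one sequence of every
    required species and the MRCA of every cross-species pair of those
    sequences is a speciation node.  Trees must be event-labeled.  The result
    is sorted by family id (order-independent).
    """
    required = set(required_species)
    if not required:
        raise ValueError("required_species must be non-empty")
    getter = make_species_getter(species_map)
    chosen = []
    for fam, tree in labeled_trees.items():
        per_species: dict[str, int] = {}
        for tip in tree.tips():
            sp = getter(tip.name)
            if sp in required:
                per_species[sp] = per_species.get(sp, 0) + 1
        if set(per_species) != required or any(c != 1 for c in per_species.values()):
            continue
        # any duplication on the path between two required-species leaves
        # breaks one-to-one-ness; check via MRCA labels
        tips = [t for t in tree.tips() if getter(t.name) in required]
        ok = True
        for i in range(len(tips)):
            for j in range(i + 1, len(tips)):
                mrca = tree.lowest_common_ancestor([tips[i], tips[j]])
                if getattr(mrca, "event", None) != "speciation":
                    ok = False
                    break
            if not ok:
                break
        if ok:
            chosen.append(fam)
    return sorted(chosen)


def trim_alignment(
    aln: Mapping[str, str],
    gap_score_cutoff: float = 0.1,
    entropy_cutoff: float | None = None,
) -> tuple[dict[str, str], list[int]]:
    """Column filtering by gap score and (optionally) Shannon entropy.

    A column is kept iff the fraction of non-gap residues is >= the gap-score
    cutoff and, when an entropy cutoff is given, its Shannon entropy (bits,
    over non-gap residues) is <= that cutoff.  Returns the trimmed alignment
    and the kept columns' original 1-based indices.  Idempotent by
    construction.  Removing every column is an error.
    """
    ncol = check_rectangular(aln)
    names = list(aln)
    nseq = len(names)
    if nseq == 0 or ncol == 0:
        raise ValueError("empty alignment")
    kept: list[int] = []
    for j in range(ncol):
        column = [aln[n][j] for n in names]
        residues = [c for c in column if c in AMINO_ACIDS]
        if len(residues) / nseq < gap_score_cutoff:
            continue
        if entropy_cutoff is not None and residues:
            counts: dict[str, int] = {}
            for c in residues:
                counts[c] = counts.get(c, 0) + 1
            tot = len(residues)
            h = -sum(
                (k / tot) * math.log2(k / tot) for k in counts.values()
            )
            if h > entropy_cutoff:
                continue
        kept.append(j + 1)
    if not kept:
        raise ValueError(
            "trimming removed every column; relax gap_score_cutoff/entropy_cutoff"
        )
    trimmed = {
        n: "".join(aln[n][j - 1] for j in kept) for n in names
    }
    return trimmed, kept


def concatenate(
    families: Sequence[tuple[str, Mapping[str, str], str]],
    species_order: Sequence[str],
    species_map: Mapping[str, str] | None = None,
) -> tuple[dict[str, str], list[Partition]]:
    """Concatenate one-to-one family alignments into a partitioned matrix.

    ``families`` is a list of (family_id, alignment, model_name); alignment
    rows may be keyed by species code directly or by sequence id following
    the leaf-naming convention.  Families are grouped into blocks by model
    (blocks ordered by model name, families in stable input order within a
    block); rows follow ``species_order``.  A family missing a species is an
    error.
    """
    species = list(species_order)
    getter = make_species_getter(species_map)
    per_family_rows: dict[str, dict[str, str]] = {}
    lengths: dict[str, int] = {}
    for fam, aln, _model in families:
        ncol = check_rectangular(aln)
        lengths[fam] = ncol
        if set(aln) >= set(species):
            rows = {sp: aln[sp] for sp in species}
        else:
            rows = {}
            for key, seq in aln.items():
                sp = getter(key)
                if sp in rows:
                    raise ValueError(
                        f"family {fam}: multiple sequences for species {sp}"
                    )
                rows[sp] = seq
            missing = set(species) - set(rows)
            if missing:
                raise ValueError(
                    f"family {fam} missing species {sorted(missing)}"
                )
        per_family_rows[fam] = rows
    by_model: dict[str, list[str]] = {}
    for fam, _aln, model in families:
        by_model.setdefault(model, []).append(fam)
    matrix = {sp: [] for sp in species}
    partitions: list[Partition] = []
    cursor = 1
    for model in sorted(by_model):
        fams = by_model[model]
        width = sum(lengths[f] for f in fams)
        for f in fams:
            for sp in species:
                matrix[sp].append(per_family_rows[f][sp])
        partitions.append(
            Partition(
                name=model,
                model=model,
                start=cursor,
                end=cursor + width - 1,
                families=tuple(fams),
            )
        )
        cursor += width
    return {sp: "".join(parts) for sp, parts in matrix.items()}, partitions


def write_partition_file(partitions: Sequence[Partition], path) -> None:
    """Standard partition lines: ``MODEL, name = start-end`` (1-based)."""
    with open(path, "w") as fh:
        for p in partitions:
            fh.write(f"{p.model}, {p.name} = {p.start}-{p.end}\n")


@dataclass
class CompositionProfile:
    """Per-species amino-acid composition and its principal components."""

    species: list[str]
    frequencies: np.ndarray        # (n_species, 20), rows sum to 1
    coordinates: np.ndarray        # (n_species, n_components)
    explained_variance: np.ndarray
    chi2: pd.DataFrame             # per-species homogeneity vs pooled

    @property
    def total_variance(self) -> float:
        return float(self.explained_variance.sum())


def composition_pca(matrix: Mapping[str, str]) -> CompositionProfile:
    """PCA of per-species amino-acid frequency vectors.

    Frequencies are computed over non-gap sites, centered across species,
    and eigendecomposed (covariance with 1/(n-1) normalization).  A
    per-species chi-square statistic against the pooled composition (df 19)
    flags compositionally deviant taxa.
    """
    species = list(matrix)
    if len(species) < 3:
        raise ValueError("composition PCA needs at least 3 species")
    counts = np.zeros((len(species), 20))
    for i, sp in enumerate(species):
        for ch in matrix[sp]:
            j = AMINO_ACIDS.find(ch)
            if j >= 0:
                counts[i, j] += 1
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        empty = [sp for sp, t in zip(species, totals) if t == 0]
        raise ValueError(f"species with no residues: {empty}")
    freqs = counts / totals[:, None]
    centered = freqs - freqs.mean(axis=0, keepdims=True)
    cov = centered.T @ centered / (len(species) - 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = np.maximum(w[order], 0.0), v[:, order]
    coords = centered @ v
    pooled = counts.sum(axis=0) / counts.sum()
    from scipy.stats import chi2 as chi2_dist

    stats_rows = []
    for i, sp in enumerate(species):
        expected = pooled * totals[i]
        mask = expected > 0
        stat = float(((counts[i, mask] - expected[mask]) ** 2 / expected[mask]).sum())
        df = int(mask.sum()) - 1
        stats_rows.append(
            {
                "species": sp,
                "chi2": stat,
                "df": df,
                "p": float(chi2_dist.sf(stat, df)),
            }
        )
    return CompositionProfile(
        species=species,
        frequencies=freqs,
        coordinates=coords,
        explained_variance=w,
        chi2=pd.DataFrame(stats_rows),
    )
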