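"""Phylome bookkeeping: homology-hit filtering, phylome combination, and
coverage diagnostics.

A *phylome* is the complete collection of gene trees for every gene of a
seed transcriptome/species; each tree is indexed by its seed sequence id.
A combined phylome takes a primary phylome as the main source of trees and
falls back, in order, to other phylomes for transcripts the primary does not
represent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats
from skbio import TreeNode

__all__ = [
    "HitRecord",
    "Phylome",
    "CombinedPhylome",
    "filter_homolog_hits",
    "read_hit_table",
    "combine_phylomes",
    "coverage_report",
]


@dataclass(frozen=True)
class HitRecord:
    """One tabular homology hit (single continuous aligned region)."""

    query: str
    subject: str
    evalue: float
    qstart: int  # 1-based inclusive
    qend: int
    qlen: int

    def __post_init__(self):
        if not (1 <= self.qstart <= self.qend <= self.qlen):
            raise ValueError(
                f"invalid aligned interval [{self.qstart}, {self.qend}] "
                f"for query {self.query!r} of length {self.qlen}"
            )
        if self.evalue < 0:
            raise ValueError("e-value must be non-negative")

    @property
    def coverage(self) -> float:
        return (self.qend - self.qstart + 1) / self.qlen


def read_hit_table(path) -> list[HitRecord]:
    """Read a 6-column TSV: query, subject, evalue, qstart, qend, qlen."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns")
            hits.append(
                HitRecord(
                    query=parts[0], subject=parts[1], evalue=float(parts[2]),
                    qstart=int(parts[3]), qend=int(parts[4]), qlen=int(parts[5]),
                )
            )
    return hits


def filter_homolog_hits(
    hits: Iterable[HitRecord],
    evalue_max: float = 1e-5,
    min_query_coverage: float = 0.30,
    max_hits: int = 200,
) -> list[HitRecord]:
    """Select homolog candidates per query.

    Keeps hits with e-value <= ``evalue_max`` whose continuous aligned region
    is strictly longer than ``min_query_coverage`` of the query length, then
    retains per query at most ``max_hits`` by ascending e-value (ties broken
    by subject id).  Defaults implement the standard phylome-pipeline filter
    (1e-5, 30%, 200); pass ``min_query_coverage=0.15`` for the seed-genome
    preset.
    """
    by_query: dict[str, list[HitRecord]] = {}
    for h in hits:
        if h.evalue <= evalue_max and h.coverage > min_query_coverage:
            by_query.setdefault(h.query, []).append(h)
    out: list[HitRecord] = []
    for query in by_query:
        ranked = sorted(by_query[query], key=lambda h: (h.evalue, h.subject))
        out.extend(ranked[:max_hits])
    return out


@dataclass
class Phylome:
    """Seed sequence id -> gene tree, with per-tree provenance."""

    trees: dict[str, TreeNode]
    provenance: dict[str, str] = field(default_factory=dict)
    name: str = "phylome"

    def __post_init__(self):
        if not self.provenance:
            self.provenance = {sid: self.name for sid in self.trees}

    def seed_ids(self) -> set[str]:
        return set(self.trees)

    def all_leaf_ids(self) -> set[str]:
        leaves: set[str] = set()
        for tree in self.trees.values():
            leaves.update(t.name for t in tree.tips())
        return leaves

    def represents(self, transcript: str, level: str = "leaf") -> bool:
        """Whether a transcript appears in the phylome.

        ``level="leaf"`` (default): as any leaf of any tree;
        ``level="seed"``: as a seed sequence only.
        """
        if level == "seed":
            return transcript in self.trees
        return transcript in self.all_leaf_ids()


@dataclass
class CombinedPhylome:
    """Result of layering fallback phylomes under a primary one."""

    trees: dict[str, TreeNode]
    provenance: dict[str, str]
    covered: dict[str, set[str]]    # species -> covered transcript ids
    uncovered: dict[str, set[str]]  # species -> transcripts in no phylome

    def coverage_fraction(self, species: str) -> float:
        cov, unc = self.covered.get(species, set()), self.uncovered.get(species, set())
        total = len(cov) + len(unc)
        return len(cov) / total if total else 0.0


def combine_phylomes(
    primary: Phylome,
    fallbacks: Sequence[Phylome],
    targets: Mapping[str, Iterable[str]],
    representation_level: str = "leaf",
) -> CombinedPhylome:
    """Layer fallback phylomes under a primary one.

    A target transcript is attributed to the primary phylome whenever the
    primary represents it (by default as any leaf of any tree); otherwise the
    first fallback whose *seed set* contains it contributes its seed tree.
    Transcripts in neither are listed uncovered.
    """
    primary_leaves = (
        primary.all_leaf_ids() if representation_level == "leaf"
        else primary.seed_ids()
    )
    trees: dict[str, TreeNode] = {}
    provenance: dict[str, str] = {}
    covered: dict[str, set[str]] = {}
    uncovered: dict[str, set[str]] = {}
    for species, ids in targets.items():
        covered[species] = set()
        uncovered[species] = set()
        for tid in ids:
            if tid in primary_leaves:
                covered[species].add(tid)
                provenance[tid] = "primary"
                if tid in primary.trees:
                    trees[tid] = primary.trees[tid]
                continue
            for fb in fallbacks:
                if tid in fb.trees:
                    covered[species].add(tid)
                    if tid not in provenance:
                        provenance[tid] = f"fallback:{fb.name}"
                        trees[tid] = fb.trees[tid]
                    break
            else:
                uncovered[species].add(tid)
    return CombinedPhylome(
        trees=trees, provenance=provenance, covered=covered, uncovered=uncovered
    )


def coverage_report(
    phylome: Phylome | CombinedPhylome,
    targets: Mapping[str, Iterable[str]],
    ortholog_lengths: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-species coverage and homolog-count diagnostics.

    Returns one row per species: covered fraction of target transcripts and
    mean homologs per tree (leaves besides the seed).  With
    ``ortholog_lengths`` (columns: transcript, length, ortholog_length) the
    Pearson correlation between per-tree homolog count and transcript length
    relative to its reference ortholog is added (r, two-sided p); fewer than
    3 usable points flags the correlation as unavailable.
    """
    if isinstance(phylome, CombinedPhylome):
        covered_lookup = {
            sp: set(phylome.covered.get(sp, set())) for sp in targets
        }
        trees = phylome.trees
    else:
        leaves = phylome.all_leaf_ids()
        covered_lookup = {
            sp: {t for t in ids if t in leaves} for sp, ids in targets.items()
        }
        trees = phylome.trees
    homolog_counts = {
        sid: tree.count(tips=True) - 1 for sid, tree in trees.items()
    }
    rows = []
    for species, ids in targets.items():
        ids = set(ids)
        cov = covered_lookup[species] & ids
        seeds = [sid for sid in cov if sid in homolog_counts]
        mean_homologs = (
            sum(homolog_counts[s] for s in seeds) / len(seeds) if seeds else float("nan")
        )
        row = {
            "species": species,
            "n_targets": len(ids),
            "n_covered": len(cov),
            "coverage_pct": 100.0 * len(cov) / len(ids) if ids else float("nan"),
            "mean_homologs_per_tree": mean_homologs,
        }
        if ortholog_lengths is not None:
            sub = ortholog_lengths[ortholog_lengths.transcript.isin(seeds)]
            sub = sub[sub.ortholog_length > 0]
            if len(sub) >= 3:
                rel = sub.length / sub.ortholog_length
                counts = sub.transcript.map(homolog_counts)
                r, p = stats.pearsonr(counts, rel)
                row["pearson_r"], row["pearson_p"] = r, p
            else:
                row["pearson_r"], row["pearson_p"] = float("nan"), float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
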