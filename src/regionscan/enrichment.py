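"""Overlap-significance machinery.

One-tailed hypergeometric tests with probe-weighted backgrounds (gene sets
counted by the probes they own on the array, not by gene number), CpG-island
category tests, BED-interval overlap tests (DNase hot spots), and an
empirical multi-list overlap test by resampling from the background region
list.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from .model import (
    ISLAND_CATEGORIES,
    IntervalSet,
    ProbeManifest,
    Region,
    ValidationError,
)

log = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "hypergeom_p",
    "probe_weighted_gene_enrichment",
    "category_enrichment",
    "interval_overlap_count",
    "dnase_enrichment",
    "multi_list_overlap_p",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset

    def __post_init__(self):
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        object.__setattr__(
            self, "genes", frozenset(str(g).strip().upper() for g in self.genes)
        )


@dataclass(frozen=True)
class EnrichmentResult:
    list_name: str
    set_name: str
    overlap_k: int
    draw_n: int
    success_K: int
    background_N: int
    p: float
    extra: tuple = ()

    def __post_init__(self):
        if self.overlap_k > min(self.draw_n, self.success_K):
            raise ValidationError("overlap exceeds draw or success count")
        if self.draw_n > self.background_N or self.success_K > self.background_N:
            raise ValidationError("draw or success count exceeds background")


def hypergeom_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail one-sided hypergeometric P(X >= k).

    X counts successes in a draw of n from a population of N containing K
    successes.
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValidationError(f"invalid hypergeometric counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def _probes_in_regions(regions: list[Region]) -> list[str]:
    out = []
    for r in regions:
        out.extend(r.probe_ids)
    return out


def probe_weighted_gene_enrichment(
    region_list: list,
    gene_set: GeneSet,
    background: list[Region],
    manifest: ProbeManifest,
    list_name: str = "query",
) -> EnrichmentResult:
    """Gene-set enrichment of a region list, weighted by array probes.

    Background N = probes contained in background regions; K = those probes
    annotated to any gene of the set; n = probes in the query regions; k =
    query probes annotated to set genes.  Gene-level overlap (set genes seen
    in the query) is reported alongside.
    """
    gene_of = pd.Series(manifest.df["genes"].to_numpy(), index=manifest.probe_ids)
    bg_probes = _probes_in_regions(background)
    q_probes = _probes_in_regions(region_list)
    in_set = gene_of.map(lambda gs: bool(gs & gene_set.genes))
    N = len(bg_probes)
    K = int(in_set.loc[bg_probes].sum())
    n = len(q_probes)
    k = int(in_set.loc[q_probes].sum())
    if K == 0:
        warnings.warn(
            f"gene set {gene_set.name!r} has no probes in the background; p = 1",
            stacklevel=2,
        )
        p = 1.0
    else:
        p = hypergeom_p(k, n, K, N)
    overlap_genes = frozenset().union(*gene_of.loc[q_probes]) & gene_set.genes if q_probes else frozenset()
    return EnrichmentResult(
        list_name=list_name,
        set_name=gene_set.name,
        overlap_k=k,
        draw_n=n,
        success_K=K,
        background_N=N,
        p=p,
        extra=tuple(sorted(overlap_genes)),
    )


def category_enrichment(
    region_list: list,
    background: list[Region],
    manifest: ProbeManifest,
    categories: tuple = ISLAND_CATEGORIES,
    list_name: str = "query",
    correct: bool = True,
) -> pd.DataFrame:
    """Per-CpG-category hypergeometric enrichment of query vs background
    probes, with BH correction across the categories reported together."""
    cat_of = pd.Series(manifest.df["island_category"].to_numpy(), index=manifest.probe_ids)
    bg = cat_of.loc[_probes_in_regions(background)]
    q = cat_of.loc[_probes_in_regions(region_list)]
    rows = []
    for c in categories:
        K = int((bg == c).sum())
        if K == 0:
            log.info("category %s absent from background; skipped", c)
            continue
        k = int((q == c).sum())
        rows.append(
            {
                "list_name": list_name,
                "category": c,
                "overlap_k": k,
                "draw_n": len(q),
                "success_K": K,
                "background_N": len(bg),
                "p": hypergeom_p(k, len(q), K, len(bg)),
            }
        )
    df = pd.DataFrame(rows)
    if correct and len(df):
        from statsmodels.stats.multitest import multipletests

        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def _trees(intervals: IntervalSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in intervals.by_chrom().items():
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start"].to_numpy(), sub["end"].to_numpy())
        )
    return trees


def interval_overlap_count(regions: list, intervals: IntervalSet) -> int:
    """Number of regions overlapping >= 1 interval by >= 1 bp (half-open)."""
    trees = _trees(intervals)
    count = 0
    for r in regions:
        t = trees.get(r.chrom)
        if t is not None and t.overlaps(r.start, r.end):
            count += 1
    return count


def dnase_enrichment(
    region_list: list,
    background: list[Region],
    hotspots: IntervalSet,
    list_name: str = "query",
    set_name: str = "hotspots",
) -> EnrichmentResult:
    """Hypergeometric enrichment of hot-spot overlap at the region level.

    N = background regions, K = background regions overlapping a hot spot,
    n = query regions, k = query regions overlapping a hot spot.
    """
    trees = _trees(hotspots)

    def n_overlap(regs):
        return sum(
            1
            for r in regs
            if (t := trees.get(r.chrom)) is not None and t.overlaps(r.start, r.end)
        )

    N, K = len(background), n_overlap(background)
    n, k = len(region_list), n_overlap(region_list)
    p = 1.0 if K == 0 else hypergeom_p(k, n, K, N)
    return EnrichmentResult(list_name, set_name, k, n, K, N, p)


def multi_list_overlap_p(
    lists: list[list],
    background: list[Region],
    reps: int = 100_000,
    seed: int | np.random.SeedSequence | None = 0,
    literal_direction: bool = False,
) -> float:
    """Empirical significance of the common overlap of >= 3 region lists.

    Per repetition, |list_i| regions are drawn uniformly without replacement
    from the background for each list and the intersection size recorded.
    The default (enrichment) p is the fraction of repetitions whose null
    overlap is >= the observed overlap.  ``literal_direction`` instead counts
    repetitions where the observed overlap is smaller than the null overlap
    (a depletion-style reading).
    """
    if len(lists) < 2:
        raise ValidationError("need at least two lists")
    if reps < 100:
        warnings.warn(f"reps={reps} is small; empirical p will be coarse", stacklevel=2)
    bg_ids = [r.region_id for r in background]
    id_index = {rid: i for i, rid in enumerate(bg_ids)}
    sizes = [len(lst) for lst in lists]
    observed_sets = []
    for lst in lists:
        s = {r.region_id if isinstance(r, Region) else str(r) for r in lst}
        missing = s - set(bg_ids)
        if missing:
            raise ValidationError(f"list members outside background: {sorted(missing)[:3]}")
        observed_sets.append(s)
    observed = len(set.intersection(*observed_sets))
    rng = np.random.default_rng(seed)
    N = len(bg_ids)
    count = 0
    for _ in range(reps):
        inter = np.ones(N, dtype=bool)
        hit = np.zeros(N, dtype=bool)
        for size in sizes:
            hit[:] = False
            hit[rng.choice(N, size=size, replace=False)] = True
            inter &= hit
        null_overlap = int(inter.sum())
        if literal_direction:
            count += observed < null_overlap
        else:
            count += null_overlap >= observed
    return count / reps
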