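"""Synthetic manifests, methylation matrices and phenotypes.

The generators emulate the statistical structure the region method assumes
on sparse CpG arrays: a long-tailed inter-probe spacing law (a mixture of
short within-cluster gaps and heavy-tailed between-cluster gaps spanning
2 bp to tens of Mb), cis-correlation of methylation between neighbouring
probes (shared cluster factors in both the baseline level and the noise),
age-linear planted differentially methylated regions, and group-specific
variance inflation with an AR(1)-correlated log spread field for planted
variably methylated regions.

Every generator is a pure function of (scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .clustering import cluster_labels, cluster_probes
from .model import (
    ISLAND_CATEGORIES,
    MethylationMatrix,
    PhenotypeTable,
    ProbeManifest,
    Region,
    ValidationError,
)

__all__ = [
    "SimScenario",
    "generate_manifest",
    "generate_age_series",
    "generate_group_series",
    "default_dmr_plan",
    "default_vmr_plan",
]

MAX_GAP = 20_000_000  # widest inter-probe spacing emulated, bp


@dataclass(frozen=True)
class SimScenario:
    """Study conditions for the synthetic test bed.

    Defaults give a 5,000-probe, 4-chromosome layout in which roughly
    three-quarters of gaps are short enough to cluster at L = 1 kb, age
    effects of 0.002 fractional methylation per year, sampling noise of
    0.03, and a moderately autocorrelated log-spread field (rho = 0.5).
    """

    n_probes: int = 5000
    n_chroms: int = 4
    short_gap_fraction: float = 0.8   # P(gap drawn from the short component)
    short_gap_mean: float = 200.0     # mean bp of the short (within-cluster) gaps
    long_gap_exponent: float = 0.75   # Pareto tail index of the long gaps
    planted_dmrs: tuple[tuple[int, float], ...] = ()   # (region index, slope/yr)
    planted_vmrs: tuple[tuple[int, float], ...] = ()   # (region index, log-MAD shift)
    noise_sd: float = 0.03            # per-sample methylation noise sd
    cluster_noise_share: float = 0.45 # fraction of noise variance shared in-cluster
    baseline_jitter_sd: float = 0.03  # probe-level scatter around cluster baseline
    ar1_rho: float = 0.5              # log-spread autocorrelation along probes
    ar1_sigma: float = 0.3            # log-spread AR(1) innovation sd
    base_sd: float = 0.04             # median per-probe sampling sd (group mode)
    cross_hyb_rate: float = 0.01
    L: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.short_gap_fraction <= 1):
            raise ValidationError("short_gap_fraction must be in [0,1]")
        if not (abs(self.ar1_rho) < 1):
            raise ValidationError("|ar1_rho| must be < 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


def _rng(scn: SimScenario, stage: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=scn.seed, spawn_key=(stage,))
    )


def generate_manifest(scn: SimScenario) -> ProbeManifest:
    """Probe layout with mixture-law inter-probe gaps.

    Short gaps are exponential (clipped to [2, L]) so they never break a
    cluster at the scenario's L; long gaps are Pareto-tailed above L, capped
    at 20 Mb.  Gene symbols are assigned per contiguous block so gene-level
    enrichment has realistic granularity.
    """
    rng = _rng(scn, 0)
    per_chrom = np.full(scn.n_chroms, scn.n_probes // scn.n_chroms)
    per_chrom[: scn.n_probes % scn.n_chroms] += 1
    rows = []
    block = 0
    for c in range(scn.n_chroms):
        n = per_chrom[c]
        short = rng.random(n - 1) < scn.short_gap_fraction if n > 1 else np.empty(0, bool)
        gaps = np.empty(max(n - 1, 0))
        n_short = int(short.sum())
        gaps[short] = np.clip(
            rng.exponential(scn.short_gap_mean, n_short), 2, scn.L
        ).round()
        n_long = gaps.size - n_short
        gaps[~short] = np.minimum(
            scn.L + 1 + (rng.pareto(scn.long_gap_exponent, n_long) * 5000).round(),
            MAX_GAP,
        )
        pos = 1000 + np.concatenate([[0], np.cumsum(gaps)]).astype(np.int64)
        block += 1
        for i in range(n):
            if i > 0 and gaps[i - 1] > scn.L:
                block += 1
            rows.append(
                {
                    "probe_id": f"cg{c:02d}{i:06d}",
                    "chrom": f"chr{c + 1}",
                    "pos": int(pos[i]),
                    "genes": f"G{block:05d}",
                    "island_category": ISLAND_CATEGORIES[
                        rng.choice(6, p=[0.3, 0.1, 0.1, 0.05, 0.05, 0.4])
                    ],
                    "cross_hybridizing": bool(rng.random() < scn.cross_hyb_rate),
                }
            )
    return ProbeManifest(pd.DataFrame(rows))


def _eligible_region_indices(regions: list[Region], min_probes: int) -> list[int]:
    return [i for i, r in enumerate(regions) if r.n_probes >= min_probes]


def default_dmr_plan(
    scn: SimScenario,
    manifest: ProbeManifest,
    n_planted: int = 20,
    slope: float = 0.002,
    min_probes: int = 3,
) -> SimScenario:
    """Scenario with ``n_planted`` age-linear regions planted in evenly
    spaced eligible clusters, alternating hyper/hypo direction."""
    regions = cluster_probes(manifest, scn.L)
    eligible = _eligible_region_indices(regions, min_probes)
    if len(eligible) < n_planted:
        raise ValidationError(f"only {len(eligible)} clusters with >= {min_probes} probes")
    picks = [eligible[i] for i in np.linspace(0, len(eligible) - 1, n_planted).astype(int)]
    planted = tuple(
        (idx, slope if j % 2 == 0 else -slope) for j, idx in enumerate(picks)
    )
    return replace(scn, planted_dmrs=planted)


def default_vmr_plan(
    scn: SimScenario,
    manifest: ProbeManifest,
    n_planted: int = 15,
    shift: float = 1.5,
    min_probes: int = 3,
) -> SimScenario:
    """Scenario with ``n_planted`` variance-inflated regions (log-MAD shift)
    planted in evenly spaced eligible clusters."""
    regions = cluster_probes(manifest, scn.L)
    eligible = _eligible_region_indices(regions, min_probes)
    if len(eligible) < n_planted:
        raise ValidationError(f"only {len(eligible)} clusters with >= {min_probes} probes")
    picks = [eligible[i] for i in np.linspace(0, len(eligible) - 1, n_planted).astype(int)]
    return replace(scn, planted_vmrs=tuple((idx, shift) for idx in picks))


def _baselines(
    scn: SimScenario,
    manifest: ProbeManifest,
    labels: np.ndarray,
    rng: np.random.Generator,
    planted: dict[int, float] | None = None,
) -> np.ndarray:
    """Per-probe baseline methylation: a cluster-level U(0.1, 0.9) level plus
    probe jitter, so neighbouring probes are similar within one sample.
    Planted clusters get mid-range baselines that keep the signal inside
    [0, 1] over the age span."""
    n = len(manifest)
    n_clusters = labels.max() + 1 if labels.size and labels.max() >= 0 else 0
    cluster_base = rng.uniform(0.1, 0.9, size=max(n_clusters, 1))
    if planted:
        for idx, effect in planted.items():
            lo, hi = (0.30, 0.45) if effect > 0 else (0.55, 0.70)
            cluster_base[idx] = rng.uniform(lo, hi)
    base = np.where(labels >= 0, cluster_base[np.maximum(labels, 0)], rng.uniform(0.1, 0.9, n))
    base = base + rng.normal(0.0, scn.baseline_jitter_sd, n)
    return np.clip(base, 0.05, 0.95)


def _correlated_noise(
    scn: SimScenario, labels: np.ndarray, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Compound-symmetric in-cluster noise: a shared cluster factor plus a
    probe-specific term, total sd = noise_sd."""
    n = labels.size
    n_clusters = labels.max() + 1 if labels.size and labels.max() >= 0 else 0
    z_probe = rng.standard_normal((n, n_samples))
    if n_clusters == 0:
        return scn.noise_sd * z_probe
    z_cluster = rng.standard_normal((n_clusters, n_samples))
    shared = np.zeros((n, n_samples))
    in_cluster = labels >= 0
    shared[in_cluster] = z_cluster[labels[in_cluster]]
    w = scn.cluster_noise_share
    mix = np.where(
        in_cluster[:, None], np.sqrt(w) * shared + np.sqrt(1 - w) * z_probe, z_probe
    )
    return scn.noise_sd * mix


def generate_age_series(
    scn: SimScenario, manifest: ProbeManifest, ages: np.ndarray
) -> tuple[MethylationMatrix, PhenotypeTable, pd.DataFrame]:
    """Methylation matrix with planted age-linear regions.

    Returns (matrix, phenotypes, truth) where truth has one row per planted
    region (region_id, probe ids, slope).
    """
    ages = np.asarray(ages, dtype=float)
    rng = _rng(scn, 1)
    labels = cluster_labels(manifest, scn.L)
    regions = cluster_probes(manifest, scn.L)
    planted = dict(scn.planted_dmrs)
    for idx in planted:
        if idx < 0 or idx >= len(regions):
            raise ValidationError(f"planted region index {idx} out of range")
    base = _baselines(scn, manifest, labels, rng, planted)
    n = len(manifest)
    signal = np.zeros((n, ages.size))
    truth_rows = []
    for idx, slope in planted.items():
        r = regions[idx]
        rows = manifest.row_indexer(r.probe_ids)
        signal[rows] += slope * ages[None, :]
        extreme = base[rows].max() + max(slope * ages.max(), 0)
        if extreme > 1 or (base[rows].min() + min(slope * ages.max(), 0)) < 0:
            import warnings

            warnings.warn(
                f"planted slope {slope}/yr drives region {r.region_id} outside [0,1];"
                " values will clip",
                stacklevel=2,
            )
        truth_rows.append(
            {
                "region_index": idx,
                "region_id": r.region_id,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "probe_ids": ";".join(r.probe_ids),
                "slope": slope,
            }
        )
    noise = _correlated_noise(scn, labels, ages.size, rng) if scn.noise_sd > 0 else 0.0
    values = np.clip(base[:, None] + signal + noise, 0.0, 1.0)
    sample_ids = [f"S{i:04d}" for i in range(ages.size)]
    matrix = MethylationMatrix(
        pd.DataFrame(values, index=manifest.probe_ids, columns=sample_ids), manifest
    )
    pheno = PhenotypeTable(pd.DataFrame({"sample_id": sample_ids, "age": ages}))
    return matrix, pheno, pd.DataFrame(truth_rows)


def generate_group_series(
    scn: SimScenario,
    manifest: ProbeManifest,
    groups: dict[str, int],
    shift_group: str | None = None,
) -> tuple[MethylationMatrix, PhenotypeTable, pd.DataFrame]:
    """Methylation matrix with group-specific variance structure.

    Each group gets a per-probe log sampling-sd field: log(base_sd) plus a
    stationary AR(1) series within each cluster (iid with the stationary
    marginal sd for singletons).  Planted regions add their log shift in
    ``shift_group`` (default: the last group listed).  Samples are then drawn
    independently given the sd field and clipped to [0, 1].
    """
    rng = _rng(scn, 2)
    labels = cluster_labels(manifest, scn.L)
    regions = cluster_probes(manifest, scn.L)
    planted = dict(scn.planted_vmrs)
    for idx in planted:
        if idx < 0 or idx >= len(regions):
            raise ValidationError(f"planted region index {idx} out of range")
    if shift_group is None:
        shift_group = list(groups)[-1]
    if shift_group not in groups:
        raise ValidationError(f"shift_group {shift_group!r} not among groups")
    base = _baselines(scn, manifest, labels, rng)
    # keep planted regions mid-range so inflated spread is not clipped away
    for idx in planted:
        rows = manifest.row_indexer(regions[idx].probe_ids)
        base[rows] = rng.uniform(0.35, 0.65, rows.size)
    n = len(manifest)
    marginal_sd = scn.ar1_sigma / np.sqrt(1 - scn.ar1_rho**2)
    from .model import AR1Params
    from .vmr import _simulate_ar1_panel

    params = AR1Params(rho=scn.ar1_rho, sigma=scn.ar1_sigma)
    blocks: list[pd.DataFrame] = []
    sample_rows = []
    truth_rows = []
    for g, size in groups.items():
        log_sd = np.log(scn.base_sd) + np.where(
            labels >= 0, 0.0, rng.normal(0.0, marginal_sd, n)
        )
        if regions:
            lengths = np.array([r.n_probes for r in regions])
            panel = _simulate_ar1_panel(lengths, params, rng)
            offs = 0
            for r, ln in zip(regions, lengths):
                rows = manifest.row_indexer(r.probe_ids)
                log_sd[rows] += panel[offs : offs + ln]
                offs += ln
        if g == shift_group:
            for idx, shift in planted.items():
                r = regions[idx]
                rows = manifest.row_indexer(r.probe_ids)
                log_sd[rows] += shift
                truth_rows.append(
                    {
                        "region_index": idx,
                        "region_id": r.region_id,
                        "chrom": r.chrom,
                        "start": r.start,
                        "end": r.end,
                        "probe_ids": ";".join(r.probe_ids),
                        "log_mad_shift": shift,
                        "group": g,
                    }
                )
        sd = np.exp(log_sd)
        z = rng.standard_normal((n, size))
        vals = np.clip(base[:, None] + sd[:, None] * z, 0.0, 1.0)
        ids = [f"{g}{i:04d}" for i in range(size)]
        blocks.append(pd.DataFrame(vals, index=manifest.probe_ids, columns=ids))
        sample_rows.extend({"sample_id": s, "group": g} for s in ids)
    matrix = MethylationMatrix(pd.concat(blocks, axis=1), manifest)
    pheno = PhenotypeTable(pd.DataFrame(sample_rows))
    return matrix, pheno, pd.DataFrame(truth_rows)
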