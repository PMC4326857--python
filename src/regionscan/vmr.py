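"""Variably methylated region (VMR) detection.

The per-probe statistic is the median absolute deviation (MAD) of
methylation across the samples of one age group.  Candidate VMRs are runs of
>= 2 consecutive probes within a distance cluster whose MAD scores all
exceed the 95th percentile.  Significance comes from a parametric bootstrap:
log-MAD values along a region are modelled as a stationary first-order
autoregressive (AR(1)) process whose parameters are estimated by Burg's
method on all regions with enough probes and averaged; synthetic MAD
landscapes are then generated over the real probe layout, the identification
procedure is rerun on each, and observed areas are compared with the pooled
null areas.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dmr import (
    _detect_runs,
    _pass_labels,
    _region_arrays,
    detect_candidates,
    empirical_pvalues,
    estimate_qvalues,
    percentile_thresholds,
    _run_areas,
)
from .model import (
    AR1Params,
    MADVector,
    MethylationMatrix,
    NullAreaDistribution,
    PhenotypeTable,
    ProbeStatVector,
    Region,
    ScoredRegion,
    Thresholds,
    ValidationError,
)

__all__ = [
    "compute_mad",
    "fit_ar1_burg",
    "pool_ar1",
    "simulate_null_vmr_areas",
    "run_vmr_pipeline",
    "mad_percentile_ratio",
    "VMRResult",
]

#: reflection-coefficient clamp keeping |rho| strictly inside the unit circle
_RHO_EPS = 1e-10


def compute_mad(
    matrix: MethylationMatrix, group_samples: list[str], group: str = "group"
) -> MADVector:
    """Per-probe MAD of methylation across one group's samples.

    Unscaled median(|x - median(x)|): no 1.4826 normal-consistency factor.
    """
    if len(group_samples) < 3:
        raise ValidationError("MAD needs at least 3 samples in the group")
    sub = matrix.values[sorted(group_samples)].to_numpy()
    med = np.nanmedian(sub, axis=1, keepdims=True)
    mad = np.nanmedian(np.abs(sub - med), axis=1)
    return MADVector(pd.Series(mad, index=matrix.probe_ids), group=group)


def fit_ar1_burg(series: np.ndarray, center: bool = True) -> AR1Params:
    """Order-1 Burg estimate of an AR(1) process.

    The reflection coefficient minimises the summed forward and backward
    prediction error of the mean-centred series:
    rho = 2 * sum(x_i * x_{i+1}) / sum(x_i^2 + x_{i+1}^2), which lies in
    [-1, 1] by Cauchy-Schwarz; it is clamped strictly inside.  The innovation
    standard deviation is sqrt((1 - rho^2) * var0) with var0 the mean square
    of the centred series.  ``center=False`` skips the internal demeaning for
    callers that have already removed a mean estimated on more data (short
    series demeaned individually give downward-biased rho).
    """
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        raise ValidationError("AR(1) fit needs a series of length >= 3")
    if not np.isfinite(x).all():
        raise ValidationError("non-finite values in series")
    if center:
        x = x - x.mean()
    var0 = float(np.mean(x * x))
    if var0 == 0:
        raise ValidationError("zero-variance series")
    num = 2.0 * float(np.sum(x[:-1] * x[1:]))
    den = float(np.sum(x[:-1] ** 2 + x[1:] ** 2))
    rho = num / den
    rho = float(np.clip(rho, -1.0 + _RHO_EPS, 1.0 - _RHO_EPS))
    sigma = float(np.sqrt(max((1.0 - rho**2) * var0, 0.0)))
    if sigma == 0.0:
        sigma = np.sqrt(var0) * np.sqrt(2 * _RHO_EPS)  # degenerate |rho| -> 1 edge
    return AR1Params(rho=rho, sigma=sigma)


def pool_ar1(
    mads: MADVector,
    regions: list[Region],
    min_probes: int = 50,
    log_floor: float = 1e-6,
) -> AR1Params:
    """Average Burg AR(1) estimates of log-MAD over all sufficiently long
    regions (natural log; MAD floored at ``log_floor`` before the log).

    The stationary mean of the log-MAD landscape is estimated once across
    all qualifying regions and removed before the per-region fits: demeaning
    each short region individually would bias rho downward by roughly
    (1 + 3 rho) / n.
    """
    series_list = []
    for r in regions:
        if r.n_probes < min_probes:
            continue
        vals = mads.values.loc[list(r.probe_ids)].to_numpy()
        if np.isnan(vals).any():
            continue
        series = np.log(np.maximum(vals, log_floor))
        if np.ptp(series) == 0:
            continue
        series_list.append(series)
    rhos, sigmas = [], []
    if series_list:
        grand_mean = float(np.mean(np.concatenate(series_list)))
        for series in series_list:
            fit = fit_ar1_burg(series - grand_mean, center=False)
            rhos.append(fit.rho)
            sigmas.append(fit.sigma)
    if not rhos:
        raise ValidationError(
            f"no region with >= {min_probes} probes and varying MAD; "
            "reduce min_probes"
        )
    return AR1Params(rho=float(np.mean(rhos)), sigma=float(np.mean(sigmas)))


def _simulate_ar1_panel(
    lengths: np.ndarray, params: AR1Params, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) series for many independent segments, concatenated.

    Vectorised across segments: segments are padded to the maximum length and
    the recursion runs along the position axis.
    """
    lengths = np.asarray(lengths)
    if lengths.size == 0:
        return np.empty(0)
    m = int(lengths.max())
    z = rng.standard_normal((lengths.size, m))
    k = np.empty((lengths.size, m))
    k[:, 0] = params.marginal_sd * z[:, 0]
    for r in range(1, m):
        k[:, r] = params.rho * k[:, r - 1] + params.sigma * z[:, r]
    mask = np.arange(m)[None, :] < lengths[:, None]
    return k[mask]


def simulate_null_vmr_areas(
    manifest,
    regions: list[Region],
    pooled: AR1Params,
    x: int,
    n_sim: int = 100,
    seed: int | np.random.SeedSequence | None = 0,
    upper: float = 95.0,
    q1_obs: float | None = None,
    mean_log: float = 0.0,
) -> NullAreaDistribution:
    """Null VMR areas from an AR(1) parametric bootstrap on the real layout.

    Per simulation: a stationary log-MAD AR(1) series around ``mean_log``
    (the observed mean log-MAD level, so null areas live on the data scale)
    is generated within each cluster (independent across clusters) and
    exponentiated; the simulation's own ``upper`` percentile is taken as the
    cut (or the observed cut ``q1_obs`` if supplied); candidate runs are
    detected; ``x`` of them are sampled without replacement (all if fewer)
    and their areas pooled.
    """
    if x < 1:
        raise ValidationError("x (observed VMR count) must be >= 1")
    if n_sim < 1:
        raise ValidationError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    # flatten the clustered probe layout once
    lengths = np.array([r.n_probes for r in regions], dtype=np.int64)
    if regions:
        pos = np.concatenate([_anchors(manifest, r) for r in regions])
        cluster_ids = np.repeat(np.arange(len(regions)), lengths)
    else:
        pos = np.empty(0)
        cluster_ids = np.empty(0, dtype=np.int64)
    areas_all, counts = [], []
    for _ in range(n_sim):
        log_mad = mean_log + _simulate_ar1_panel(lengths, pooled, rng)
        mad = np.exp(log_mad)
        q1 = float(np.percentile(mad, upper)) if q1_obs is None else q1_obs
        labels = _pass_labels(mad, Thresholds(q1=q1), "vmr")
        starts, ends = _detect_runs(labels, cluster_ids)
        a = _run_areas(starts, ends, pos.astype(float), mad)
        if a.size > x:
            a = a[rng.choice(a.size, size=x, replace=False)]
        areas_all.append(a)
        counts.append(a.size)
    return NullAreaDistribution(
        areas=np.concatenate(areas_all) if areas_all else np.empty(0),
        n_per_sim=tuple(counts),
    )


def _anchors(manifest, region: Region) -> np.ndarray:
    return manifest.pos[manifest.row_indexer(region.probe_ids)]


class VMRResult:
    """Output bundle of the VMR pipeline."""

    def __init__(self, candidates, significant, thresholds, null, ar1, fdr_cut):
        self.candidates = candidates
        self.significant = significant
        self.thresholds = thresholds
        self.null = null
        self.ar1 = ar1
        self.fdr_cut = fdr_cut


def run_vmr_pipeline(
    matrix: MethylationMatrix,
    pheno: PhenotypeTable,
    manifest,
    group: str,
    config=None,
    harmonize_groups: list[str] | None = None,
) -> VMRResult:
    """End-to-end VMR discovery for one age group.

    cluster -> cross-hybridizing filter -> per-probe MAD -> 95th-percentile
    cut (optionally the lowest cut across several groups) -> candidate runs
    -> areas -> AR(1) parametric-bootstrap null -> empirical p -> BH q ->
    keep q < fdr_cut.
    """
    from .clustering import cluster_probes, filter_cross_hybridizing
    from .config import RunConfig
    from .dmr import harmonize_thresholds

    cfg = config or RunConfig()
    regions = cluster_probes(manifest, cfg.L)
    regions = filter_cross_hybridizing(regions, manifest, cfg.max_cross_hyb_fraction)
    mads = compute_mad(matrix, pheno.group_samples(group), group=group)
    stats = ProbeStatVector(mads.values, "mad")
    if harmonize_groups:
        ths = []
        for g in harmonize_groups:
            mg = compute_mad(matrix, pheno.group_samples(g), group=g)
            ths.append(
                percentile_thresholds(ProbeStatVector(mg.values, "mad"), cfg.upper_pct)
            )
        th = harmonize_thresholds(ths)
    else:
        th = percentile_thresholds(stats, cfg.upper_pct)
    candidates = detect_candidates(regions, stats, th, mode="vmr", manifest=manifest)
    if not candidates:
        return VMRResult([], [], th, None, None, cfg.fdr_cut)
    ar1 = pool_ar1(mads, regions, min_probes=cfg.min_probes_ar, log_floor=cfg.log_floor)
    clustered = [p for r in regions for p in r.probe_ids]
    mean_log = float(
        np.nanmean(np.log(np.maximum(mads.values.loc[clustered].to_numpy(), cfg.log_floor)))
    )
    null = simulate_null_vmr_areas(
        manifest,
        regions,
        ar1,
        x=len(candidates),
        n_sim=cfg.n_sim,
        seed=cfg.substream("bootstrap"),
        upper=cfg.upper_pct,
        mean_log=mean_log,
    )
    candidates = empirical_pvalues(candidates, null, laplace=cfg.laplace_p)
    qs = estimate_qvalues([r.p for r in candidates])
    candidates = [r.with_significance(r.p, float(q)) for r, q in zip(candidates, qs)]
    significant = [r for r in candidates if r.q < cfg.fdr_cut]
    return VMRResult(candidates, significant, th, null, ar1, cfg.fdr_cut)


def mad_percentile_ratio(groups: list[MADVector], pct: float = 95.0) -> pd.DataFrame:
    """Pairwise ratio of the ``pct``-percentile MAD between groups.

    Entry (a, b) is pct-percentile(a) / pct-percentile(b).
    """
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    names = [g.group for g in groups]
    pcts = {g.group: float(np.nanpercentile(g.values.to_numpy(), pct)) for g in groups}
    for name, v in pcts.items():
        if v == 0:
            raise ValidationError(f"zero {pct}th-percentile MAD in group {name!r}")
    return pd.DataFrame(
        [[pcts[a] / pcts[b] for b in names] for a in names], index=names, columns=names
    )
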