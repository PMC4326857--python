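"""Differentially methylated region (DMR) detection.

The per-probe statistic is the slope (or its t-statistic) of an ordinary
least-squares regression of fractional methylation on age.  Candidate DMRs
are runs of >= 2 consecutive probes inside a distance cluster whose
statistics all exceed the 95th percentile of positive values (hyper) or all
fall below the 5th percentile of negative values (hypo).  Each candidate is
scored by the trapezoidal area of |statistic| against genomic position, and
significance comes from a phenotype-permutation null: ages are shuffled
across samples, the whole identification procedure is rerun (thresholds
included), and the observed area is compared with the pooled null areas.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .model import (
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
    "fit_probe_statistics",
    "percentile_thresholds",
    "harmonize_thresholds",
    "detect_candidates",
    "region_area",
    "permutation_null",
    "empirical_pvalues",
    "estimate_qvalues",
    "run_dmr_pipeline",
    "power_comparison",
    "DMRResult",
]

#: probes with more than this fraction of missing samples get an undefined
#: statistic (excluded from thresholds and unable to join candidate runs)
MAX_MISSING_FRACTION = 0.2


# ---------------------------------------------------------------------------
# per-probe statistics

def _ols_beta_t(Y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised simple OLS of each row of Y on x, NaN-aware.

    Returns (beta, t) with NaN where a probe has too few observations or an
    x with no variance among its observed samples.
    """
    mask = np.isfinite(Y)
    n = mask.sum(axis=1).astype(float)
    Sx = mask @ x
    Sxx = mask @ (x * x)
    Y0 = np.where(mask, Y, 0.0)
    Sy = Y0.sum(axis=1)
    Syy = (Y0 * Y0).sum(axis=1)
    Sxy = Y0 @ x
    with np.errstate(invalid="ignore", divide="ignore"):
        sxx = Sxx - Sx * Sx / n
        sxy = Sxy - Sx * Sy / n
        syy = Syy - Sy * Sy / n
        beta = sxy / sxx
        rss = np.maximum(syy - beta * sxy, 0.0)
        dof = n - 2
        s2 = rss / dof
        with np.errstate(invalid="ignore", divide="ignore"):
            t = beta / np.sqrt(s2 / sxx)
        t = np.where(s2 == 0, np.sign(beta) * np.inf, t)
        t = np.where(beta == 0, 0.0, t)
    undef = (n < 3) | (sxx <= 0)
    beta = np.where(undef, np.nan, beta)
    t = np.where(undef, np.nan, t)
    return beta, t


def fit_probe_statistics(
    matrix: MethylationMatrix,
    pheno: PhenotypeTable,
    covariates: list[str] | None = None,
    stat_type: str = "beta",
) -> ProbeStatVector:
    """Per-probe OLS of methylation on age (plus optional covariates).

    Returns the slope on age (``beta``) or its t-statistic (``t``).  Probes
    with more than 20% missing samples are left undefined; otherwise the fit
    uses the available samples.
    """
    if stat_type not in ("beta", "t"):
        raise ValidationError(f"stat_type must be beta or t, got {stat_type!r}")
    samples = matrix.sample_ids
    if len(samples) < 3:
        raise ValidationError("need at least 3 samples")
    ages = pheno.ages_for(samples)
    if np.std(ages) == 0:
        raise ValidationError("age has zero variance")
    Y = matrix.values.to_numpy()
    missing_frac = np.isnan(Y).mean(axis=1)
    if covariates:
        beta, t = _ols_beta_t_cov(Y, ages, pheno.df.loc[samples, covariates].to_numpy(float))
    else:
        beta, t = _ols_beta_t(Y, ages)
    vals = beta if stat_type == "beta" else t
    vals = np.where(missing_frac > MAX_MISSING_FRACTION, np.nan, vals)
    return ProbeStatVector(pd.Series(vals, index=matrix.probe_ids), stat_type)


def _ols_beta_t_cov(Y: np.ndarray, x: np.ndarray, W: np.ndarray):
    """Multiple-regression path (age + covariates); complete-case per probe."""
    X = np.column_stack([np.ones_like(x), x, W])
    p = X.shape[1]
    beta = np.full(Y.shape[0], np.nan)
    t = np.full(Y.shape[0], np.nan)
    complete = np.isfinite(Y)
    for j in range(Y.shape[0]):
        m = complete[j]
        if m.sum() < p + 1:
            continue
        Xm, ym = X[m], Y[j, m]
        XtX = Xm.T @ Xm
        try:
            XtX_inv = np.linalg.inv(XtX)
        except np.linalg.LinAlgError:
            continue
        b = XtX_inv @ (Xm.T @ ym)
        resid = ym - Xm @ b
        dof = m.sum() - p
        s2 = resid @ resid / dof if dof > 0 else np.nan
        beta[j] = b[1]
        se = np.sqrt(s2 * XtX_inv[1, 1])
        t[j] = b[1] / se if se > 0 else np.sign(b[1]) * np.inf
    return beta, t


# ---------------------------------------------------------------------------
# thresholds

def percentile_thresholds(
    stats: ProbeStatVector, upper: float = 95.0, lower: float = 5.0
) -> Thresholds:
    """Percentile cut-offs with linear interpolation between order statistics.

    For signed statistics, q1 is the ``upper`` percentile of the positive
    subset only and q2 the ``lower`` percentile of the negative subset only.
    For MAD statistics, q1 is the ``upper`` percentile of all defined values.
    """
    v = stats.defined().to_numpy()
    if stats.stat_type == "mad":
        if v.size == 0:
            raise ValidationError("no defined MAD values")
        return Thresholds(q1=float(np.percentile(v, upper)), q2=None)
    pos = v[v > 0]
    neg = v[v < 0]
    if pos.size == 0:
        raise ValidationError("no positive statistics: cannot compute upper threshold")
    if neg.size == 0:
        raise ValidationError("no negative statistics: cannot compute lower threshold")
    return Thresholds(
        q1=float(np.percentile(pos, upper)),
        q2=float(np.percentile(neg, lower)),
    )


def harmonize_thresholds(per_dataset: list[Thresholds]) -> Thresholds:
    """Least-extreme cut on each side across datasets (lowest upper cut,
    highest lower cut), for multi-dataset analyses."""
    if len(per_dataset) < 1:
        raise ValidationError("need at least one Thresholds")
    q1 = min(t.q1 for t in per_dataset)
    q2s = [t.q2 for t in per_dataset if t.q2 is not None]
    return Thresholds(q1=q1, q2=max(q2s) if q2s else None)


# ---------------------------------------------------------------------------
# candidate detection (shared fast path)

def _pass_labels(values: np.ndarray, th: Thresholds, mode: str) -> np.ndarray:
    """+1 above q1, -1 below q2 (signed mode), 0 otherwise.  Ties at the cut
    do not pass (the cut-offs are strict)."""
    lab = np.zeros(values.shape, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        lab[values > th.q1] = 1
        if mode == "dmr":
            if th.q2 is None:
                raise ValidationError("dmr mode needs a lower threshold")
            lab[values < th.q2] = -1
    return lab


def _detect_runs(
    labels: np.ndarray, cluster_ids: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Maximal runs (start, end inclusive indices) of identical nonzero label
    within one cluster, length >= 2."""
    valid = (labels != 0) & (cluster_ids >= 0)
    if not valid.any():
        empty = np.empty(0, dtype=np.int64)
        return empty, empty
    cont = (
        valid[1:]
        & valid[:-1]
        & (labels[1:] == labels[:-1])
        & (cluster_ids[1:] == cluster_ids[:-1])
    )
    start_flag = valid.copy()
    start_flag[1:] &= ~cont
    end_flag = valid.copy()
    end_flag[:-1] &= ~cont
    starts = np.flatnonzero(start_flag)
    ends = np.flatnonzero(end_flag)
    keep = (ends - starts) >= 1
    return starts[keep], ends[keep]


def _run_areas(
    starts: np.ndarray, ends: np.ndarray, pos: np.ndarray, absvals: np.ndarray
) -> np.ndarray:
    """Trapezoidal areas for many runs at once via a cumulative-sum trick."""
    if starts.size == 0:
        return np.empty(0)
    a = np.nan_to_num(absvals, nan=0.0)
    contrib = np.empty(len(pos))
    contrib[:-1] = (pos[1:] - pos[:-1]) * (a[:-1] + a[1:]) / 2.0
    contrib[-1] = 0.0
    cum = np.concatenate([[0.0], np.cumsum(contrib)])
    return cum[ends] - cum[starts]


def _region_arrays(stats: ProbeStatVector, regions: list[Region]) -> np.ndarray:
    """Cluster id per probe of the statistic vector (-1 outside any region)."""
    index = stats.values.index
    cluster = pd.Series(-1, index=index, dtype=np.int64)
    for i, r in enumerate(regions):
        cluster.loc[list(r.probe_ids)] = i
    return cluster.to_numpy()


def detect_candidates(
    regions: list[Region],
    stats: ProbeStatVector,
    th: Thresholds,
    mode: str = "dmr",
    manifest=None,
) -> list[ScoredRegion]:
    """Find candidate regions: maximal runs of >= 2 consecutive probes inside
    a distance cluster, all above q1 (hyper / variable) or all below q2
    (hypo).  A probe failing the cut, switching sign, or lacking a defined
    statistic breaks the run.  Areas are filled in; p and q stay None.
    """
    if mode not in ("dmr", "vmr"):
        raise ValidationError(f"mode must be dmr or vmr, got {mode!r}")
    values = stats.values.to_numpy()
    cluster_ids = _region_arrays(stats, regions)
    pos = _positions_for(stats, regions, manifest)
    labels = _pass_labels(values, th, mode)
    starts, ends = _detect_runs(labels, cluster_ids)
    areas = _run_areas(starts, ends, pos.astype(float), np.abs(values))
    ids = stats.values.index.to_numpy()
    out = []
    for s, e, area in zip(starts, ends, areas):
        chrom = regions[cluster_ids[s]].chrom
        direction = (
            "variable" if mode == "vmr" else ("hyper" if labels[s] > 0 else "hypo")
        )
        out.append(
            ScoredRegion(
                region_id=f"{chrom}:{pos[s]}-{pos[e]}:{direction}",
                chrom=chrom,
                probe_ids=tuple(ids[s : e + 1]),
                start=int(pos[s]) - 1,
                end=int(pos[e]),
                direction=direction,
                member_stats=tuple(float(v) for v in values[s : e + 1]),
                member_pos=tuple(int(p) for p in pos[s : e + 1]),
                area=float(area),
            )
        )
    return out


def _positions_for(stats: ProbeStatVector, regions: list[Region], manifest) -> np.ndarray:
    if manifest is None:
        raise ValidationError("candidate detection requires a manifest for positions")
    return manifest.pos[manifest.row_indexer(stats.values.index)]


def region_area(candidate: ScoredRegion) -> float:
    """Trapezoidal integral of |statistic| against bp position."""
    pos = np.asarray(candidate.member_pos, dtype=float)
    if len(pos) < 2:
        raise ValidationError("area needs at least 2 probes")
    d = np.diff(pos)
    if (d <= 0).any():
        raise ValidationError("duplicate or non-increasing probe positions")
    s = np.abs(np.asarray(candidate.member_stats, dtype=float))
    return float(np.sum(d * (s[:-1] + s[1:]) / 2.0))


# ---------------------------------------------------------------------------
# permutation null and significance

def permutation_null(
    matrix: MethylationMatrix,
    pheno: PhenotypeTable,
    regions: list[Region],
    manifest,
    stat_type: str = "beta",
    upper: float = 95.0,
    lower: float = 5.0,
    K: int = 100,
    seed: int | np.random.SeedSequence | None = 0,
    frozen_thresholds: Thresholds | None = None,
    _identity: bool = False,
) -> NullAreaDistribution:
    """Null area distribution from phenotype permutation.

    Per permutation: ages are shuffled across samples, per-probe statistics
    refit, thresholds recomputed (unless ``frozen_thresholds`` is given), the
    run-detection rerun, and all resulting areas pooled.  Fully reproducible
    from ``seed``.  ``_identity`` forces the identity permutation (testing
    hook: null areas then equal the observed candidate areas).
    """
    if K < 1:
        raise ValidationError("K must be >= 1")
    rng = np.random.default_rng(seed)
    samples = matrix.sample_ids
    ages = pheno.ages_for(samples)
    Y = matrix.values.to_numpy()
    missing_frac = np.isnan(Y).mean(axis=1)
    stats0 = ProbeStatVector(
        pd.Series(np.nan, index=matrix.probe_ids), stat_type
    )
    cluster_ids = _region_arrays(stats0, regions)
    pos = _positions_for(stats0, regions, manifest).astype(float)
    areas_all: list[np.ndarray] = []
    counts: list[int] = []
    for _ in range(K):
        perm = np.arange(len(ages)) if _identity else rng.permutation(len(ages))
        beta, t = _ols_beta_t(Y, ages[perm])
        vals = beta if stat_type == "beta" else t
        vals = np.where(missing_frac > MAX_MISSING_FRACTION, np.nan, vals)
        sv = ProbeStatVector(pd.Series(vals, index=matrix.probe_ids), stat_type)
        th = frozen_thresholds or percentile_thresholds(sv, upper, lower)
        labels = _pass_labels(vals, th, "dmr")
        starts, ends = _detect_runs(labels, cluster_ids)
        a = _run_areas(starts, ends, pos, np.abs(vals))
        areas_all.append(a)
        counts.append(a.size)
    return NullAreaDistribution(
        areas=np.concatenate(areas_all) if areas_all else np.empty(0),
        n_per_sim=tuple(counts),
    )


def empirical_pvalues(
    observed: list[ScoredRegion],
    null: NullAreaDistribution,
    laplace: bool = False,
) -> list[ScoredRegion]:
    """Empirical p per region: the fraction of pooled null areas at least as
    large as the observed area (ties count).  ``laplace`` switches to
    (1 + count) / (1 + total) for users needing strictly positive p."""
    total = null.areas.size
    if total == 0:
        raise ValidationError("empty null area distribution")
    out = []
    for r in observed:
        c = null.count_geq(r.area)
        p = (1 + c) / (1 + total) if laplace else c / total
        out.append(r.with_significance(p=float(p)))
    return out


def estimate_qvalues(pvalues: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values outside [0,1]")
    return multipletests(p, method="fdr_bh")[1]


class DMRResult:
    """Output bundle of the DMR pipeline."""

    def __init__(self, candidates, significant, thresholds, null, fdr_cut):
        self.candidates = candidates
        self.significant = significant
        self.thresholds = thresholds
        self.null = null
        self.fdr_cut = fdr_cut

    @property
    def n_hyper(self) -> int:
        return sum(1 for r in self.significant if r.direction == "hyper")

    @property
    def n_hypo(self) -> int:
        return sum(1 for r in self.significant if r.direction == "hypo")

    @property
    def fraction_hypo(self) -> float:
        """Fraction of significant regions hypomethylated with advancing age."""
        n = len(self.significant)
        return self.n_hypo / n if n else float("nan")


def run_dmr_pipeline(
    matrix: MethylationMatrix,
    pheno: PhenotypeTable,
    manifest,
    config=None,
) -> DMRResult:
    """End-to-end DMR discovery.

    cluster -> cross-hybridizing filter -> per-probe fit -> percentile
    thresholds -> candidate runs -> areas -> permutation null -> empirical p
    -> BH q -> keep q < fdr_cut.
    """
    from .clustering import cluster_probes, filter_cross_hybridizing
    from .config import RunConfig

    cfg = config or RunConfig()
    regions = cluster_probes(manifest, cfg.L)
    regions = filter_cross_hybridizing(regions, manifest, cfg.max_cross_hyb_fraction)
    stats = fit_probe_statistics(matrix, pheno, cfg.covariates, cfg.stat_type)
    th = percentile_thresholds(stats, cfg.upper_pct, cfg.lower_pct)
    candidates = detect_candidates(regions, stats, th, mode="dmr", manifest=manifest)
    null = permutation_null(
        matrix,
        pheno,
        regions,
        manifest,
        stat_type=cfg.stat_type,
        upper=cfg.upper_pct,
        lower=cfg.lower_pct,
        K=cfg.K,
        seed=cfg.substream("permutation"),
        frozen_thresholds=th if cfg.frozen_thresholds else None,
    )
    candidates = empirical_pvalues(candidates, null, laplace=cfg.laplace_p)
    qs = estimate_qvalues([r.p for r in candidates])
    candidates = [r.with_significance(r.p, float(q)) for r, q in zip(candidates, qs)]
    significant = [r for r in candidates if r.q < cfg.fdr_cut]
    return DMRResult(candidates, significant, th, null, cfg.fdr_cut)


# ---------------------------------------------------------------------------
# power comparison: single-probe vs region testing burden

#: asymptotic relative efficiency of the Wilcoxon-Mann-Whitney test vs the
#: t-test under a normal parent, and its distribution-free lower bound
ARE_NORMAL = 3.0 / np.pi
ARE_MIN = 0.864


def power_comparison(
    effect_size_d: float,
    n1: int,
    n2: int,
    alpha_family: float = 0.05,
    m_single: int = 450_000,
    m_region: int = 55_003,
    parent: str = "normal",
) -> tuple[float, float]:
    """Achieved power of a two-group Wilcoxon-Mann-Whitney test under
    Bonferroni correction, for single-probe vs region-level testing burdens.

    Normal approximation: the WMW test on standardized effect d behaves like
    a two-sample z-test on ARE-deflated sample sizes, so the power at
    per-test level alpha/m is Phi(ncp - z) + Phi(-ncp - z) with
    ncp = d * sqrt(ARE * n1 n2 / (n1 + n2)).
    """
    if m_single <= 0 or m_region <= 0:
        raise ValidationError("number of tests must be positive")
    if n1 < 2 or n2 < 2 or effect_size_d <= 0:
        raise ValidationError("need n1, n2 >= 2 and d > 0")
    are = {"normal": ARE_NORMAL, "min": ARE_MIN}[parent]
    ncp = effect_size_d * np.sqrt(are * n1 * n2 / (n1 + n2))

    def pw(m: int) -> float:
        z = sps.norm.ppf(1 - (alpha_family / m) / 2)
        return float(sps.norm.cdf(ncp - z) + sps.norm.cdf(-ncp - z))

    return pw(m_single), pw(m_region)
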