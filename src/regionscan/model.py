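"""Shared data model for region-centric methylation analysis.

Coordinates are 0-based half-open internally.  Probe anchor positions are
read as 1-based genomic coordinates (the convention of array manifests) and
converted on ingestion: an anchor at 1-based position ``pos`` occupies the
half-open interval ``[pos - 1, pos)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ISLAND_CATEGORIES",
    "ValidationError",
    "FormatError",
    "normalize_chrom",
    "ProbeManifest",
    "MethylationMatrix",
    "PhenotypeTable",
    "IntervalSet",
    "Region",
    "ScoredRegion",
    "Thresholds",
    "ProbeStatVector",
    "MADVector",
    "AR1Params",
    "NullAreaDistribution",
]

#: The six genomic categories used for CpG-island context annotation.
ISLAND_CATEGORIES = ("island", "n_shore", "s_shore", "n_shelf", "s_shelf", "open_sea")


class ValidationError(ValueError):
    """Input data violates a documented invariant."""


class FormatError(ValueError):
    """A file could not be interpreted under the declared column mapping."""


def normalize_chrom(name: str) -> str:
    """Normalise chromosome naming so that ``chr1`` and ``1`` compare equal."""
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s


class ProbeManifest:
    """Ordered per-chromosome probe coordinates with annotation.

    Wraps a DataFrame with columns ``probe_id``, ``chrom``, ``pos`` (1-based
    anchor), ``genes`` (frozenset of symbols), ``island_category`` and
    ``cross_hybridizing``.  Rows are sorted by ``(chrom, pos)`` on
    construction; iteration order is therefore a deterministic function of
    content only.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"probe_id", "chrom", "pos"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"manifest missing columns: {sorted(missing)}")
        df = df.copy()
        df["probe_id"] = df["probe_id"].astype(str)
        if df["probe_id"].duplicated().any():
            dups = df.loc[df["probe_id"].duplicated(), "probe_id"].tolist()[:5]
            raise ValidationError(f"duplicate probe ids: {dups}")
        df["chrom"] = df["chrom"].map(normalize_chrom)
        try:
            df["pos"] = df["pos"].astype(np.int64)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric probe position: {exc}") from None
        if "genes" not in df.columns:
            df["genes"] = [frozenset()] * len(df)
        else:
            df["genes"] = df["genes"].map(_as_gene_set)
        if "island_category" not in df.columns:
            df["island_category"] = "open_sea"
        else:
            bad = set(df["island_category"].unique()) - set(ISLAND_CATEGORIES)
            if bad:
                raise ValidationError(f"unknown island categories: {sorted(bad)}")
        if "cross_hybridizing" not in df.columns:
            df["cross_hybridizing"] = False
        df["cross_hybridizing"] = df["cross_hybridizing"].astype(bool)
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        self.df = df[["probe_id", "chrom", "pos", "genes", "island_category", "cross_hybridizing"]]
        self._index = pd.Index(self.df["probe_id"])

    def __len__(self) -> int:
        return len(self.df)

    @property
    def probe_ids(self) -> pd.Index:
        return self._index

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.df["pos"].to_numpy()

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def row_indexer(self, probe_ids: Iterable[str]) -> np.ndarray:
        idx = self._index.get_indexer(list(probe_ids))
        if (idx < 0).any():
            raise KeyError("probe id(s) not in manifest")
        return idx

    def genes_of(self, probe_id: str) -> frozenset:
        return self.df["genes"].iloc[self._index.get_loc(probe_id)]

    def subset(self, probe_ids: Iterable[str]) -> "ProbeManifest":
        return ProbeManifest(self.df.iloc[self.row_indexer(probe_ids)])


def _as_gene_set(value) -> frozenset:
    if isinstance(value, frozenset):
        return value
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return frozenset()
    if isinstance(value, (set, list, tuple)):
        return frozenset(str(g).strip().upper() for g in value if str(g).strip())
    return frozenset(g.strip().upper() for g in str(value).split(";") if g.strip())


class MethylationMatrix:
    """Probes x samples fractional methylation, aligned to a manifest.

    Values are floats in [0, 1]; missing entries are NaN (explicitly marked,
    never silently zero).  Sample columns are kept in canonical sorted order
    so downstream results do not depend on input column order.
    """

    #: numerical slack allowed outside [0, 1] before a value is rejected
    RANGE_TOL = 1e-9

    def __init__(self, values: pd.DataFrame, manifest: ProbeManifest | None = None):
        if values.columns.duplicated().any():
            raise ValidationError("sample id collision in matrix columns")
        values = values.astype(float)
        finite = values.to_numpy()
        with np.errstate(invalid="ignore"):
            bad = np.isfinite(finite) & (
                (finite < -self.RANGE_TOL) | (finite > 1 + self.RANGE_TOL)
            )
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"methylation value out of [0,1]: {finite[i, j]!r} at "
                f"probe {values.index[i]!r}, sample {values.columns[j]!r}"
            )
        values = values.clip(0.0, 1.0)
        values = values[sorted(values.columns)]
        if manifest is not None:
            keep = values.index.intersection(manifest.probe_ids)
            order = [p for p in manifest.probe_ids if p in set(keep)]
            self.n_dropped = len(values) - len(order)
            values = values.loc[order]
        else:
            self.n_dropped = 0
        self.values = values
        self.manifest = manifest

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationMatrix":
        out = MethylationMatrix.__new__(MethylationMatrix)
        out.values = self.values[sorted(sample_ids)]
        out.manifest = self.manifest
        out.n_dropped = 0
        return out


class PhenotypeTable:
    """Per-sample phenotype: age (years) and/or group label, plus covariates."""

    def __init__(self, df: pd.DataFrame):
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        df = df.copy()
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            raise ValidationError("duplicate sample ids in phenotype table")
        if "age" in df.columns:
            df["age"] = df["age"].astype(float)
            if (df["age"] < 0).any():
                raise ValidationError("negative age in phenotype table")
        self.df = df.sort_index()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def ages_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        if "age" not in self.df.columns:
            raise ValidationError("phenotype table has no 'age' column")
        missing = set(sample_ids) - set(self.df.index)
        if missing:
            raise ValidationError(f"samples missing from phenotype table: {sorted(missing)[:5]}")
        return self.df.loc[list(sample_ids), "age"].to_numpy()

    def group_samples(self, group: str, column: str = "group") -> list[str]:
        if column not in self.df.columns:
            raise ValidationError(f"phenotype table has no {column!r} column")
        return list(self.df.index[self.df[column].astype(str) == str(group)])


class IntervalSet:
    """Sorted half-open genomic intervals (0-based), optional score column."""

    def __init__(self, df: pd.DataFrame):
        required = {"chrom", "start", "end"}
        if required - set(df.columns):
            raise FormatError(f"interval table needs columns {sorted(required)}")
        df = df.copy()
        df["chrom"] = df["chrom"].map(normalize_chrom)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            raise ValidationError("interval with start >= end")
        self.df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def by_chrom(self) -> Mapping[str, pd.DataFrame]:
        return dict(tuple(self.df.groupby("chrom", sort=False)))


@dataclass(frozen=True)
class Region:
    """A maximal run of probes with every adjacent anchor gap <= L."""

    region_id: str
    chrom: str
    probe_ids: tuple[str, ...]
    start: int  # 0-based inclusive (first anchor start)
    end: int    # 0-based exclusive (last anchor end)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


@dataclass(frozen=True)
class Thresholds:
    """Percentile cut-offs on the per-probe statistic.

    ``q1`` is the upper cut (95th percentile of positive statistics, or of
    all MAD scores in variability mode); ``q2`` the lower cut (5th percentile
    of negative statistics), None in MAD mode.
    """

    q1: float
    q2: float | None = None

    def __post_init__(self):
        if self.q2 is not None and not (self.q1 > 0 > self.q2):
            raise ValidationError(f"expected q1 > 0 > q2, got q1={self.q1}, q2={self.q2}")


@dataclass(frozen=True)
class ScoredRegion:
    """A candidate region with its per-probe statistics and area statistic.

    ``p`` and ``q`` stay None until the region has been compared with a null
    area distribution.
    """

    region_id: str
    chrom: str
    probe_ids: tuple[str, ...]
    start: int
    end: int
    direction: str  # hyper | hypo | variable
    member_stats: tuple[float, ...]
    member_pos: tuple[int, ...]  # 1-based anchors, strictly increasing
    area: float
    p: float | None = None
    q: float | None = None

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def with_significance(self, p: float, q: float | None = None) -> "ScoredRegion":
        return replace(self, p=p, q=q)


@dataclass
class ProbeStatVector:
    """One differential statistic per probe, aligned to a matrix/manifest.

    ``stat_type`` is ``beta`` (regression slope on age), ``t`` (its
    t-statistic) or ``mad`` (median absolute deviation within a group).
    Undefined probes are NaN and are excluded from percentile computation.
    """

    values: pd.Series
    stat_type: str

    def __post_init__(self):
        if self.stat_type not in ("beta", "t", "mad"):
            raise ValidationError(f"unknown stat_type {self.stat_type!r}")
        self.values = self.values.astype(float)

    def defined(self) -> pd.Series:
        return self.values.dropna()


@dataclass
class MADVector:
    """Per-probe median absolute deviation within one sample group."""

    values: pd.Series
    group: str

    def __post_init__(self):
        v = self.values.dropna()
        if (v < 0).any():
            raise ValidationError("negative MAD")


@dataclass(frozen=True)
class AR1Params:
    """First-order autoregressive parameters: k_i = rho * k_{i-1} + e_i,
    e_i ~ N(0, sigma^2)."""

    rho: float
    sigma: float

    def __post_init__(self):
        if not (abs(self.rho) < 1):
            raise ValidationError(f"|rho| must be < 1, got {self.rho}")
        if not (self.sigma > 0 and math.isfinite(self.sigma)):
            raise ValidationError(f"sigma must be finite positive, got {self.sigma}")

    @property
    def marginal_sd(self) -> float:
        """Stationary (marginal) standard deviation of the process."""
        return self.sigma / math.sqrt(1.0 - self.rho**2)


@dataclass
class NullAreaDistribution:
    """Null region areas pooled across permutations / simulations."""

    areas: np.ndarray
    n_per_sim: tuple[int, ...]

    def __post_init__(self):
        self.areas = np.asarray(self.areas, dtype=float)
        if (self.areas < 0).any():
            raise ValidationError("negative null area")
        if self.areas.size != sum(self.n_per_sim):
            raise ValidationError("per-simulation counts do not sum to pool size")
        self._sorted = np.sort(self.areas)

    @property
    def n_simulations(self) -> int:
        return len(self.n_per_sim)

    def count_geq(self, area: float) -> int:
        """Number of pooled null areas >= ``area`` (ties count)."""
        return int(self._sorted.size - np.searchsorted(self._sorted, area, side="left"))
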