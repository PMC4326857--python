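"""Readers and writers for manifests, matrices, phenotypes, intervals and
region result tables.

All tabular IO is TSV by default with a configurable column mapping, so that
exports from different annotation releases can be ingested without editing
files.  Region tables are written both as TSV (full detail, round-trippable)
and BED6 (for genome-browser use).
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    FormatError,
    IntervalSet,
    MethylationMatrix,
    PhenotypeTable,
    ProbeManifest,
    ScoredRegion,
    ValidationError,
)

log = logging.getLogger(__name__)

MANIFEST_COLUMNS = {
    "probe_id": "probe_id",
    "chrom": "chrom",
    "pos": "pos",
    "genes": "genes",
    "island_category": "island_category",
    "cross_hybridizing": "cross_hybridizing",
}


def read_manifest(path, columns: Mapping[str, str] | None = None, sep: str = "\t") -> ProbeManifest:
    """Read a probe manifest table.

    ``columns`` maps canonical field names (keys of :data:`MANIFEST_COLUMNS`)
    to the column names present in the file; unmapped optional fields get
    defaults.  Probes are returned sorted by (chrom, pos).
    """
    mapping = dict(MANIFEST_COLUMNS)
    if columns:
        mapping.update(columns)
    df = pd.read_csv(path, sep=sep, dtype=str)
    for canon in ("probe_id", "chrom", "pos"):
        if mapping[canon] not in df.columns:
            raise FormatError(f"manifest file lacks required column {mapping[canon]!r}")
    out = pd.DataFrame({"probe_id": df[mapping["probe_id"]], "chrom": df[mapping["chrom"]]})
    pos = pd.to_numeric(df[mapping["pos"]], errors="coerce")
    if pos.isna().any():
        bad = df.loc[pos.isna(), mapping["pos"]].iloc[0]
        raise FormatError(f"non-numeric probe position {bad!r}")
    out["pos"] = pos.astype(np.int64)
    for opt in ("genes", "island_category", "cross_hybridizing"):
        if mapping[opt] in df.columns:
            col = df[mapping[opt]]
            if opt == "cross_hybridizing":
                col = col.fillna("0").isin(["1", "True", "true", "TRUE", "yes", "Y"])
            out[opt] = col
    return ProbeManifest(out)


def read_matrix(path, manifest: ProbeManifest | None = None, sep: str = "\t") -> MethylationMatrix:
    """Read a probes x samples methylation table (first column probe ids).

    Rows are reordered to manifest order; probes absent from the manifest are
    dropped with a logged count.  ``NA``/empty cells become missing values.
    """
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", "NaN", ""])
    df.index = df.index.astype(str)
    mat = MethylationMatrix(df, manifest)
    if mat.n_dropped:
        log.info("read_matrix: dropped %d probes absent from manifest", mat.n_dropped)
    return mat


def read_phenotypes(path, sep: str = "\t") -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep=sep, dtype={"sample_id": str}))


def read_intervals(path, sep: str = "\t") -> IntervalSet:
    """Read a BED-like interval file (chrom, start, end[, name, score])."""
    df = pd.read_csv(path, sep=sep, header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names + list(df.columns[len(names):])
    return IntervalSet(df)


def read_snps(path, sep: str = "\t") -> pd.DataFrame:
    """Read a SNP table with columns chrom, pos (1-based), maf."""
    df = pd.read_csv(path, sep=sep)
    need = {"chrom", "pos", "maf"}
    if need - set(df.columns):
        raise FormatError(f"SNP table needs columns {sorted(need)}")
    from .model import normalize_chrom

    df = df.copy()
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["pos"] = df["pos"].astype(np.int64)
    df["maf"] = df["maf"].astype(float)
    if ((df["maf"] < 0) | (df["maf"] > 0.5)).any():
        raise ValidationError("MAF outside [0, 0.5]")
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def read_gene_set(path, name: str | None = None):
    """Read a plain-text gene list, one symbol per line; symbols upper-cased."""
    from .enrichment import GeneSet

    with open(path) as fh:
        genes = {line.strip().upper() for line in fh if line.strip()}
    return GeneSet(name=name or str(path), genes=frozenset(genes))


REGION_TABLE_COLUMNS = [
    "region_id", "chrom", "start", "end", "n_probes", "probe_ids",
    "direction", "area", "p", "q",
]


def bed_score(p: float) -> int:
    """BED score line: min(1000, round(-10 * log10(max(p, 1e-100))))."""
    return min(1000, round(-10.0 * math.log10(max(p, 1e-100))))


def write_region_table(regions: Sequence[ScoredRegion], path, bed_path=None) -> None:
    """Write scored regions as a TSV, and optionally as BED6.

    Floats are written with shortest round-trip repr, so read-back reproduces
    areas and p/q values exactly.
    """
    rows = []
    for r in regions:
        if r.p is None or r.q is None:
            raise ValidationError(f"region {r.region_id} is unscored (p/q missing)")
        rows.append(
            {
                "region_id": r.region_id,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "n_probes": r.n_probes,
                "probe_ids": ";".join(r.probe_ids),
                "direction": r.direction,
                "area": repr(r.area),
                "p": repr(r.p),
                "q": repr(r.q),
                "member_stats": ";".join(repr(s) for s in r.member_stats),
                "member_pos": ";".join(str(x) for x in r.member_pos),
            }
        )
    df = pd.DataFrame(rows, columns=REGION_TABLE_COLUMNS + ["member_stats", "member_pos"])
    df.to_csv(path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for r in regions:
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t{bed_score(r.p)}\t.\n"
                )


def read_region_table(path) -> list[ScoredRegion]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        out.append(
            ScoredRegion(
                region_id=row["region_id"],
                chrom=row["chrom"],
                probe_ids=tuple(row["probe_ids"].split(";")),
                start=int(row["start"]),
                end=int(row["end"]),
                direction=row["direction"],
                member_stats=tuple(float(s) for s in row["member_stats"].split(";")),
                member_pos=tuple(int(x) for x in row["member_pos"].split(";")),
                area=float(row["area"]),
                p=float(row["p"]),
                q=float(row["q"]),
            )
        )
    return out
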