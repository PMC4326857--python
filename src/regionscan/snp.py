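"""SNP-free classification of probes and regions.

A probe is SNP free if no common variant (MAF above the cut, strictly) lies
within the probe body (50 bp downstream of the anchor) or within 100 bp
flanking either end: a 250-bp window in total.  A region is SNP free iff all
its member probes are.  Common variants near a probe can create apparent
inter-individual methylation variability (meQTL effects), which this filter
flags.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import Region, normalize_chrom

__all__ = ["probe_snp_free", "region_snp_free", "snp_free_fraction", "SNPIndex"]

PROBE_LEN = 50   # bp of genomic footprint downstream of the anchor
FLANK = 100      # bp beyond each end of the probe body


class SNPIndex:
    """Per-chromosome sorted positions of SNPs above a MAF cut (0-based)."""

    def __init__(self, snps: pd.DataFrame, maf_cut: float = 0.05):
        kept = snps[snps["maf"] > maf_cut]  # "maximum MAF > 5%": strict
        self._by_chrom = {
            normalize_chrom(c): np.sort(sub["pos"].to_numpy(np.int64)) - 1
            for c, sub in kept.groupby("chrom")
        }

    def any_in(self, chrom: str, start0: int, end0: int) -> bool:
        pos = self._by_chrom.get(normalize_chrom(chrom))
        if pos is None or pos.size == 0:
            return False
        lo = np.searchsorted(pos, start0, side="left")
        hi = np.searchsorted(pos, end0, side="left")
        return hi > lo


def probe_snp_free(
    chrom: str,
    pos: int,
    snps: pd.DataFrame | SNPIndex,
    maf_cut: float = 0.05,
    probe_len: int = PROBE_LEN,
    flank: int = FLANK,
) -> bool:
    """True iff no SNP with MAF > ``maf_cut`` lies in the half-open window
    [anchor - flank, anchor + probe_len + flank), 0-based.

    ``pos`` is the 1-based anchor coordinate as annotated in the manifest.
    """
    index = snps if isinstance(snps, SNPIndex) else SNPIndex(snps, maf_cut)
    anchor0 = int(pos) - 1
    return not index.any_in(chrom, anchor0 - flank, anchor0 + probe_len + flank)


def region_snp_free(
    region: Region,
    snps: pd.DataFrame | SNPIndex,
    manifest=None,
    maf_cut: float = 0.05,
    probe_len: int = PROBE_LEN,
    flank: int = FLANK,
) -> bool:
    """True iff every member probe of the region is SNP free."""
    index = snps if isinstance(snps, SNPIndex) else SNPIndex(snps, maf_cut)
    anchors = _member_anchors(region, manifest)
    return all(
        probe_snp_free(region.chrom, a, index, maf_cut, probe_len, flank)
        for a in anchors
    )


def _member_anchors(region, manifest) -> list[int]:
    if getattr(region, "member_pos", None):
        return list(region.member_pos)
    if manifest is None:
        raise ValueError("need a manifest to resolve probe anchors")
    return list(manifest.pos[manifest.row_indexer(region.probe_ids)])


def snp_free_fraction(
    region_lists: dict[str, list],
    snps: pd.DataFrame | SNPIndex,
    manifest=None,
    maf_cut: float = 0.05,
) -> pd.DataFrame:
    """Per named list: count and fraction of SNP-free regions.

    Fractions are reported as percentages rounded to one decimal; empty
    lists report NA.
    """
    index = snps if isinstance(snps, SNPIndex) else SNPIndex(snps, maf_cut)
    rows = []
    for name, regions in region_lists.items():
        n_total = len(regions)
        n_free = sum(
            1 for r in regions if region_snp_free(r, index, manifest, maf_cut)
        )
        rows.append(
            {
                "list_name": name,
                "n_free": n_free,
                "n_total": n_total,
                "fraction_pct": round(100.0 * n_free / n_total, 1) if n_total else np.nan,
            }
        )
    return pd.DataFrame(rows)
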