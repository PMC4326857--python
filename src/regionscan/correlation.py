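"""Correlation of methylation values between neighbouring probes.

Enumerates all probe pairs within a genomic window, bins them by distance
into near-equal-count bins, and computes a Pearson correlation of the two
members' methylation values (one sample) across the pairs of each bin.  The
decay of this correlation with distance motivates the choice of the
clustering distance L.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .model import MethylationMatrix, ProbeManifest

__all__ = ["enumerate_pairs", "binned_correlation"]


def enumerate_pairs(
    manifest: ProbeManifest, window: int = 100_000, tiling: bool = False
) -> pd.DataFrame:
    """All unordered same-chromosome probe pairs with distance <= window.

    Returns a DataFrame with manifest row indices ``idx_a``/``idx_b`` and
    ``distance`` in bp.  With ``tiling=True``, pairs are instead restricted to
    probes falling inside the same fixed window-sized tile (pairs straddling a
    tile boundary are missed; kept for comparison with tiled analyses).
    """
    chrom = manifest.chrom
    pos = manifest.pos
    ia, ib, dist = [], [], []
    for c in manifest.chromosomes():
        idx = np.flatnonzero(chrom == c)
        p = pos[idx]
        if tiling:
            tiles = p // window
        for i in range(len(idx)):
            j = i + 1
            while j < len(idx) and p[j] - p[i] <= window:
                if not tiling or tiles[j] == tiles[i]:
                    ia.append(idx[i])
                    ib.append(idx[j])
                    dist.append(p[j] - p[i])
                j += 1
    return pd.DataFrame(
        {
            "idx_a": np.asarray(ia, dtype=np.int64),
            "idx_b": np.asarray(ib, dtype=np.int64),
            "distance": np.asarray(dist, dtype=np.int64),
        }
    )


def binned_correlation(
    pairs: pd.DataFrame, sample_values: np.ndarray, n_bins: int = 50
) -> pd.DataFrame:
    """Distance-binned Pearson correlation over probe pairs for one sample.

    Pairs are sorted by distance and split into ``n_bins`` contiguous chunks
    whose sizes differ by at most one.  Per bin: median distance, Pearson r of
    (value_a, value_b) across the bin's pairs, and the pair count.  A bin with
    zero variance on either coordinate gets r = NaN (undefined) without
    affecting other bins.
    """
    if len(pairs) < 2 * n_bins:
        raise ValueError(f"need >= 2 pairs per bin: {len(pairs)} pairs, {n_bins} bins")
    sample_values = np.asarray(sample_values, dtype=float)
    order = np.argsort(pairs["distance"].to_numpy(), kind="stable")
    d = pairs["distance"].to_numpy()[order]
    va = sample_values[pairs["idx_a"].to_numpy()[order]]
    vb = sample_values[pairs["idx_b"].to_numpy()[order]]
    rows = []
    for chunk in np.array_split(np.arange(len(d)), n_bins):
        a, b = va[chunk], vb[chunk]
        if np.std(a) == 0 or np.std(b) == 0 or np.isnan(a).any() or np.isnan(b).any():
            r = np.nan
        else:
            r = stats.pearsonr(a, b).statistic
        rows.append(
            {
                "median_distance": float(np.median(d[chunk])),
                "pearson_r": r,
                "n_pairs": len(chunk),
            }
        )
    return pd.DataFrame(rows)
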