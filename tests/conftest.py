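import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import regionscan as rs

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_manifest(positions, chrom="chr1", **extra):
    """Minimal manifest from a list of 1-based anchors (single chromosome)."""
    if isinstance(positions, dict):
        rows = []
        for c, ps in positions.items():
            rows += [{"probe_id": f"{c}_{p}", "chrom": c, "pos": p} for p in ps]
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(len(positions))],
                "chrom": chrom,
                "pos": list(positions),
            }
        )
    for k, v in extra.items():
        df[k] = v
    return rs.ProbeManifest(df)


def brute_cluster(manifest, L):
    """O(n^2)-style reference clustering: walk probes, break on chromosome
    change or gap > L, keep runs of >= 2 probes."""
    out = []
    run = []
    rows = list(manifest.df.itertuples())
    for i, r in enumerate(rows):
        if run and (r.chrom != rows[i - 1].chrom or r.pos - rows[i - 1].pos > L):
            if len(run) >= 2:
                out.append(tuple(x.probe_id for x in run))
            run = []
        run.append(r)
    if len(run) >= 2:
        out.append(tuple(x.probe_id for x in run))
    return out


def recovered_fraction(significant, truth):
    """Fraction of planted regions overlapped by >= 1 significant call."""
    truth_sets = [set(r.split(";")) for r in truth["probe_ids"]]
    if not truth_sets:
        return float("nan")
    hits = sum(
        any(set(s.probe_ids) & t for s in significant) for t in truth_sets
    )
    return hits / len(truth_sets)


def off_truth_fraction(significant, truth):
    """Fraction of significant calls not overlapping any planted region."""
    truth_sets = [set(r.split(";")) for r in truth["probe_ids"]]
    if not significant:
        return 0.0
    off = sum(
        1 for s in significant if not any(set(s.probe_ids) & t for t in truth_sets)
    )
    return off / len(significant)


@pytest.fixture
def toy_manifest():
    return make_manifest([100, 600, 1500, 4000, 4500])


@pytest.fixture
def random_manifest():
    rng = np.random.default_rng(1234)
    pos = np.sort(rng.choice(np.arange(100, 300_000), size=200, replace=False))
    return make_manifest(pos.tolist())
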