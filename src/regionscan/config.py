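"""Run configuration shared by the pipelines and the CLI.

A single global seed is expanded into named per-stage substreams
(permutation, bootstrap, simulation) so each stochastic stage is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .model import ValidationError

_STAGE_OFFSETS = {"permutation": 1, "bootstrap": 2, "simulation": 3, "overlap": 4}


@dataclass
class RunConfig:
    L: int = 1000                   # clustering distance threshold, bp
    upper_pct: float = 95.0         # upper percentile cut on the statistic
    lower_pct: float = 5.0          # lower percentile cut (signed mode)
    K: int = 100                    # phenotype permutations
    n_sim: int = 100                # parametric-bootstrap simulations (VMR)
    fdr_cut: float = 0.05           # keep regions with q below this
    seed: int = 0
    stat_type: str = "beta"         # beta | t
    covariates: list[str] | None = None
    max_cross_hyb_fraction: float = 0.2
    min_probes_ar: int = 50         # min probes per region for AR(1) fitting
    log_floor: float = 1e-6         # MAD floor before log transform
    laplace_p: bool = False         # (1+c)/(1+N) empirical p smoothing
    frozen_thresholds: bool = False # reuse observed cuts inside permutations
    literal_overlap_direction: bool = False
    columns: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 < self.lower_pct < self.upper_pct < 100):
            raise ValidationError("need 0 < lower_pct < upper_pct < 100")
        if self.K < 1:
            raise ValidationError("K must be >= 1")
        if not (0 < self.fdr_cut <= 1):
            raise ValidationError("fdr_cut must be in (0, 1]")
        if self.L <= 0:
            raise ValidationError("L must be positive")

    def substream(self, stage: str) -> np.random.SeedSequence:
        """Deterministic per-stage seed derived from the global seed."""
        return np.random.SeedSequence(entropy=self.seed, spawn_key=(_STAGE_OFFSETS[stage],))

    def to_dict(self) -> dict:
        return asdict(self)
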