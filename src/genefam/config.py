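"""Pipeline configuration: every tunable threshold with its default.

Defaults mirror the published analysis protocol this package re-implements:
a 1e-10 e-value gate for the domain scan, a 1e-20 gate (plus best-hit ratio
and 50% coverage) for paralog similarity, a 200-kb window for tandem
duplication, a 6-gene gap for collinear blocks, 1000 bootstrap replicates
with collapse below 50% support, a neutral substitution rate of
2.6e-9 /site/year for dating, FPKM > 1 for "expressed", 2-fold / one-half
for stress up/down calls, a 0.5 correlation cut for expression patterns,
and at most 8 motifs of width 8-100.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass
class PipelineConfig:
    domain_evalue: float = 1e-10
    similarity_evalue: float = 1e-20
    best_hit_ratio: float = 1e-20  # multiplier on the best non-self-hit e-value
    min_coverage: float = 0.5
    tandem_window: int = 200_000  # bp
    collinearity_gap: int = 6  # max intervening non-anchor genes
    min_anchors: int = 2
    bootstrap_replicates: int = 1000
    collapse_support: float = 50.0  # percent
    neutral_rate_r: float = 2.6e-9  # substitutions/site/year
    fpkm_expressed: float = 1.0
    fold_up: float = 2.0
    fold_down: float = 0.5
    cluster_threshold: float = 0.5  # Pearson correlation cut
    max_motifs: int = 8
    motif_width_range: tuple[int, int] = (8, 100)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in fields(self):
            if f.name in ("rng_seed", "motif_width_range"):
                continue
            value = getattr(self, f.name)
            if not value > 0:
                raise ValueError(f"config threshold {f.name} must be strictly positive, got {value!r}")
        if not (self.fold_down < 1.0 < self.fold_up):
            raise ValueError(
                f"fold thresholds must satisfy fold_down < 1 < fold_up, "
                f"got {self.fold_down}, {self.fold_up}"
            )
        lo, hi = self.motif_width_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid motif width range {self.motif_width_range}")


DEFAULT_CONFIG = PipelineConfig()
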