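"""Analysis cut-offs shared by every stage.

The defaults are the study's printed values: 1.5-fold change with raw
P < 0.02 for differential expression, a 1-SD margin for the
greater-than-additive synergy rule, gene windows of gene body +/- 50 kb,
receptor-to-mark proximity of 1 kb, and a 300-gene random control cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class Thresholds:
    """Cut-offs for DE calling, synergy, and peak-proximity mapping.

    Parameters
    ----------
    fc_cutoff : float
        Fold-change ratio required to call a probe differentially
        expressed (down-regulation uses the reciprocal, symmetric on
        the log2 scale). Must exceed 1.
    alpha_de : float
        Per-probe p-value cut-off for DE and for the synergy Welch test.
    alpha_refine : float
        P-value cut-off for the intersection refinement test
        (combined treatment vs single hormone).
    sd_multiplier : float
        Number of standard deviations the combined signal must depart
        from the additive expectation (synergy criterion 2).
    flank_bp : int
        Flank added on each side of the gene body when searching for
        receptor peaks.
    proximity_bp : int
        Maximum edge-to-edge gap between a receptor peak and an
        enhancer-mark peak for the pair to count as co-localized.
    n_control_genes : int
        Size of the random non-regulated control cohort.
    rng_seed : int
        Seed for the control-cohort sampler and any other stage
        randomness.
    """

    fc_cutoff: float = 1.5
    alpha_de: float = 0.02
    alpha_refine: float = 0.05
    sd_multiplier: float = 1.0
    flank_bp: int = 50_000
    proximity_bp: int = 1_000
    n_control_genes: int = 300
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.fc_cutoff > 1:
            raise ValueError(f"fc_cutoff must exceed 1, got {self.fc_cutoff}")
        for name in ("alpha_de", "alpha_refine"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {a}")
        if self.sd_multiplier < 0:
            raise ValueError("sd_multiplier must be non-negative")
        for name in ("flank_bp", "proximity_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_control_genes <= 0:
            raise ValueError("n_control_genes must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Thresholds":
        known = {k: d[k] for k in cls.__dataclass_fields__ if k in d}
        return cls(**known)
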