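"""Parameter containers shared across the pipeline stages.

Each dataclass validates its fields on construction and raises
:class:`~vigornet.errors.ConfigError` naming the offending field, so a bad
YAML config fails fast with an actionable message.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ConfigError

#: Crosstalk categories are numbered 1..8; see :mod:`vigornet.crosstalk`.
CATEGORY_IDS = tuple(range(1, 9))


@dataclass(frozen=True)
class CrosstalkThresholds:
    """Differential-calling thresholds for the transcript and protein layers.

    Transcripts are called with a fold-change and an adjusted-P rule
    (FC > ``t_fc`` with adj. P < ``t_alpha`` is *up*; FC < 1/``t_fc`` with
    adj. P < ``t_alpha`` is *down*).  Proteins are called on the
    quantitative ratio alone (ratio > ``p_ratio`` up, ratio < 1/``p_ratio``
    down).  All inequalities are strict; boundary values are *unchanged*.
    """

    t_fc: float = 1.2
    t_alpha: float = 0.05
    p_ratio: float = 1.3

    def __post_init__(self) -> None:
        if not self.t_fc > 1:
            raise ConfigError(f"t_fc must be > 1, got {self.t_fc}")
        if not 0 < self.t_alpha < 1:
            raise ConfigError(f"t_alpha must be in (0, 1), got {self.t_alpha}")
        if not self.p_ratio > 1:
            raise ConfigError(f"p_ratio must be > 1, got {self.p_ratio}")

    @property
    def ratio_down_bound(self) -> float:
        """Lower protein ratio bound, 1/p_ratio (0.769... for 1.3)."""
        return 1.0 / self.p_ratio


@dataclass(frozen=True)
class ConsensusParams:
    """Parameters of the subsample-consensus network ensemble.

    ``n_subsets`` half-size subsamples are drawn independently; an edge
    enters the consensus network when it recurs in at least
    ``min_count = ceil(confidence * n_subsets)`` subset networks
    (30 subsets at 60% confidence give 18).
    """

    n_subsets: int = 30
    subset_fraction: float = 0.5
    confidence: float = 0.6
    max_regulators_per_target: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subsets < 1:
            raise ConfigError(f"n_subsets must be >= 1, got {self.n_subsets}")
        if not 0 < self.subset_fraction <= 1:
            raise ConfigError(
                f"subset_fraction must be in (0, 1], got {self.subset_fraction}"
            )
        if not 0 < self.confidence <= 1:
            raise ConfigError(f"confidence must be in (0, 1], got {self.confidence}")
        if self.max_regulators_per_target < 1:
            raise ConfigError(
                "max_regulators_per_target must be >= 1, got "
                f"{self.max_regulators_per_target}"
            )

    @property
    def min_count(self) -> int:
        """Occurrence threshold: ceil(confidence * n_subsets)."""
        return math.ceil(self.confidence * self.n_subsets)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic-data generator.

    Defaults describe a desk-scale stand-in for a multi-experiment
    expression compendium: 300 genes in 60 samples, 20 designated
    regulator genes each driving 8 targets with a log-scale coefficient of
    1.5 against Gaussian noise of SD 0.5.
    """

    n_samples: int = 60
    n_genes: int = 300
    n_factors: int = 20
    targets_per_factor: int = 8
    effect_size: float = 1.5
    noise_sd: float = 0.5
    planted_category_counts: dict[int, int] = field(
        default_factory=lambda: {c: 10 for c in CATEGORY_IDS}
    )
    ppi_edges: int = 200
    ppi_score_range: tuple[int, int] = (0, 1000)
    n_mirna_targets: int = 14
    output_scale: str = "linear"  # "linear" (FPKM-like) or "log"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genes", "n_factors", "targets_per_factor",
                     "ppi_edges", "n_mirna_targets"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ConfigError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.n_factors >= self.n_genes:
            raise ConfigError(
                f"n_factors must be < n_genes, got {self.n_factors} >= {self.n_genes}"
            )
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        lo, hi = self.ppi_score_range
        if not (0 <= lo <= hi <= 1000):
            raise ConfigError(
                f"ppi_score_range must satisfy 0 <= lo <= hi <= 1000, got {self.ppi_score_range}"
            )
        max_pairs = self.n_genes * (self.n_genes - 1) // 2
        if self.ppi_edges > max_pairs:
            raise ConfigError(
                f"ppi_edges exceeds the number of unordered gene pairs ({max_pairs})"
            )
        for cat, cnt in self.planted_category_counts.items():
            if cat not in CATEGORY_IDS:
                raise ConfigError(f"planted_category_counts: unknown category {cat}")
            if cnt < 0:
                raise ConfigError(
                    f"planted_category_counts[{cat}] must be >= 0, got {cnt}"
                )
        if sum(self.planted_category_counts.values()) > self.n_genes:
            raise ConfigError(
                "planted_category_counts: total exceeds n_genes "
                f"({sum(self.planted_category_counts.values())} > {self.n_genes})"
            )
        if self.n_mirna_targets > self.n_genes:
            raise ConfigError("n_mirna_targets exceeds n_genes")
        if self.output_scale not in ("linear", "log"):
            raise ConfigError(
                f"output_scale must be 'linear' or 'log', got {self.output_scale!r}"
            )
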