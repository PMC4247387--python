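"""Analysis configuration: every tunable threshold of the pipeline in one place."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

from .errors import ConfigurationError


@dataclass
class AnalysisConfig:
    """Thresholds and knobs shared across pipeline stages.

    The defaults encode the study conventions: quantifiability requires >= 2
    unique peptides and identification in 14 of 15 samples; age association
    requires one-way ANOVA and Pearson-vs-age both at p <= 0.05 (0.1 in
    subset mode); equivalence uses a fixed range of 0.3 on the log10 scale;
    abundance is binned into four classes; enrichment keeps raw p <= 0.01
    and discards sets with <= 5 background members; overlapping terms are
    grouped at Cohen's kappa >= 0.5.
    """

    min_unique_peptides: int = 2
    min_samples_identified_fraction: float = 14 / 15
    anova_alpha: float = 0.05
    pearson_alpha: float = 0.05
    subset_alpha: float = 0.1
    equivalence_epsilon: float = 0.3  # log10 units
    tost_alpha: float = 0.05
    tost_welch: bool = False
    n_abundance_classes: int = 4
    abundance_mode: str = "width"  # "width" (equal log10 width) or "count"
    mrna_low_median_quantile: float = 0.25
    enet_mixing_alpha: float = 0.5
    cv_folds: int = 10
    lambda_rule: str = "1se"  # "1se" (default) or "min"
    enrich_alpha: float = 0.01
    min_set_size: int = 6  # discard sets with <= 5 background members
    kappa_threshold: float = 0.5
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("anova_alpha", "pearson_alpha", "subset_alpha", "tost_alpha",
                     "enrich_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigurationError(f"{name} must be in (0,1), got {v}")
        if self.equivalence_epsilon <= 0:
            raise ConfigurationError("equivalence_epsilon must be > 0")
        if self.n_abundance_classes < 2:
            raise ConfigurationError("n_abundance_classes must be >= 2")
        if not 0 < self.enet_mixing_alpha <= 1:
            raise ConfigurationError("enet_mixing_alpha must be in (0,1]")
        if not 0 <= self.min_samples_identified_fraction <= 1:
            raise ConfigurationError("min_samples_identified_fraction must be in [0,1]")
        if self.abundance_mode not in ("width", "count"):
            raise ConfigurationError("abundance_mode must be 'width' or 'count'")
        if self.lambda_rule not in ("min", "1se"):
            raise ConfigurationError("lambda_rule must be 'min' or '1se'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
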