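"""Per-stage configuration blocks, loadable from YAML.

Every stochastic stage takes an explicit seed; thresholds are validated
against their legal ranges at construction.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .types import ValidationError


@dataclass
class SimulateConfig:
    n_samples: int = 96
    min_age: float = 0.15
    max_age: float = 25.0
    n_sites: int = 2000
    frac_clock: float = 0.025
    frac_pacemaker: float = 0.15
    noise_sd: float = 0.01
    curve_a: float = 5.0
    curve_c: float = 1.0
    tissue_effect_sd: float = 0.01
    sex_effect_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.frac_clock <= 1 and 0 <= self.frac_pacemaker <= 1):
            raise ValidationError("site fractions must be in [0,1]")
        if self.frac_clock + self.frac_pacemaker > 1:
            raise ValidationError("site fractions sum above 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not (0 <= self.min_age < self.max_age):
            raise ValidationError("need 0 <= min_age < max_age")


@dataclass
class ClockConfig:
    tissue: str | None = None
    alpha: float = 0.5
    transform: str = "sqrt"
    offset: float = 0.0
    cv_folds: int | str = "loo"  # 'loo' or k >= 2
    lambda_rule: str = "1se"  # or 'min'
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-3
    tol: float = 1e-7
    cv_tol: float = 1e-4
    max_iter: int = 100_000
    seed: int = 0  # k-fold shuffling

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValidationError("alpha must be in [0,1]")
        if self.transform not in ("sqrt", "identity"):
            raise ValidationError(f"unknown transform {self.transform!r}")
        if self.cv_folds != "loo" and int(self.cv_folds) < 2:
            raise ValidationError("cv_folds must be 'loo' or an int >= 2")
        if self.lambda_rule not in ("min", "1se"):
            raise ValidationError(f"unknown lambda_rule {self.lambda_rule!r}")


@dataclass
class EPMConfig:
    r_threshold: float = 0.75
    tol: float = 1e-6
    max_iter: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.r_threshold <= 1:
            raise ValidationError("r_threshold must be in (0,1]")


@dataclass
class FilterConfig:
    """Hard-filter thresholds (GATK-style) plus frequency filters."""

    qd_min: float = 2.0
    fs_max: float = 60.0
    sor_max: float = 3.0
    mq_min: float = 40.0
    mq_rank_sum_min: float = -12.5
    read_pos_rank_sum_min: float = -8.0
    maf_min: float = 0.01
    min_mac: int = 0  # set 3 to drop singletons and private doubletons


@dataclass
class ROHConfig:
    window_snps: int = 150
    window_het: int = 0
    window_missing: int = 2
    hit_frac: float = 0.05
    min_snps: int = 150
    min_length_kb: float = 1500.0

    def __post_init__(self) -> None:
        if self.window_snps < 1 or self.min_snps < 1:
            raise ValidationError("window_snps and min_snps must be >= 1")
        if not 0 < self.hit_frac <= 1:
            raise ValidationError("hit_frac must be in (0,1]")


@dataclass
class AccelConfig:
    method: str = "residual"  # 'difference' | 'residual' | 'residual_methods_literal'
    hc_flavor: str = "HC3"
    exclude_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.method not in ("difference", "residual", "residual_methods_literal"):
            raise ValidationError(f"unknown accel method {self.method!r}")
        if self.hc_flavor not in ("HC0", "HC1", "HC3"):
            raise ValidationError(f"unknown HC flavor {self.hc_flavor!r}")


@dataclass
class EWASConfig:
    alpha: float = 1e-4
    top_k: int = 500
    z_cap: float = 40.0
    weighted: bool = True  # Stouffer weights sqrt(n) per tissue

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0,1)")


@dataclass
class PipelineConfig:
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    clock: ClockConfig = field(default_factory=ClockConfig)
    epm: EPMConfig = field(default_factory=EPMConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    roh: ROHConfig = field(default_factory=ROHConfig)
    accel: AccelConfig = field(default_factory=AccelConfig)
    ewas: EWASConfig = field(default_factory=EWASConfig)
    screened_length_bp: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        blocks = {}
        for name, sub in (
            ("simulate", SimulateConfig),
            ("clock", ClockConfig),
            ("epm", EPMConfig),
            ("filters", FilterConfig),
            ("roh", ROHConfig),
            ("accel", AccelConfig),
            ("ewas", EWASConfig),
        ):
            blocks[name] = sub(**raw.get(name, {}))
        return cls(**blocks, screened_length_bp=raw.get("screened_length_bp"))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
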