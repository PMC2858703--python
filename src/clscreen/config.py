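"""Screen-simulation configuration.

All tunables of the synthetic pooled screen live in one flat dataclass so a
run is fully described by a single YAML file plus a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Sampling days of the screen; day 1 is the reference channel.
DEFAULT_SAMPLE_DAYS: tuple[int, ...] = (1, 9, 21, 33)

#: Growth conditions: NR = 2% glucose, CR = 0.5% glucose.
CONDITIONS: tuple[str, str] = ("NR", "CR")

#: Lifespan classes planted by the simulator.
CLASSES: tuple[str, ...] = ("short", "normal", "long", "cr_unresponsive")


@dataclass
class PoolConfig:
    """Parameters of the simulated pooled aging screen.

    Times are in days, intensities in arbitrary fluorescence units on the
    scale of recovered-cell counts.
    """

    # sampling design
    sample_days: tuple[int, ...] = DEFAULT_SAMPLE_DAYS
    conditions: tuple[str, ...] = CONDITIONS
    plating_depth: int = 2_000_000

    # pool composition
    n_mutants: int = 4800
    n_essential: int = 1000
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "short": 0.05,
            "normal": 0.86,
            "long": 0.05,
            "cr_unresponsive": 0.04,
        }
    )

    # survival-law parameters (Weibull S(d) = exp(-(d/tau)^k)).
    # The "normal" class is WT-like and tight by definition; planted
    # phenotype classes scale tau by a factor with its own spread
    # (deletion effect sizes are heterogeneous).
    tau_nr_mean: float = 12.0
    tau_nr_sd: float = 0.3
    tau_min: float = 1.0
    shape_k: float = 1.5
    cr_tau_factor: float = 1.6
    short_tau_factor: float = 1.0 / 3.0
    short_tau_factor_sd: float = 0.10
    long_tau_factor: float = 3.0
    long_tau_factor_sd: float = 0.6

    # tag hybridization
    eff_low: float = 0.4
    eff_high: float = 1.0
    missing_tag_prob: float = 0.005

    # adaptive regrowth ("gasping")
    regrowth_prob: float = 0.005
    regrowth_factor: float = 25.0

    # intensity noise
    noise_cv: float = 0.05
    background_mean: float = 10.0
    background_cv: float = 0.25

    # initial pool-fraction dispersion (log-normal sigma before normalizing)
    abundance_sigma: float = 0.25

    seed: int = 0

    def __post_init__(self) -> None:
        self.sample_days = tuple(int(d) for d in self.sample_days)
        self.conditions = tuple(self.conditions)
        if len(self.sample_days) < 2 or list(self.sample_days) != sorted(
            set(self.sample_days)
        ):
            raise ValueError("sample_days must be strictly increasing with >= 2 days")
        if self.plating_depth <= 0:
            raise ValueError("plating_depth must be positive")
        for name in ("noise_cv", "background_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.background_mean <= 0:
            raise ValueError("background_mean must be positive")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions must sum to 1, got {total}")
        unknown = set(self.class_fractions) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown lifespan classes: {sorted(unknown)}")

    @property
    def reference_day(self) -> int:
        return self.sample_days[0]

    @property
    def later_days(self) -> tuple[int, ...]:
        return self.sample_days[1:]

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["sample_days"] = list(self.sample_days)
        data["conditions"] = list(self.conditions)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PoolConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} did not parse to a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
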