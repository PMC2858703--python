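"""Synthetic pooled-deletion-collection aging screen.

Generates two-channel tag-intensity tables with known ground truth so that
the ratio/calling pipeline can be exercised and validated without array
data.  The population model: each viable deletion mutant g dies off in
stationary phase following a Weibull survival law

    S_g(d) = exp(-(d / tau_g,c)^k),

with a per-condition characteristic time tau (calorie restriction raises
tau for CR-responsive mutants).  Survivors recovered by plating a fixed
sampling depth are a multinomial draw over the pool; barcode intensities
are counts scaled by per-gene tag efficiencies, corrupted by multiplicative
log-normal noise, plus an additive nonspecific-hybridization background.
Probes for essential genes have no corresponding mutant in the pool and
therefore receive background signal only.  Occasional adaptive-regrowth
("gasping") events multiply a mutant's viable count from a random later
day onward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from clscreen.config import CLASSES, PoolConfig

TAGS = ("UP", "DN")

# fixed stage labels -> independent child RNG streams of the master seed
_STAGE = {"pool": 1, "aging": 2, "plating": 3, "intensity": 4}


def _stage_rng(seed: int, stage: str, *extra: int) -> np.random.Generator:
    """Deterministic per-stage RNG derived from one master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _STAGE[stage], *map(int, extra)])
    )


@dataclass
class MutantProfile:
    """Ground-truth parameters for one gene's barcoded deletion mutant."""

    gene_id: str
    essential: bool
    tau_nr: float
    tau_cr: float
    shape_k: float
    initial_abundance: float
    uptag_eff: float
    dntag_eff: float
    uptag_missing: bool = False
    dntag_missing: bool = False
    regrowth_prob: float = 0.0
    true_class: str = "normal"

    def __post_init__(self) -> None:
        if self.tau_nr <= 0 or self.tau_cr <= 0:
            raise ValueError(f"{self.gene_id}: tau must be positive")
        if self.essential and self.initial_abundance != 0:
            raise ValueError(f"{self.gene_id}: essential genes have no mutant in the pool")
        for eff, missing in ((self.uptag_eff, self.uptag_missing),
                             (self.dntag_eff, self.dntag_missing)):
            if not missing and not (0 < eff <= 1):
                raise ValueError(f"{self.gene_id}: tag efficiency must be in (0, 1]")
        if self.true_class not in CLASSES:
            raise ValueError(f"{self.gene_id}: unknown class {self.true_class!r}")

    def tau(self, condition: str) -> float:
        return self.tau_nr if condition == "NR" else self.tau_cr

    def tag_eff(self, tag: str) -> float:
        return self.uptag_eff if tag == "UP" else self.dntag_eff

    def tag_missing(self, tag: str) -> bool:
        return self.uptag_missing if tag == "UP" else self.dntag_missing


@dataclass
class ScreenTruth:
    """Realized per-gene truth of one simulated screen."""

    classes: dict[str, str]
    #: condition -> DataFrame (genes x days) of Weibull survival fractions
    survival: dict[str, pd.DataFrame]
    #: (gene, condition) -> day the regrowth jump fired, if any
    regrowth_day: dict[tuple[str, str], int] = field(default_factory=dict)

    def to_frame(self, profiles: Sequence[MutantProfile]) -> pd.DataFrame:
        by_id = {p.gene_id: p for p in profiles}
        rows = []
        for gene, cls in self.classes.items():
            p = by_id[gene]
            rows.append(
                {
                    "gene_id": gene,
                    "true_class": cls,
                    "essential": p.essential,
                    "tau_nr": p.tau_nr,
                    "tau_cr": p.tau_cr,
                    "regrowth_day_nr": self.regrowth_day.get((gene, "NR"), ""),
                    "regrowth_day_cr": self.regrowth_day.get((gene, "CR"), ""),
                }
            )
        return pd.DataFrame(rows)


def weibull_survival(day: float, tau: float, k: float) -> float:
    """S(d) = exp(-(d/tau)^k); the simulator's survival law."""
    return float(np.exp(-((day / tau) ** k)))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, size: int) -> np.ndarray:
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size - filled)
        keep = draw[draw >= low]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def _apportion(n: int, fractions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n mutants to classes."""
    items = sorted(fractions.items())
    exact = {c: n * f for c, f in items}
    counts = {c: int(np.floor(v)) for c, v in exact.items()}
    short = n - sum(counts.values())
    by_remainder = sorted(items, key=lambda cf: exact[cf[0]] - counts[cf[0]], reverse=True)
    for c, _ in by_remainder[:short]:
        counts[c] += 1
    return counts


def build_pool(
    n_mutants: int,
    class_fractions: Mapping[str, float] | None = None,
    seed: int = 0,
    config: PoolConfig | None = None,
) -> list[MutantProfile]:
    """Construct the pooled population of barcoded deletion mutants.

    ``n_mutants`` viable mutants are assigned lifespan classes by
    largest-remainder apportionment of ``class_fractions``; tau_nr is drawn
    from a truncated normal, scaled down for the short class and up for the
    long class, and tau_cr = cr_tau_factor * tau_nr except for the
    cr_unresponsive class (tau_cr = tau_nr).  ``config.n_essential``
    probe-only essential genes are appended with zero pool abundance.
    """
    if n_mutants < 1:
        raise ValueError("n_mutants must be >= 1")
    config = config or PoolConfig()
    fractions = dict(class_fractions or config.class_fractions)
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class fractions must sum to 1, got {total}")
    unknown = set(fractions) - set(CLASSES)
    if unknown:
        raise ValueError(f"unknown classes: {sorted(unknown)}")

    rng = _stage_rng(seed, "pool")
    counts = _apportion(n_mutants, fractions)
    classes: list[str] = []
    for cls in CLASSES:
        classes.extend([cls] * counts.get(cls, 0))
    classes = list(np.asarray(classes, dtype=object)[rng.permutation(n_mutants)])

    base_tau = _truncated_normal(
        rng, config.tau_nr_mean, config.tau_nr_sd, config.tau_min, n_mutants
    )
    abundance = rng.lognormal(0.0, config.abundance_sigma, size=n_mutants)
    abundance /= abundance.sum()
    eff = rng.uniform(config.eff_low, config.eff_high, size=(n_mutants, 2))
    missing = rng.random(size=(n_mutants, 2)) < config.missing_tag_prob

    profiles: list[MutantProfile] = []
    # effect-size factors: deletion phenotypes have heterogeneous strength,
    # so the planted classes scale tau by a factor with its own spread
    short_factor = np.maximum(
        rng.normal(config.short_tau_factor, config.short_tau_factor_sd, n_mutants),
        0.05,
    )
    long_factor = np.maximum(
        rng.normal(config.long_tau_factor, config.long_tau_factor_sd, n_mutants),
        1.2,
    )

    for i in range(n_mutants):
        cls = classes[i]
        tau_nr = base_tau[i]
        if cls == "short":
            tau_nr *= float(short_factor[i])
        elif cls == "long":
            tau_nr *= float(long_factor[i])
        tau_cr = tau_nr if cls == "cr_unresponsive" else tau_nr * config.cr_tau_factor
        profiles.append(
            MutantProfile(
                gene_id=f"YMUT{i:04d}",
                essential=False,
                tau_nr=tau_nr,
                tau_cr=tau_cr,
                shape_k=config.shape_k,
                initial_abundance=float(abundance[i]),
                uptag_eff=float(eff[i, 0]),
                dntag_eff=float(eff[i, 1]),
                uptag_missing=bool(missing[i, 0]),
                dntag_missing=bool(missing[i, 1]),
                regrowth_prob=config.regrowth_prob,
                true_class=cls,
            )
        )
    for j in range(config.n_essential):
        profiles.append(
            MutantProfile(
                gene_id=f"YESS{j:04d}",
                essential=True,
                tau_nr=config.tau_nr_mean,
                tau_cr=config.tau_nr_mean,
                shape_k=config.shape_k,
                initial_abundance=0.0,
                uptag_eff=1.0,
                dntag_eff=1.0,
                true_class="normal",
            )
        )
    return profiles


def simulate_pool_aging(
    profiles: Sequence[MutantProfile],
    config: PoolConfig,
    seed: int | None = None,
) -> tuple[dict[str, pd.DataFrame], ScreenTruth]:
    """Expected viable-cell trajectories per condition, with regrowth events.

    Returns ``(trajectories, truth)`` where ``trajectories[cond]`` is a
    DataFrame indexed by gene_id with one column per sample day holding the
    expected relative viable-cell count (initial abundance x survival, times
    any regrowth jump).  Essential genes stay at zero.
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    seed = config.seed if seed is None else seed
    rng = _stage_rng(seed, "aging")
    days = np.asarray(config.sample_days, dtype=float)
    genes = [p.gene_id for p in profiles]

    survival: dict[str, pd.DataFrame] = {}
    trajectories: dict[str, pd.DataFrame] = {}
    regrowth_day: dict[tuple[str, str], int] = {}
    for cond in config.conditions:
        tau = np.array([p.tau(cond) for p in profiles])
        k = np.array([p.shape_k for p in profiles])
        surv = np.exp(-((days[None, :] / tau[:, None]) ** k[:, None]))
        abundance = np.array([p.initial_abundance for p in profiles])
        viable = abundance[:, None] * surv
        # adaptive regrowth: one Bernoulli per (mutant, timecourse); the jump
        # day is uniform over the post-reference sample days
        for i, p in enumerate(profiles):
            if p.essential or p.regrowth_prob <= 0:
                continue
            if rng.random() < p.regrowth_prob:
                d_idx = rng.integers(1, len(config.sample_days))
                regrowth_day[(p.gene_id, cond)] = int(config.sample_days[d_idx])
                viable[i, d_idx:] *= config.regrowth_factor
        survival[cond] = pd.DataFrame(surv, index=genes, columns=config.sample_days)
        trajectories[cond] = pd.DataFrame(viable, index=genes, columns=config.sample_days)

    truth = ScreenTruth(
        classes={p.gene_id: p.true_class for p in profiles},
        survival=survival,
        regrowth_day=regrowth_day,
    )
    return trajectories, truth


class PoolExtinctError(RuntimeError):
    """Raised when no mutant in the pool has viable cells left to plate."""


def sample_survivors(
    trajectories: pd.DataFrame,
    day: int,
    plating_depth: int,
    seed: int = 0,
) -> pd.Series:
    """Multinomial plating recovery of ``plating_depth`` cells at ``day``.

    Cell recovery probabilities are proportional to the expected viable
    counts; the returned integer counts sum to ``plating_depth`` exactly.
    """
    if day not in trajectories.columns:
        raise ValueError(f"day {day} not among sampled days {list(trajectories.columns)}")
    viable = trajectories[day].to_numpy(dtype=float)
    total = viable.sum()
    if total <= 0:
        raise PoolExtinctError(f"pool extinct at day {day}: no viable cells to plate")
    rng = _stage_rng(seed, "plating", day)
    counts = rng.multinomial(int(plating_depth), viable / total)
    return pd.Series(counts, index=trajectories.index, name=f"count_d{day}")


def synthesize_intensities(
    counts_ref_day: pd.Series,
    counts_day_d: pd.Series,
    profiles: Sequence[MutantProfile],
    config: PoolConfig,
    seed: int = 0,
    condition: str = "NR",
    day: int | None = None,
) -> pd.DataFrame:
    """Two-channel probe intensities for one co-hybridized array.

    Per probe (gene x tag): intensity = count x tag efficiency x LN noise
    + background draw, for each channel.  Essential probes carry no mutant
    DNA and receive the background draw only; probes whose tag is flagged
    missing are emitted with empty (NaN) intensities.
    """
    if not counts_ref_day.index.equals(counts_day_d.index):
        raise ValueError("reference and later-day counts must cover the same genes")
    if (counts_ref_day < 0).any() or (counts_day_d < 0).any():
        raise ValueError("counts must be non-negative")
    day = int(day) if day is not None else int(config.later_days[0])
    rng = _stage_rng(seed, "intensity", day, 0 if condition == "NR" else 1)

    by_id = {p.gene_id: p for p in profiles}
    missing_index = set()
    eff = {}
    for tag in TAGS:
        eff[tag] = np.array([by_id[g].tag_eff(tag) for g in counts_ref_day.index])
        for g in counts_ref_day.index:
            if by_id[g].tag_missing(tag):
                missing_index.add((g, tag))

    # log-normal multiplicative noise with the configured CV on the count term
    sigma = np.sqrt(np.log1p(config.noise_cv**2))
    mu = -(sigma**2) / 2.0  # unit mean
    # background: log-normal with mean background_mean and CV background_cv
    bg_sigma = np.sqrt(np.log1p(config.background_cv**2))
    bg_mu = np.log(config.background_mean) - bg_sigma**2 / 2.0

    n = len(counts_ref_day)
    frames = []
    for tag in TAGS:
        rows = {
            "gene_id": counts_ref_day.index,
            "tag": tag,
            "condition": condition,
            "day": day,
        }
        for channel, counts in (("intensity_ref", counts_ref_day),
                                ("intensity_day", counts_day_d)):
            noise = rng.lognormal(mu, sigma, size=n) if sigma > 0 else np.ones(n)
            background = (
                rng.lognormal(bg_mu, bg_sigma, size=n)
                if bg_sigma > 0
                else np.full(n, config.background_mean)
            )
            signal = counts.to_numpy(dtype=float) * eff[tag] * noise + background
            rows[channel] = signal
        frame = pd.DataFrame(rows)
        mask = frame.apply(lambda r: (r["gene_id"], r["tag"]) in missing_index, axis=1)
        frame.loc[mask, ["intensity_ref", "intensity_day"]] = np.nan
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    present = out[["intensity_ref", "intensity_day"]].notna().all(axis=1)
    assert (out.loc[present, ["intensity_ref", "intensity_day"]] > 0).all().all()
    return out


def simulate_screen(
    profiles: Sequence[MutantProfile],
    config: PoolConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, ScreenTruth]:
    """Run the full screen: aging, plating per day, one array per later day.

    Returns the TagIntensityTable (gene x tag x condition x day records with
    both channel intensities) and the realized ground truth.  Each later-day
    array gets independent labeling/hybridization noise, but the recovered
    cell counts for a given (condition, day) plating are drawn once.
    """
    seed = config.seed if seed is None else seed
    trajectories, truth = simulate_pool_aging(profiles, config, seed=seed)
    tables = []
    for ci, cond in enumerate(config.conditions):
        traj = trajectories[cond]
        counts = {
            d: sample_survivors(traj, d, config.plating_depth, seed=seed * 2 + ci)
            for d in config.sample_days
        }
        for d in config.later_days:
            tables.append(
                synthesize_intensities(
                    counts[config.reference_day],
                    counts[d],
                    profiles,
                    config,
                    seed=seed,
                    condition=cond,
                    day=d,
                )
            )
    return pd.concat(tables, ignore_index=True), truth


# ---------------------------------------------------------------------------
# plain-text output


def write_intensities(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_truth(truth: ScreenTruth, profiles: Sequence[MutantProfile],
                path: str | Path) -> None:
    truth.to_frame(profiles).to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_essentials(profiles: Iterable[MutantProfile], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{p.gene_id}\n" for p in profiles if p.essential)
    )
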