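"""Reproducible whole-pipeline experiments on simulated screens.

These drive the simulator through ratio processing and candidate calling to
measure how well the screen's selection criteria recover planted lifespan
classes, and to check population-level directions (e.g. the CR viability
boost).  Thresholds are rescaled in proportion to pool size relative to the
full-collection defaults (bottom-200 / top-500 cuts for a ~4,800-mutant
pool).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from clscreen.arrays import (
    compute_ratio_table,
    estimate_background,
    filter_gene_universe,
    population_summary,
)
from clscreen.calling import (
    call_long_lived,
    call_short_lived,
    cross_tabulate_calls,
)
from clscreen.config import PoolConfig
from clscreen.simulate import build_pool, simulate_screen

FULL_POOL = 4800
SHORT_RANK_CUT = 200
LONG_RANK_CUT = 500


def scaled_cut(full_cut: int, n_mutants: int, full_pool: int = FULL_POOL) -> int:
    """Rank cut rescaled proportionally to pool size."""
    return int(round(full_cut * n_mutants / full_pool))


def simulated_pipeline(config: PoolConfig, seed: int):
    """Simulate a screen and run it through ratios + universe filtering.

    Uses the reference-channel-intensity background metric, the direct
    signal-presence criterion (see the methods note), so that genuinely
    dying mutants are not discarded as background.
    """
    profiles = build_pool(config.n_mutants, config.class_fractions,
                          seed=seed, config=config)
    intensities, truth = simulate_screen(profiles, config, seed=seed)
    essential = frozenset(p.gene_id for p in profiles if p.essential)
    ratios = compute_ratio_table(intensities)
    backgrounds = estimate_background(intensities, essential, mode="ref_intensity")
    universe = filter_gene_universe(intensities, backgrounds, essential,
                                    mode="ref_intensity")
    return profiles, ratios, universe, truth, essential


@dataclass
class RecoveryResult:
    precision_short: float
    recall_short: float
    precision_long: float
    recall_long: float
    n_mutants: int
    universe_size: int


def planted_recovery(
    seed: int,
    n_mutants: int = 2000,
    short_frac: float = 0.05,
    long_frac: float = 0.05,
) -> RecoveryResult:
    """Precision/recall of short- and long-lived calling on planted classes."""
    config = PoolConfig(
        n_mutants=n_mutants,
        n_essential=max(1, scaled_cut(1000, n_mutants)),
        class_fractions={
            "short": short_frac,
            "long": long_frac,
            "normal": 1.0 - short_frac - long_frac,
        },
        seed=seed,
    )
    _, ratios, universe, truth, _ = simulated_pipeline(config, seed)
    short = call_short_lived(ratios, universe,
                             rank_cut=scaled_cut(SHORT_RANK_CUT, n_mutants))
    long_ = call_long_lived(ratios, universe,
                            rank_cut=scaled_cut(LONG_RANK_CUT, n_mutants))
    cs = cross_tabulate_calls(short.genes, truth.classes, "short")
    cl = cross_tabulate_calls(long_.genes, truth.classes, "long")
    return RecoveryResult(
        precision_short=cs.precision, recall_short=cs.recall,
        precision_long=cl.precision, recall_long=cl.recall,
        n_mutants=n_mutants, universe_size=len(universe.dual_genes),
    )


def mean_recovery(seeds) -> dict[str, float]:
    """Planted-class recovery averaged over seeds."""
    results = [planted_recovery(seed) for seed in seeds]
    return {
        field: float(np.mean([getattr(r, field) for r in results]))
        for field in ("precision_short", "recall_short",
                      "precision_long", "recall_long")
    }


def cr_direction(seed: int, n_mutants: int = 500) -> tuple[float, float]:
    """Median day-33 abundance ratio under NR vs CR.

    With tau_cr > tau_nr for CR-responsive mutants, the pool's median day-33
    ratio should be higher under CR (the population-wide viability boost).
    """
    config = PoolConfig(n_mutants=n_mutants,
                        n_essential=max(1, scaled_cut(1000, n_mutants)),
                        seed=seed)
    _, ratios, universe, _, _ = simulated_pipeline(config, seed)
    day = config.sample_days[-1]
    nr = population_summary(ratios, universe.dual_genes, day, "NR")
    cr = population_summary(ratios, universe.dual_genes, day, "CR")
    return nr["median"], cr["median"]
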