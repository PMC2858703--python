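import pandas as pd
import pytest

from clscreen.arrays import (
    ProcessingReport,
    compute_ratio_table,
    estimate_background,
    filter_gene_universe,
)
from clscreen.config import PoolConfig
from clscreen.simulate import build_pool, simulate_screen


@pytest.fixture(scope="session")
def small_config() -> PoolConfig:
    return PoolConfig(n_mutants=300, n_essential=60, seed=7)


@pytest.fixture(scope="session")
def small_screen(small_config):
    """A 300-mutant simulated screen shared across read-only tests."""
    profiles = build_pool(small_config.n_mutants, small_config.class_fractions,
                          seed=small_config.seed, config=small_config)
    intensities, truth = simulate_screen(profiles, small_config)
    return profiles, intensities, truth


@pytest.fixture(scope="session")
def small_pipeline(small_config, small_screen):
    """Ratio table + filtered universe for the small screen."""
    profiles, intensities, _ = small_screen
    essential = frozenset(p.gene_id for p in profiles if p.essential)
    report = ProcessingReport()
    ratios = compute_ratio_table(intensities, report)
    backgrounds = estimate_background(intensities, essential, mode="ref_intensity")
    universe = filter_gene_universe(intensities, backgrounds, essential,
                                    mode="ref_intensity", report=report)
    return ratios, universe, essential, report


def make_ratio_table(records):
    """Build a RatioTable from (gene, tag, condition, day, ratio) tuples."""
    import numpy as np

    frame = pd.DataFrame(
        records, columns=["gene_id", "tag", "condition", "day", "ratio"]
    )
    frame["log_ratio"] = np.log2(frame["ratio"])
    return frame
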