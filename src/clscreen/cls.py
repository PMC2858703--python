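"""Individual-strain chronological lifespan (CLS) assay arithmetic.

Colony-forming-unit (CFU) time courses are reduced to survival fractions
relative to a reference day; strains are classified long/short/normal
against a wild-type course by the time-averaged difference of log10
survival; and screen-validation summaries (percent survival after an acute
challenge, confirmation rates, gene-set overlaps) are computed with the
rounding convention used for printed percentages (half away from zero, one
decimal).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CFU_COLUMNS = ["strain", "condition", "day", "cfu", "dilution"]


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round half away from zero (printed-percentage convention).

    ``numpy.round`` rounds half to even (81.25 -> 81.2); printed rates like
    13/16 -> 81.3% need half away from zero.
    """
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def survival_curve(series: pd.DataFrame, reference_day: int | None = None) -> pd.Series:
    """Survival fractions from a CFU time course.

    fraction(d) = cfu(d) * dilution(d) / (cfu(ref) * dilution(ref)); the
    reference day defaults to the earliest day and maps to exactly 1.
    """
    required = {"day", "cfu"}
    if not required <= set(series.columns):
        raise ValueError(f"CFU series needs columns {sorted(required)}")
    frame = series.sort_values("day")
    days = frame["day"].to_numpy()
    if len(days) != len(np.unique(days)):
        raise ValueError("duplicate days in CFU series")
    dilution = frame["dilution"].to_numpy(dtype=float) if "dilution" in frame else np.ones(len(frame))
    absolute = frame["cfu"].to_numpy(dtype=float) * dilution
    reference_day = int(days[0]) if reference_day is None else int(reference_day)
    if reference_day not in days:
        raise ValueError(f"reference day {reference_day} not in series")
    ref_value = absolute[list(days).index(reference_day)]
    if ref_value <= 0:
        raise ValueError("reference-day CFU must be positive")
    return pd.Series(absolute / ref_value, index=pd.Index(days, name="day"),
                     name="survival")


@dataclass
class LifespanVerdict:
    """Relative-lifespan call for one strain against a wild-type course."""

    strain: str
    verdict: str  # short | normal | long
    statistic: float  # time-averaged log10 survival difference (strain - WT)
    margin: float
    reference: str = "WT"


def classify_lifespan(
    strain_curve: pd.Series,
    wt_curve: pd.Series,
    margin: float = 0.5,
    strain: str = "strain",
    reference: str = "WT",
) -> LifespanVerdict:
    """Long/short/normal call from paired survival curves.

    The statistic is the trapezoid-averaged difference of log10 survival
    over the shared days (units: log10 viability, i.e. the average
    fold-difference in survivors on a log scale).  |statistic| <= margin
    gives "normal"; the sign gives long (positive) or short (negative).
    The default margin of 0.5 log10 units (about 3-fold average survival
    difference) keeps replicate wild-type courses classified as normal.
    """
    shared = strain_curve.index.intersection(wt_curve.index).sort_values()
    if len(shared) < 2:
        raise ValueError("need at least 2 shared days to classify")
    days = shared.to_numpy(dtype=float)
    diff = (np.log10(strain_curve.loc[shared].to_numpy(dtype=float))
            - np.log10(wt_curve.loc[shared].to_numpy(dtype=float)))
    statistic = float(np.trapezoid(diff, days) / (days[-1] - days[0]))
    if abs(statistic) <= margin:
        verdict = "normal"
    else:
        verdict = "long" if statistic > 0 else "short"
    return LifespanVerdict(strain=strain, verdict=verdict,
                           statistic=statistic, margin=margin,
                           reference=reference)


def percent_survival(
    cfu_treated: float | Sequence[float],
    cfu_untreated: float | Sequence[float],
) -> float | tuple[float, float]:
    """Acute-challenge survival: 100 x treated / untreated CFU.

    Scalars give a single percentage (which may exceed 100); replicate
    sequences give (mean, SD) of the per-replicate percentages, with the
    sample (ddof=1) standard deviation.
    """
    if np.isscalar(cfu_treated) != np.isscalar(cfu_untreated):
        raise ValueError("treated and untreated must both be scalars or both sequences")
    if np.isscalar(cfu_treated):
        if cfu_untreated <= 0:
            raise ValueError("untreated CFU must be positive")
        return 100.0 * float(cfu_treated) / float(cfu_untreated)
    treated = np.asarray(cfu_treated, dtype=float)
    untreated = np.asarray(cfu_untreated, dtype=float)
    if treated.shape != untreated.shape:
        raise ValueError("replicate arrays must align")
    if (untreated <= 0).any():
        raise ValueError("untreated CFU must be positive")
    pct = 100.0 * treated / untreated
    return float(pct.mean()), float(pct.std(ddof=1))


def confirmation_rate(n_confirmed: int, n_tested: int) -> float:
    """Retest confirmation percentage, one decimal, half away from zero."""
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    if not 0 <= n_confirmed <= n_tested:
        raise ValueError("need 0 <= n_confirmed <= n_tested")
    return round_half_away(100.0 * n_confirmed / n_tested, 1)


def gene_set_overlap(set_a: Iterable[str], set_b: Iterable[str]) -> tuple[int, float]:
    """(|A intersect B|, percentage of A shared), percentage to one decimal."""
    a = set(set_a)
    if not a:
        raise ValueError("set_a must be non-empty")
    count = len(a & set(set_b))
    return count, round_half_away(100.0 * count / len(a), 1)


def read_cfu_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = set(CFU_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"CFU table lacks columns {sorted(missing)}")
    return frame
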