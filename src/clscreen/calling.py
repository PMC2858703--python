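"""Rank/ratio candidate calling for the pooled CLS screen.

Implements the screen's three published selection criteria on a ratio
table: short-lived (day-9 abundance ratios ranked in the bottom ``rank_cut``
for both tags AND day-21 ratio below ``ratio_cut`` for both tags),
long-lived (day-33 ratios in the top ``rank_cut`` for both tags AND day-21
ratio above ``ratio_cut`` for both tags), and CR-unresponsive (NR and CR
mean log ratios within a fractional tolerance at every time point, plus a
t-test on the pooled log ratios).  Ranking uses competition (minimum-rank)
semantics, i.e. spreadsheet RANK behavior: ties share the lowest rank and
the next distinct value skips accordingly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from clscreen.arrays import TAGS, GeneUniverse

P_RULES = ("p_lt_alpha", "p_ge_alpha")


@dataclass
class CandidateCallSet:
    """Genes passing one selection criterion, with their justification."""

    criterion: str
    genes: list[str]
    justification: pd.DataFrame
    thresholds: dict[str, object] = field(default_factory=dict)
    excluded: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def write(self, path: str | Path) -> None:
        out = self.justification.copy()
        out.insert(1, "criterion", self.criterion)
        out.to_csv(path, sep="\t", index=False, float_format="%.17g")
        sidecar = Path(path).with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "criterion": self.criterion,
                    "n_called": len(self.genes),
                    "thresholds": self.thresholds,
                    "excluded": self.excluded,
                },
                indent=2,
                sort_keys=True,
                default=str,
            )
        )


def _slice(ratios: pd.DataFrame, day: int, condition: str) -> pd.DataFrame:
    subset = ratios[(ratios["day"] == day) & (ratios["condition"] == condition)]
    if subset.empty:
        raise ValueError(f"no records for day {day}, condition {condition}")
    return subset


def rank_mutants(
    ratios: pd.DataFrame,
    universe: GeneUniverse,
    day: int,
    condition: str = "NR",
    direction: str = "ascending",
) -> pd.DataFrame:
    """Competition ranks of each tag's ratios within that tag's universe.

    Returns a DataFrame indexed by gene_id with one integer column per tag;
    rank 1 is the lowest ratio when ``direction='ascending'`` and the
    highest when ``'descending'``.  Genes outside a tag's universe get NaN.
    """
    if direction not in ("ascending", "descending"):
        raise ValueError(f"unknown direction {direction!r}")
    subset = _slice(ratios, day, condition)
    columns = {}
    for tag in TAGS:
        tag_rows = subset[(subset["tag"] == tag)
                          & subset["gene_id"].isin(universe.tag_genes(tag))]
        values = tag_rows.set_index("gene_id")["ratio"]
        columns[tag] = values.rank(method="min", ascending=(direction == "ascending"))
    ranks = pd.DataFrame(columns)
    ranks.index.name = "gene_id"
    return ranks


def call_short_lived(
    ratios: pd.DataFrame,
    universe: GeneUniverse,
    rank_cut: int = 200,
    ratio_cut: float = 0.3,
    condition: str = "NR",
    rank_day: int = 9,
    ratio_day: int = 21,
    ranks: pd.DataFrame | None = None,
) -> CandidateCallSet:
    """Short-lived calls: early collapse confirmed at mid-course.

    A gene is called iff its ``rank_day`` ascending rank is <= ``rank_cut``
    for BOTH tags (rank cut inclusive) and its ``ratio_day`` ratio is
    strictly below ``ratio_cut`` for BOTH tags.  Later days are never
    consulted.  Only dual-tag-universe genes are eligible.
    """
    if ranks is None:
        ranks = rank_mutants(ratios, universe, rank_day, condition, "ascending")
    late = _slice(ratios, ratio_day, condition)
    table = _assemble(ranks, late, universe, rank_day, ratio_day)
    called = table[
        (table[f"rank_up_d{rank_day}"] <= rank_cut)
        & (table[f"rank_dn_d{rank_day}"] <= rank_cut)
        & (table[f"ratio_up_d{ratio_day}"] < ratio_cut)
        & (table[f"ratio_dn_d{ratio_day}"] < ratio_cut)
    ]
    return CandidateCallSet(
        criterion="short_lived",
        genes=sorted(called["gene_id"]),
        justification=called.reset_index(drop=True),
        thresholds={
            "rank_cut": int(rank_cut),
            "ratio_cut": float(ratio_cut),
            "rank_day": rank_day,
            "ratio_day": ratio_day,
            "condition": condition,
        },
    )


def call_long_lived(
    ratios: pd.DataFrame,
    universe: GeneUniverse,
    rank_cut: int = 500,
    ratio_cut: float = 1.0,
    condition: str = "NR",
    rank_day: int = 33,
    ratio_day: int = 21,
    ranks: pd.DataFrame | None = None,
) -> CandidateCallSet:
    """Long-lived calls: late persistence with mid-course enrichment.

    A gene is called iff its ``rank_day`` descending rank is <= ``rank_cut``
    for BOTH tags and its ``ratio_day`` ratio is strictly above
    ``ratio_cut`` for BOTH tags.
    """
    if ranks is None:
        ranks = rank_mutants(ratios, universe, rank_day, condition, "descending")
    mid = _slice(ratios, ratio_day, condition)
    table = _assemble(ranks, mid, universe, rank_day, ratio_day)
    called = table[
        (table[f"rank_up_d{rank_day}"] <= rank_cut)
        & (table[f"rank_dn_d{rank_day}"] <= rank_cut)
        & (table[f"ratio_up_d{ratio_day}"] > ratio_cut)
        & (table[f"ratio_dn_d{ratio_day}"] > ratio_cut)
    ]
    return CandidateCallSet(
        criterion="long_lived",
        genes=sorted(called["gene_id"]),
        justification=called.reset_index(drop=True),
        thresholds={
            "rank_cut": int(rank_cut),
            "ratio_cut": float(ratio_cut),
            "rank_day": rank_day,
            "ratio_day": ratio_day,
            "condition": condition,
        },
    )


def _assemble(
    ranks: pd.DataFrame,
    ratio_rows: pd.DataFrame,
    universe: GeneUniverse,
    rank_day: int,
    ratio_day: int,
) -> pd.DataFrame:
    """Join per-tag ranks and per-tag ratios over the dual-tag universe."""
    parts = {"gene_id": sorted(universe.dual_genes)}
    table = pd.DataFrame(parts).set_index("gene_id")
    for tag in TAGS:
        table[f"rank_{tag.lower()}_d{rank_day}"] = ranks[tag]
        values = ratio_rows[ratio_rows["tag"] == tag].set_index("gene_id")["ratio"]
        table[f"ratio_{tag.lower()}_d{ratio_day}"] = values
    return table.dropna().reset_index()


def call_cr_unresponsive(
    ratios: pd.DataFrame,
    universe: GeneUniverse,
    frac_cut: float = 0.1,
    alpha: float = 0.05,
    p_rule: str = "p_lt_alpha",
    days: Sequence[int] = (9, 21, 33),
) -> CandidateCallSet:
    """Genes whose NR and CR log-ratio trajectories are indistinguishable.

    Clause 1: at EVERY time point, the absolute fractional difference
    |xbar_NR - xbar_CR| / |(xbar_NR + xbar_CR) / 2| between the per-day mean
    log ratios (mean over tags) is below ``frac_cut``; genes with a zero
    denominator at any day are excluded and reported as undefined.
    Clause 2: a two-sided Welch t-test on the gene's NR vs CR log ratios
    pooled over tags and days, with the pass rule given by ``p_rule``
    ("p_lt_alpha" passes when p < alpha, following the screen's printed
    inequality; "p_ge_alpha" is the conventional not-significantly-different
    reading).  A gene is called when both clauses pass.
    """
    if p_rule not in P_RULES:
        raise ValueError(f"p_rule must be one of {P_RULES}")
    eligible = sorted(universe.dual_genes)
    sub = ratios[ratios["gene_id"].isin(universe.dual_genes)
                 & ratios["day"].isin(days)].dropna(subset=["log_ratio"])
    by_day = sub.groupby(["gene_id", "condition", "day"])["log_ratio"].mean()
    pooled = sub.groupby(["gene_id", "condition"])["log_ratio"]
    obs = {key: grp.to_numpy() for key, grp in pooled}

    rows = []
    undefined: list[str] = []
    too_few: list[str] = []
    for gene in eligible:
        nr = obs.get((gene, "NR"), np.empty(0))
        cr = obs.get((gene, "CR"), np.empty(0))
        if len(nr) < 2 or len(cr) < 2:
            too_few.append(gene)
            continue
        fracs = {}
        bad = False
        for day in days:
            try:
                x_nr = by_day.loc[(gene, "NR", day)]
                x_cr = by_day.loc[(gene, "CR", day)]
            except KeyError:
                bad = True
                break
            denom = (x_nr + x_cr) / 2.0
            if denom == 0:
                undefined.append(gene)
                bad = True
                break
            fracs[day] = abs(x_nr - x_cr) / abs(denom)
        if bad:
            continue
        clause1 = all(f < frac_cut for f in fracs.values())
        p_value = float(stats.ttest_ind(nr, cr, equal_var=False).pvalue)
        clause2 = p_value < alpha if p_rule == "p_lt_alpha" else p_value >= alpha
        row = {"gene_id": gene, "p_value": p_value,
               "clause1": clause1, "clause2": clause2}
        for day in days:
            row[f"frac_diff_d{day}"] = fracs[day]
        rows.append(row)

    table = pd.DataFrame(rows)
    called = table[table["clause1"] & table["clause2"]] if not table.empty else table
    return CandidateCallSet(
        criterion="cr_unresponsive",
        genes=sorted(called["gene_id"]) if not called.empty else [],
        justification=called.reset_index(drop=True),
        thresholds={
            "frac_cut": float(frac_cut),
            "alpha": float(alpha),
            "p_rule": p_rule,
            "days": list(days),
        },
        excluded={"undefined_denominator": undefined,
                  "too_few_observations": too_few},
    )


@dataclass
class ConfusionCounts:
    """Calls vs planted truth for one criterion."""

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")


def cross_tabulate_calls(
    called: Iterable[str],
    truth: Mapping[str, str],
    positive_class: str,
) -> ConfusionCounts:
    """TP/FP/FN of a call set against ground-truth class labels."""
    called_set = set(called)
    positives = {g for g, cls in truth.items() if cls == positive_class}
    tp = len(called_set & positives)
    return ConfusionCounts(tp=tp, fp=len(called_set) - tp, fn=len(positives) - tp)


def verify_call_set(
    call_set: CandidateCallSet,
    ratios: pd.DataFrame,
    universe: GeneUniverse,
) -> bool:
    """Audit: re-derive every justification value from the ratio table.

    Recomputes the call set from scratch with the stored thresholds and
    checks that the called genes and their clause values match.  Raises
    AssertionError on any discrepancy; returns True otherwise.
    """
    th = call_set.thresholds
    if call_set.criterion == "short_lived":
        fresh = call_short_lived(ratios, universe, rank_cut=th["rank_cut"],
                                 ratio_cut=th["ratio_cut"], condition=th["condition"],
                                 rank_day=th["rank_day"], ratio_day=th["ratio_day"])
    elif call_set.criterion == "long_lived":
        fresh = call_long_lived(ratios, universe, rank_cut=th["rank_cut"],
                                ratio_cut=th["ratio_cut"], condition=th["condition"],
                                rank_day=th["rank_day"], ratio_day=th["ratio_day"])
    elif call_set.criterion == "cr_unresponsive":
        fresh = call_cr_unresponsive(ratios, universe, frac_cut=th["frac_cut"],
                                     alpha=th["alpha"], p_rule=th["p_rule"],
                                     days=th["days"])
    else:
        raise ValueError(f"unknown criterion {call_set.criterion!r}")
    assert fresh.genes == call_set.genes, "called gene set not reproducible"
    left = call_set.justification.sort_values("gene_id").reset_index(drop=True)
    right = fresh.justification.sort_values("gene_id").reset_index(drop=True)
    pd.testing.assert_frame_equal(left[sorted(left.columns)],
                                  right[sorted(right.columns)])
    assert not set(call_set.genes) - universe.dual_genes, \
        "called gene outside the dual-tag universe"
    return True
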