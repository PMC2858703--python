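"""Two-channel tag-intensity processing.

Turns a TagIntensityTable into abundance ratios R_d = I_d / I_ref per
(gene, tag, condition, day), estimates the nonspecific-hybridization
background from essential-gene probes (probes with no mutant in the pool),
filters the gene universe so only genes with signal from both tags remain,
and computes box-plot style population summaries of the aging pool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

TAGS = ("UP", "DN")

INTENSITY_COLUMNS = ["gene_id", "tag", "condition", "day",
                     "intensity_ref", "intensity_day"]
RATIO_COLUMNS = ["gene_id", "tag", "condition", "day", "ratio", "log_ratio"]

#: background/filter metric modes: "ratio" averages essential-gene abundance
#: ratios (the screen's printed rule); "ref_intensity" averages their
#: reference-channel intensities (a direct signal-presence criterion).
BACKGROUND_MODES = ("ratio", "ref_intensity")


@dataclass
class ProcessingReport:
    """Bookkeeping from intensity -> ratio conversion and filtering."""

    records_read: int = 0
    records_dropped_missing: int = 0
    records_dropped_zero_ref: int = 0
    backgrounds: dict[str, float] = field(default_factory=dict)
    background_mode: str = ""
    universe_sizes: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


@dataclass
class GeneUniverse:
    """Per-tag and dual-tag gene sets surviving the background filter."""

    up_genes: frozenset[str]
    dn_genes: frozenset[str]
    backgrounds: dict[str, float]
    mode: str

    @property
    def dual_genes(self) -> frozenset[str]:
        return self.up_genes & self.dn_genes

    def tag_genes(self, tag: str) -> frozenset[str]:
        return self.up_genes if tag == "UP" else self.dn_genes

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "mode": self.mode,
                    "backgrounds": self.backgrounds,
                    "up_genes": sorted(self.up_genes),
                    "dn_genes": sorted(self.dn_genes),
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneUniverse":
        data = json.loads(Path(path).read_text())
        return cls(
            up_genes=frozenset(data["up_genes"]),
            dn_genes=frozenset(data["dn_genes"]),
            backgrounds=data["backgrounds"],
            mode=data["mode"],
        )


def compute_ratio_table(
    intensities: pd.DataFrame,
    report: ProcessingReport | None = None,
) -> pd.DataFrame:
    """Abundance ratios R_d = intensity_day / intensity_ref with log2 ratios.

    Records with a missing channel or a non-positive reference intensity are
    dropped (never imputed) and counted in the report.
    """
    if intensities.empty:
        raise ValueError("empty intensity table")
    missing_cols = set(INTENSITY_COLUMNS) - set(intensities.columns)
    if missing_cols:
        raise ValueError(f"intensity table lacks columns {sorted(missing_cols)}")
    report = report if report is not None else ProcessingReport()
    report.records_read += len(intensities)

    present = intensities[["intensity_ref", "intensity_day"]].notna().all(axis=1)
    report.records_dropped_missing += int((~present).sum())
    table = intensities.loc[present].copy()
    positive_ref = table["intensity_ref"] > 0
    report.records_dropped_zero_ref += int((~positive_ref).sum())
    table = table.loc[positive_ref]
    if table.empty:
        raise ValueError("no usable records: all rows missing or zero-reference")

    table["ratio"] = table["intensity_day"] / table["intensity_ref"]
    table["log_ratio"] = np.log2(table["ratio"])
    return table[RATIO_COLUMNS].reset_index(drop=True)


def _metric_frame(table: pd.DataFrame, mode: str) -> pd.DataFrame:
    if mode not in BACKGROUND_MODES:
        raise ValueError(f"unknown background mode {mode!r}")
    column = "ratio" if mode == "ratio" else "intensity_ref"
    if column not in table.columns:
        raise ValueError(
            f"background mode {mode!r} needs column {column!r}; "
            "pass a ratio table for 'ratio' mode or an intensity table "
            "for 'ref_intensity' mode"
        )
    return table[["gene_id", "tag", column]].rename(columns={column: "metric"}).dropna()


def estimate_background(
    table: pd.DataFrame,
    essential_set: Iterable[str],
    mode: str = "ratio",
) -> dict[str, float]:
    """Per-tag background B = mean metric over essential-gene probes.

    Essential genes have no mutant in the pool, so their probes measure
    nonspecific hybridization only.
    """
    essential = frozenset(essential_set)
    if not essential:
        raise ValueError("essential_set must be non-empty")
    metric = _metric_frame(table, mode)
    metric = metric[metric["gene_id"].isin(essential)]
    out: dict[str, float] = {}
    for tag in TAGS:
        values = metric.loc[metric["tag"] == tag, "metric"]
        if values.empty:
            raise ValueError(f"no essential-gene records for tag {tag}")
        out[tag] = float(values.mean())
    return out


def filter_gene_universe(
    table: pd.DataFrame,
    backgrounds: Mapping[str, float],
    essential_set: Iterable[str],
    mode: str = "ratio",
    report: ProcessingReport | None = None,
) -> GeneUniverse:
    """Retain non-essential genes whose per-tag metric clears the background.

    A gene's per-tag metric is the mean of the mode's column over all of the
    gene's records for that tag; the gene stays in a tag's universe when the
    metric is >= that tag's background (genes below background are treated
    as signal-free for the tag).  The dual-tag universe is the intersection.
    """
    essential = frozenset(essential_set)
    metric = _metric_frame(table, mode)
    per_gene = metric.groupby(["tag", "gene_id"])["metric"].mean()
    sets: dict[str, frozenset[str]] = {}
    for tag in TAGS:
        if tag not in backgrounds:
            raise ValueError(f"no background value for tag {tag}")
        values = per_gene.loc[tag] if tag in per_gene.index.get_level_values(0) else pd.Series(dtype=float)
        kept = values.index[values >= backgrounds[tag]]
        sets[tag] = frozenset(kept) - essential
    universe = GeneUniverse(
        up_genes=sets["UP"],
        dn_genes=sets["DN"],
        backgrounds={t: float(backgrounds[t]) for t in TAGS},
        mode=mode,
    )
    if report is not None:
        report.backgrounds = universe.backgrounds
        report.background_mode = mode
        report.universe_sizes = {
            "UP": len(universe.up_genes),
            "DN": len(universe.dn_genes),
            "dual": len(universe.dual_genes),
        }
    return universe


def population_summary(
    ratios: pd.DataFrame,
    universe_genes: Iterable[str],
    day: int,
    condition: str,
) -> dict[str, float]:
    """Five-number summary plus mean of the pool's ratios at one time point.

    Quartiles use linear interpolation (numpy default, R type 7), matching
    standard box-plot conventions.
    """
    genes = frozenset(universe_genes)
    if not genes:
        raise ValueError("empty gene universe")
    subset = ratios[
        (ratios["day"] == day)
        & (ratios["condition"] == condition)
        & ratios["gene_id"].isin(genes)
    ]["ratio"]
    if subset.empty:
        raise ValueError(f"no ratios for day {day}, condition {condition}")
    values = subset.to_numpy(dtype=float)
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    return {
        "min": float(values.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(values.max()),
        "mean": float(values.mean()),
        "n": int(values.size),
    }


# ---------------------------------------------------------------------------
# plain-text I/O


def read_intensities(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip",
                       dtype={"gene_id": str, "tag": str, "condition": str})


def read_ratio_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip",
                       dtype={"gene_id": str, "tag": str, "condition": str})


def write_ratio_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_essential_list(path: str | Path) -> frozenset[str]:
    """One ORF per line, or two tab-separated columns (gene_id, flag)."""
    genes = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) == 1:
            genes.add(parts[0])
        elif parts[1].strip().lower() in {"1", "true", "yes", "essential"}:
            genes.add(parts[0])
    return frozenset(genes)


def read_supplementary_workbook(
    workbook_path: str | Path,
    column_map_path: str | Path,
) -> pd.DataFrame:
    """Read a measured-ratio workbook (first sheet) into a RatioTable.

    The YAML column map avoids hard-coding the spreadsheet layout.  Keys:
    ``gene_id`` names the identifier column; ``ratios`` is a list of
    ``{column, tag, condition, day}`` entries, one per ratio column.
    """
    from openpyxl import load_workbook

    cmap = yaml.safe_load(Path(column_map_path).read_text())
    sheet = load_workbook(workbook_path, read_only=True, data_only=True).worksheets[0]
    rows = list(sheet.values)
    header = [str(c) if c is not None else "" for c in rows[0]]
    frame = pd.DataFrame(rows[1:], columns=header)

    gene_col = cmap["gene_id"]
    records = []
    for entry in cmap["ratios"]:
        col = entry["column"]
        sub = frame[[gene_col, col]].dropna()
        ratio = pd.to_numeric(sub[col], errors="coerce")
        records.append(
            pd.DataFrame(
                {
                    "gene_id": sub[gene_col].astype(str),
                    "tag": entry["tag"],
                    "condition": entry["condition"],
                    "day": int(entry["day"]),
                    "ratio": ratio,
                }
            ).dropna(subset=["ratio"])
        )
    table = pd.concat(records, ignore_index=True)
    positive = table["ratio"] > 0
    table["log_ratio"] = np.nan
    table.loc[positive, "log_ratio"] = np.log2(table.loc[positive, "ratio"])
    return table
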