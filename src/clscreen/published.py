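"""Published screen outputs used as inputs to validation arithmetic.

The long-lived candidate table (per-tag day-33 descending ranks, day-21
abundance ratios, and the retest verdict for each ORF) and the screen's
retest tallies.  These are measured screen results consumed as data; the
package recomputes every derived quantity (clause checks, confirmation
rates, overlaps) from them.
"""

from __future__ import annotations

import pandas as pd

# columns: ORF, gene, UPTAG day-33 rank, UPTAG day-21 ratio,
#          DNTAG day-33 rank, DNTAG day-21 ratio, retest verdict
# verdict: L = long, S = short, N = normal, UN = untested
_LONG_LIVED_ROWS = [
    ("YER056C", "FCY2", 3, 6.91, 7, 5.47, "L"),
    ("YPL056C", "LCL1", 5, 3.23, 12, 3.80, "L"),
    ("YKL046C", "DCW1", 6, 5.06, 2, 7.84, "L"),
    ("YNL099C", "OCA1", 8, 9.39, 10, 9.56, "N"),
    ("YOL013C", "HRD1", 9, 48.76, 1, 167.92, "S"),
    ("YBL053W", "YBL053W", 11, 1.41, 11, 1.35, "N"),
    ("YJL201W", "ECM25", 12, 1.02, 16, 1.06, "N"),
    ("YDR425W", "SNX41", 16, 16.06, 13, 17.37, "L"),
    ("YCR011C", "ADP1", 18, 26.85, 4, 42.99, "S"),
    ("YLL013C", "PUF3", 22, 1.93, 5, 3.99, "S"),
    ("YLR154C", "RNH203", 23, 1.66, 6, 2.04, "N"),
    ("YLR104W", "LCL2", 24, 6.67, 14, 20.63, "L"),
    ("YBL052C", "SAS3", 25, 2.27, 18, 1.71, "N"),
    ("YPL015C", "HST2", 39, 1.40, 20, 1.99, "N"),
    ("YGR204W", "ADE3", 43, 1.21, 194, 1.10, "L"),
    ("YJL129C", "TRK1", 55, 9.26, 264, 9.03, "N"),
    ("YMR169C", "ALD3", 75, 1.88, 51, 1.08, "S"),
    ("YBR057C", "MUM2", 89, 3.71, 139, 1.47, "L"),
    ("YDR181C", "SAS4", 94, 1.51, 481, 1.41, "L"),
    ("YFR032C-A", "RPL29", 129, 1.07, 501, 1.09, "N"),
    ("YDL118W", "YDL118W", 135, 1.19, 218, 1.47, "N"),
    ("YFR008W", "FAR7", 155, 2.37, 128, 2.27, "S"),
    ("YOR295W", "UAF30", 176, 2.53, 80, 1.34, "L"),
    ("YGL003C", "CDH1", 179, 1.40, 433, 1.36, "N"),
    ("YGL056C", "SDS23", 181, 1.42, 463, 1.63, "L"),
    ("YDR485C", "VPS72", 198, 10.70, 415, 10.22, "N"),
    ("YGL085W", "LCL3", 222, 1.42, 378, 1.12, "L"),
    ("YLR043C", "TRX1", 263, 6.95, 84, 3.03, "S"),
    ("YER054C", "GIP2", 285, 1.38, 324, 1.63, "N"),
    ("YDL122W", "UBP1", 301, 11.51, 198, 12.43, "UN"),
    ("YNL144C", "YNL144C", 309, 6.70, 468, 2.22, "N"),
    ("YDL059C", "RAD59", 325, 1.59, 267, 1.57, "N"),
    ("YDR220C", "YDR220C", 370, 2.35, 65, 1.75, "N"),
    ("YLR236C", "YLR236C", 372, 1.68, 487, 2.03, "S"),
    ("YBL106C", "SRO77", 375, 3.71, 94, 3.69, "S"),
    ("YGR021W", "YGR021W", 393, 1.04, 228, 2.02, "N"),
    ("YMR300C", "ADE4", 438, 2.41, 83, 2.46, "L"),
    ("YLR207W", "HRD3", 449, 31.26, 261, 77.13, "S"),
    ("YGR017W", "YGR017W", 456, 1.81, 414, 1.91, "N"),
    ("YDR312W", "SSF2", 474, 1.27, 355, 1.67, "N"),
]

LONG_LIVED_COLUMNS = [
    "orf", "gene", "rank_up_d33", "ratio_up_d21",
    "rank_dn_d33", "ratio_dn_d21", "verdict",
]

# retest tallies reported alongside the candidate lists
SHORT_CANDIDATES = 117
SHORT_RETESTED = 16
SHORT_CONFIRMED = 13
CR_UNRESPONSIVE_RETESTED = 41
CR_UNRESPONSIVE_CONFIRMED = 2
SHORT_OVERLAP_WITH_PRIOR_SCREEN = 68  # candidates also in the earlier
# plate-based screen's bottom-1000 short-lived list


def long_lived_candidates() -> pd.DataFrame:
    """The published long-lived candidate table as a DataFrame."""
    return pd.DataFrame(_LONG_LIVED_ROWS, columns=LONG_LIVED_COLUMNS)


def check_long_lived_clauses(
    table: pd.DataFrame | None = None,
    rank_cut: int = 500,
    ratio_cut: float = 1.0,
) -> pd.Series:
    """Re-evaluate the long-lived selection clauses on stored rank/ratio rows.

    Returns a boolean Series (indexed by ORF): day-33 rank <= rank_cut for
    both tags AND day-21 ratio > ratio_cut for both tags.
    """
    table = long_lived_candidates() if table is None else table
    passes = (
        (table["rank_up_d33"] <= rank_cut)
        & (table["rank_dn_d33"] <= rank_cut)
        & (table["ratio_up_d21"] > ratio_cut)
        & (table["ratio_dn_d21"] > ratio_cut)
    )
    passes.index = table["orf"]
    return passes
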