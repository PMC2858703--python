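"""Ratio computation, background estimation, universe filtering, and
population summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from clscreen.arrays import (
    ProcessingReport,
    compute_ratio_table,
    estimate_background,
    filter_gene_universe,
    population_summary,
    read_intensities,
    read_ratio_table,
    read_essential_list,
    read_supplementary_workbook,
    write_ratio_table,
)


def intensity_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["gene_id", "tag", "condition", "day",
                 "intensity_ref", "intensity_day"],
    )


class TestComputeRatios:
    def test_identity_channels_give_unit_ratios(self):
        frame = intensity_frame(
            [(f"Y{i}", t, "NR", 9, 50.0, 50.0) for i in range(5) for t in ("UP", "DN")]
        )
        ratios = compute_ratio_table(frame)
        assert (ratios["ratio"] == 1.0).all()
        assert (ratios["log_ratio"] == 0.0).all()

    def test_arithmetic(self):
        ratios = compute_ratio_table(intensity_frame([("Y1", "UP", "NR", 9, 4.0, 2.0)]))
        assert ratios.loc[0, "ratio"] == 0.5
        assert ratios.loc[0, "log_ratio"] == -1.0

    def test_drops_are_counted_never_imputed(self):
        frame = intensity_frame([
            ("Y1", "UP", "NR", 9, 4.0, 2.0),
            ("Y2", "UP", "NR", 9, np.nan, 2.0),
            ("Y3", "UP", "NR", 9, 0.0, 2.0),
        ])
        report = ProcessingReport()
        ratios = compute_ratio_table(frame, report)
        assert list(ratios["gene_id"]) == ["Y1"]
        assert report.records_read == 3
        assert report.records_dropped_missing == 1
        assert report.records_dropped_zero_ref == 1

    def test_empty_and_all_missing_raise(self):
        with pytest.raises(ValueError, match="empty"):
            compute_ratio_table(intensity_frame([]))
        all_missing = intensity_frame([("Y1", "UP", "NR", 9, np.nan, np.nan)])
        with pytest.raises(ValueError, match="no usable records"):
            compute_ratio_table(all_missing)

    @given(scale=st.floats(min_value=1e-3, max_value=1e6),
           ref=st.floats(min_value=0.1, max_value=1e4),
           day=st.floats(min_value=0.1, max_value=1e4))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, scale, ref, day):
        # multiplying both channels by a constant leaves the ratio unchanged
        base = compute_ratio_table(intensity_frame([("Y1", "UP", "NR", 9, ref, day)]))
        scaled = compute_ratio_table(
            intensity_frame([("Y1", "UP", "NR", 9, ref * scale, day * scale)])
        )
        assert scaled.loc[0, "ratio"] == pytest.approx(base.loc[0, "ratio"], rel=1e-9)


class TestBackground:
    def test_constant_and_mean(self):
        frame = intensity_frame([
            ("YE1", "UP", "NR", 9, 10.0, 10.0),
            ("YE2", "UP", "NR", 9, 10.0, 20.0),
            ("YE3", "UP", "NR", 9, 10.0, 30.0),
            ("YE1", "DN", "NR", 9, 10.0, 40.0),
        ])
        ratios = compute_ratio_table(frame)
        bg = estimate_background(ratios, {"YE1", "YE2", "YE3"}, mode="ratio")
        assert bg["UP"] == pytest.approx(2.0)  # mean of {1, 2, 3}
        assert bg["DN"] == pytest.approx(4.0)

    def test_ref_intensity_mode_recovers_simulator_background(
        self, small_config, small_screen
    ):
        profiles, intensities, _ = small_screen
        essential = {p.gene_id for p in profiles if p.essential}
        bg = estimate_background(intensities, essential, mode="ref_intensity")
        ess_rows = intensities[intensities["gene_id"].isin(essential)]
        n = (ess_rows["tag"] == "UP").sum()
        sd = small_config.background_mean * small_config.background_cv
        for tag in ("UP", "DN"):
            assert abs(bg[tag] - small_config.background_mean) < 3 * sd / np.sqrt(n)

    def test_errors(self):
        frame = intensity_frame([("Y1", "UP", "NR", 9, 1.0, 1.0)])
        with pytest.raises(ValueError, match="non-empty"):
            estimate_background(frame, set(), mode="ref_intensity")
        with pytest.raises(ValueError, match="no essential-gene records"):
            estimate_background(frame, {"Y1"}, mode="ref_intensity")  # no DN rows
        with pytest.raises(ValueError, match="unknown background mode"):
            estimate_background(frame, {"Y1"}, mode="loess")


class TestUniverseFilter:
    frame = intensity_frame([
        ("Y1", "UP", "NR", 9, 100.0, 50.0),
        ("Y1", "DN", "NR", 9, 100.0, 50.0),
        ("Y2", "UP", "NR", 9, 5.0, 50.0),   # UP below background
        ("Y2", "DN", "NR", 9, 100.0, 50.0),
        ("YE1", "UP", "NR", 9, 10.0, 10.0),
        ("YE1", "DN", "NR", 9, 10.0, 10.0),
    ])

    def test_dual_and_per_tag_membership(self):
        universe = filter_gene_universe(self.frame, {"UP": 10.0, "DN": 10.0},
                                        {"YE1"}, mode="ref_intensity")
        assert "Y1" in universe.dual_genes
        assert "Y2" not in universe.dual_genes
        assert "Y2" in universe.dn_genes  # survives on its DN tag alone

    def test_never_admits_essential_and_monotone_in_background(self):
        essential = {"YE1"}
        sizes = []
        for b in (1.0, 10.0, 50.0, 200.0):
            uni = filter_gene_universe(self.frame, {"UP": b, "DN": b},
                                       essential, mode="ref_intensity")
            assert not (uni.up_genes | uni.dn_genes) & essential
            sizes.append(len(uni.dual_genes))
        assert sizes == sorted(sizes, reverse=True)

    def test_simulated_universe_excludes_all_essentials(self, small_pipeline):
        _, universe, essential, report = small_pipeline
        assert not (universe.up_genes | universe.dn_genes) & essential
        assert report.universe_sizes["dual"] <= min(report.universe_sizes["UP"],
                                                    report.universe_sizes["DN"])


class TestPopulationSummary:
    def test_constant_ratios(self):
        table = pd.DataFrame({
            "gene_id": ["Y1", "Y2", "Y3"], "tag": "UP", "condition": "NR",
            "day": 9, "ratio": 1.0, "log_ratio": 0.0,
        })
        summary = population_summary(table, {"Y1", "Y2", "Y3"}, 9, "NR")
        assert all(summary[k] == 1.0 for k in ("min", "q1", "median", "q3", "max", "mean"))

    def test_hand_quartiles(self):
        table = pd.DataFrame({
            "gene_id": [f"Y{i}" for i in range(5)], "tag": "UP",
            "condition": "NR", "day": 9,
            "ratio": [0.0, 1.0, 2.0, 3.0, 4.0], "log_ratio": np.nan,
        })
        summary = population_summary(table, {f"Y{i}" for i in range(5)}, 9, "NR")
        assert (summary["q1"], summary["median"], summary["q3"]) == (1.0, 2.0, 3.0)

    @given(st.lists(st.floats(min_value=0.001, max_value=100), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_quartiles_match_sorted_interpolation_oracle(self, values):
        # naive oracle: sort, take index q*(n-1), linearly interpolate
        def naive_quantile(sorted_v, q):
            pos = q * (len(sorted_v) - 1)
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            return sorted_v[lo] + (pos - lo) * (sorted_v[hi] - sorted_v[lo])

        table = pd.DataFrame({
            "gene_id": [f"Y{i}" for i in range(len(values))], "tag": "UP",
            "condition": "NR", "day": 9, "ratio": values, "log_ratio": np.nan,
        })
        summary = population_summary(table, set(table["gene_id"]), 9, "NR")
        ordered = sorted(values)
        for key, q in (("q1", 0.25), ("median", 0.5), ("q3", 0.75)):
            assert summary[key] == pytest.approx(naive_quantile(ordered, q), rel=1e-9)

    def test_empty_universe_raises(self):
        table = pd.DataFrame({"gene_id": ["Y1"], "tag": "UP", "condition": "NR",
                              "day": 9, "ratio": [1.0], "log_ratio": [0.0]})
        with pytest.raises(ValueError, match="empty"):
            population_summary(table, set(), 9, "NR")


class TestIO:
    def test_ratio_table_roundtrip_bit_identical(self, tmp_path, small_pipeline):
        ratios, *_ = small_pipeline
        path = tmp_path / "ratios.tsv"
        write_ratio_table(ratios, path)
        back = read_ratio_table(path)
        pd.testing.assert_frame_equal(ratios, back, check_exact=True)

    def test_essential_list_formats(self, tmp_path):
        path = tmp_path / "ess.txt"
        path.write_text("# comment\nYAL001C\nYBL002W\t1\nYCL003C\t0\n")
        assert read_essential_list(path) == {"YAL001C", "YBL002W"}

    def test_synthetic_workbook_roundtrip(self, tmp_path):
        # synthetic stand-in workbook exercising the column-map reader
        from openpyxl import Workbook

        wb = Workbook()
        ws = wb.active
        ws.append(["ORF", "UP D9 NR", "DN D9 NR"])
        ws.append(["YAL001C", 0.5, 0.6])
        ws.append(["YBL002W", 1.5, None])
        xlsx = tmp_path / "synthetic_ratios.xlsx"
        wb.save(xlsx)
        cmap = tmp_path / "colmap.yaml"
        cmap.write_text(
            "gene_id: ORF\n"
            "ratios:\n"
            "  - {column: UP D9 NR, tag: UP, condition: NR, day: 9}\n"
            "  - {column: DN D9 NR, tag: DN, condition: NR, day: 9}\n"
        )
        table = read_supplementary_workbook(xlsx, cmap)
        assert len(table) == 3  # the None cell is dropped
        row = table[(table["gene_id"] == "YAL001C") & (table["tag"] == "UP")]
        assert row["ratio"].iloc[0] == 0.5
        assert row["log_ratio"].iloc[0] == -1.0


def test_day33_ratio_tracks_planted_death_rate(small_screen, small_pipeline):
    # per-gene day-33 NR ratio correlates negatively with the planted death
    # rate 1/tau (Spearman rho < -0.5)
    profiles, _, _ = small_screen
    ratios, universe, _, _ = small_pipeline
    day33 = ratios[(ratios["day"] == 33) & (ratios["condition"] == "NR")]
    per_gene = day33.groupby("gene_id")["ratio"].mean()
    tau = pd.Series({p.gene_id: p.tau_nr for p in profiles if not p.essential})
    shared = per_gene.index.intersection(tau.index)
    rho = stats.spearmanr(per_gene.loc[shared], 1.0 / tau.loc[shared]).statistic
    assert rho < -0.5
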