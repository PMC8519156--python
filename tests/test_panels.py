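"""Marker ranking, distance pruning, step-wise schedules and panel
combination."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from breedpanel.errors import CombineError, ScheduleShortfallError
from breedpanel.panels import (
    Panel,
    audit_panel_distances,
    combine_panels,
    distance_sweep,
    prune_select,
    rank_markers,
    ratio_sweep,
    read_panel_tsv,
    stepwise_select,
    write_panel_tsv,
)


def marker_map(chroms, positions, ids=None):
    n = len(positions)
    return pd.DataFrame(
        {
            "id": ids if ids is not None else [f"m{i}" for i in range(n)],
            "chrom": chroms,
            "pos": positions,
            "a1": "A",
            "a2": "B",
        }
    )


def random_ranked(rng, n=500, n_chrom=10, chrom_len=100_000_000):
    mm = marker_map(
        [str(1 + int(c)) for c in rng.integers(0, n_chrom, n)],
        rng.integers(1, chrom_len, n),
    )
    return rank_markers(rng.random(n), mm, "test")


class TestRankMarkers:
    def test_sorted_by_delta_descending(self):
        mm = marker_map(["1", "1", "1"], [100, 200, 300])
        ranked = rank_markers(np.array([0.2, 0.9, 0.5]), mm)
        assert ranked["delta"].to_list() == [0.9, 0.5, 0.2]
        assert ranked["marker_id"].to_list() == ["m1", "m2", "m0"]

    def test_ties_broken_by_coordinate(self):
        mm = marker_map(["1", "1"], [100, 50])
        ranked = rank_markers(np.array([0.7, 0.7]), mm)
        assert ranked["pos"].to_list() == [50, 100]

    def test_matches_stable_sort_oracle(self, rng):
        n = 1000
        mm = marker_map(
            [str(1 + int(c)) for c in rng.integers(0, 5, n)],
            rng.integers(1, 10**8, n),
        )
        deltas = rng.choice(np.round(np.linspace(0, 1, 50), 3), size=n)  # many ties
        ranked = rank_markers(deltas, mm)
        order = sorted(
            range(n),
            key=lambda i: (-deltas[i], int(mm["chrom"][i]), mm["pos"][i], mm["id"][i]),
        )
        assert ranked["marker_id"].to_list() == [mm["id"][i] for i in order]

    def test_undefined_deltas_excluded_and_empty_rejected(self):
        mm = marker_map(["1", "1"], [100, 200])
        ranked = rank_markers(np.array([np.nan, 0.4]), mm)
        assert ranked["marker_id"].to_list() == ["m1"]
        with pytest.raises(Exception):
            rank_markers(np.array([np.nan, np.nan]), mm)


class TestPruneSelect:
    def test_hand_trace(self):
        mm = marker_map(["1", "1", "1"], [1_000_000, 2_000_000, 10_000_000])
        ranked = rank_markers(np.array([0.99, 0.98, 0.97]), mm)
        panel = prune_select(ranked, 5.0, 2)
        assert panel.table["pos"].to_list() == [1_000_000, 10_000_000]
        assert not panel.shortfall

    def test_threshold_is_inclusive(self):
        mm = marker_map(["1", "1"], [1_000_000, 6_000_000])  # exactly 5 Mb apart
        ranked = rank_markers(np.array([0.9, 0.8]), mm)
        assert len(prune_select(ranked, 5.0, 2)) == 2
        assert len(prune_select(ranked, 5.001, 2)) == 1

    def test_different_chromosomes_never_conflict(self, rng):
        mm = marker_map([str(i + 1) for i in range(8)], [500] * 8)
        ranked = rank_markers(rng.random(8), mm)
        panel = prune_select(ranked, 10.0, 8)
        assert len(panel) == 8

    def test_matches_brute_force_greedy_oracle(self, rng):
        ranked = random_ranked(rng, n=500)
        panel = prune_select(ranked, 3.0, 100)
        accepted = []
        for row in ranked.itertuples(index=False):
            if len(accepted) >= 100:
                break
            if all(
                r.chrom != row.chrom or abs(r.pos - row.pos) >= 3_000_000
                for r in accepted
            ):
                accepted.append(row)
        assert panel.table["marker_id"].to_list() == [r.marker_id for r in accepted]

    def test_prefix_stability(self, rng):
        ranked = random_ranked(rng, n=300)
        panel = prune_select(ranked, 4.0, 50)
        last_id = panel.table["marker_id"].iloc[-1]
        cut = ranked.index[ranked["marker_id"] == last_id][0]
        truncated = ranked.iloc[: cut + 1]
        panel2 = prune_select(truncated, 4.0, 50)
        assert panel.table["marker_id"].to_list() == panel2.table["marker_id"].to_list()

    def test_shortfall_flagged(self):
        mm = marker_map(["1", "1"], [1_000_000, 2_000_000])
        ranked = rank_markers(np.array([0.9, 0.8]), mm)
        panel = prune_select(ranked, 5.0, 2)
        assert panel.shortfall and len(panel) == 1


class TestStepwiseSelect:
    def test_single_step_reduces_to_prune_select(self, rng):
        ranked = random_ranked(rng, n=200)
        one = prune_select(ranked, 5.0, 30)
        step = stepwise_select(ranked, [(30, 5.0)])
        assert step.table["marker_id"].to_list() == one.table["marker_id"].to_list()

    def test_two_step_hand_trace(self):
        mm = marker_map(
            ["1"] * 6,
            [1_000_000, 3_000_000, 7_000_000, 8_000_000, 20_000_000, 2_000_000],
            ids=list("ABCDEF"),
        )
        ranked = rank_markers(np.array([0.99, 0.98, 0.97, 0.96, 0.95, 0.94]), mm)
        panel = stepwise_select(ranked, [(2, 5.0), (2, 2.0)])
        # step 1 (5 Mb): A (1 Mb), skip B (2 Mb from A), C (6 Mb from A)
        # step 2 (2 Mb): B (2 Mb from A, 4 Mb from C), skip D (1 Mb from C), E
        assert panel.table["marker_id"].to_list() == ["A", "C", "B", "E"]
        assert panel.table["step_distance_mb"].to_list() == [5.0, 5.0, 2.0, 2.0]

    def test_distance_constraints_hold_by_audit(self, rng):
        ranked = random_ranked(rng, n=400)
        panel = stepwise_select(ranked, [(20, 6.0), (20, 3.0), (20, 1.0)])
        assert audit_panel_distances(panel)

    def test_shortfall_is_an_error(self):
        mm = marker_map(["1"] * 3, [1_000_000, 2_000_000, 3_000_000])
        ranked = rank_markers(np.array([0.9, 0.8, 0.7]), mm)
        with pytest.raises(ScheduleShortfallError, match="step 1"):
            stepwise_select(ranked, [(3, 5.0)])

    def test_distances_must_decrease(self, rng):
        ranked = random_ranked(rng, n=50)
        with pytest.raises(ValueError):
            stepwise_select(ranked, [(5, 3.0), (5, 3.0)])


class TestDistanceSweep:
    def test_row_per_distance_with_realized_size(self, rng):
        ranked = random_ranked(rng, n=300)
        sweep = distance_sweep(ranked, [1.0, 1.5, 2.0], 40, lambda p: {"metric": 1.0})
        assert len(sweep) == 3
        assert (sweep["panel_size"] <= 40).all()
        assert set(sweep.columns) >= {"distance_mb", "panel_size", "shortfall", "metric"}


def two_disjoint_panels(rng, n_each=600):
    ranked = random_ranked(rng, n=2 * n_each, n_chrom=20)
    a = Panel(ranked.iloc[:n_each].assign(
        rank=np.arange(1, n_each + 1), step_distance_mb=1.0
    ).reset_index(drop=True))
    b = Panel(ranked.iloc[n_each:].assign(
        rank=np.arange(1, n_each + 1), step_distance_mb=1.0
    ).reset_index(drop=True))
    return a, b


class TestCombinePanels:
    def test_ratio_25_of_500(self, rng):
        a, b = two_disjoint_panels(rng)
        panel = combine_panels(a, b, 500, 25)
        assert len(panel) == 500
        assert (panel.table["marker_id"][:125] == a.table["marker_id"][:125]).all()
        assert (panel.table["marker_id"][125:].to_numpy()
                == b.table["marker_id"][:375].to_numpy()).all()

    def test_ratio_35_of_400(self, rng):
        a, b = two_disjoint_panels(rng)
        panel = combine_panels(a, b, 400, 35)
        src = panel.table["marker_id"].isin(set(a.table["marker_id"])).sum()
        assert (src, len(panel) - src) == (140, 260)

    def test_extreme_ratio_is_top_of_a(self, rng):
        a, b = two_disjoint_panels(rng)
        panel = combine_panels(a, b, 500, 99.9)
        assert panel.table["marker_id"].to_list() == a.table["marker_id"][:500].to_list()

    def test_shared_markers_taken_once_from_a(self, rng):
        a, b = two_disjoint_panels(rng, n_each=300)
        # make b's top marker a duplicate of a's top marker
        b.table.iloc[0] = a.table.iloc[0]
        panel = combine_panels(a, b, 200, 50)
        assert panel.table["marker_id"].is_unique
        assert len(panel) == 200
        from_b = (~panel.table["marker_id"].isin(set(a.table["marker_id"]))).sum()
        assert from_b == 100  # B still contributes its quota, skipping the dup

    def test_insufficient_markers_rejected(self, rng):
        a, b = two_disjoint_panels(rng, n_each=100)
        with pytest.raises(CombineError):
            combine_panels(a, b, 500, 50)


class TestRatioSweep:
    def test_default_grid_cardinality(self, rng):
        a, b = two_disjoint_panels(rng)
        grid = ratio_sweep(a, b, lambda p: {"r2": float(len(p))})
        assert len(grid) == 45  # 5 sizes x 9 ratios
        assert (grid.groupby("size")["r2"].first() == [100, 200, 300, 400, 500]).all()


class TestPanelTsv:
    def test_round_trip(self, rng, tmp_path):
        ranked = random_ranked(rng, n=100)
        panel = stepwise_select(ranked, [(10, 5.0), (10, 2.0)])
        path = tmp_path / "panel.tsv"
        write_panel_tsv(panel, path)
        back = read_panel_tsv(path)
        pd.testing.assert_frame_equal(
            back.table.astype({"pos": np.int64}),
            panel.table.astype({"pos": np.int64}),
            check_dtype=False,
        )
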