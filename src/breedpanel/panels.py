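"""Ancestry-informative marker selection.

Markers are ranked by absolute allele-frequency difference between two
reference groups and selected greedily down the ranked list under a
minimum physical-distance constraint between accepted markers on the
same chromosome.  A step-wise schedule selects successive blocks under
progressively smaller distances (each step's distance enforced against
every previously accepted marker), and two optimized panels can be
combined in a stated ratio for multi-way ancestry.

Distances are measured between 1-based bp positions as |pos_i - pos_j|
and the threshold is inclusive: a candidate at exactly the pruning
distance is accepted.  Markers rejected at a large-distance step are
reconsidered at later, smaller-distance steps (the full ranked list is
rescanned each step).
"""
from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import chrom_sort_key
from .errors import CombineError, ComputationError, ScheduleShortfallError

PANEL_COLUMNS = [
    "rank",
    "marker_id",
    "chrom",
    "pos",
    "delta",
    "source_comparison",
    "step_distance_mb",
]

#: Step-wise schedules of the two optimized panels: (n_markers, distance_mb)
#: blocks with strictly decreasing distances.
DEFAULT_SCHEDULES = {
    "EXO_vs_IND": [(100, 8.5), (100, 7.5), (100, 6.5), (100, 4.5), (100, 3.5)],
    "HF_vs_J": [(100, 5.0), (200, 4.0), (200, 3.0)],
}

DEFAULT_SIZES = (100, 200, 300, 400, 500)
DEFAULT_RATIOS = (50, 45, 40, 35, 30, 25, 20, 15, 10)
DEFAULT_DISTANCE_GRID = tuple(np.arange(1.0, 10.01, 0.5))


@dataclass
class Panel:
    """An ordered SNP subset with per-marker selection provenance."""

    table: pd.DataFrame
    shortfall: bool = False

    def __len__(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> list[str]:
        return self.table["marker_id"].to_list()

    def validate(self) -> None:
        t = self.table
        if t["marker_id"].duplicated().any():
            raise ComputationError("duplicate marker ids in panel")
        if len(t) and list(t["rank"]) != list(range(1, len(t) + 1)):
            raise ComputationError("panel ranks must be consecutive from 1")


def rank_markers(
    diff_vector: np.ndarray, marker_map: pd.DataFrame, source: str = ""
) -> pd.DataFrame:
    """Rank markers by |delta p| descending.

    Ties are broken by (chromosome, position, marker id) ascending; loci
    with undefined differences are excluded.  Returns a DataFrame with
    columns ``marker_id, chrom, pos, delta, source_comparison``.
    """
    delta = np.asarray(diff_vector, float)
    if len(delta) != len(marker_map):
        raise ValueError("diff vector and marker map lengths differ")
    df = pd.DataFrame(
        {
            "marker_id": marker_map["id"].astype(str).to_numpy(),
            "chrom": marker_map["chrom"].astype(str).to_numpy(),
            "pos": marker_map["pos"].astype(np.int64).to_numpy(),
            "delta": delta,
            "source_comparison": source,
        }
    )
    df = df[np.isfinite(delta)]
    if df.empty:
        raise ComputationError("no markers with a defined frequency difference")
    df["_ckey"] = df["chrom"].map(chrom_sort_key)
    df = df.sort_values(["_ckey", "pos", "marker_id"], kind="mergesort")
    df = df.sort_values("delta", ascending=False, kind="mergesort")
    return df.drop(columns="_ckey").reset_index(drop=True)


class _DistanceIndex:
    """Per-chromosome sorted position lists for nearest-accepted lookups."""

    def __init__(self):
        self._by_chrom: dict[str, list[int]] = {}

    def add(self, chrom: str, pos: int) -> None:
        insort(self._by_chrom.setdefault(chrom, []), pos)

    def min_distance(self, chrom: str, pos: int) -> float:
        positions = self._by_chrom.get(chrom)
        if not positions:
            return np.inf
        i = bisect_left(positions, pos)
        best = np.inf
        if i < len(positions):
            best = min(best, positions[i] - pos)
        if i > 0:
            best = min(best, pos - positions[i - 1])
        return best


def prune_select(
    ranked: pd.DataFrame,
    distance_mb: float,
    n_target: int,
    already_accepted: pd.DataFrame | None = None,
    source: str | None = None,
) -> Panel:
    """Greedy distance-pruned selection down a ranked list.

    A candidate is accepted iff its distance to every accepted marker
    (including ``already_accepted``) on the same chromosome is at least
    ``distance_mb`` megabases.  Stops after ``n_target`` acceptances or
    when the list is exhausted (then ``shortfall`` is set).
    """
    if distance_mb <= 0:
        raise ValueError("pruning distance must be positive")
    d_bp = int(round(distance_mb * 1e6))
    index = _DistanceIndex()
    taken_ids: set[str] = set()
    if already_accepted is not None and len(already_accepted):
        for row in already_accepted.itertuples(index=False):
            index.add(str(row.chrom), int(row.pos))
            taken_ids.add(str(row.marker_id))
    rows = []
    for row in ranked.itertuples(index=False):
        if len(rows) >= n_target:
            break
        mid = str(row.marker_id)
        if mid in taken_ids:
            continue
        chrom, pos = str(row.chrom), int(row.pos)
        if index.min_distance(chrom, pos) < d_bp:
            continue
        index.add(chrom, pos)
        taken_ids.add(mid)
        rows.append(
            {
                "marker_id": mid,
                "chrom": chrom,
                "pos": pos,
                "delta": float(row.delta),
                "source_comparison": source
                if source is not None
                else getattr(row, "source_comparison", ""),
                "step_distance_mb": distance_mb,
            }
        )
    table = pd.DataFrame(rows, columns=PANEL_COLUMNS[1:])
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return Panel(table, shortfall=len(table) < n_target)


def stepwise_select(
    ranked: pd.DataFrame, schedule, source: str | None = None
) -> Panel:
    """Step-wise decreasing-distance selection.

    ``schedule`` is a sequence of ``(n_markers, distance_mb)`` steps with
    strictly decreasing distances.  Each step rescans the full ranked
    list (minus already-accepted markers) and enforces its distance
    against all previously accepted markers, so step outputs are nested.
    A shortfall at any step raises :class:`ScheduleShortfallError`.
    """
    schedule = [(int(n), float(d)) for n, d in schedule]
    if not schedule:
        raise ValueError("empty schedule")
    distances = [d for _, d in schedule]
    if any(b >= a for a, b in zip(distances, distances[1:])):
        raise ValueError("schedule distances must be strictly decreasing")
    if any(n < 1 for n, _ in schedule):
        raise ValueError("each step must request at least one marker")
    accepted: pd.DataFrame | None = None
    parts = []
    for i, (n_step, dist) in enumerate(schedule, start=1):
        step_panel = prune_select(ranked, dist, n_step, already_accepted=accepted, source=source)
        if step_panel.shortfall:
            raise ScheduleShortfallError(i, n_step, len(step_panel), dist)
        parts.append(step_panel.table)
        accepted = pd.concat(parts, ignore_index=True)
    table = pd.concat(parts, ignore_index=True)
    table["rank"] = np.arange(1, len(table) + 1)
    panel = Panel(table)
    panel.validate()
    return panel


def audit_panel_distances(panel: Panel) -> bool:
    """Independent all-pairs check of a panel's own distance constraints.

    Every pair of same-chromosome markers must be at least the *later*
    (smaller) of their two recorded step distances apart.
    """
    t = panel.table
    for i in range(len(t)):
        for j in range(i + 1, len(t)):
            if t["chrom"].iat[i] != t["chrom"].iat[j]:
                continue
            required = min(t["step_distance_mb"].iat[i], t["step_distance_mb"].iat[j])
            gap = abs(int(t["pos"].iat[i]) - int(t["pos"].iat[j]))
            if gap < int(round(required * 1e6)):
                return False
    return True


def distance_sweep(
    ranked: pd.DataFrame,
    distances,
    n_target: int,
    evaluator,
    source: str | None = None,
) -> pd.DataFrame:
    """Evaluate one pruned panel per distance.

    ``evaluator`` maps a :class:`Panel` to a dict of metric columns
    (e.g. ``r2_IND``).  Shortfall panels are evaluated as-is and the row
    is flagged rather than fatal.
    """
    rows = []
    for d in distances:
        panel = prune_select(ranked, float(d), n_target, source=source)
        row = {
            "distance_mb": float(d),
            "panel_size": len(panel),
            "shortfall": panel.shortfall,
        }
        row.update(evaluator(panel))
        rows.append(row)
    return pd.DataFrame(rows)


def combine_panels(
    panel_a: Panel, panel_b: Panel, total_size: int, ratio_a_percent: float
) -> Panel:
    """Combine two optimized panels in a stated ratio.

    Takes the top ``round(total_size * ratio/100)`` entries of panel A
    and fills the remainder from the top of panel B, preserving each
    panel's internal order (A block first).  A marker present in both is
    taken once, from A, with B contributing one extra to keep the size.
    """
    if not 0 < ratio_a_percent < 100:
        raise ValueError("ratio must lie strictly between 0 and 100")
    n_a = int(round(total_size * ratio_a_percent / 100.0))
    if n_a > len(panel_a):
        raise CombineError(
            f"panel A has {len(panel_a)} markers; {n_a} requested"
        )
    a_part = panel_a.table.head(n_a)
    a_ids = set(a_part["marker_id"])
    b_rows = panel_b.table[~panel_b.table["marker_id"].isin(a_ids)]
    n_b = total_size - n_a
    if n_b > len(b_rows):
        raise CombineError(
            f"panel B supplies only {len(b_rows)} unique markers; {n_b} needed"
        )
    table = pd.concat([a_part, b_rows.head(n_b)], ignore_index=True)
    table["rank"] = np.arange(1, len(table) + 1)
    panel = Panel(table)
    panel.validate()
    return panel


def ratio_sweep(
    panel_a: Panel,
    panel_b: Panel,
    evaluator,
    sizes=DEFAULT_SIZES,
    ratios=DEFAULT_RATIOS,
) -> pd.DataFrame:
    """Evaluate the grid of combined panels over sizes x A-ratios."""
    rows = []
    for size in sizes:
        for ratio in ratios:
            panel = combine_panels(panel_a, panel_b, int(size), float(ratio))
            row = {"size": int(size), "ratio_a": float(ratio)}
            row.update(evaluator(panel))
            rows.append(row)
    return pd.DataFrame(rows)


def select_optimum(
    grid: pd.DataFrame, constraint_column: str, constraint_min: float, objective_columns
) -> pd.Series:
    """Best sweep row: smallest panel meeting the constraint with the
    highest mean of the objective metrics (ties -> fewer markers)."""
    ok = grid[grid[constraint_column] >= constraint_min].copy()
    if ok.empty:
        raise ComputationError(
            f"no grid row satisfies {constraint_column} >= {constraint_min}"
        )
    ok["_objective"] = ok[list(objective_columns)].mean(axis=1)
    ok = ok.sort_values(["_objective", "size"], ascending=[False, True], kind="mergesort")
    return ok.iloc[0].drop("_objective")


# ----------------------------------------------------------------------
# TSV round-trip (mirrors the published panel-table layout)


def write_panel_tsv(panel: Panel, path) -> None:
    panel.table[PANEL_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_panel_tsv(path) -> Panel:
    table = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str})
    panel = Panel(table[PANEL_COLUMNS])
    panel.validate()
    return panel
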