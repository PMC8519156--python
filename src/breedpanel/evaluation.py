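"""Panel performance against full-marker ancestry estimates.

A small panel is judged by how well its ancestry estimates recover the
estimates obtained with all markers: accuracy is the squared Pearson
correlation, linear bias the mean of (panel - full) deviations, and
dispersion their sample standard deviation.  Reports can be restricted
to subgroups defined on the full-marker estimates (e.g. crosses with
Jersey content below 50%).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeMatrix
from .admixture import estimate_cohort
from .errors import ComputationError

REPORT_COLUMNS = [
    "ancestry",
    "subgroup",
    "n",
    "r_squared",
    "linear_bias",
    "sd_deviation",
    "flagged",
]


def accuracy(est_small, est_full) -> float:
    """Squared Pearson correlation between panel and full estimates."""
    a = np.asarray(est_small, float)
    b = np.asarray(est_full, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("accuracy needs two equal-length vectors of length >= 2")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ComputationError("zero variance; correlation undefined")
    r = stats.pearsonr(a, b).statistic
    return float(r * r)


def bias(est_small, est_full) -> tuple[float, float]:
    """Mean and sample SD (n-1) of the (panel - full) deviations."""
    a = np.asarray(est_small, float)
    b = np.asarray(est_full, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("bias needs two equal-length vectors of length >= 2")
    dev = a - b
    return float(dev.mean()), float(dev.std(ddof=1))


def _ancestry_columns(full_estimates: pd.DataFrame) -> list[str]:
    return [c[2:] for c in full_estimates.columns if c.startswith("q_")]


def compare_estimates(
    small: pd.DataFrame,
    full: pd.DataFrame,
    subgroups: dict | None = None,
) -> pd.DataFrame:
    """Per-ancestry accuracy/bias report of panel vs full estimates.

    ``subgroups`` maps a label to a boolean-mask callable evaluated on
    the *full* estimates.  Subgroups with n < 2 or degenerate variance
    are flagged rather than fatal.
    """
    missing = full.index.difference(small.index)
    if len(missing):
        raise ComputationError(f"panel estimates missing for {list(missing[:5])}")
    small = small.loc[full.index]
    groups: dict[str, np.ndarray] = {"all": np.ones(len(full), dtype=bool)}
    for name, fn in (subgroups or {}).items():
        groups[name] = np.asarray(fn(full), dtype=bool)
    rows = []
    for ancestry in _ancestry_columns(full):
        col = f"q_{ancestry}"
        if col not in small.columns:
            continue
        for name, mask in groups.items():
            n = int(mask.sum())
            row = {
                "ancestry": ancestry,
                "subgroup": name,
                "n": n,
                "r_squared": np.nan,
                "linear_bias": np.nan,
                "sd_deviation": np.nan,
                "flagged": False,
            }
            if n < 2:
                row["flagged"] = True
            else:
                a = small.loc[mask, col].to_numpy()
                b = full.loc[mask, col].to_numpy()
                row["linear_bias"], row["sd_deviation"] = bias(a, b)
                try:
                    row["r_squared"] = accuracy(a, b)
                except ComputationError:
                    row["flagged"] = True
            rows.append(row)
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def evaluate_panel(
    gm: GenotypeMatrix,
    panel,
    reference_populations: list[str],
    full_estimates: pd.DataFrame,
    subgroups: dict | None = None,
    **estimate_kwargs,
) -> pd.DataFrame:
    """Estimate the cohort with the panel and report accuracy and bias."""
    small = estimate_cohort(gm, reference_populations, panel=panel, **estimate_kwargs)
    return compare_estimates(small, full_estimates, subgroups=subgroups)


def make_evaluator(
    gm: GenotypeMatrix,
    reference_populations: list[str],
    full_estimates: pd.DataFrame,
    ancestries: list[str] | None = None,
    **estimate_kwargs,
):
    """Closure used by the distance/ratio sweeps.

    Maps a panel to flat metric columns ``r2_<anc>`` and ``bias_<anc>``.
    """
    if ancestries is None:
        ancestries = _ancestry_columns(full_estimates)

    def evaluator(panel) -> dict[str, float]:
        small = estimate_cohort(
            gm, reference_populations, panel=panel, **estimate_kwargs
        )
        out: dict[str, float] = {}
        for anc in ancestries:
            col = f"q_{anc}"
            a = small.loc[full_estimates.index, col].to_numpy()
            b = full_estimates[col].to_numpy()
            out[f"r2_{anc}"] = accuracy(a, b)
            out[f"bias_{anc}"], out[f"sd_{anc}"] = bias(a, b)
        return out

    return evaluator


def write_report_tsv(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format="%.10g")
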