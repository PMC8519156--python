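"""Shared fixtures.

The heavy study-scale simulation (calibrated four-population cohort,
full-marker estimates, step-wise panels and combined-panel metrics) is
computed once per session and shared across the evaluation, synthetic
and acceptance tests.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from breedpanel import (
    DEFAULT_SCHEDULES,
    GenotypeMatrix,
    abs_freq_diff,
    allele_frequencies,
    combine_panels,
    estimate_cohort,
    make_evaluator,
    rank_markers,
    stepwise_select,
)
from breedpanel.panels import distance_sweep
from breedpanel.simulate import study_preset, simulate_cohort

REFS = ["H", "F", "J", "IND"]
POOLED = {"EXO": ["H", "F", "J"], "HF": ["H", "F"]}
PANEL_SIZES = (100, 200, 300, 400, 500)


def reference_frequencies(gm: GenotypeMatrix):
    ref_gm = gm.subset_samples(gm.samples["population"].isin(REFS).to_numpy())
    return allele_frequencies(ref_gm, pooled=POOLED)


@pytest.fixture(scope="session")
def preset_run():
    """Full study-scale run: cohort, full-marker estimates, panels and
    combined-panel metrics at the 25:75 ratio for all panel sizes."""
    cfg = study_preset()  # shipped seed, 200 targets, L = 20,000
    gm, truth, _ = simulate_cohort(cfg)
    full = estimate_cohort(gm, REFS)
    pf = reference_frequencies(gm)
    ranked = {
        "EXO_vs_IND": rank_markers(
            abs_freq_diff(pf, "EXO", "IND"), pf.markers, "EXO_vs_IND"
        ),
        "HF_vs_J": rank_markers(abs_freq_diff(pf, "HF", "J"), pf.markers, "HF_vs_J"),
    }
    panels = {
        name: stepwise_select(ranked[name], DEFAULT_SCHEDULES[name], source=name)
        for name in ranked
    }
    evaluator = make_evaluator(gm, REFS, full)
    metrics_by_size = {
        size: evaluator(
            combine_panels(panels["EXO_vs_IND"], panels["HF_vs_J"], size, 25)
        )
        for size in PANEL_SIZES
    }
    return {
        "config": cfg,
        "gm": gm,
        "truth": truth,
        "full": full,
        "pf": pf,
        "ranked": ranked,
        "panels": panels,
        "metrics_by_size": metrics_by_size,
    }


@pytest.fixture(scope="session")
def clustered_sweep():
    """Pruning-distance sweep on a cohort whose most informative loci sit
    in tight clusters of highly correlated near-copies."""
    cfg = study_preset(seed=777, n_target=100, L=4000, clustered=True)
    gm, truth, _ = simulate_cohort(cfg)
    full = estimate_cohort(gm, REFS)
    pf = reference_frequencies(gm)
    ranked = rank_markers(abs_freq_diff(pf, "EXO", "IND"), pf.markers, "EXO_vs_IND")
    evaluator = make_evaluator(gm, REFS, full, ancestries=["IND"])
    sweep = distance_sweep(ranked, [1.0, 4.0, 4.5, 5.0], 100, evaluator)
    return sweep


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_genotype_matrix(
    rng, n_samples=6, n_markers=20, missing_rate=0.1, populations=None
) -> GenotypeMatrix:
    calls = rng.integers(0, 3, size=(n_samples, n_markers)).astype(np.int8)
    calls[rng.random(calls.shape) < missing_rate] = -1
    markers = pd.DataFrame(
        {
            "id": [f"m{i}" for i in range(n_markers)],
            "chrom": [str(1 + i % 3) for i in range(n_markers)],
            "pos": 1000 * (1 + np.arange(n_markers)),
            "a1": "A",
            "a2": "B",
        }
    )
    if populations is None:
        populations = ["P1"] * n_samples
    samples = pd.DataFrame(
        {"id": [f"s{i}" for i in range(n_samples)], "population": populations}
    )
    return GenotypeMatrix.create(calls, markers, samples)
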