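"""End-to-end panel-design workflow with a validated configuration.

Stages: simulate/ingest -> QC -> reference frequencies -> rank ->
step-wise select -> combine -> estimate (full + panels) -> evaluate.
Every stage writes TSV outputs into the run directory and the run ends
with a JSON manifest recording package version, seeds and SHA-256
hashes of each output, so reruns can be verified byte-for-byte.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .admixture import estimate_cohort, write_estimates_tsv
from .core import GenotypeMatrix
from .errors import ConfigError
from .evaluation import compare_estimates, make_evaluator, write_report_tsv
from .genotype_io import (
    autosome_filter,
    ibs_duplicate_filter,
    qc_filter,
    read_plink,
    read_vcf,
    write_labels,
    write_plink,
)
from .panels import (
    DEFAULT_SCHEDULES,
    combine_panels,
    rank_markers,
    stepwise_select,
    write_panel_tsv,
)
from .popgen import abs_freq_diff, allele_frequencies, write_frequencies_tsv
from .simulate import study_preset, simulate_cohort, write_truth_tsv

log = logging.getLogger(__name__)


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateSection(_Section):
    preset: str = "study"
    n_target: int = 200
    L: int = 20000
    clustered: bool = False
    missing_rate: float = 0.01


class InputSection(_Section):
    bed: str | None = None
    bim: str | None = None
    fam: str | None = None
    vcf: str | None = None
    labels: str | None = None


class QCSection(_Section):
    min_marker_call_rate: float = 0.9
    min_sample_call_rate: float = 0.9
    ibs_threshold: float = 0.98
    autosomes: list[str] | None = None


class GroupsSection(_Section):
    references: list[str] = Field(default_factory=lambda: ["H", "F", "J", "IND"])
    pooled: dict[str, list[str]] = Field(
        default_factory=lambda: {"EXO": ["H", "F", "J"], "HF": ["H", "F"]}
    )


class ComparisonSection(_Section):
    name: str
    group_a: str
    group_b: str
    schedule: list[tuple[int, float]]


class CombineSection(_Section):
    panel_a: str = "EXO_vs_IND"
    panel_b: str = "HF_vs_J"
    sizes: list[int] = Field(default_factory=lambda: [500])
    ratios: list[float] = Field(default_factory=lambda: [25.0])


class EstimationSection(_Section):
    tol: float = 1e-8
    max_iter: int = 2000


def _default_comparisons() -> list[ComparisonSection]:
    return [
        ComparisonSection(
            name="EXO_vs_IND", group_a="EXO", group_b="IND",
            schedule=DEFAULT_SCHEDULES["EXO_vs_IND"],
        ),
        ComparisonSection(
            name="HF_vs_J", group_a="HF", group_b="J",
            schedule=DEFAULT_SCHEDULES["HF_vs_J"],
        ),
    ]


class RunConfig(_Section):
    """Schema-validated pipeline configuration (unknown keys rejected)."""

    seed: int = 1
    out_dir: str = "breedpanel_run"
    simulate: SimulateSection | None = None
    input: InputSection | None = None
    qc: QCSection = Field(default_factory=QCSection)
    groups: GroupsSection = Field(default_factory=GroupsSection)
    comparisons: list[ComparisonSection] = Field(default_factory=_default_comparisons)
    combine: CombineSection = Field(default_factory=CombineSection)
    estimation: EstimationSection = Field(default_factory=EstimationSection)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig | dict | str | Path) -> Path:
    """Execute the full workflow; returns the run directory."""
    if isinstance(config, (str, Path)):
        config = load_config(config)
    elif isinstance(config, dict):
        config = RunConfig(**config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    def record(name: str, *paths: Path) -> None:
        stages.append(
            {"name": name, "outputs": {p.name: _sha256(p) for p in paths}}
        )

    # 1 -- simulate or ingest -----------------------------------------
    if (config.simulate is None) == (config.input is None):
        raise ConfigError("exactly one of 'simulate' or 'input' must be given")
    if config.simulate is not None:
        sim = config.simulate
        if sim.preset != "study":
            raise ConfigError(f"unknown preset {sim.preset!r}")
        sim_cfg = study_preset(
            seed=config.seed,
            n_target=sim.n_target,
            L=sim.L,
            clustered=sim.clustered,
            missing_rate=sim.missing_rate,
        )
        gm, truth, _ = simulate_cohort(sim_cfg)
        write_plink(gm, out / "genotypes")
        write_labels(gm.samples, out / "labels.tsv")
        write_truth_tsv(truth, out / "truth.tsv")
        record(
            "simulate",
            out / "genotypes.bed", out / "genotypes.bim", out / "genotypes.fam",
            out / "labels.tsv", out / "truth.tsv",
        )
    else:
        inp = config.input
        if inp.vcf:
            gm = read_vcf(inp.vcf, inp.labels)
        elif inp.bed and inp.bim and inp.fam:
            gm = read_plink(inp.bed, inp.bim, inp.fam, inp.labels)
        else:
            raise ConfigError("input needs either 'vcf' or 'bed'+'bim'+'fam'")
        stages.append({"name": "ingest", "outputs": {}})

    # 2 -- QC ----------------------------------------------------------
    qc = config.qc
    n_m0, n_s0 = gm.n_markers, gm.n_samples
    gm = autosome_filter(gm, qc.autosomes)
    gm = qc_filter(gm, qc.min_marker_call_rate, qc.min_sample_call_rate)
    gm = ibs_duplicate_filter(gm, qc.ibs_threshold)
    qc_summary = pd.DataFrame(
        [
            {"stage": "input", "markers": n_m0, "samples": n_s0},
            {"stage": "after_qc", "markers": gm.n_markers, "samples": gm.n_samples},
        ]
    )
    qc_summary.to_csv(out / "qc_summary.tsv", sep="\t", index=False)
    record("qc", out / "qc_summary.tsv")

    # 3 -- reference allele frequencies --------------------------------
    refs = config.groups.references
    ref_gm = gm.subset_samples(gm.samples["population"].isin(refs).to_numpy())
    pf = allele_frequencies(ref_gm, pooled=config.groups.pooled)
    write_frequencies_tsv(pf, out / "frequencies.tsv")
    record("freqs", out / "frequencies.tsv")

    # 4 -- rank ---------------------------------------------------------
    ranked = {}
    rank_paths = []
    for comp in config.comparisons:
        r = rank_markers(
            abs_freq_diff(pf, comp.group_a, comp.group_b), pf.markers, comp.name
        )
        ranked[comp.name] = r
        path = out / f"ranked_{comp.name}.tsv"
        r.to_csv(path, sep="\t", index=False, float_format="%.10g")
        rank_paths.append(path)
    record("rank", *rank_paths)

    # 5 -- step-wise select ---------------------------------------------
    panels = {}
    select_paths = []
    for comp in config.comparisons:
        panel = stepwise_select(ranked[comp.name], comp.schedule, source=comp.name)
        panels[comp.name] = panel
        path = out / f"panel_{comp.name}.tsv"
        write_panel_tsv(panel, path)
        select_paths.append(path)
    record("select", *select_paths)

    # 6 -- combine -------------------------------------------------------
    combined = {}
    combine_paths = []
    for size in config.combine.sizes:
        for ratio in config.combine.ratios:
            panel = combine_panels(
                panels[config.combine.panel_a],
                panels[config.combine.panel_b],
                int(size),
                float(ratio),
            )
            key = f"{size}_{ratio:g}"
            combined[key] = panel
            path = out / f"panel_combined_{key}.tsv"
            write_panel_tsv(panel, path)
            combine_paths.append(path)
    record("combine", *combine_paths)

    # 7 -- estimate (full markers + every combined panel) ----------------
    est = config.estimation
    full = estimate_cohort(gm, refs, tol=est.tol, max_iter=est.max_iter)
    write_estimates_tsv(full, out / "estimates_full.tsv")
    est_paths = [out / "estimates_full.tsv"]
    small = {}
    for key, panel in combined.items():
        small[key] = estimate_cohort(
            gm, refs, panel=panel, tol=est.tol, max_iter=est.max_iter
        )
        path = out / f"estimates_panel_{key}.tsv"
        write_estimates_tsv(small[key], path)
        est_paths.append(path)
    record("estimate", *est_paths)

    # 8 -- evaluate -------------------------------------------------------
    reports = []
    for key, est_df in small.items():
        report = compare_estimates(est_df, full)
        report.insert(0, "panel", key)
        reports.append(report)
    evaluation = pd.concat(reports, ignore_index=True)
    write_report_tsv(evaluation, out / "evaluation.tsv")
    record("evaluate", out / "evaluation.tsv")

    manifest = {
        "package": "breedpanel",
        "version": __version__,
        "seed": config.seed,
        "stages": stages,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("pipeline finished: %d stages in %s", len(stages), out)
    return out
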