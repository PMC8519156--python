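"""Synthetic crossbred genotypes under a hierarchical Balding–Nichols
drift model.

Population structure is a rooted tree with a drift parameter F on each
branch: given the parent's allele frequency p, a child node draws

    p' ~ Beta( p (1-F)/F , (1-p)(1-F)/F )

independently per locus, so E[p'] = p and Var[p'] = F p (1-p).  The
default topology mirrors an indicine/taurine cattle system: a deep
split between an indigenous indicine population (IND) and the taurine
ancestor, which splits into Jersey (J) and a Holstein/Friesian ancestor
carrying Holstein (H) and Friesian (F).  Branch drifts of the shipped
preset are calibrated by bisection so the realized pairwise Hudson F_ST
values sit near 0.16 (J-H), 0.137 (J-F) and 0.074 (H-F), with the
indicine/taurine differentiation at about 0.35.

Reference individuals are pure members of a leaf population; crossbred
targets carry a known ancestry vector q and draw dosages
x_l ~ Binomial(2, sum_k q_k p_kl).  Loci are independent given the
frequencies; an optional clustered-informativeness mode plants tight
physical clusters of highly correlated copies of the most ancestry-
informative loci, recreating the local-LD redundancy that physical-
distance pruning is designed to defeat.
"""
from __future__ import annotations

import functools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, TARGET_LABEL, GenotypeMatrix, chrom_sort_key
from .errors import CalibrationError
from .popgen import PopulationFrequencies, fst_from_frequencies

log = logging.getLogger(__name__)

#: Seed shipped with the study-like preset.
PRESET_SEED = 20210309

_CAL_SEED = 701  # internal seed of the drift-calibration simulations
_CAL_L = 50000


# ----------------------------------------------------------------------
# population tree


@dataclass(frozen=True)
class TreeNode:
    """Node of the population tree; ``drift`` is F on the branch leading
    to this node (0 at the root).  Leaves carry population names."""

    name: str | None
    drift: float
    children: tuple["TreeNode", ...] = ()

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out: list[str] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def validate(self) -> None:
        if self.drift < 0 or self.drift >= 1:
            raise ValueError("branch drift must lie in [0, 1)")
        for child in self.children:
            if not 0 < child.drift < 1:
                raise ValueError("non-root branch drift must lie in (0, 1)")
            child.validate()


def four_breed_tree(
    f_ind: float, f_tau: float, f_j: float, f_hf: float, f_h: float, f_f: float
) -> TreeNode:
    """Indicine/taurine topology: (IND, (J, (H, F)))."""
    return TreeNode(
        None,
        0.0,
        (
            TreeNode("IND", f_ind),
            TreeNode(
                None,
                f_tau,
                (
                    TreeNode("J", f_j),
                    TreeNode(None, f_hf, (TreeNode("H", f_h), TreeNode("F", f_f))),
                ),
            ),
        ),
    )


def two_population_tree(f: float, names=("A", "B")) -> TreeNode:
    """Two populations drifted independently from a common ancestor;
    pairwise Hudson F_ST concentrates near ``f``."""
    return TreeNode(None, 0.0, (TreeNode(names[0], f), TreeNode(names[1], f)))


# ----------------------------------------------------------------------
# configuration


def default_chromosomes(n: int = 29) -> list[tuple[str, int]]:
    """Cattle-like autosome map: 29 chromosomes from 160 Mb down to 40 Mb."""
    lengths = np.linspace(160e6, 40e6, n).astype(np.int64)
    return [(str(i + 1), int(lengths[i])) for i in range(n)]


@dataclass
class SimulationConfig:
    """Study conditions of a synthetic cohort.

    The preset defaults mirror the design the toolkit targets: reference
    panels of 24 Holstein, 24 Friesian, 24 Jersey and 101 indicine
    animals; crossbred targets whose indicine fraction spans ~1-99%
    (uniform) with the taurine remainder split Dirichlet(4, 4, 1) over
    (H, F, J); 29 autosomes with uniformly placed markers.
    """

    tree: TreeNode
    n_ref: dict[str, int]
    n_target: int
    L: int
    chromosomes: list[tuple[str, int]] = field(default_factory=default_chromosomes)
    freq_range: tuple[float, float] = (0.05, 0.95)
    target_q: np.ndarray | None = None
    dirichlet_alpha: tuple | None = None
    deep_population: str = "IND"
    deep_range: tuple[float, float] = (0.01, 0.99)
    #: Mixture of cross types for the taurine remainder: (weight, Dirichlet
    #: alpha per taurine breed).  Default: mostly Holstein-Friesian-type
    #: crosses plus a small Jersey-type fraction.
    taurine_mixture: list[tuple[float, dict[str, float]]] = field(
        default_factory=lambda: [
            (0.936, {"H": 4.6, "F": 4.4, "J": 1.0}),
            (0.064, {"H": 1.0, "F": 2.5, "J": 3.1}),
        ]
    )
    missing_rate: float = 0.01
    seed: int = PRESET_SEED
    clustered: bool = False
    cluster_top: int = 150
    cluster_copies: int = 4
    cluster_rho: float = 0.95
    cluster_spacing_bp: int = 700_000

    @property
    def populations(self) -> list[str]:
        return self.tree.leaves()

    def validate(self) -> None:
        self.tree.validate()
        if sum(length for _, length in self.chromosomes) <= 0:
            raise ValueError("total chromosome length must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        for pop in self.n_ref:
            if pop not in self.populations:
                raise ValueError(f"n_ref references unknown population {pop!r}")


@dataclass
class TruthTable:
    """Known ancestry vectors of the simulated targets."""

    table: pd.DataFrame  # index sample_id, columns q_<pop>

    def q_matrix(self, populations: list[str]) -> np.ndarray:
        return self.table[[f"q_{p}" for p in populations]].to_numpy()


# ----------------------------------------------------------------------
# frequency simulation


def _drift_frequencies(p: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    if f <= 0:
        return p.copy()
    scale = (1.0 - f) / f
    child = rng.beta(np.maximum(p * scale, 1e-12), np.maximum((1.0 - p) * scale, 1e-12))
    return np.clip(child, 1e-9, 1.0 - 1e-9)


def _walk_tree(node: TreeNode, p: np.ndarray, rng, out: dict[str, np.ndarray]) -> None:
    if not node.children:
        out[node.name] = p
        return
    for child in node.children:  # pre-order, deterministic
        _walk_tree(child, _drift_frequencies(p, child.drift, rng), rng, out)


def _leaf_frequencies(config: SimulationConfig, rng) -> dict[str, np.ndarray]:
    lo, hi = config.freq_range
    p0 = rng.uniform(lo, hi, size=config.L)
    out: dict[str, np.ndarray] = {}
    _walk_tree(config.tree, p0, rng, out)
    return out


def _marker_positions(config: SimulationConfig, rng) -> pd.DataFrame:
    labels = [c for c, _ in config.chromosomes]
    lengths = np.array([length for _, length in config.chromosomes], float)
    chrom_idx = rng.choice(len(labels), size=config.L, p=lengths / lengths.sum())
    pos = (rng.random(config.L) * lengths[chrom_idx]).astype(np.int64) + 1
    return pd.DataFrame(
        {"chrom": [labels[i] for i in chrom_idx], "pos": pos, "a1": "A", "a2": "B"}
    )


def _simulate_frequency_table(config: SimulationConfig, rng):
    """Leaf frequencies + marker map; returns (pf, parent_index).

    ``parent_index[j]`` is the column index of the locus a clustered
    near-copy was cloned from (-1 for base loci).
    """
    leaf = _leaf_frequencies(config, rng)
    markers = _marker_positions(config, rng)
    pops = config.populations
    freqs = np.stack([leaf[p] for p in pops])
    parent = np.full(config.L, -1, dtype=np.int64)

    if config.clustered:
        deep = config.deep_population
        others = [p for p in pops if p != deep]
        delta = np.abs(leaf[deep] - np.mean([leaf[p] for p in others], axis=0))
        top = np.argsort(-delta, kind="stable")[: config.cluster_top]
        extra_markers, extra_freqs, extra_parent = [], [], []
        for j in top:
            for c in range(1, config.cluster_copies + 1):
                extra_markers.append(
                    {
                        "chrom": markers["chrom"].iat[j],
                        "pos": int(markers["pos"].iat[j]) + c * config.cluster_spacing_bp,
                        "a1": "A",
                        "a2": "B",
                    }
                )
                extra_freqs.append(freqs[:, j])
                extra_parent.append(j)
        markers = pd.concat([markers, pd.DataFrame(extra_markers)], ignore_index=True)
        freqs = np.concatenate([freqs, np.stack(extra_freqs, axis=1)], axis=1)
        parent = np.concatenate([parent, np.asarray(extra_parent, dtype=np.int64)])

    markers.insert(0, "id", [f"snp{i:06d}" for i in range(len(markers))])
    keys = [
        (chrom_sort_key(c), int(p), str(i))
        for c, p, i in zip(markers["chrom"], markers["pos"], markers["id"])
    ]
    order = np.asarray(sorted(range(len(keys)), key=keys.__getitem__))
    remap = {old: new for new, old in enumerate(order)}
    parent = parent[order]
    parent = np.array([-1 if p < 0 else remap[p] for p in parent], dtype=np.int64)
    markers = markers.iloc[order].reset_index(drop=True)
    freqs = freqs[:, order]
    counts = np.full_like(freqs, np.inf)
    pf = PopulationFrequencies(pops, freqs, counts, markers)
    return pf, parent


def simulate_frequencies(config: SimulationConfig) -> PopulationFrequencies:
    """Per-leaf allele frequencies with marker positions (deterministic
    under ``config.seed``)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    pf, _ = _simulate_frequency_table(config, rng)
    return pf


# ----------------------------------------------------------------------
# cohort simulation


def _draw_target_q(config: SimulationConfig, rng) -> np.ndarray:
    pops = config.populations
    n = config.n_target
    if n == 0:
        return np.zeros((0, len(pops)))
    if config.target_q is not None:
        q = np.asarray(config.target_q, float)
        if q.shape != (n, len(pops)):
            raise ValueError("explicit target_q has wrong shape")
        return q
    if config.dirichlet_alpha is not None:
        return rng.dirichlet(config.dirichlet_alpha, size=n)
    # study-like law: deep (indicine) fraction uniform, taurine remainder
    # split by a mixture of cross-type Dirichlets over the remaining breeds
    deep = rng.uniform(*config.deep_range, size=n)
    others = [p for p in pops if p != config.deep_population]
    weights = np.array([w for w, _ in config.taurine_mixture], float)
    weights /= weights.sum()
    component = rng.choice(len(weights), size=n, p=weights)
    split = np.empty((n, len(others)))
    for c, (_, alpha) in enumerate(config.taurine_mixture):
        mask = component == c
        if mask.any():
            split[mask] = rng.dirichlet([alpha[p] for p in others], size=int(mask.sum()))
    q = np.zeros((n, len(pops)))
    q[:, pops.index(config.deep_population)] = deep
    for j, p in enumerate(others):
        q[:, pops.index(p)] = (1.0 - deep) * split[:, j]
    return q


def simulate_cohort(config: SimulationConfig):
    """Simulate references plus crossbred targets.

    Returns ``(GenotypeMatrix, TruthTable, PopulationFrequencies)``; the
    frequency table is the same one :func:`simulate_frequencies` yields
    for the same config.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pf, parent = _simulate_frequency_table(config, rng)
    pops = config.populations
    K, L = pf.freqs.shape

    sample_ids: list[str] = []
    labels: list[str] = []
    q_rows: list[np.ndarray] = []
    for k, pop in enumerate(pops):
        for i in range(config.n_ref.get(pop, 0)):
            sample_ids.append(f"{pop}_{i + 1:03d}")
            labels.append(pop)
            q_rows.append(np.eye(K)[k])
    target_q = _draw_target_q(config, rng)
    for i in range(config.n_target):
        sample_ids.append(f"TGT_{i + 1:03d}")
        labels.append(TARGET_LABEL)
        q_rows.append(target_q[i])
    Q = np.stack(q_rows) if q_rows else np.zeros((0, K))

    pi = Q @ pf.freqs
    calls = rng.binomial(2, pi).astype(np.int8)

    clones = np.flatnonzero(parent >= 0)
    if clones.size:
        copy_mask = rng.random((calls.shape[0], clones.size)) < config.cluster_rho
        calls[:, clones] = np.where(copy_mask, calls[:, parent[clones]], calls[:, clones])

    if config.missing_rate > 0:
        calls[rng.random(calls.shape) < config.missing_rate] = MISSING

    gm = GenotypeMatrix.create(
        calls,
        pf.markers,
        pd.DataFrame({"id": sample_ids, "population": labels}),
    )
    truth = TruthTable(
        pd.DataFrame(
            {f"q_{p}": target_q[:, j] for j, p in enumerate(pops)},
            index=pd.Index(
                [s for s, lab in zip(sample_ids, labels) if lab == TARGET_LABEL],
                name="sample_id",
            ),
        )
    )
    return gm, truth, pf


# ----------------------------------------------------------------------
# drift calibration and the study-like preset


def _realized_fsts(drift: dict[str, float], L: int, seed: int) -> dict[tuple[str, str], float]:
    tree = four_breed_tree(**drift)
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(0.05, 0.95, size=L)
    leaf: dict[str, np.ndarray] = {}
    _walk_tree(tree, p0, rng, leaf)
    pairs = [("J", "H"), ("J", "F"), ("H", "F"), ("IND", "H"), ("IND", "F"), ("IND", "J")]
    return {(a, b): fst_from_frequencies(leaf[a], leaf[b]) for a, b in pairs}


def _bisect(fun, lo: float, hi: float, target: float, iters: int = 22) -> float:
    """Bisection for an increasing noisy function; clamps at the ends."""
    if fun(lo) >= target:
        return lo
    if fun(hi) <= target:
        return hi
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if fun(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@functools.lru_cache(maxsize=4)
def calibrate_drift(
    fst_jh: float = 0.16,
    fst_jf: float = 0.137,
    fst_hf: float = 0.074,
    fst_deep: float = 0.35,
    L: int = _CAL_L,
    seed: int = _CAL_SEED,
    tolerance: float = 0.02,
) -> dict[str, float]:
    """Tune branch drifts so realized pairwise Hudson F_ST matches the
    three taurine targets within +-``tolerance`` and the deep
    indicine/taurine split sits near ``fst_deep``.

    Sequential bisection, two passes: the deep-branch scale first, then
    the H/F branch scale (their ratio is fixed by the J-H vs J-F
    asymmetry), then the Jersey branch.
    """
    # initial guesses from the small-F approximation FST(a,b) ~ (Fa+Fb)/2
    asym = fst_jh - fst_jf
    w_h = fst_hf + asym
    w_f = max(fst_hf - asym, 0.01)
    drift = {
        "f_ind": fst_deep * 0.7,
        "f_tau": fst_deep * 0.7,
        "f_j": 2 * (fst_jh + fst_jf) / 2 - fst_hf,
        "f_hf": 0.02,
        "f_h": w_h,
        "f_f": w_f,
    }

    def deep_fst(d):
        f = _realized_fsts(d, L, seed)
        return np.mean([f[("IND", "H")], f[("IND", "F")], f[("IND", "J")]])

    for _ in range(2):
        # deep split scale
        s = _bisect(
            lambda v: deep_fst({**drift, "f_ind": v, "f_tau": v}),
            0.02, 0.6, fst_deep,
        )
        drift["f_ind"] = drift["f_tau"] = s
        # H/F scale at fixed ratio
        ratio = w_h / w_f
        s = _bisect(
            lambda v: _realized_fsts({**drift, "f_h": v * ratio, "f_f": v}, L, seed)[("H", "F")],
            0.005, 0.3, fst_hf,
        )
        drift["f_h"], drift["f_f"] = s * ratio, s
        # Jersey branch against the mean of the two J comparisons
        def j_mean(v):
            f = _realized_fsts({**drift, "f_j": v}, L, seed)
            return 0.5 * (f[("J", "H")] + f[("J", "F")])

        drift["f_j"] = _bisect(j_mean, 0.005, 0.5, (fst_jh + fst_jf) / 2)

    realized = _realized_fsts(drift, L, seed)
    checks = {
        ("J", "H"): fst_jh,
        ("J", "F"): fst_jf,
        ("H", "F"): fst_hf,
    }
    for pair, target in checks.items():
        if abs(realized[pair] - target) > tolerance:
            raise CalibrationError(
                f"F_ST{pair} calibrated to {realized[pair]:.3f}, target {target}"
            )
    if deep_fst(drift) < 0.3:
        raise CalibrationError("indicine/taurine differentiation below 0.3")
    log.info("calibrated drift: %s (realized F_ST %s)", drift, realized)
    return drift


def study_preset(
    seed: int = PRESET_SEED,
    n_target: int = 200,
    L: int = 20000,
    clustered: bool = False,
    missing_rate: float = 0.01,
) -> SimulationConfig:
    """Study-like preset: 4 calibrated populations, reference sizes
    24/24/24 taurine and 101 indicine, crossbred targets spanning the
    indicine range."""
    drift = calibrate_drift()
    return SimulationConfig(
        tree=four_breed_tree(**drift),
        n_ref={"IND": 101, "H": 24, "F": 24, "J": 24},
        n_target=n_target,
        L=L,
        missing_rate=missing_rate,
        seed=seed,
        clustered=clustered,
    )


def two_population_config(
    f: float, n: int, L: int, seed: int, missing_rate: float = 0.0
) -> SimulationConfig:
    """Two Balding–Nichols populations at drift ``f`` on one chromosome
    grid; used for F_ST calibration checks."""
    return SimulationConfig(
        tree=two_population_tree(f),
        n_ref={"A": n, "B": n},
        n_target=0,
        L=L,
        missing_rate=missing_rate,
        seed=seed,
        deep_population="A",
    )


def write_truth_tsv(truth: TruthTable, path) -> None:
    truth.table.to_csv(path, sep="\t", float_format="%.10g")
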