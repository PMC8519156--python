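"""Population-genetic summaries: allele frequencies, frequency
differentials, F_ST, the VanRaden genomic relationship matrix and PCA.

Frequencies are always frequencies of the counted allele (PLINK A1 /
VCF ALT); because every population lives in one merged genotype matrix,
frequency differences between groups are orientation-consistent without
any strand handling.

F_ST defaults to Hudson's estimator in ratio-of-averages form (low bias,
no within-population weighting choices); a two-population
Weir–Cockerham estimator is available as an alternative because global
F_ST values are estimator-dependent.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix
from .errors import ComputationError, GroupLookupError

# ----------------------------------------------------------------------
# allele frequencies


@dataclass
class PopulationFrequencies:
    """Per-population counted-allele frequencies.

    ``freqs[k, l]`` is the frequency of the counted allele of locus ``l``
    in population ``k`` (NaN where the group has no non-missing call);
    ``counts[k, l]`` the number of observed alleles (2 x genotyped
    individuals).  ``markers`` carries the marker map of the source
    matrix so ranked lists keep their coordinates.
    """

    populations: list[str]
    freqs: np.ndarray
    counts: np.ndarray
    markers: pd.DataFrame

    def index_of(self, group: str) -> int:
        try:
            return self.populations.index(group)
        except ValueError:
            raise GroupLookupError(f"unknown population group {group!r}") from None

    def group(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        k = self.index_of(group)
        return self.freqs[k], self.counts[k]

    def to_frame(self) -> pd.DataFrame:
        out = self.markers[["id", "chrom", "pos", "a1"]].rename(
            columns={"id": "marker_id", "a1": "allele_counted"}
        )
        for k, pop in enumerate(self.populations):
            out[f"p_{pop}"] = self.freqs[k]
            out[f"n_{pop}"] = self.counts[k]
        return out


def allele_frequencies(
    gm: GenotypeMatrix,
    grouping: dict | None = None,
    pooled: dict[str, list[str]] | None = None,
) -> PopulationFrequencies:
    """Counted-allele frequency per group at every locus.

    Parameters
    ----------
    grouping:
        sample id -> group name; defaults to the sample table's
        ``population`` column.
    pooled:
        extra groups defined as unions of base groups, e.g.
        ``{"EXO": ["H", "F", "J"], "HF": ["H", "F"]}``; computed over the
        union of member samples (which equals the sample-size-weighted
        mean of member frequencies when missingness is balanced).
    """
    if grouping is None:
        groups = gm.samples["population"].astype(str)
    else:
        groups = gm.samples["id"].map(grouping).astype(str)
    base = list(dict.fromkeys(groups))  # first-appearance order
    names = base + [p for p in (pooled or {}) if p not in base]

    x = gm.calls_float()
    obs = np.isfinite(x)
    xz = np.where(obs, x, 0.0)
    freqs = np.empty((len(names), gm.n_markers))
    counts = np.empty_like(freqs)
    member_map = {name: [name] for name in base}
    if pooled:
        for name, members in pooled.items():
            unknown = [m for m in members if m not in base]
            if unknown:
                raise GroupLookupError(f"pooled group {name!r} references unknown groups {unknown}")
            member_map[name] = list(members)
    for k, name in enumerate(names):
        mask = groups.isin(member_map[name]).to_numpy()
        if not mask.any():
            raise GroupLookupError(f"group {name!r} has no samples")
        cnt = 2.0 * obs[mask].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[k] = np.where(cnt > 0, xz[mask].sum(axis=0) / cnt, np.nan)
        counts[k] = cnt
    return PopulationFrequencies(names, freqs, counts, gm.markers.copy())


def abs_freq_diff(pf: PopulationFrequencies, group_a: str, group_b: str) -> np.ndarray:
    """|p_A - p_B| per locus; NaN where either frequency is undefined."""
    pa, _ = pf.group(group_a)
    pb, _ = pf.group(group_b)
    return np.abs(pa - pb)


# ----------------------------------------------------------------------
# F_ST


def hudson_fst_components(pa, pb, na, nb) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus numerator/denominator of Hudson's F_ST estimator.

    N_l = (pA - pB)^2 - pA(1-pA)/(nA-1) - pB(1-pB)/(nB-1)
    D_l = pA(1-pB) + pB(1-pA)

    with n the number of sampled alleles.  Loci with n <= 1 alleles in
    either group (or undefined frequency) come back as NaN.
    """
    pa, pb = np.asarray(pa, float), np.asarray(pb, float)
    na, nb = np.asarray(na, float), np.asarray(nb, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
        den = pa * (1 - pb) + pb * (1 - pa)
    bad = ~np.isfinite(pa) | ~np.isfinite(pb) | (na <= 1) | (nb <= 1)
    num = np.where(bad, np.nan, num)
    den = np.where(bad, np.nan, den)
    return num, den


def global_fst(pf: PopulationFrequencies, group_a: str, group_b: str) -> float:
    """Genome-wide Hudson F_ST between two groups (ratio of averages)."""
    pa, na = pf.group(group_a)
    pb, nb = pf.group(group_b)
    num, den = hudson_fst_components(pa, pb, na, nb)
    usable = np.isfinite(num) & np.isfinite(den)
    if not usable.any() or np.nansum(den[usable]) <= 0:
        raise ComputationError(
            f"no usable loci for F_ST between {group_a!r} and {group_b!r}"
        )
    return float(num[usable].sum() / den[usable].sum())


def fst_from_frequencies(pa: np.ndarray, pb: np.ndarray) -> float:
    """Hudson F_ST of two *population* frequency vectors (no sampling
    correction); the quantity the finite-sample estimator targets."""
    pa, pb = np.asarray(pa, float), np.asarray(pb, float)
    num = ((pa - pb) ** 2).sum()
    den = (pa * (1 - pb) + pb * (1 - pa)).sum()
    if den <= 0:
        raise ComputationError("degenerate frequency vectors")
    return float(num / den)


def weir_cockerham_fst(gm: GenotypeMatrix, group_a: str, group_b: str) -> float:
    """Two-population Weir & Cockerham (1984) theta-hat, ratio of sums.

    Needs observed heterozygosity, hence works from genotypes rather
    than a frequency table.
    """
    x = gm.calls_float()
    pops = gm.samples["population"].astype(str).to_numpy()
    masks = [pops == group_a, pops == group_b]
    if not all(m.any() for m in masks):
        raise GroupLookupError(f"groups {group_a!r}/{group_b!r} not both present")
    r = 2
    n_i = np.stack([np.isfinite(x[m]).sum(axis=0) for m in masks]).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = np.stack([np.nansum(x[m], axis=0) for m in masks]) / (2 * n_i)
        h_i = np.stack([np.nanmean(x[m] == 1, axis=0) for m in masks])
        n_bar = n_i.mean(axis=0)
        n_c = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2
            - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
    usable = np.isfinite(a) & np.isfinite(b) & np.isfinite(c) & (n_i > 1).all(axis=0)
    if not usable.any():
        raise ComputationError("no usable loci for Weir-Cockerham F_ST")
    denom = (a + b + c)[usable].sum()
    if denom <= 0:
        raise ComputationError("zero total variance in Weir-Cockerham F_ST")
    return float(a[usable].sum() / denom)


# ----------------------------------------------------------------------
# GRM and PCA


@dataclass
class GRMResult:
    """VanRaden genomic relationship matrix ZZ'/(2 sum p(1-p))."""

    matrix: np.ndarray
    scaling_constant: float
    sample_ids: list[str]


def vanraden_grm(gm: GenotypeMatrix) -> GRMResult:
    """VanRaden method-1 GRM.

    Missing calls are replaced by the per-locus mean genotype; the
    centred matrix is Z = (M - 1) - 2(p - 0.5) with p computed over all
    samples in the matrix; monomorphic loci contribute nothing and are
    excluded from the scaling sum 2*sum p(1-p).
    """
    if gm.n_samples < 2:
        raise ComputationError("GRM needs at least two samples")
    x = gm.calls_float()
    mean_geno = np.nanmean(x, axis=0)
    if not np.isfinite(mean_geno).all():
        raise ComputationError("locus with no non-missing call")
    x = np.where(np.isfinite(x), x, mean_geno)
    p = mean_geno / 2.0
    het = p * (1.0 - p)
    poly = het > 0
    scale = 2.0 * het[poly].sum()
    if not poly.any() or scale <= 0:
        raise ComputationError("all loci monomorphic; GRM scaling undefined")
    z = x - 2.0 * p  # == (M - 1) - 2(p - 0.5)
    grm = (z @ z.T) / scale
    grm = (grm + grm.T) / 2.0  # enforce exact symmetry
    return GRMResult(grm, scale, gm.samples["id"].to_list())


@dataclass
class PCAResult:
    coordinates: np.ndarray
    variance_explained: np.ndarray
    sample_ids: list[str]


def pca_from_grm(grm: GRMResult, n_components: int = 10) -> PCAResult:
    """Principal components from the eigendecomposition of the GRM.

    Scores are eigenvectors scaled by sqrt(eigenvalue); variance
    fractions are taken over positive eigenvalues only.  Component signs
    are fixed by making the largest-magnitude loading positive.
    """
    g = np.asarray(grm.matrix, float)
    if not np.isfinite(g).all():
        raise ComputationError("non-finite entries in GRM")
    n = g.shape[0]
    if n_components > n - 1:
        raise ValueError("n_components must be <= n_samples - 1")
    lam, vec = np.linalg.eigh(g)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    pos = lam > 0
    total = lam[pos].sum()
    c = min(n_components, int(pos.sum()))
    scores = vec[:, :c] * np.sqrt(lam[:c])
    for j in range(c):
        if scores[np.argmax(np.abs(scores[:, j])), j] < 0:
            scores[:, j] *= -1
    return PCAResult(scores, lam[:c] / total, list(grm.sample_ids))


# ----------------------------------------------------------------------
# TSV writers


def write_frequencies_tsv(pf: PopulationFrequencies, path) -> None:
    pf.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_grm_tsv(grm: GRMResult, path) -> None:
    pd.DataFrame(grm.matrix, index=grm.sample_ids, columns=grm.sample_ids).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def write_pca_tsv(pca: PCAResult, path) -> None:
    cols = {f"PC{i + 1}": pca.coordinates[:, i] for i in range(pca.coordinates.shape[1])}
    df = pd.DataFrame({"sample_id": pca.sample_ids, **cols})
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
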