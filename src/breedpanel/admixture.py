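"""Supervised ancestry-proportion estimation.

Model: a diploid individual with ancestry vector q on the K-simplex
carries, at locus l, counted-allele dosage x_l ~ Binomial(2, pi_l) with
pi_l = sum_k q_k p_kl, where p_kl are ancestral allele frequencies.  The
log-likelihood is

    l(q) = sum_l [ x_l log(sum_k q_k p_kl) + (2 - x_l) log(sum_k q_k (1 - p_kl)) ]

with missing loci skipped.  Supervision is a fixed-P projection: the
ancestral frequencies are point estimates from labeled reference
samples and are held fixed while q is maximized per individual with an
EM algorithm on the simplex.  The EM update

    q_k <- (1 / 2 L_obs) sum_l [ x_l a_kl + (2 - x_l) b_kl ]
    a_kl = q_k p_kl / sum_j q_j p_jl,   b_kl = q_k (1-p_kl) / sum_j q_j (1-p_jl)

preserves non-negativity and normalization, and the log-likelihood is
non-decreasing at every iteration.  Frequencies are clamped into
[eps, 1-eps] so fixed differences cannot produce -inf likelihoods.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix
from .errors import ComputationError
from .popgen import allele_frequencies

#: Clamp applied to reference allele frequencies inside the likelihood.
FREQ_EPS = 1e-6

DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 2000

#: Higher-order ancestries reported alongside the per-breed proportions.
DEFAULT_AGGREGATES = {"HF": ["H", "F"], "EXO": ["H", "F", "J"]}


@dataclass
class AncestryEstimate:
    """Ancestry proportions of one individual."""

    q: np.ndarray
    loglik: float
    iterations: int
    converged: bool


def _as_dosage_matrix(x) -> np.ndarray:
    """Coerce dosages to float64 with NaN for missing (accepts -1 codes)."""
    x = np.asarray(x, float)
    x = np.where(x < 0, np.nan, x)
    return np.atleast_2d(x)


def loglik(x, P: np.ndarray, q: np.ndarray) -> float:
    """Binomial admixture log-likelihood of one individual."""
    X = _as_dosage_matrix(x)
    if X.shape[0] != 1:
        raise ValueError("loglik expects a single dosage vector")
    obs = np.isfinite(X[0])
    if not obs.any():
        raise ComputationError("all loci missing")
    Pc = np.clip(np.asarray(P, float), FREQ_EPS, 1 - FREQ_EPS)
    q = np.asarray(q, float)
    xo = X[0, obs]
    d1 = q @ Pc[:, obs]
    d0 = q @ (1.0 - Pc[:, obs])
    return float(np.sum(xo * np.log(d1) + (2.0 - xo) * np.log(d0)))


def _em_batch(
    X: np.ndarray,
    P: np.ndarray,
    tol: float,
    max_iter: int,
    init: np.ndarray | None = None,
    track: bool = False,
):
    """Run the EM fixed-point for a batch of individuals.

    Converged individuals are frozen (dropped from the active set); the
    reported log-likelihood is recomputed at the final q.
    """
    n, L = X.shape
    K = P.shape[0]
    Pc = np.clip(np.asarray(P, float), FREQ_EPS, 1 - FREQ_EPS)
    P0 = 1.0 - Pc
    miss = ~np.isfinite(X)
    if miss.all(axis=1).any():
        raise ComputationError("individual with all loci missing")
    Xa = np.where(miss, 0.0, X)
    Xb = np.where(miss, 0.0, 2.0 - Xa)
    L_obs = (~miss).sum(axis=1).astype(float)

    Q = np.full((n, K), 1.0 / K) if init is None else np.tile(np.asarray(init, float), (n, 1))
    ll = np.full(n, -np.inf)
    iters = np.zeros(n, dtype=int)
    converged = np.zeros(n, dtype=bool)
    history: list[np.ndarray] = []
    active = np.arange(n)
    for it in range(1, max_iter + 1):
        Qa = Q[active]
        XaA, XbA = Xa[active], Xb[active]
        DA = Qa @ Pc
        DB = Qa @ P0
        ll_new = (XaA * np.log(DA)).sum(axis=1) + (XbA * np.log(DB)).sum(axis=1)
        if track:
            history.append(ll_new.copy())
        gain = ll_new - ll[active]
        ll[active] = ll_new
        Qn = Qa * ((XaA / DA) @ Pc.T + (XbA / DB) @ P0.T) / (2.0 * L_obs[active, None])
        Qn /= Qn.sum(axis=1, keepdims=True)
        Q[active] = Qn
        iters[active] = it
        done = gain < tol
        converged[active[done]] = True
        active = active[~done]
        if active.size == 0:
            break
    # final log-likelihood at the returned q
    DA = Q @ Pc
    DB = Q @ P0
    ll = (Xa * np.log(DA)).sum(axis=1) + (Xb * np.log(DB)).sum(axis=1)
    return Q, ll, iters, converged, history


def estimate_ancestry(
    x,
    P: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    init: np.ndarray | None = None,
    return_history: bool = False,
):
    """Maximum-likelihood ancestry vector of one individual.

    Parameters
    ----------
    x:
        Length-L dosage vector; missing as NaN or negative codes.
    P:
        K x L reference allele frequencies (rows = ancestral groups).
    init:
        Starting point on the simplex; uniform 1/K by default.
    return_history:
        Also return the per-iteration log-likelihood trace (used to
        verify EM monotonicity).
    """
    X = _as_dosage_matrix(x)
    Q, ll, iters, conv, history = _em_batch(
        X, P, tol=tol, max_iter=max_iter, init=init, track=return_history
    )
    est = AncestryEstimate(Q[0], float(ll[0]), int(iters[0]), bool(conv[0]))
    if return_history:
        return est, np.array([h[0] for h in history])
    return est


def estimate_cohort(
    gm: GenotypeMatrix,
    reference_populations: list[str],
    panel=None,
    *,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    aggregates: dict[str, list[str]] | None = None,
    targets: list[str] | None = None,
) -> pd.DataFrame:
    """Supervised ancestry estimates for every target individual.

    Reference allele frequencies are computed from the samples labeled
    with ``reference_populations`` (restricted to the panel's markers if
    a panel is given; duplicate panel entries are collapsed) and held
    fixed.  Samples with any other label are targets unless an explicit
    target id list is given.  Loci with an undefined frequency in any
    reference group are skipped.  Returns a DataFrame indexed by sample
    id with columns ``q_<POP>``, aggregate proportions (by default
    HF = H + F and EXO = H + F + J, where present), ``loglik``,
    ``iterations`` and ``converged``.
    """
    if panel is not None:
        ids = getattr(panel, "marker_ids", panel)
        ids = list(dict.fromkeys(ids))
        gm = gm.subset_markers(gm.marker_index(ids))
    pops = gm.samples["population"].astype(str)
    ref_mask = pops.isin(reference_populations).to_numpy()
    for pop in reference_populations:
        if not (pops == pop).any():
            raise ComputationError(f"reference group {pop!r} has no samples")
    if targets is None:
        target_mask = ~ref_mask
    else:
        target_mask = gm.samples["id"].isin(targets).to_numpy()
    if not target_mask.any():
        raise ComputationError("no target samples to estimate")

    refs = gm.subset_samples(ref_mask)
    pf = allele_frequencies(refs)
    P = np.stack([pf.group(pop)[0] for pop in reference_populations])
    defined = np.isfinite(P).all(axis=0)
    P = P[:, defined]
    X = gm.subset_samples(target_mask).calls_float()[:, defined]
    if X.shape[1] == 0:
        raise ComputationError("no loci with defined reference frequencies")

    Q, ll, iters, conv, _ = _em_batch(X, P, tol=tol, max_iter=max_iter)
    out = pd.DataFrame(
        {f"q_{pop}": Q[:, k] for k, pop in enumerate(reference_populations)},
        index=pd.Index(gm.samples["id"][target_mask], name="sample_id"),
    )
    agg = DEFAULT_AGGREGATES if aggregates is None else aggregates
    for name, members in agg.items():
        if all(m in reference_populations for m in members):
            out[f"q_{name}"] = sum(out[f"q_{m}"] for m in members)
    out["loglik"] = ll
    out["iterations"] = iters
    out["converged"] = conv
    return out


def write_estimates_tsv(estimates: pd.DataFrame, path) -> None:
    estimates.to_csv(path, sep="\t", float_format="%.10g")


def read_estimates_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")
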