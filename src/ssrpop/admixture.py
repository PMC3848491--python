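"""Model-based admixture clustering for multi-allelic co-dominant markers.

This is a Gibbs sampler over the classic admixture model: each individual i
has membership proportions q_i (Dirichlet(alpha) prior, alpha inferred by
random-walk Metropolis), each allele copy carries a latent origin cluster z,
and each cluster k has allele frequencies P_k,l per locus.  Two frequency
priors are offered: ``independent`` (Dirichlet(1) per cluster and locus) and
``correlated``, in which cluster frequencies drift from a shared ancestral
pool, P_k,l ~ Dirichlet(p_A,l (1-F_k)/F_k), with the drift parameters F_k
and the ancestral frequencies p_A updated by Metropolis-Hastings.  Missing
genotypes simply contribute no allele copies.

The data log-probability reported per run is the usual harmonic-style
estimate mean(logL) - var(logL)/2 over thinned post-burn-in samples; the
number of clusters is chosen by the second-order rate of change of that
quantity across K normalized by its run-to-run standard deviation (the
Delta-K statistic).  Replicate runs are aligned by column permutation
(exhaustive for K <= 6, Hungarian above) before averaging Q, and
individuals are assigned to a cluster only when their mean membership
reaches a threshold (default 0.8), otherwise they are reported
UNSTRUCTURED.  A nested driver repeats the full scan inside each assigned
cluster.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from .genodata import MISSING, GenotypeMatrix, subset

__all__ = [
    "UNSTRUCTURED",
    "StructureRun",
    "EvannoTable",
    "Assignment",
    "AlignmentResult",
    "run_admixture",
    "k_scan",
    "evanno",
    "align_runs",
    "assign",
    "nested_structure",
    "full_structure_analysis",
]

UNSTRUCTURED = "UNSTRUCTURED"


@dataclass
class StructureRun:
    """Posterior summaries of one MCMC run."""

    K: int
    Q: np.ndarray                      # (N, K) posterior-mean memberships
    P: list[dict[int, np.ndarray]]     # not used downstream; per-locus means
    lnPD: float
    alpha: float
    F_k: np.ndarray | None
    seed: int | None
    burn_in: int
    mcmc_len: int
    individuals: list[str]
    loci: list[str]
    model: str

    def q_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.Q, index=self.individuals,
            columns=[f"q{k + 1}" for k in range(self.K)],
        )
        df.insert(0, "max_cluster", self.Q.argmax(axis=1) + 1)
        return df


@dataclass
class EvannoTable:
    """Per-K summary of replicate data log-probabilities and Delta-K."""

    table: pd.DataFrame  # index K; columns mean_lnPD sd_lnPD Lprime Lsecond deltaK

    @property
    def best_k(self) -> int:
        dk = self.table["deltaK"].dropna()
        if dk.empty:
            raise ValueError("Delta-K undefined at every interior K")
        return int(dk.idxmax())


@dataclass
class Assignment:
    """Per-individual cluster label (or UNSTRUCTURED) and max membership."""

    table: pd.DataFrame  # index individual; columns label, q_max
    threshold: float

    def members(self, label: str) -> list[str]:
        t = self.table
        return list(t.index[t["label"] == label])

    def labels(self) -> list[str]:
        labs = sorted(set(self.table["label"]) - {UNSTRUCTURED})
        return labs


@dataclass
class AlignmentResult:
    aligned: list[np.ndarray]
    G: np.ndarray        # pairwise similarity after per-pair optimal permutation
    mean_Q: np.ndarray


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

def _index_panel(g: GenotypeMatrix):
    """Allele labels -> dense per-locus indices; flattened copy arrays."""
    L = g.n_loci
    alleles_per_locus: list[np.ndarray] = []
    idx = np.full((g.n_individuals, L, 2), -1, dtype=np.int64)
    for j in range(L):
        col = g.calls[:, j, :]
        obs = col[col[:, 0] != MISSING]
        alleles = np.unique(obs) if obs.size else np.array([0])
        alleles_per_locus.append(alleles)
        lut = {int(a): t for t, a in enumerate(alleles)}
        for i in range(g.n_individuals):
            a, b = col[i]
            if a != MISSING:
                idx[i, j] = (lut[int(a)], lut[int(b)])
    mask = idx[:, :, 0] >= 0
    ind_arr, loc_arr = np.nonzero(mask)
    ind_arr = np.repeat(ind_arr, 2)
    loc_arr = np.repeat(loc_arr, 2)
    al_arr = idx[mask].ravel()
    return alleles_per_locus, ind_arr, loc_arr, al_arr


def _dirichlet_rows(rng: np.random.Generator, shape_params: np.ndarray,
                    axis: int = -1) -> np.ndarray:
    """Vectorized Dirichlet sampling via normalized gammas (0-shape -> 0)."""
    gam = rng.standard_gamma(shape_params)
    tot = gam.sum(axis=axis, keepdims=True)
    tot[tot == 0] = 1.0
    return gam / tot


def _log_dirichlet(x: np.ndarray, a: np.ndarray, mask: np.ndarray,
                   axis: int = -1) -> np.ndarray:
    """Masked log Dirichlet density, summed over ``axis``."""
    a = np.where(mask, a, 1.0)
    xx = np.where(mask, np.maximum(x, 1e-300), 1.0)
    term = (a - 1.0) * np.log(xx) - gammaln(a)
    term = np.where(mask, term, 0.0)
    return gammaln(np.where(mask, a, 0.0).sum(axis=axis)) + term.sum(axis=axis)


def run_admixture(
    g: GenotypeMatrix,
    K: int,
    model: str = "correlated",
    alpha0: float = 1.0,
    burn_in: int = 2_000,
    mcmc_len: int = 10_000,
    thin: int = 10,
    seed: int | None = None,
    infer_alpha: bool = True,
) -> StructureRun:
    """One MCMC run of the admixture model; returns posterior means.

    ``burn_in`` sweeps are discarded, then ``mcmc_len`` sweeps are run and
    every ``thin``-th is retained for the posterior means and the data
    log-probability estimate.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if burn_in < 0 or mcmc_len < thin:
        raise ValueError("invalid chain lengths")
    if model not in ("independent", "correlated"):
        raise ValueError(f"unknown model {model!r}")
    rng = np.random.default_rng(seed)
    N, L = g.n_individuals, g.n_loci
    alleles_per_locus, ind_arr, loc_arr, al_arr = _index_panel(g)
    amax = max(len(a) for a in alleles_per_locus)
    valid = np.zeros((L, amax), dtype=bool)
    for j, a in enumerate(alleles_per_locus):
        valid[j, : len(a)] = True
    M = len(ind_arr)

    # initial state
    alpha = float(alpha0)
    Q = np.full((N, K), 1.0 / K)
    counts0 = np.zeros((L, amax))
    np.add.at(counts0, (loc_arr, al_arr), 1.0)
    base = np.where(valid, counts0 + 1.0, 0.0)
    P = np.stack([_dirichlet_rows(rng, base) for _ in range(K)])  # (K, L, amax)
    pA = _dirichlet_rows(rng, base)
    F = np.full(K, 0.1)

    q_acc = np.zeros_like(Q)
    logliks: list[float] = []
    n_kept = 0
    p_acc = np.zeros_like(P)

    total = burn_in + mcmc_len
    for sweep in range(total):
        # -- latent origins z ------------------------------------------------
        Pg = P[:, loc_arr, al_arr]            # (K, M)
        probs = Q[ind_arr] * Pg.T             # (M, K)
        tot = probs.sum(axis=1, keepdims=True)
        bad = tot[:, 0] <= 0
        if bad.any():
            probs[bad] = 1.0 / K
            tot[bad] = 1.0
        cum = np.cumsum(probs, axis=1)
        u = rng.random(M) * cum[:, -1]
        z = (cum < u[:, None]).sum(axis=1)

        # -- q update --------------------------------------------------------
        n_ik = np.bincount(ind_arr * K + z, minlength=N * K).reshape(N, K)
        Q = _dirichlet_rows(rng, alpha + n_ik)
        np.maximum(Q, 1e-12, out=Q)
        Q /= Q.sum(axis=1, keepdims=True)

        # -- allele-frequency update ----------------------------------------
        c_kla = np.bincount(
            (z * L + loc_arr) * amax + al_arr, minlength=K * L * amax
        ).reshape(K, L, amax).astype(float)
        if model == "independent":
            lam = np.where(valid, 1.0, 0.0)[None, :, :]
        else:
            lam = np.where(valid, pA, 0.0)[None, :, :] * (
                (1.0 - F) / F
            )[:, None, None]
        P = _dirichlet_rows(rng, lam + c_kla)
        P = np.where(valid[None], np.maximum(P, 1e-12), 0.0)
        P /= P.sum(axis=2, keepdims=True)

        if model == "correlated":
            # -- F_k: logit random walk -------------------------------------
            y = np.log(F / (1 - F))
            y_new = y + rng.normal(0.0, 0.15, size=K)
            F_new = 1.0 / (1.0 + np.exp(-y_new))
            lam_new = np.where(valid, pA, 0.0)[None] * ((1 - F_new) / F_new)[:, None, None]
            lp_old = _log_dirichlet(P, lam, np.broadcast_to(valid, P.shape)).sum(axis=1)
            lp_new = _log_dirichlet(P, lam_new, np.broadcast_to(valid, P.shape)).sum(axis=1)
            jac = np.log(F_new * (1 - F_new)) - np.log(F * (1 - F))
            acc = np.log(rng.random(K)) < lp_new - lp_old + jac
            F = np.where(acc, F_new, F)

            # -- ancestral frequencies: Dirichlet-proposal MH per locus -----
            conc = 200.0
            prop = _dirichlet_rows(rng, np.where(valid, conc * pA + 1e-6, 0.0))
            prop = np.where(valid, np.maximum(prop, 1e-12), 0.0)
            prop /= prop.sum(axis=1, keepdims=True)
            lamF = ((1 - F) / F)[:, None, None]
            lp_t_old = _log_dirichlet(
                P, np.where(valid, pA, 0.0)[None] * lamF,
                np.broadcast_to(valid, P.shape),
            ).sum(axis=0)
            lp_t_new = _log_dirichlet(
                P, np.where(valid, prop, 0.0)[None] * lamF,
                np.broadcast_to(valid, P.shape),
            ).sum(axis=0)
            # Hastings correction for the asymmetric Dirichlet proposal
            lq_fwd = _log_dirichlet(prop, conc * pA + 1e-6, valid)
            lq_rev = _log_dirichlet(pA, conc * prop + 1e-6, valid)
            acc_l = np.log(rng.random(L)) < lp_t_new - lp_t_old + lq_rev - lq_fwd
            pA = np.where(acc_l[:, None], prop, pA)

        # -- alpha: random-walk Metropolis, uniform prior on (0, 10] --------
        if infer_alpha and K > 1:
            a_new = alpha + rng.normal(0.0, 0.05)
            if 0 < a_new <= 10:
                lp = (
                    N * (gammaln(K * a_new) - K * gammaln(a_new))
                    + (a_new - alpha) * np.log(np.maximum(Q, 1e-300)).sum()
                    - N * (gammaln(K * alpha) - K * gammaln(alpha))
                )
                if np.log(rng.random()) < lp:
                    alpha = float(a_new)

        # -- accumulate ------------------------------------------------------
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            q_acc += Q
            p_acc += P
            Pg = P[:, loc_arr, al_arr]
            lik = (Q[ind_arr] * Pg.T).sum(axis=1)
            ll = float(np.log(np.maximum(lik, 1e-300)).sum())
            if not np.isfinite(ll):
                raise FloatingPointError(f"non-finite likelihood at sweep {sweep}")
            logliks.append(ll)
            n_kept += 1

    ll_arr = np.array(logliks)
    lnpd = float(ll_arr.mean() - ll_arr.var() / 2.0)
    q_mean = q_acc / n_kept
    p_mean = p_acc / n_kept
    p_out = [
        {int(a): p_mean[:, j, t] for t, a in enumerate(alleles_per_locus[j])}
        for j in range(L)
    ]
    return StructureRun(
        K=K, Q=q_mean, P=p_out, lnPD=lnpd, alpha=alpha,
        F_k=F.copy() if model == "correlated" else None,
        seed=seed, burn_in=burn_in, mcmc_len=mcmc_len,
        individuals=list(g.individuals), loci=list(g.loci), model=model,
    )


def k_scan(
    g: GenotypeMatrix,
    k_range: Sequence[int] = range(1, 11),
    repeats: int = 10,
    seed: int | None = None,
    **run_kwargs,
) -> list[StructureRun]:
    """Independent repeats of :func:`run_admixture` over a range of K."""
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(list(k_range)) * repeats)
    runs = []
    t = 0
    for K in k_range:
        for _r in range(repeats):
            runs.append(run_admixture(g, K=K, seed=int(seeds[t] % (2**31)), **run_kwargs))
            t += 1
    return runs


# ---------------------------------------------------------------------------
# Choosing K
# ---------------------------------------------------------------------------

def evanno(runs: Sequence[StructureRun]) -> EvannoTable:
    """Delta-K table from replicate runs over consecutive K values.

    L'(K) = mean L(K) - mean L(K-1); |L''(K)| = |L'(K+1) - L'(K)| computed
    from the per-K means; Delta-K = |L''(K)| / sd[L(K)], defined at interior
    K with positive run-to-run standard deviation.
    """
    by_k: dict[int, list[float]] = {}
    for r in runs:
        by_k.setdefault(r.K, []).append(r.lnPD)
    ks = sorted(by_k)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >= 3 consecutive K values")
    if any(len(v) < 2 for v in by_k.values()):
        raise ValueError("need >= 2 repeats per K")
    mean = np.array([np.mean(by_k[k]) for k in ks])
    sd = np.array([np.std(by_k[k], ddof=1) for k in ks])
    lprime = np.full(len(ks), np.nan)
    lprime[1:] = np.diff(mean)
    lsec = np.full(len(ks), np.nan)
    lsec[1:-1] = np.abs(np.diff(mean, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        dk = lsec / np.where(sd > 0, sd, np.nan)
    table = pd.DataFrame(
        {
            "n_runs": [len(by_k[k]) for k in ks],
            "mean_lnPD": mean, "sd_lnPD": sd,
            "Lprime": lprime, "Lsecond": lsec, "deltaK": dk,
        },
        index=pd.Index(ks, name="K"),
    )
    return EvannoTable(table)


# ---------------------------------------------------------------------------
# Replicate alignment (label switching) and assignment
# ---------------------------------------------------------------------------

def _g_similarity(Q: np.ndarray, Qp: np.ndarray) -> float:
    n = Q.shape[0]
    return 1.0 - np.linalg.norm(Q - Qp) / np.sqrt(2.0 * n)

def _best_permutation(Q: np.ndarray, Qp: np.ndarray, method: str):
    """Column permutation of Qp maximizing similarity to Q."""
    K = Q.shape[1]
    if method == "exhaustive" or (method == "auto" and K <= 6):
        best, best_g = None, -np.inf
        for perm in itertools.permutations(range(K)):
            gg = _g_similarity(Q, Qp[:, perm])
            if gg > best_g:
                best, best_g = perm, gg
        return list(best), best_g
    # Hungarian on squared column distances
    cost = ((Q[:, :, None] - Qp[:, None, :]) ** 2).sum(axis=0)
    rows, cols = linear_sum_assignment(cost)
    perm = [int(c) for _, c in sorted(zip(rows, cols))]
    return perm, _g_similarity(Q, Qp[:, perm])


def align_runs(Qs: Sequence[np.ndarray], method: str = "auto") -> AlignmentResult:
    """Align replicate Q matrices by column permutation.

    Pairwise G values use each pair's own optimal permutation; the returned
    matrices are all aligned to the first run and averaged into ``mean_Q``.
    """
    Qs = [np.asarray(q, dtype=float) for q in Qs]
    shape = Qs[0].shape
    if any(q.shape != shape for q in Qs):
        raise ValueError("all Q matrices must share one shape")
    R = len(Qs)
    G = np.ones((R, R))
    for i, j in itertools.combinations(range(R), 2):
        _, gg = _best_permutation(Qs[i], Qs[j], method)
        G[i, j] = G[j, i] = gg
    aligned = [Qs[0]]
    for j in range(1, R):
        perm, _ = _best_permutation(Qs[0], Qs[j], method)
        aligned.append(Qs[j][:, perm])
    return AlignmentResult(aligned=aligned, G=G, mean_Q=np.mean(aligned, axis=0))


def assign(mean_q: np.ndarray, threshold: float = 0.8,
           individuals: Sequence[str] | None = None) -> Assignment:
    """Threshold assignment: argmax cluster if q_max >= threshold else
    UNSTRUCTURED."""
    mean_q = np.asarray(mean_q, dtype=float)
    if not np.allclose(mean_q.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("membership rows must sum to 1")
    if individuals is None:
        individuals = [f"S{i + 1}" for i in range(mean_q.shape[0])]
    qmax = mean_q.max(axis=1)
    arg = mean_q.argmax(axis=1) + 1
    labels = [
        f"pop{a}" if qm >= threshold else UNSTRUCTURED
        for a, qm in zip(arg, qmax)
    ]
    table = pd.DataFrame({"label": labels, "q_max": qmax}, index=list(individuals))
    return Assignment(table=table, threshold=threshold)


# ---------------------------------------------------------------------------
# Drivers
# ---------------------------------------------------------------------------

@dataclass
class StructureAnalysis:
    """K-scan + Evanno + alignment + assignment for one panel."""

    runs: list[StructureRun]
    evanno: EvannoTable | None
    best_k: int
    alignment: AlignmentResult | None
    assignment: Assignment
    note: str = ""


def full_structure_analysis(
    g: GenotypeMatrix,
    k_range: Sequence[int] = range(1, 11),
    repeats: int = 10,
    threshold: float = 0.8,
    delta_k_min: float = 2.0,
    seed: int | None = None,
    **run_kwargs,
) -> StructureAnalysis:
    """Scan K, pick it by Delta-K, align the chosen-K replicates, assign.

    When Delta-K is unavailable (too narrow a K range) or its maximum falls
    below ``delta_k_min`` the panel is treated as unstructured (best K = 1,
    every individual assigned to the single cluster).
    """
    runs = k_scan(g, k_range=k_range, repeats=repeats, seed=seed, **run_kwargs)
    note = ""
    ev: EvannoTable | None = None
    try:
        ev = evanno(runs)
        best_k = ev.best_k
        if float(ev.table["deltaK"].max()) < delta_k_min:
            best_k, note = 1, "no substructure: Delta-K below threshold"
    except ValueError as e:
        best_k, note = 1, f"no substructure: {e}"
    if best_k == 1:
        n = g.n_individuals
        alignment = None
        assignment = assign(np.ones((n, 1)), threshold=0.0, individuals=g.individuals)
    else:
        qs = [r.Q for r in runs if r.K == best_k]
        alignment = align_runs(qs)
        assignment = assign(alignment.mean_Q, threshold, individuals=g.individuals)
    return StructureAnalysis(
        runs=runs, evanno=ev, best_k=best_k, alignment=alignment,
        assignment=assignment, note=note,
    )


def nested_structure(
    g: GenotypeMatrix,
    assignment: Assignment,
    k_range: Sequence[int] = range(1, 11),
    repeats: int = 10,
    threshold: float = 0.8,
    min_group_size: int = 10,
    delta_k_min: float = 2.0,
    seed: int | None = None,
    **run_kwargs,
) -> dict[str, StructureAnalysis]:
    """Second-level clustering inside each assigned cluster.

    UNSTRUCTURED individuals are excluded; groups smaller than
    ``min_group_size`` are skipped (recorded with a note).  Returns one
    :class:`StructureAnalysis` per first-level label.
    """
    ss = np.random.SeedSequence(seed)
    out: dict[str, StructureAnalysis] = {}
    for label, child_seed in zip(assignment.labels(), ss.spawn(len(assignment.labels()))):
        ids = assignment.members(label)
        if len(ids) < min_group_size:
            n = len(ids)
            out[label] = StructureAnalysis(
                runs=[], evanno=None, best_k=1, alignment=None,
                assignment=assign(np.ones((n, 1)), threshold=0.0, individuals=ids),
                note=f"skipped: group size {n} < {min_group_size}",
            )
            continue
        sub = subset(g, individuals=ids)
        out[label] = full_structure_analysis(
            sub, k_range=k_range, repeats=repeats, threshold=threshold,
            delta_k_min=delta_k_min,
            seed=int(child_seed.generate_state(1)[0] % (2**31)), **run_kwargs,
        )
    return out
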