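"""Hierarchical AMOVA, pairwise Fst and principal coordinate analysis.

AMOVA treats the two allele copies of each diploid individual as the units
and the distance between two copies as allele identity/non-identity (the
infinite-allele view; no stepwise size weighting).  Sums of squares are
partitioned into among groups, among individuals within groups, and within
individuals; variance components follow the standard moment equations and
give Fst = Va/(Va+Vb+Vc), Fis = Vb/(Vb+Vc), Fit = (Va+Vb)/(Va+Vb+Vc).
Missing cells are dropped per locus (pairwise-available), and per-locus
components are summed across loci.  Negative components are retained in the
ratios (flagged) unless truncation is requested.

Permutation null distributions follow the hierarchy: whole individuals are
permuted among groups for Fst, allele copies among individuals within
groups for Fis, and copies across everything for Fit; p-values use the
add-one estimator (#null >= observed + 1)/(n_perm + 1).

PCoA is the classical metric scaling of a distance matrix: Gower double
centering of -d^2/2, eigendecomposition, coordinates scaled by the square
root of the eigenvalue, axis percentages over the positive eigenvalues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeMatrix, GenodataError, subset
from .phylogeny import DistanceMatrix

__all__ = [
    "VarianceComponents",
    "PcoaResult",
    "amova",
    "pairwise_fst",
    "pcoa",
]


@dataclass
class VarianceComponents:
    """AMOVA decomposition with F-statistics and permutation p-values.

    ``table`` rows: among_groups / among_individuals / within_individuals /
    total with columns df, SS, variance, pct.
    """

    table: pd.DataFrame
    fst: float
    fis: float
    fit: float
    p_fst: float | None
    p_fis: float | None
    p_fit: float | None
    negative_components: bool
    monomorphic: bool = False


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame      # individuals x axes
    eigenvalues: np.ndarray        # all eigenvalues, descending
    percent: np.ndarray            # per retained axis, over positive eigenvalues


# ---------------------------------------------------------------------------
# AMOVA internals
# ---------------------------------------------------------------------------

def _per_locus_ss(col: np.ndarray, gidx: np.ndarray, n_groups: int):
    """Sums of squares at one locus from (N, 2) allele-index calls.

    Returns (ss_ag, ss_ai, ss_wi, n_ind, group_sizes) or None when fewer
    than two groups carry data at the locus.
    """
    ok = col[:, 0] >= 0
    if not ok.any():
        return None
    calls = col[ok]
    gi = gidx[ok]
    present = np.unique(gi)
    if len(present) < 2:
        return None
    n_alleles = int(calls.max()) + 1

    def ss_of(copies: np.ndarray) -> float:
        m = len(copies)
        cnt = np.bincount(copies, minlength=n_alleles)
        return (m * m - float(np.dot(cnt, cnt))) / (2.0 * m)

    all_copies = calls.ravel()
    ss_total = ss_of(all_copies)
    ss_wg = 0.0
    sizes = []
    for gctr in present:
        sel = calls[gi == gctr].ravel()
        ss_wg += ss_of(sel)
        sizes.append(len(sel) // 2)
    ss_wi = float(np.count_nonzero(calls[:, 0] != calls[:, 1])) / 2.0
    ss_ag = ss_total - ss_wg
    ss_ai = ss_wg - ss_wi
    return ss_ag, ss_ai, ss_wi, len(calls), np.array(sizes)


def _components(col_list, gidx: np.ndarray, n_groups: int):
    """Summed per-locus variance components (Va, Vb, Vc)."""
    va = vb = vc = 0.0
    for col in col_list:
        res = _per_locus_ss(col, gidx, n_groups)
        if res is None:
            continue
        ss_ag, ss_ai, ss_wi, n_l, sizes = res
        g_l = len(sizes)
        df_ag, df_ai, df_wi = g_l - 1, n_l - g_l, n_l
        if df_ai <= 0:
            continue
        ms_wi = ss_wi / df_wi
        ms_ai = ss_ai / df_ai
        ms_ag = ss_ag / df_ag
        n_c = (n_l - float(np.sum(sizes**2)) / n_l) / (g_l - 1)
        vc_l = ms_wi
        vb_l = (ms_ai - ms_wi) / 2.0
        va_l = (ms_ag - ms_ai) / (2.0 * n_c)
        va += va_l
        vb += vb_l
        vc += vc_l
    return va, vb, vc


def _f_stats(va: float, vb: float, vc: float):
    tot = va + vb + vc
    fst = va / tot if tot != 0 else float("nan")
    fis = vb / (vb + vc) if (vb + vc) != 0 else float("nan")
    fit = (va + vb) / tot if tot != 0 else float("nan")
    return fst, fis, fit


def _prepare(g: GenotypeMatrix, groups: Mapping[str, Sequence[str]]):
    labels = list(groups)
    order: list[str] = []
    gidx_list: list[int] = []
    for t, lab in enumerate(labels):
        ids = list(groups[lab])
        if len(ids) < 2:
            raise GenodataError(f"group {lab!r} has fewer than 2 individuals")
        order += ids
        gidx_list += [t] * len(ids)
    sub = subset(g, individuals=order)
    gidx = np.asarray(gidx_list)
    # per-locus dense allele indices, -1 missing
    cols = []
    for j in range(sub.n_loci):
        col = sub.calls[:, j, :]
        obs_mask = col[:, 0] != MISSING
        alleles = np.unique(col[obs_mask])
        lut = {int(a): t for t, a in enumerate(alleles)}
        out = np.full_like(col, -1)
        for i in np.nonzero(obs_mask)[0]:
            out[i] = (lut[int(col[i, 0])], lut[int(col[i, 1])])
        cols.append(out)
    return sub, cols, gidx, labels


def amova(
    g: GenotypeMatrix,
    groups: Mapping[str, Sequence[str]],
    n_perm: int = 1000,
    seed: int | None = None,
    truncate_negative: bool = False,
) -> VarianceComponents:
    """Three-level AMOVA over the given grouping with permutation tests.

    ``groups`` maps group label -> individual ids (each group >= 2).  With
    ``n_perm`` 0 no permutation p-values are computed.
    """
    if len(groups) < 2:
        raise GenodataError("need at least 2 groups")
    sub, cols, gidx, labels = _prepare(g, groups)
    n_groups = len(labels)
    N = sub.n_individuals
    va, vb, vc = _components(cols, gidx, n_groups)
    if truncate_negative:
        va, vb, vc = max(va, 0.0), max(vb, 0.0), max(vc, 0.0)
    monomorphic = va == 0 and vb == 0 and vc == 0
    fst, fis, fit = _f_stats(va, vb, vc)

    # sums of squares for the report table
    ss_ag = ss_ai = ss_wi = 0.0
    for col in cols:
        res = _per_locus_ss(col, gidx, n_groups)
        if res is not None:
            ss_ag += res[0]
            ss_ai += res[1]
            ss_wi += res[2]

    p_fst = p_fis = p_fit = None
    if n_perm > 0 and not monomorphic:
        rng = np.random.default_rng(seed)
        hits_st = hits_is = hits_it = 0
        for _ in range(n_perm):
            perm_g = rng.permutation(gidx)
            s, _, _ = _f_stats(*_components(cols, perm_g, n_groups))
            if s >= fst:
                hits_st += 1
        for _ in range(n_perm):
            cols_p = [_permute_copies_within_groups(c, gidx, rng) for c in cols]
            _, s, _ = _f_stats(*_components(cols_p, gidx, n_groups))
            if s >= fis:
                hits_is += 1
        for _ in range(n_perm):
            cols_p = [_permute_copies(c, rng) for c in cols]
            _, _, s = _f_stats(*_components(cols_p, gidx, n_groups))
            if s >= fit:
                hits_it += 1
        p_fst = (hits_st + 1) / (n_perm + 1)
        p_fis = (hits_is + 1) / (n_perm + 1)
        p_fit = (hits_it + 1) / (n_perm + 1)

    tot_v = va + vb + vc
    pct = [100 * v / tot_v if tot_v != 0 else float("nan") for v in (va, vb, vc)]
    table = pd.DataFrame(
        {
            "df": [n_groups - 1, N - n_groups, N, 2 * N - 1],
            "SS": [ss_ag, ss_ai, ss_wi, ss_ag + ss_ai + ss_wi],
            "variance": [va, vb, vc, tot_v],
            "pct": pct + [100.0 if tot_v != 0 else float("nan")],
        },
        index=["among_groups", "among_individuals", "within_individuals", "total"],
    )
    return VarianceComponents(
        table=table, fst=fst, fis=fis, fit=fit,
        p_fst=p_fst, p_fis=p_fis, p_fit=p_fit,
        negative_components=(min(va, vb, vc) < 0),
        monomorphic=monomorphic,
    )


def _permute_copies(col: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = col.copy()
    ok = out[:, 0] >= 0
    copies = out[ok].ravel()
    rng.shuffle(copies)
    out[ok] = copies.reshape(-1, 2)
    return out


def _permute_copies_within_groups(col: np.ndarray, gidx: np.ndarray,
                                  rng: np.random.Generator) -> np.ndarray:
    out = col.copy()
    for gctr in np.unique(gidx):
        sel = (gidx == gctr) & (out[:, 0] >= 0)
        copies = out[sel].ravel()
        rng.shuffle(copies)
        out[sel] = copies.reshape(-1, 2)
    return out


def pairwise_fst(
    g: GenotypeMatrix,
    groups: Mapping[str, Sequence[str]],
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-group AMOVA Fst for every pair of groups.

    Returns (fst_matrix, p_matrix) as symmetric DataFrames with zero
    diagonal (p diagonal NaN).
    """
    labels = list(groups)
    if len(labels) < 2:
        raise GenodataError("need at least 2 groups")
    fst = pd.DataFrame(0.0, index=labels, columns=labels)
    pvals = pd.DataFrame(np.nan, index=labels, columns=labels)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(labels) * (len(labels) - 1) // 2)
    t = 0
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            res = amova(
                g, {labels[i]: groups[labels[i]], labels[j]: groups[labels[j]]},
                n_perm=n_perm,
                seed=int(children[t].generate_state(1)[0] % (2**31)),
            )
            t += 1
            fst.iloc[i, j] = fst.iloc[j, i] = res.fst
            if res.p_fst is not None:
                pvals.iloc[i, j] = pvals.iloc[j, i] = res.p_fst
    return fst, pvals


# ---------------------------------------------------------------------------
# Principal coordinates
# ---------------------------------------------------------------------------

def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> PcoaResult:
    """Classical metric scaling (Gower) of a distance matrix.

    On a Euclidean-embeddable matrix the pairwise distances of the
    coordinates reproduce the input exactly.  Negative eigenvalues (non-
    Euclidean input) are excluded from both the axes and the percentages.
    """
    d = dm.values
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-10 * abs(evals).max(), 1e-12)
    n_pos = int(pos.sum())
    if n_axes is None:
        n_axes = n_pos
    elif n_axes > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; truncating"
        )
        n_axes = n_pos
    coords = evecs[:, :n_axes] * np.sqrt(np.maximum(evals[:n_axes], 0.0))
    pct = 100.0 * evals[:n_axes] / evals[pos].sum() if n_pos else np.zeros(0)
    frame = pd.DataFrame(
        coords, index=dm.ids, columns=[f"PCo{k + 1}" for k in range(n_axes)]
    )
    return PcoaResult(coordinates=frame, eigenvalues=evals, percent=np.asarray(pct))
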