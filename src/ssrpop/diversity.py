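"""Per-locus and per-subset SSR diversity statistics and rarefaction.

Statistics per locus: observed allele count Ao, effective allele count
Ae = 1/sum(p_i^2), observed heterozygosity Ho, Nei gene diversity
He = 1 - sum(p_i^2), Wright's fixation index F = 1 - Ho/He, power of
discrimination PD = 1 - sum(g_j^2) over observed unordered-genotype
frequencies, major-allele frequency MAF, and distinct-genotype count Gn.
He is the plug-in estimator by default; an unbiased n/(n-1) correction is
optional.  F is undefined (NaN) at a monomorphic locus and excluded from
panel means.

Rarefaction draws subsamples of m individuals WITHOUT replacement and
reports the mean per-locus Ao averaged over loci with a distribution-free
two-sided Chebyshev band, mean +/- sqrt(1/alpha) * sd over replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genodata import (
    MISSING,
    GenotypeMatrix,
    SampleMetadata,
    GenodataError,
    allele_frequencies,
    subset,
)

__all__ = [
    "LocusDiversity",
    "RarefactionCurve",
    "locus_stats",
    "panel_summary",
    "subset_summary",
    "rarefaction",
    "chebyshev_k",
]

_STAT_COLS = ["n", "Ao", "Ae", "Ho", "He", "F", "PD", "MAF", "Gn"]


@dataclass(frozen=True)
class LocusDiversity:
    """Diversity statistics for one locus (NaN F means undefined)."""

    locus: str
    n: int
    Ao: int
    Ae: float
    Ho: float
    He: float
    F: float
    PD: float
    MAF: float
    Gn: int

    def as_series(self) -> pd.Series:
        return pd.Series(
            [self.n, self.Ao, self.Ae, self.Ho, self.He, self.F, self.PD,
             self.MAF, self.Gn],
            index=_STAT_COLS, name=self.locus,
        )


@dataclass
class RarefactionCurve:
    """Mean rarefied allele count with Chebyshev bounds per sample size m.

    ``table`` columns: m, mean, lo, hi, sd; ``B`` is the replicate count,
    ``alpha`` the two-sided tail probability of the band.
    """

    table: pd.DataFrame
    B: int
    alpha: float


def locus_stats(g: GenotypeMatrix, locus: str, unbiased_he: bool = False) -> LocusDiversity:
    """Compute the full per-locus diversity record.

    Requires at least one non-missing call at the locus.  With
    ``unbiased_he`` the gene diversity is scaled by n/(n-1) (n in
    individuals), and F uses that corrected He.
    """
    obs = g.locus_calls(locus)
    n = len(obs)
    if n == 0:
        raise GenodataError(f"locus {locus!r} has no non-missing calls")
    copies = obs.ravel()
    alleles, counts = np.unique(copies, return_counts=True)
    p = counts / counts.sum()
    ao = len(alleles)
    sum_p2 = float(np.sum(p**2))
    ae = 1.0 / sum_p2
    he = 1.0 - sum_p2
    if unbiased_he and n > 1:
        he *= n / (n - 1)
    ho = float(np.mean(obs[:, 0] != obs[:, 1]))
    f = 1.0 - ho / he if he > 0 else float("nan")
    # unordered genotype frequencies (homozygotes included)
    geno, gcounts = np.unique(obs, axis=0, return_counts=True)
    gfreq = gcounts / n
    pd_ = 1.0 - float(np.sum(gfreq**2))
    return LocusDiversity(
        locus=locus, n=n, Ao=ao, Ae=ae, Ho=ho, He=he, F=f, PD=pd_,
        MAF=float(p.max()), Gn=len(geno),
    )


def panel_table(g: GenotypeMatrix, unbiased_he: bool = False) -> pd.DataFrame:
    """Per-locus statistics for every locus, as a table shaped for export."""
    rows = [locus_stats(g, loc, unbiased_he).as_series() for loc in g.loci]
    return pd.DataFrame(rows)


def panel_summary(g: GenotypeMatrix, unbiased_he: bool = False) -> pd.Series:
    """Arithmetic mean of each per-locus statistic plus the total allele count.

    Undefined F values (monomorphic loci) are excluded from the F mean.
    """
    if g.n_loci == 0:
        raise GenodataError("empty panel")
    tab = panel_table(g, unbiased_he)
    out = tab.mean(axis=0, skipna=True)
    out["total_alleles"] = float(tab["Ao"].sum())
    out["n_loci"] = float(g.n_loci)
    return out


def summarize_printed_panel(tab: pd.DataFrame) -> pd.Series:
    """Summary (total and mean Ao, recomputed F) from an already-tabulated
    per-locus panel such as the packaged published one."""
    out = pd.Series(dtype=float)
    out["total_alleles"] = float(tab["Ao"].sum())
    out["mean_Ao"] = float(tab["Ao"].mean())
    out["mean_Ho"] = float(tab["Ho"].mean())
    out["mean_He"] = float(tab["He"].mean())
    return out


def fixation_index(ho: float, he: float) -> float:
    """Wright's per-locus fixation index F = 1 - Ho/He (NaN when He = 0)."""
    return 1.0 - ho / he if he > 0 else float("nan")


def subset_summary(g: GenotypeMatrix, metadata: SampleMetadata | None = None,
                   grouping: str | dict[str, list[str]] = "origin",
                   unbiased_he: bool = False) -> pd.DataFrame:
    """One :func:`panel_summary` row per group.

    ``grouping`` is either a metadata column name or an explicit mapping of
    group label -> individual ids.  Frequencies are re-estimated within each
    group's subset.
    """
    if isinstance(grouping, str):
        if metadata is None:
            raise ValueError("metadata required when grouping by column name")
        groups = metadata.groups(grouping)
    else:
        groups = {k: list(v) for k, v in grouping.items()}
    rows = {}
    for label, ids in groups.items():
        if not ids:
            raise GenodataError(f"empty group: {label!r}")
        rows[label] = panel_summary(subset(g, individuals=ids), unbiased_he)
    return pd.DataFrame(rows).T


def chebyshev_k(alpha: float) -> float:
    """Half-width multiplier of the two-sided Chebyshev band, sqrt(1/alpha)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return math.sqrt(1.0 / alpha)


def rarefaction(g: GenotypeMatrix, sizes, B: int = 100, alpha: float = 0.05,
                seed: int | None = None) -> RarefactionCurve:
    """Bootstrap-style rarefaction of the mean observed allele count.

    For each subsample size m, draw ``B`` subsets of m individuals without
    replacement, compute the per-locus allele count averaged over loci, and
    report the replicate mean with Chebyshev bounds mean +/- k*sd,
    k = sqrt(1/alpha).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    N = g.n_individuals
    rows = []
    for m in sizes:
        m = int(m)
        if not 2 <= m <= N:
            raise ValueError(f"subsample size {m} outside [2, {N}]")
        reps = np.empty(B)
        for b in range(B):
            idx = rng.choice(N, size=m, replace=False)
            sub = g.calls[idx]  # (m, L, 2)
            mean_ao = 0.0
            for j in range(g.n_loci):
                col = sub[:, j, :]
                obs = col[col[:, 0] != MISSING]
                mean_ao += len(np.unique(obs)) if obs.size else 0
            reps[b] = mean_ao / g.n_loci
        mean = float(reps.mean())
        sd = float(reps.std(ddof=1))
        k = chebyshev_k(alpha)
        rows.append((m, mean, mean - k * sd, mean + k * sd, sd))
    table = pd.DataFrame(rows, columns=["m", "mean", "lo", "hi", "sd"])
    return RarefactionCurve(table=table, B=B, alpha=alpha)
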