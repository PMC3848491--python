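"""Allele-pair linkage disequilibrium on unphased diploid genotypes.

Following the allele-pair convention for multi-allelic markers, each allele
at a locus is binarized against all others, giving a 0/1/2 dosage per
individual; every pair of such binarized alleles at two distinct loci is one
comparison.  Two-locus haplotype frequencies are estimated by EM over the
double-heterozygote phase ambiguity (expectation-maximization of the
gametic likelihood under random union of gametes), from which
D = p_AB - p_A p_B and r^2 = D^2 / (p_A(1-p_A) p_B(1-p_B)).  Significance
is a Monte-Carlo permutation test shuffling one locus among individuals.

Rare alleles (frequency below ``maf_min``, default 5%) are removed before
scanning because they inflate r^2.  Comparisons are classified intra- vs
inter-chromosome from a marker map; genetic distance (cM) is defined within
a linkage group and physical distance (Kbp) within a shared scaffold.  The
decay of intra-chromosome LD with distance is summarized by four
equal-count bins and a least-squares fit of r^2 = a + b ln(d) through the
bin means, reporting the distance d* at which the fitted curve crosses a
threshold (default r^2 = 0.1), or NO_DECAY when it never does.

For a locus left with exactly two alleles after filtering, its two
binarizations are complements with identical r^2; both records are emitted
but only one carries ``unique=True`` for counting.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genodata import (
    MISSING,
    GenotypeMatrix,
    MarkerMap,
    allele_frequencies,
    recode_rare_alleles,
)

__all__ = [
    "LDRecord",
    "DecayFit",
    "LDSummary",
    "NO_DECAY",
    "em_haplotype_freqs",
    "allele_pair_r2",
    "ld_significance",
    "ld_scan",
    "ld_summary",
    "decay_fit",
    "per_linkage_group",
    "records_frame",
]

#: Sentinel decay distance when the fitted curve never crosses the threshold.
NO_DECAY = None


@dataclass(frozen=True)
class LDRecord:
    """One allele-pair comparison between two loci."""

    locus_a: str
    allele_a: int
    locus_b: str
    allele_b: int
    r2: float
    D: float
    n: int
    p_value: float | None = None
    intra_chromosome: bool | None = None
    linkage_group_a: int | None = None
    linkage_group_b: int | None = None
    dist_cm: float = float("nan")
    dist_kbp: float = float("nan")
    unique: bool = True
    converged: bool = True
    defined: bool = True


@dataclass
class DecayFit:
    """Equal-count-bin decay summary and logarithmic fit r^2 = a + b ln d."""

    bins: pd.DataFrame          # columns: mean_dist, mean_r2, count
    intercept: float
    slope: float
    d_star: float | None        # threshold crossing, or NO_DECAY
    metric: str
    r2_star: float


@dataclass
class LDSummary:
    """Per-subpopulation comparison counts and above-threshold percentages."""

    total: int
    inter_count: int
    inter_pct_above: float
    intra_count: int
    intra_pct_above: float
    r2_threshold: float

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "n_comparisons": self.total,
                "inter_chromosome": self.inter_count,
                "pct_inter_above": self.inter_pct_above,
                "intra_chromosome": self.intra_count,
                "pct_intra_above": self.intra_pct_above,
            }
        )


# ---------------------------------------------------------------------------
# EM haplotype-frequency estimation (two binarized loci)
# ---------------------------------------------------------------------------

def _dosage(g: GenotypeMatrix, locus: str, allele: int) -> np.ndarray:
    j = g.locus_index(locus)
    col = g.calls[:, j, :]
    d = (col == allele).sum(axis=1).astype(np.int64)
    d[col[:, 0] == MISSING] = -1
    return d


def _geno_table(da: np.ndarray, db: np.ndarray) -> np.ndarray:
    """3x3 joint dosage counts over individuals typed at both loci."""
    ok = (da >= 0) & (db >= 0)
    return np.bincount(da[ok] * 3 + db[ok], minlength=9).reshape(3, 3).astype(float)


def em_haplotype_freqs(table: np.ndarray, tol: float = 1e-8,
                       max_iter: int = 1000, track_loglik: bool = False):
    """EM for two-locus haplotype frequencies from a 3x3 dosage table.

    Starts at linkage equilibrium (product of the margins).  Returns
    ``(freqs, converged, loglik_path)`` where ``freqs`` is the dict of
    haplotype frequencies {"AB", "Ab", "aB", "ab"} and ``loglik_path`` the
    observed-data log-likelihood after each iteration (non-decreasing;
    empty unless ``track_loglik``).
    """
    t = np.asarray(table, dtype=float)
    n = t.sum()
    if n < 2:
        raise ValueError("need at least 2 individuals typed at both loci")
    pa = (2 * t[2].sum() + t[1].sum()) / (2 * n)
    pb = (2 * t[:, 2].sum() + t[:, 1].sum()) / (2 * n)
    n11 = t[1, 1]
    # phase-known haplotype counts (the margins are preserved by every
    # EM iterate, so p_AB is the only free parameter)
    b_AB = 2 * t[2, 2] + t[2, 1] + t[1, 2]
    b_Ab = 2 * t[2, 0] + t[2, 1] + t[1, 0]
    b_aB = 2 * t[0, 2] + t[0, 1] + t[1, 2]
    b_ab = 2 * t[0, 0] + t[0, 1] + t[1, 0]
    two_n = 2 * n

    def run(pab0):
        p_AB = pab0
        p_Ab = pa - pab0
        p_aB = pb - pab0
        p_ab_ = 1 - pa - pb + pab0
        path: list[float] = []
        converged = False
        for _ in range(max_iter):
            num = p_AB * p_ab_
            den = num + p_Ab * p_aB
            h = num / den if den > 0 else 0.5
            nAB = (b_AB + h * n11) / two_n
            nAb = (b_Ab + (1 - h) * n11) / two_n
            naB = (b_aB + (1 - h) * n11) / two_n
            nab = (b_ab + h * n11) / two_n
            if track_loglik:
                path.append(_table_loglik(
                    t, {"AB": nAB, "Ab": nAb, "aB": naB, "ab": nab}))
            delta = max(abs(nAB - p_AB), abs(nAb - p_Ab),
                        abs(naB - p_aB), abs(nab - p_ab_))
            p_AB, p_Ab, p_aB, p_ab_ = nAB, nAb, naB, nab
            if delta < tol:
                converged = True
                break
        return {"AB": p_AB, "Ab": p_Ab, "aB": p_aB, "ab": p_ab_}, converged, path

    if n11 == 0:
        # no phase ambiguity: single fixed point, reached in one step
        return run(pa * pb)
    # with double heterozygotes the likelihood in p_AB can be bimodal:
    # start from linkage equilibrium and both Frechet-bound extremes,
    # keep the highest-likelihood solution
    lo = max(0.0, pa + pb - 1.0)
    hi = min(pa, pb)
    starts = [pa * pb, lo + 0.02 * (hi - lo), hi - 0.02 * (hi - lo)]
    best = None
    best_ll = -math.inf
    for s in starts:
        cand = run(s)
        ll = _table_loglik(t, cand[0])
        if ll > best_ll + 1e-12:
            best, best_ll = cand, ll
    return best


def _table_loglik(t: np.ndarray, p: dict[str, float]) -> float:
    """Observed-data log-likelihood of the 3x3 dosage table under random
    union of gametes."""
    hap = np.array([[p["ab"], p["aB"]], [p["Ab"], p["AB"]]])  # [daco, dbco]
    ll = 0.0
    for i in range(3):
        for j in range(3):
            if t[i, j] == 0:
                continue
            prob = 0.0
            # genotype = union of two gametes (x1,y1) + (x2,y2), x1+x2=i, y1+y2=j
            for x1 in range(2):
                for y1 in range(2):
                    x2, y2 = i - x1, j - y1
                    if 0 <= x2 <= 1 and 0 <= y2 <= 1:
                        prob += hap[x1, y1] * hap[x2, y2]
            ll += t[i, j] * math.log(max(prob, 1e-300))
    return ll


def _r2_from_freqs(p: dict[str, float]):
    pa = p["AB"] + p["Ab"]
    pb = p["AB"] + p["aB"]
    d = p["AB"] - pa * pb
    denom = pa * (1 - pa) * pb * (1 - pb)
    if denom <= 0:
        return float("nan"), d
    return d * d / denom, d


def allele_pair_r2(g: GenotypeMatrix, locus_a: str, allele_a: int,
                   locus_b: str, allele_b: int) -> LDRecord:
    """r^2 and D between two binarized alleles at two loci (no distances).

    A binarization monomorphic among the jointly-typed individuals yields an
    undefined r^2 (``defined=False``).
    """
    da = _dosage(g, locus_a, allele_a)
    db = _dosage(g, locus_b, allele_b)
    t = _geno_table(da, db)
    n = int(t.sum())
    if n < 2:
        raise ValueError(
            f"fewer than 2 individuals typed at both {locus_a!r} and {locus_b!r}"
        )
    pa = (2 * t[2].sum() + t[1].sum()) / (2 * n)
    pb = (2 * t[:, 2].sum() + t[:, 1].sum()) / (2 * n)
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return LDRecord(locus_a, allele_a, locus_b, allele_b,
                        r2=float("nan"), D=float("nan"), n=n, defined=False)
    p, converged, _ = em_haplotype_freqs(t)
    r2, d = _r2_from_freqs(p)
    return LDRecord(locus_a, allele_a, locus_b, allele_b,
                    r2=r2, D=d, n=n, converged=converged)


def _r2_of_table(t: np.ndarray) -> float:
    n = t.sum()
    pa = (2 * t[2].sum() + t[1].sum()) / (2 * n)
    pb = (2 * t[:, 2].sum() + t[:, 1].sum()) / (2 * n)
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return float("nan")
    p, _, _ = em_haplotype_freqs(t)
    return _r2_from_freqs(p)[0]


def ld_significance(g: GenotypeMatrix, record: LDRecord, n_perm: int = 999,
                    seed: int | None = None) -> float:
    """Monte-Carlo permutation p-value for one comparison.

    One locus's genotype column is permuted among individuals ``n_perm``
    times; p = (#{r^2_perm >= r^2_obs} + 1)/(n_perm + 1).
    """
    da = _dosage(g, record.locus_a, record.allele_a)
    db = _dosage(g, record.locus_b, record.allele_b)
    obs = record.r2
    if not np.isfinite(obs):
        return 1.0
    if obs == 0.0:
        return 1.0
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(db)
        t = _geno_table(da, perm)
        r2p = _r2_of_table(t)
        if np.isfinite(r2p) and r2p >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Scanning a panel
# ---------------------------------------------------------------------------

def ld_scan(
    g: GenotypeMatrix,
    marker_map: MarkerMap | None = None,
    maf_min: float = 0.05,
    n_perm: int = 0,
    seed: int | None = None,
) -> list[LDRecord]:
    """All allele-pair comparisons between distinct loci after rare-allele
    removal, annotated with chromosome split and map distances."""
    filtered = recode_rare_alleles(g, maf_min) if maf_min > 0 else g
    aft = allele_frequencies(filtered)
    retained = {loc: sorted(aft.freqs[loc]) for loc in filtered.loci}
    ss = np.random.SeedSequence(seed)
    records: list[LDRecord] = []
    dosages: dict[tuple[str, int], np.ndarray] = {}
    for loc in filtered.loci:
        for al in retained[loc]:
            dosages[(loc, al)] = _dosage(filtered, loc, al)

    pair_seeds = iter(ss.spawn(len(filtered.loci) * (len(filtered.loci) - 1) // 2 + 1))
    for la, lb in itertools.combinations(filtered.loci, 2):
        intra = None
        lg_a = lg_b = None
        dist_cm = dist_kbp = float("nan")
        if marker_map is not None and la in marker_map.loci and lb in marker_map.loci:
            lg_a = marker_map.linkage_group(la)
            lg_b = marker_map.linkage_group(lb)
            intra = lg_a == lg_b
            dist_cm = marker_map.cm_distance(la, lb)
            dist_kbp = marker_map.kbp_distance(la, lb)
        child = next(pair_seeds)
        perm_rng = (np.random.default_rng(child.generate_state(1)[0])
                    if n_perm > 0 else None)
        biallelic_a = len(retained[la]) == 2
        biallelic_b = len(retained[lb]) == 2
        for ia, aa in enumerate(retained[la]):
            for ib, ab in enumerate(retained[lb]):
                da, db = dosages[(la, aa)], dosages[(lb, ab)]
                t = _geno_table(da, db)
                n = int(t.sum())
                if n < 2:
                    continue
                pa = (2 * t[2].sum() + t[1].sum()) / (2 * n)
                pb = (2 * t[:, 2].sum() + t[:, 1].sum()) / (2 * n)
                unique = (not biallelic_a or ia == 0) and (not biallelic_b or ib == 0)
                if pa in (0.0, 1.0) or pb in (0.0, 1.0):
                    rec = LDRecord(la, aa, lb, ab, float("nan"), float("nan"), n,
                                   intra_chromosome=intra, linkage_group_a=lg_a,
                                   linkage_group_b=lg_b, dist_cm=dist_cm,
                                   dist_kbp=dist_kbp, unique=unique, defined=False)
                else:
                    p, conv, _ = em_haplotype_freqs(t)
                    r2, d = _r2_from_freqs(p)
                    pval = None
                    if perm_rng is not None and np.isfinite(r2):
                        hits = 0
                        for _ in range(n_perm):
                            tp = _geno_table(da, perm_rng.permutation(db))
                            r2p = _r2_of_table(tp)
                            if np.isfinite(r2p) and r2p >= r2 - 1e-12:
                                hits += 1
                        pval = (hits + 1) / (n_perm + 1)
                    rec = LDRecord(la, aa, lb, ab, r2, d, n, p_value=pval,
                                   intra_chromosome=intra, linkage_group_a=lg_a,
                                   linkage_group_b=lg_b, dist_cm=dist_cm,
                                   dist_kbp=dist_kbp, unique=unique, converged=conv)
                records.append(rec)
    return records


def records_frame(records: list[LDRecord]) -> pd.DataFrame:
    """Records as a flat DataFrame for TSV export."""
    return pd.DataFrame([r.__dict__ for r in records])


def ld_summary(records: list[LDRecord], r2_threshold: float = 0.1) -> LDSummary:
    """Counts and above-threshold percentages over the given records.

    Records with undefined r^2 count toward totals but not the percentages'
    numerators; pass a pre-filtered list (e.g. unique-only) to control what
    is counted.
    """
    if not records:
        raise ValueError("no records")
    intra = [r for r in records if r.intra_chromosome]
    inter = [r for r in records if r.intra_chromosome is False]
    def pct(rs):
        if not rs:
            return float("nan")
        above = sum(1 for r in rs if np.isfinite(r.r2) and r.r2 > r2_threshold)
        return 100.0 * above / len(rs)
    return LDSummary(
        total=len(records),
        inter_count=len(inter), inter_pct_above=pct(inter),
        intra_count=len(intra), intra_pct_above=pct(intra),
        r2_threshold=r2_threshold,
    )


def decay_fit(records: list[LDRecord], metric: str = "kbp", n_bins: int = 4,
              r2_star: float = 0.1) -> DecayFit:
    """Equal-count-bin logarithmic decay fit of intra-chromosome LD.

    Comparisons are sorted by distance and split into ``n_bins`` adjacent
    bins of (as near as possible) equal count; r^2 = a + b ln(d) is fitted
    by least squares through the bin means.  ``d_star`` solves the fitted
    curve at ``r2_star``; it is ``NO_DECAY`` when b >= 0 or when the
    crossing lies outside (0, 10 x max distance].
    """
    if metric not in ("cm", "kbp"):
        raise ValueError("metric must be 'cm' or 'kbp'")
    attr = "dist_cm" if metric == "cm" else "dist_kbp"
    pts = [
        (getattr(r, attr), r.r2)
        for r in records
        if r.intra_chromosome and np.isfinite(getattr(r, attr))
        and getattr(r, attr) > 0 and np.isfinite(r.r2)
    ]
    if len(pts) < n_bins:
        raise ValueError(f"need >= {n_bins} intra-chromosome records with distance")
    pts.sort(key=lambda t: t[0])
    arr = np.array(pts)
    chunks = np.array_split(arr, n_bins)
    bins = pd.DataFrame(
        {
            "mean_dist": [c[:, 0].mean() for c in chunks],
            "mean_r2": [c[:, 1].mean() for c in chunks],
            "count": [len(c) for c in chunks],
        }
    )
    slope, intercept = np.polyfit(np.log(bins["mean_dist"]), bins["mean_r2"], 1)
    d_star: float | None
    if slope >= 0:
        d_star = NO_DECAY
    else:
        exponent = (r2_star - intercept) / slope
        if exponent > math.log(10 * arr[-1, 0]):
            d_star = NO_DECAY
        else:
            d_star = float(math.exp(exponent))
            if d_star <= 0:
                d_star = NO_DECAY
    return DecayFit(bins=bins, intercept=float(intercept), slope=float(slope),
                    d_star=d_star, metric=metric, r2_star=r2_star)


def per_linkage_group(records: list[LDRecord], r2_threshold: float = 0.1,
                      linkage_groups=range(1, 9)) -> pd.Series:
    """Proportion of intra-chromosome comparisons above threshold per
    linkage group (NaN where a group has no comparisons)."""
    out = {}
    for lg in linkage_groups:
        rs = [
            r for r in records
            if r.intra_chromosome and r.linkage_group_a == lg
        ]
        if not rs:
            out[lg] = float("nan")
        else:
            above = sum(1 for r in rs if np.isfinite(r.r2) and r.r2 > r2_threshold)
            out[lg] = above / len(rs)
    return pd.Series(out, name="prop_in_ld")
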