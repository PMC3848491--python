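"""Synthetic SSR panels with known truth.

Two generators cover the statistical structure the analyses assume:

* :func:`simulate_structured` draws K subpopulations whose allele
  frequencies drift from a common ancestral pool under the correlated-
  frequencies model (P_k,l ~ Dirichlet(p_A,l (1-F_k)/F_k)), with optional
  per-individual admixture (q_i ~ Dirichlet(alpha)) and partial selfing.
  Selfing is applied as its equilibrium inbreeding coefficient
  F_is = s/(2-s): with that probability the two allele copies at a locus
  are identical by descent, depressing Ho below He by the same factor.

* :func:`simulate_ld_panel` forward-simulates a small founder population
  through G generations of random mating (with selfing probability s) and
  Haldane crossovers (Poisson count at length/100 cM, uniform placement),
  so intra-chromosome LD decays with genetic distance while unlinked loci
  approach the 1/(2N)-scale background.

:func:`fixture_panels` bundles small deterministic panels used across the
test-suite and the worked examples, including a hierarchical 2x(2) design
for the nested clustering driver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genodata import (
    MISSING,
    GenotypeMatrix,
    MarkerMap,
    load_packaged_marker_map,
)

__all__ = [
    "SimTruth",
    "simulate_structured",
    "simulate_hierarchical",
    "simulate_ld_panel",
    "fixture_panels",
    "equilibrium_inbreeding",
]

#: SSR-like fragment sizes: allele j at any locus is labelled 150 + 2j.
_BASE_SIZE = 150


@dataclass
class SimTruth:
    """Ground truth of a simulated panel."""

    K: int
    ancestral_freqs: list[np.ndarray] | None
    cluster_freqs: list[list[np.ndarray]] | None  # [k][locus] -> freq vector
    drift: list[float] | None
    admixture: np.ndarray | None  # (N, K) true q_i
    selfing: float
    marker_map: MarkerMap | None
    generations: int | None
    n_founders: int | None
    seed: int | None
    labels: np.ndarray | None = None  # true top-level population of origin

    def to_frame(self) -> pd.DataFrame:
        """Flat per-individual truth table (admixture + label)."""
        cols = {}
        if self.admixture is not None:
            for k in range(self.K):
                cols[f"q{k + 1}"] = self.admixture[:, k]
        if self.labels is not None:
            cols["pop"] = self.labels
        return pd.DataFrame(cols)


def equilibrium_inbreeding(s: float) -> float:
    """Equilibrium inbreeding coefficient F_is = s/(2-s) at selfing rate s."""
    if not 0 <= s <= 1:
        raise ValueError("selfing rate must be in [0, 1]")
    return s / (2.0 - s)


def _check_simplex_params(F_k: Sequence[float], s: float) -> None:
    for f in F_k:
        if not 0 <= f < 1:
            raise ValueError(f"drift parameter must be in [0, 1), got {f}")
    if not 0 <= s <= 1:
        raise ValueError(f"selfing rate must be in [0, 1], got {s}")


def simulate_structured(
    K: int,
    n_per_pop: int | Sequence[int],
    n_loci: int = 25,
    alleles_per_locus: int = 6,
    F_k: float | Sequence[float] = 0.2,
    alpha: float | None = None,
    selfing: float = 0.0,
    marker_map: MarkerMap | None = None,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Drift-structured diploid SSR panel with known admixture truth.

    With ``alpha`` None each individual belongs wholly to its population of
    origin; otherwise q_i ~ Dirichlet(alpha * 1_K) (symmetric), making every
    individual admixed.  Selfing enters as equilibrium inbreeding (see
    module docstring).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    sizes = [n_per_pop] * K if np.isscalar(n_per_pop) else list(n_per_pop)
    if len(sizes) != K:
        raise ValueError("n_per_pop must be scalar or length K")
    drift = [F_k] * K if np.isscalar(F_k) else list(F_k)
    _check_simplex_params(drift, selfing)
    rng = np.random.default_rng(seed)
    N = int(sum(sizes))

    p_anc = [rng.dirichlet(np.ones(alleles_per_locus)) for _ in range(n_loci)]
    cluster = []
    for k in range(K):
        fk = drift[k]
        if fk == 0:
            cluster.append([p.copy() for p in p_anc])
        else:
            lam = (1 - fk) / fk
            cluster.append([rng.dirichlet(np.maximum(p * lam, 1e-9)) for p in p_anc])

    labels = np.repeat(np.arange(K), sizes)
    if alpha is None:
        q = np.zeros((N, K))
        q[np.arange(N), labels] = 1.0
    else:
        q = rng.dirichlet(np.full(K, float(alpha)), size=N)

    f_is = equilibrium_inbreeding(selfing)
    calls = np.empty((N, n_loci, 2), dtype=np.int64)
    for i in range(N):
        for j in range(n_loci):
            z1 = rng.choice(K, p=q[i])
            a1 = rng.choice(alleles_per_locus, p=cluster[z1][j])
            if rng.random() < f_is:
                a2 = a1  # identical by descent
            else:
                z2 = rng.choice(K, p=q[i])
                a2 = rng.choice(alleles_per_locus, p=cluster[z2][j])
            calls[i, j] = (_BASE_SIZE + 2 * a1, _BASE_SIZE + 2 * a2)

    individuals = [f"S{i + 1:04d}" for i in range(N)]
    loci = (list(marker_map.loci[:n_loci]) if marker_map is not None
            else [f"SSR{j + 1:02d}" for j in range(n_loci)])
    g = GenotypeMatrix(individuals, loci, calls)
    truth = SimTruth(
        K=K, ancestral_freqs=p_anc, cluster_freqs=cluster, drift=drift,
        admixture=q, selfing=selfing, marker_map=marker_map,
        generations=None, n_founders=None, seed=seed, labels=labels,
    )
    return g, truth


def simulate_hierarchical(
    K_top: int = 2,
    K_sub: int = 2,
    n_per_sub: int = 30,
    n_loci: int = 25,
    alleles_per_locus: int = 8,
    F_top: float = 0.45,
    F_sub: float = 0.15,
    marker_map: MarkerMap | None = None,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Two-level population design: K_top populations each split in K_sub.

    Top-level frequencies drift strongly (``F_top``) from a common ancestor;
    within each top population, sub-population frequencies drift moderately
    (``F_sub``) from their population's pool.  Truth labels encode
    ``top * K_sub + sub``.
    """
    rng = np.random.default_rng(seed)
    p_anc = [rng.dirichlet(np.ones(alleles_per_locus)) for _ in range(n_loci)]
    lam_top = (1 - F_top) / F_top
    lam_sub = (1 - F_sub) / F_sub
    sub_freqs: list[list[np.ndarray]] = []
    for _t in range(K_top):
        p_top = [rng.dirichlet(np.maximum(p * lam_top, 1e-9)) for p in p_anc]
        for _s in range(K_sub):
            sub_freqs.append(
                [rng.dirichlet(np.maximum(p * lam_sub, 1e-9)) for p in p_top]
            )
    K_total = K_top * K_sub
    N = K_total * n_per_sub
    labels = np.repeat(np.arange(K_total), n_per_sub)
    calls = np.empty((N, n_loci, 2), dtype=np.int64)
    for i in range(N):
        fr = sub_freqs[labels[i]]
        for j in range(n_loci):
            a = rng.choice(alleles_per_locus, size=2, p=fr[j])
            calls[i, j] = _BASE_SIZE + 2 * a
    q = np.zeros((N, K_total))
    q[np.arange(N), labels] = 1.0
    loci = (list(marker_map.loci[:n_loci]) if marker_map is not None
            else [f"SSR{j + 1:02d}" for j in range(n_loci)])
    g = GenotypeMatrix([f"S{i + 1:04d}" for i in range(N)], loci, calls)
    truth = SimTruth(
        K=K_total, ancestral_freqs=p_anc, cluster_freqs=[sub_freqs],
        drift=[F_top, F_sub], admixture=q, selfing=0.0, marker_map=marker_map,
        generations=None, n_founders=None, seed=seed, labels=labels,
    )
    return g, truth


def simulate_ld_panel(
    n_founders: int = 8,
    N: int = 100,
    generations: int = 10,
    marker_map: MarkerMap | None = None,
    selfing: float = 0.0,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Forward simulation generating recombination-driven intra-chromosome LD.

    Each of the 2*``n_founders`` founder chromosomes carries a unique allele
    label at every locus, so haplotype identity is directly observable.  The
    population is propagated ``generations`` rounds: each offspring takes a
    recombinant gamete from each parent (one parent when selfing), with
    Haldane crossovers.  No mutation.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    if marker_map is None:
        marker_map = load_packaged_marker_map()
    if not 0 <= selfing <= 1:
        raise ValueError("selfing rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    mt = marker_map.table.dropna(subset=["cm"])
    groups = []  # list of (locus_ids, positions)
    for _, grp in mt.groupby("linkage_group", sort=True):
        grp = grp.sort_values("cm", kind="stable")
        groups.append((list(grp.index), grp["cm"].to_numpy(float)))
    loci = [l for ids, _ in groups for l in ids]
    L = len(loci)
    n_hap = 2 * n_founders

    # population as (N, 2, L) haplotype arrays of founder-chromosome labels
    founder_hap = np.arange(n_hap)
    pop = founder_hap[rng.integers(0, n_hap, size=(N, 2))][:, :, None] * np.ones(
        (1, 1, L), dtype=int
    )
    pop = pop.astype(np.int64)

    def gamete(ind: np.ndarray) -> np.ndarray:
        out = np.empty(L, dtype=np.int64)
        off = 0
        for ids, cm in groups:
            ln = len(ids)
            length = float(cm[-1] - cm[0]) if ln > 1 else 0.0
            n_x = rng.poisson(length / 100.0)
            cur = rng.integers(0, 2)
            if n_x == 0:
                out[off:off + ln] = ind[cur, off:off + ln]
            else:
                xpos = np.sort(rng.uniform(cm[0], cm[-1], size=n_x))
                hap_idx = (cur + np.searchsorted(xpos, cm, side="right")) % 2
                out[off:off + ln] = ind[hap_idx, np.arange(off, off + ln)]
            off += ln
        return out

    for _g in range(generations):
        nxt = np.empty_like(pop)
        for i in range(N):
            p1 = rng.integers(0, N)
            p2 = p1 if rng.random() < selfing else rng.integers(0, N)
            nxt[i, 0] = gamete(pop[p1])
            nxt[i, 1] = gamete(pop[p2])
        pop = nxt

    calls = _BASE_SIZE + 2 * np.stack([pop[:, 0, :], pop[:, 1, :]], axis=2)
    g = GenotypeMatrix([f"S{i + 1:04d}" for i in range(N)], loci, calls)
    truth = SimTruth(
        K=1, ancestral_freqs=None, cluster_freqs=None, drift=None,
        admixture=None, selfing=selfing, marker_map=marker_map,
        generations=generations, n_founders=n_founders, seed=seed,
    )
    return g, truth


def fixture_panels(seed: int = 0) -> dict[str, object]:
    """Deterministic named mini-panels shared across tests and examples.

    Keys: ``two_fixed_pops`` (two populations fixed for different alleles,
    Fst = 1 by construction), ``hw_panmictic`` (one Hardy-Weinberg
    population), ``nested_2x2`` (2 top-level populations each split in 2),
    ``ld_decay_default`` (forward-simulated LD panel), ``marker_map`` (the
    packaged 48-SSR map) and ``published_ao`` (the published per-locus
    observed-allele counts).
    """
    from .genodata import load_packaged_locus_table

    rng_seed = int(seed)
    mm = load_packaged_marker_map()

    # two populations fixed for different alleles at every locus
    n, L = 12, 10
    calls = np.empty((2 * n, L, 2), dtype=np.int64)
    calls[:n] = _BASE_SIZE
    calls[n:] = _BASE_SIZE + 2
    two_fixed = GenotypeMatrix(
        [f"A{i + 1:02d}" for i in range(n)] + [f"B{i + 1:02d}" for i in range(n)],
        [f"SSR{j + 1:02d}" for j in range(L)],
        calls,
    )
    two_fixed_groups = {
        "popA": two_fixed.individuals[:n], "popB": two_fixed.individuals[n:]
    }

    hw, hw_truth = simulate_structured(
        K=1, n_per_pop=100, n_loci=10, alleles_per_locus=5,
        F_k=0.0, selfing=0.0, seed=rng_seed + 1,
    )
    nested, nested_truth = simulate_hierarchical(seed=rng_seed + 2)
    ldp, ld_truth = simulate_ld_panel(
        n_founders=6, N=80, generations=8, marker_map=mm, seed=rng_seed + 3
    )
    return {
        "two_fixed_pops": two_fixed,
        "two_fixed_pops_groups": two_fixed_groups,
        "hw_panmictic": hw,
        "hw_panmictic_truth": hw_truth,
        "nested_2x2": nested,
        "nested_2x2_truth": nested_truth,
        "ld_decay_default": ldp,
        "ld_decay_default_truth": ld_truth,
        "marker_map": mm,
        "published_ao": load_packaged_locus_table()["Ao"],
    }
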