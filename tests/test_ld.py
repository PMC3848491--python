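"""EM haplotype frequencies, allele-pair r2, permutation tests and decay."""

import math

import numpy as np
import pytest

from ssrpop import ld as ldm
from ssrpop import synthetic_data as sd
from ssrpop.genodata import MarkerMap
import pandas as pd
from conftest import make_matrix


def grid_search_ml(table, step=1e-3):
    """1-D likelihood grid oracle.

    The ML margins equal the observed allele frequencies (every EM iterate
    preserves them), so the likelihood is maximized over the single free
    parameter p_AB within its Frechet bounds.
    """
    t = np.asarray(table, float)
    n = t.sum()
    pa = (2 * t[2].sum() + t[1].sum()) / (2 * n)
    pb = (2 * t[:, 2].sum() + t[:, 1].sum()) / (2 * n)
    lo = max(0.0, pa + pb - 1.0)
    hi = min(pa, pb)
    best, best_ll = lo, -np.inf
    for pab in np.arange(lo, hi + step / 2, step):
        p = {"AB": pab, "Ab": pa - pab, "aB": pb - pab,
             "ab": 1 - pa - pb + pab}
        if min(p.values()) < -1e-12:
            continue
        ll = ldm._table_loglik(t, p)
        if ll > best_ll:
            best, best_ll = pab, ll
    return best, best_ll


def random_tables(rng, n_tables, n_max=6):
    for _ in range(n_tables):
        n = int(rng.integers(2, n_max + 1))
        flat = rng.multinomial(n, rng.dirichlet(np.ones(9)))
        yield flat.reshape(3, 3).astype(float)


class TestEM:
    def test_perfect_coupling(self):
        g = make_matrix([[(150, 150), (200, 200)]] * 2
                        + [[(152, 152), (202, 202)]] * 2)
        rec = ldm.allele_pair_r2(g, "L1", 150, "L2", 200)
        assert rec.D == pytest.approx(0.25)
        assert rec.r2 == pytest.approx(1.0)

    def test_double_heterozygote_fixed_point(self):
        # 4 coupled AABB + 4 aabb homozygote pairs plus 1 double het
        t = np.zeros((3, 3))
        t[2, 2] = 4
        t[0, 0] = 4
        t[1, 1] = 1
        p, conv, _ = ldm.em_haplotype_freqs(t)
        assert conv
        assert p["AB"] == pytest.approx(0.5, abs=1e-6)
        assert p["ab"] == pytest.approx(0.5, abs=1e-6)
        r2, d = ldm._r2_from_freqs(p)
        assert r2 == pytest.approx(1.0, abs=1e-5)
        # cross-check against the grid-search maximum
        pab, _ = grid_search_ml(t)
        assert p["AB"] == pytest.approx(pab, abs=5e-3)

    def test_em_matches_grid_search_on_small_datasets(self):
        rng = np.random.default_rng(19)
        checked = 0
        for t in random_tables(rng, 400):
            n = t.sum()
            pa = (2 * t[2].sum() + t[1].sum()) / (2 * n)
            pb = (2 * t[:, 2].sum() + t[:, 1].sum()) / (2 * n)
            if pa in (0, 1) or pb in (0, 1):
                continue
            p, _, _ = ldm.em_haplotype_freqs(t)
            pab, grid_ll = grid_search_ml(t)
            if abs(p["AB"] - pab) > 5e-3:
                # a flat likelihood admits distinct argmaxes; require the
                # EM solution to attain the grid maximum
                em_ll = ldm._table_loglik(t, p)
                assert em_ll >= grid_ll - 1e-6
            checked += 1
        assert checked > 200

    def test_likelihood_nondecreasing(self):
        rng = np.random.default_rng(29)
        for t in random_tables(rng, 50, n_max=12):
            n = t.sum()
            pa = (2 * t[2].sum() + t[1].sum()) / (2 * n)
            pb = (2 * t[:, 2].sum() + t[:, 1].sum()) / (2 * n)
            if pa in (0, 1) or pb in (0, 1):
                continue
            _, _, path = ldm.em_haplotype_freqs(t, track_loglik=True)
            diffs = np.diff(path)
            assert (diffs >= -1e-9).all()

    def test_independent_loci_near_zero(self):
        rng = np.random.default_rng(37)
        r2s = []
        N = 1000
        for _ in range(30):
            da = rng.binomial(1, 0.4, (N, 2)).sum(1)
            db = rng.binomial(1, 0.6, (N, 2)).sum(1)
            r2s.append(ldm._r2_of_table(ldm._geno_table(da, db)))
        assert np.mean(r2s) <= 0.01

    def test_r2_symmetric_and_complement_invariant(self):
        g = make_matrix([
            [(150, 152), (200, 202)],
            [(150, 150), (200, 200)],
            [(152, 152), (202, 202)],
            [(150, 152), (200, 200)],
            [(150, 150), (200, 202)],
        ])
        a = ldm.allele_pair_r2(g, "L1", 150, "L2", 200)
        b = ldm.allele_pair_r2(g, "L2", 200, "L1", 150)
        c = ldm.allele_pair_r2(g, "L1", 152, "L2", 202)
        assert a.r2 == pytest.approx(b.r2, abs=1e-9)
        assert a.r2 == pytest.approx(c.r2, abs=1e-9)


class TestSignificance:
    def test_perfect_coupling_significant(self):
        g = make_matrix([[(150, 150), (200, 200)]] * 5
                        + [[(152, 152), (202, 202)]] * 5)
        rec = ldm.allele_pair_r2(g, "L1", 150, "L2", 200)
        p = ldm.ld_significance(g, rec, n_perm=999, seed=3)
        assert p <= 0.05

    def test_zero_r2_gives_p_one(self):
        g = make_matrix([
            [(150, 150), (200, 200)],
            [(150, 150), (202, 202)],
            [(152, 152), (200, 200)],
            [(152, 152), (202, 202)],
        ])
        rec = ldm.allele_pair_r2(g, "L1", 150, "L2", 200)
        assert rec.r2 == pytest.approx(0.0, abs=1e-12)
        assert ldm.ld_significance(g, rec, n_perm=99, seed=1) == 1.0

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(41)
        R, N = 200, 80
        rej = 0
        for _ in range(R):
            da = rng.binomial(1, 0.5, (N, 2)).sum(1)
            db = rng.binomial(1, 0.5, (N, 2)).sum(1)
            obs = ldm._r2_of_table(ldm._geno_table(da, db))
            hits = 0
            for _ in range(99):
                r2p = ldm._r2_of_table(ldm._geno_table(da, rng.permutation(db)))
                if np.isfinite(r2p) and r2p >= obs - 1e-12:
                    hits += 1
            if (hits + 1) / 100 <= 0.05:
                rej += 1
        assert 0.01 <= rej / R <= 0.10


def toy_map():
    df = pd.DataFrame(
        {
            "linkage_group": [1, 1, 2],
            "cm": [0.0, 10.0, 5.0],
            "scaffold": ["scaffold_1", "scaffold_1", "scaffold_2"],
            "bp": [0, 2_000_000, 1_000_000],
        },
        index=["L1", "L2", "L3"],
    )
    return MarkerMap(df)


class TestScan:
    def test_hand_enumeration_two_biallelic_loci(self):
        g = make_matrix([
            [(150, 150), (200, 200)],
            [(150, 152), (200, 202)],
            [(152, 152), (202, 202)],
            [(150, 150), (200, 202)],
        ])
        recs = ldm.ld_scan(g, marker_map=None, maf_min=0.0)
        assert len(recs) == 4          # 2 alleles x 2 alleles
        uniq = [r for r in recs if r.unique]
        assert len(uniq) == 1          # complements collapse for counting
        r2s = {round(r.r2, 9) for r in recs}
        assert len(r2s) == 1           # all four are the same comparison

    def test_cross_linkage_group_is_inter(self):
        g = make_matrix([
            [(150, 150), (200, 202)],
            [(150, 152), (200, 200)],
            [(152, 152), (202, 202)],
        ])
        g = make_matrix([[tuple(g.calls[i, j]) for j in range(2)]
                         for i in range(3)], loci=["L1", "L3"])
        recs = ldm.ld_scan(g, toy_map(), maf_min=0.0)
        assert all(r.intra_chromosome is False for r in recs)
        assert all(math.isnan(r.dist_cm) for r in recs)

    def test_distances_annotated_within_group(self):
        g = make_matrix([
            [(150, 150), (200, 202)],
            [(150, 152), (200, 200)],
            [(152, 152), (202, 202)],
        ], loci=["L1", "L2"])
        recs = ldm.ld_scan(g, toy_map(), maf_min=0.0)
        assert all(r.intra_chromosome for r in recs)
        assert all(r.dist_cm == 10.0 for r in recs)
        assert all(r.dist_kbp == 2000.0 for r in recs)

    def test_maf_boundary_inclusive(self):
        g = make_matrix([[(150, 150)], [(152, 152)], [(150, 152)],
                         [(150, 152)]])
        from ssrpop.genodata import recode_rare_alleles, allele_frequencies
        out = recode_rare_alleles(g, 0.5)
        aft = allele_frequencies(out)
        assert set(aft.freqs["L1"]) == {150, 152}   # both at exactly 0.5 kept


class TestSummaryAndDecay:
    def _rec(self, r2, intra, dist=1.0, lg=1):
        return ldm.LDRecord("A", 1, "B", 1, r2=r2, D=0.0, n=10,
                            intra_chromosome=intra, linkage_group_a=lg,
                            linkage_group_b=lg if intra else lg + 1,
                            dist_cm=dist, dist_kbp=dist)

    def test_summary_hand_count(self):
        recs = ([self._rec(0.5, True), self._rec(0.2, True)]
                + [self._rec(0.05, True)] * 2
                + [self._rec(0.05, False)] * 6)
        s = ldm.ld_summary(recs, 0.1)
        assert s.total == 10
        assert s.intra_count == 4
        assert s.intra_pct_above == pytest.approx(50.0)
        assert s.inter_count == 6
        assert s.inter_pct_above == 0.0

    def test_summary_threshold_edges(self):
        recs = [self._rec(0.05, True), self._rec(0.06, False)]
        s0 = ldm.ld_summary(recs, 0.1)
        assert s0.intra_pct_above == 0.0 and s0.inter_pct_above == 0.0
        s1 = ldm.ld_summary(recs, 0.0)
        assert s1.intra_pct_above == 100.0 and s1.inter_pct_above == 100.0

    def test_decay_closed_form(self):
        # bin means exactly on r2 = 0.5 - 0.1 ln d  ->  d* at 0.1 is e^4
        dists = [1.0, 5.0, 20.0, 40.0]
        recs = [self._rec(0.5 - 0.1 * math.log(d), True, dist=d) for d in dists]
        fit = ldm.decay_fit(recs, metric="cm", n_bins=4)
        assert fit.intercept == pytest.approx(0.5, abs=1e-9)
        assert fit.slope == pytest.approx(-0.1, abs=1e-9)
        assert fit.d_star == pytest.approx(math.exp(4.0), rel=1e-9)

    def test_constant_r2_is_no_decay(self):
        recs = [self._rec(0.3, True, dist=d) for d in (1, 2, 5, 10, 20, 50)]
        fit = ldm.decay_fit(recs, metric="cm")
        assert fit.d_star is ldm.NO_DECAY

    def test_too_few_records_errors(self):
        with pytest.raises(ValueError):
            ldm.decay_fit([self._rec(0.5, True)], n_bins=4)

    def test_per_linkage_group_hand_built(self):
        recs = []
        for lg in range(1, 9):
            hi = 2 if lg == 1 else 0
            recs += [self._rec(0.5, True, lg=lg) for _ in range(hi)]
            recs += [self._rec(0.01, True, lg=lg) for _ in range(2)]
        props = ldm.per_linkage_group(recs, 0.1)
        assert props[1] == pytest.approx(0.5)
        assert (props.drop(1) == 0).all()

    def test_per_linkage_group_empty_is_nan(self):
        props = ldm.per_linkage_group([self._rec(0.5, True, lg=1)], 0.1)
        assert math.isnan(props[2])


def two_group_map():
    """Packaged map restricted to linkage groups 1-2 (keeps the scans fast
    while retaining dozens of intra-chromosome pairs)."""
    from ssrpop.genodata import load_packaged_marker_map
    mm = load_packaged_marker_map()
    keep = mm.table["linkage_group"].isin([1, 2])
    return MarkerMap(mm.table[keep])


def test_forward_simulated_decay_matches_dense_oracle():
    """4-bin log-fit crossing distance agrees within a factor of two with a
    dense-bin empirical crossing on the same records."""
    mm = two_group_map()
    g, truth = sd.simulate_ld_panel(n_founders=4, N=120, generations=4,
                                    marker_map=mm, seed=3)
    recs = [r for r in ldm.ld_scan(g, mm, maf_min=0.05)
            if r.unique]
    fit = ldm.decay_fit(recs, metric="cm")
    # dense-bin oracle: 20 bins, first downward crossing of 0.1
    pts = sorted((r.dist_cm, r.r2) for r in recs
                 if r.intra_chromosome and np.isfinite(r.dist_cm)
                 and r.dist_cm > 0 and np.isfinite(r.r2))
    chunks = np.array_split(np.array(pts), 20)
    d = np.array([c[:, 0].mean() for c in chunks])
    m = np.array([c[:, 1].mean() for c in chunks])
    oracle = None
    for i in range(len(d) - 1):
        if m[i] >= 0.1 >= m[i + 1]:
            frac = (m[i] - 0.1) / (m[i] - m[i + 1])
            oracle = d[i] + frac * (d[i + 1] - d[i])
            break
    assert fit.d_star is not None and oracle is not None
    assert 0.5 <= fit.d_star / oracle <= 2.0


def test_nearest_bin_exceeds_farthest_bin_under_recombination():
    """With recombination active, close pairs retain more LD than far pairs."""
    wins = 0
    mm = two_group_map()
    for seed in range(10):
        g, truth = sd.simulate_ld_panel(n_founders=6, N=60, generations=6,
                                        marker_map=mm, seed=50 + seed)
        recs = [r for r in ldm.ld_scan(g, mm, maf_min=0.05)
                if r.unique]
        fit = ldm.decay_fit(recs, metric="cm")
        if fit.bins["mean_r2"].iloc[0] >= fit.bins["mean_r2"].iloc[-1]:
            wins += 1
    assert wins >= 9
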