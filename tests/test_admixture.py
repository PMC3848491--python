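"""Admixture-model MCMC, Delta-K model choice, alignment and assignment."""

import numpy as np
import pytest
from scipy.special import gammaln

from ssrpop import admixture as ax
from ssrpop import genodata as gd
from ssrpop import synthetic_data as sd


def fake_run(K, lnpd):
    return ax.StructureRun(
        K=K, Q=np.zeros((0, K)), P=[], lnPD=lnpd, alpha=np.nan, F_k=None,
        seed=None, burn_in=0, mcmc_len=0, individuals=[], loci=[], model="n/a")


def dirichlet_multinomial_marginal(g):
    """Closed-form marginal likelihood of pooled counts under a flat
    Dirichlet prior per locus (the K=1 independent-model marginal)."""
    lm = 0.0
    for j in range(g.n_loci):
        col = g.calls[:, j, :]
        obs = col[col[:, 0] != gd.MISSING].ravel()
        _, cnt = np.unique(obs, return_counts=True)
        A, n = len(cnt), cnt.sum()
        lm += gammaln(A) - gammaln(n + A) + np.sum(gammaln(cnt + 1.0))
    return float(lm)


@pytest.fixture(scope="module")
def separated():
    """Two populations fixed for different alleles at 10 loci."""
    fx = sd.fixture_panels(seed=0)
    g = fx["two_fixed_pops"]
    labels = np.array([0] * 12 + [1] * 12)
    return g, labels


class TestRunAdmixture:
    def test_k1_degeneracy(self):
        g, _ = sd.simulate_structured(K=1, n_per_pop=20, n_loci=5,
                                      alleles_per_locus=4, seed=5)
        run = ax.run_admixture(g, K=1, model="independent",
                               burn_in=500, mcmc_len=4000, thin=4, seed=6)
        assert np.allclose(run.Q, 1.0)
        # mean - var/2 estimate sits near (above) the exact marginal
        lm = dirichlet_multinomial_marginal(g)
        assert abs(run.lnPD - lm) <= 0.15 * abs(lm)

    def test_fixed_populations_fully_resolved(self, separated):
        g, labels = separated
        run = ax.run_admixture(g, K=2, burn_in=300, mcmc_len=1500, thin=5, seed=7)
        assert run.Q.max(axis=1).min() >= 0.99
        # clusters coincide with the true populations
        lab = run.Q.argmax(axis=1)
        assert len(set(lab[labels == 0])) == 1
        assert len(set(lab[labels == 1])) == 1

    def test_label_symmetry_across_seeds(self, separated):
        g, _ = separated
        r1 = ax.run_admixture(g, K=2, burn_in=300, mcmc_len=1500, thin=5, seed=8)
        r2 = ax.run_admixture(g, K=2, burn_in=300, mcmc_len=1500, thin=5, seed=9)
        res = ax.align_runs([r1.Q, r2.Q])
        assert res.G[0, 1] >= 0.95

    def test_invalid_parameters(self, separated):
        g, _ = separated
        with pytest.raises(ValueError):
            ax.run_admixture(g, K=0)
        with pytest.raises(ValueError):
            ax.run_admixture(g, K=2, burn_in=-1)

    def test_correlated_model_recovers_drift_and_memberships(self):
        g, truth = sd.simulate_structured(
            K=3, n_per_pop=40, n_loci=20, alleles_per_locus=6, F_k=0.25, seed=33)
        run = ax.run_admixture(g, K=3, model="correlated",
                               burn_in=600, mcmc_len=2500, thin=5, seed=34)
        res = ax.align_runs([truth.admixture, run.Q])
        mae = np.abs(res.aligned[1] - truth.admixture).mean()
        assert mae <= 0.1
        assert run.F_k is not None and np.all(run.F_k < 0.6)


class TestEvanno:
    def test_hand_arithmetic(self):
        # mean lnPD -100, -50, -45, -44 with sd 1 at every K
        a = 1 / np.sqrt(2)  # two repeats mean +/- a gives sd 1
        runs = []
        for K, m in zip(range(1, 5), [-100.0, -50.0, -45.0, -44.0]):
            runs += [fake_run(K, m - a), fake_run(K, m + a)]
        ev = ax.evanno(runs)
        assert ev.table.loc[2, "deltaK"] == pytest.approx(45.0)
        assert ev.table.loc[3, "deltaK"] == pytest.approx(4.0)
        assert ev.best_k == 2

    def test_linear_lnpd_gives_zero_second_difference(self):
        runs = []
        for K in range(1, 5):
            runs += [fake_run(K, -100.0 + 10 * K + d) for d in (-0.5, 0.5)]
        ev = ax.evanno(runs)
        assert np.allclose(ev.table["Lsecond"].dropna(), 0.0, atol=1e-9)

    def test_no_interior_k_errors(self):
        runs = [fake_run(K, -10.0 * K + d) for K in (1, 2) for d in (0, 1)]
        with pytest.raises(ValueError, match="consecutive"):
            ax.evanno(runs)

    def test_zero_sd_flagged_undefined(self):
        runs = []
        for K, m in zip(range(1, 4), [-100.0, -50.0, -45.0]):
            sd_off = 0.0 if K == 2 else 0.5
            runs += [fake_run(K, m - sd_off), fake_run(K, m + sd_off)]
        ev = ax.evanno(runs)
        assert np.isnan(ev.table.loc[2, "deltaK"])


class TestAlignAssign:
    def test_permuted_copy_recovered_exactly(self):
        rng = np.random.default_rng(12)
        q = rng.dirichlet(np.ones(4), size=30)
        res = ax.align_runs([q, q[:, [2, 0, 3, 1]]])
        assert res.G[0, 1] == pytest.approx(1.0)
        assert np.allclose(res.aligned[1], q)

    def test_k1_trivially_aligned(self):
        q = np.ones((10, 1))
        res = ax.align_runs([q, q.copy()])
        assert res.G[0, 1] == 1.0

    def test_hungarian_matches_exhaustive(self):
        rng = np.random.default_rng(13)
        q1 = rng.dirichlet(np.ones(5), size=40)
        q2 = np.clip(q1 + rng.normal(0, 0.02, q1.shape), 1e-6, None)
        q2 /= q2.sum(1, keepdims=True)
        q2 = q2[:, [4, 2, 0, 1, 3]]
        pe, ge = ax._best_permutation(q1, q2, "exhaustive")
        phg, gh = ax._best_permutation(q1, q2, "hungarian")
        assert pe == phg and ge == pytest.approx(gh)

    def test_assignment_threshold(self):
        q = np.array([[0.85, 0.15], [0.6, 0.4]])
        res = ax.assign(q, 0.8, individuals=["a", "b"])
        assert res.table.loc["a", "label"] == "pop1"
        assert res.table.loc["b", "label"] == ax.UNSTRUCTURED
        res0 = ax.assign(q, 0.0, individuals=["a", "b"])
        assert (res0.table["label"] != ax.UNSTRUCTURED).all()

    def test_assignment_requires_simplex_rows(self):
        with pytest.raises(ValueError):
            ax.assign(np.array([[0.5, 0.1]]))


class TestDrivers:
    def test_homogeneous_panel_reports_no_substructure(self):
        g, _ = sd.simulate_structured(K=1, n_per_pop=20, n_loci=5,
                                      alleles_per_locus=4, seed=5)
        res = ax.full_structure_analysis(
            g, k_range=range(1, 4), repeats=2, seed=9,
            burn_in=200, mcmc_len=800, thin=4)
        assert res.best_k == 1
        assert "no substructure" in res.note
        assert (res.assignment.table["label"] == "pop1").all()

    def test_unstructured_individuals_excluded_from_nested(self, separated):
        g, _ = separated
        # hand-built assignment: S0001 unstructured, the rest split in two
        import pandas as pd
        labels = ["UNSTRUCTURED"] + ["pop1"] * 11 + ["pop2"] * 12
        assignment = ax.Assignment(
            table=pd.DataFrame({"label": labels, "q_max": 1.0},
                               index=g.individuals),
            threshold=0.8)
        nested = ax.nested_structure(
            g, assignment, k_range=range(1, 4), repeats=2, seed=10,
            min_group_size=10, burn_in=100, mcmc_len=400, thin=4)
        seen = {i for sub in nested.values() for i in sub.assignment.table.index}
        assert "A01" not in seen
        assert seen == set(g.individuals) - {"A01"}

    def test_small_groups_skipped_with_note(self, separated):
        g, _ = separated
        import pandas as pd
        labels = ["pop1"] * 4 + ["pop2"] * 20
        assignment = ax.Assignment(
            table=pd.DataFrame({"label": labels, "q_max": 1.0},
                               index=g.individuals),
            threshold=0.8)
        nested = ax.nested_structure(
            g, assignment, k_range=range(1, 4), repeats=2, seed=11,
            min_group_size=10, burn_in=100, mcmc_len=400, thin=4)
        assert "skipped" in nested["pop1"].note
        assert nested["pop1"].best_k == 1


def test_nested_driver_recovers_two_then_four_groups():
    """Hierarchical 2x(2) design: first scan finds the 2 top populations,
    nested scans split each into its 2 subpopulations."""
    g, truth = sd.simulate_hierarchical(n_per_sub=25, n_loci=20, seed=2)
    first = ax.full_structure_analysis(
        g, k_range=range(1, 5), repeats=2, seed=7,
        burn_in=250, mcmc_len=1000, thin=5)
    assert first.best_k == 2
    nested = ax.nested_structure(
        g, first.assignment, k_range=range(1, 5), repeats=2, seed=8,
        burn_in=250, mcmc_len=1000, thin=5)
    assert len(nested) == 2
    total_subgroups = 0
    for label, sub in nested.items():
        assert sub.best_k == 2
        total_subgroups += sub.best_k
        assert sub.assignment.table["q_max"].mean() >= 0.8
    assert total_subgroups == 4
    # second-level groups refine the truth labels: members of one nested
    # group should come from a single true subpopulation (modulo the few
    # unassigned)
    truth_of = dict(zip(g.individuals, truth.labels))
    for label, sub in nested.items():
        for lab2 in sub.assignment.labels():
            members = sub.assignment.members(lab2)
            majority = max(
                {truth_of[m] for m in members},
                key=lambda t: sum(truth_of[m] == t for m in members))
            frac = sum(truth_of[m] == majority for m in members) / len(members)
            assert frac >= 0.9
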