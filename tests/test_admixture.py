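import itertools

import numpy as np
import pandas as pd
import pytest

from germid import (
    GenotypeMatrix,
    align_runs,
    assign_unknowns,
    evanno_delta_k,
    fit_admixture,
    flag_mislabels,
    select_core_members,
    simulate_reference,
)
from germid.admixture import (
    HYBRID_LABEL,
    AdmixtureFit,
    AssignmentResult,
    RunEnsemble,
    _match_permutation,
)
from germid.simulate import SimConfig, SpeciesSpec, simulate_frequencies

from conftest import make_matrix, make_passport


def two_pop_panel(seed=0, n=50, L=150, F=0.3):
    rng = np.random.default_rng(seed)
    cfg = SimConfig(seed=seed, n_loci=L,
                    species=[SpeciesSpec("A", n, F), SpeciesSpec("B", n, F)])
    _, freqs = simulate_frequencies(cfg)
    calls = np.vstack(
        [rng.binomial(2, freqs["A"], size=(n, L)),
         rng.binomial(2, freqs["B"], size=(n, L))]
    ).astype(np.int8)
    return make_matrix(calls), np.array([0] * n + [1] * n), freqs


@pytest.fixture(scope="module")
def separated_fit():
    gm, truth, _ = two_pop_panel()
    fit = fit_admixture(gm, 2, burnin=300, reps=600, seed=11)
    return gm, truth, fit


class TestFitAdmixture:
    def test_k1_degenerate(self, rng):
        gm = make_matrix(rng.integers(0, 3, size=(10, 20)).astype(np.int8))
        fit = fit_admixture(gm, 1, burnin=10, reps=10, seed=0)
        assert np.array_equal(fit.Q, np.ones((10, 1)))

    def test_two_populations_separated(self, separated_fit):
        _, truth, fit = separated_fit
        hard = fit.Q.argmax(1)
        acc = max((hard == truth).mean(), (hard != truth).mean())
        assert acc >= 0.99

    def test_q_rows_sum_to_one(self, separated_fit):
        _, _, fit = separated_fit
        assert np.allclose(fit.Q.sum(axis=1), 1.0, atol=1e-9)
        assert ((fit.P >= 0) & (fit.P <= 1)).all()

    def test_loglik_trace_finite(self, separated_fit):
        _, _, fit = separated_fit
        assert np.isfinite(fit.loglik_trace).all()

    def test_monomorphic_panel_symmetric(self):
        # no information: the posterior over ancestry is symmetric, so the
        # panel-average Q settles near 1/K once the chain has mixed
        gm = make_matrix(np.zeros((8, 4), dtype=np.int8))
        fit = fit_admixture(gm, 2, burnin=500, reps=4000, seed=1)
        assert abs(fit.Q.mean(axis=0)[0] - 0.5) < 0.15

    def test_invalid_arguments(self, rng):
        gm = make_matrix(rng.integers(0, 3, size=(4, 5)).astype(np.int8))
        with pytest.raises(ValueError):
            fit_admixture(gm, 0, burnin=10, reps=10)
        with pytest.raises(ValueError):
            fit_admixture(gm, 2, burnin=10, reps=10, fixed_labels=[5, -1, -1, -1])


class TestAlignRuns:
    def make_fit(self, Q, K, seed=0):
        n = Q.shape[0]
        return AdmixtureFit(
            K, [f"s{i}" for i in range(n)], Q, np.full((K, 3), 0.5),
            np.zeros(5), -100.0, 1.0, seed, 10, 10,
        )

    def test_recovers_column_swap(self, rng):
        q = rng.dirichlet(np.ones(3), size=8)
        ens = RunEnsemble()
        ens.add(self.make_fit(q, 3))
        ens.add(self.make_fit(q[:, [2, 0, 1]], 3))
        out = align_runs(ens)
        assert np.allclose(out.runs[3][0].Q, out.runs[3][1].Q)

    def test_planted_permutations_recovered(self, rng):
        q = rng.dirichlet(np.ones(4), size=10)
        ens = RunEnsemble()
        ens.add(self.make_fit(q, 4))
        perms = []
        for _ in range(3):
            perm = rng.permutation(4)
            perms.append(perm)
            ens.add(self.make_fit(q[:, perm], 4))
        out = align_runs(ens)
        for fit in out.runs[4]:
            assert np.allclose(fit.Q, q)

    def test_matches_brute_force_assignment(self, rng):
        # Hungarian solution equals exhaustive best permutation
        q_ref = rng.dirichlet(np.ones(4), size=12)
        q_run = rng.dirichlet(np.ones(4), size=12)
        perm = _match_permutation(q_ref, q_run)
        best = max(
            itertools.permutations(range(4)),
            key=lambda p: (q_ref * q_run[:, p]).sum(),
        )
        assert (q_ref * q_run[:, perm]).sum() == pytest.approx(
            (q_ref * q_run[:, list(best)]).sum()
        )

    def test_idempotent(self, rng):
        q = rng.dirichlet(np.ones(3), size=8)
        ens = RunEnsemble()
        ens.add(self.make_fit(q, 3))
        ens.add(self.make_fit(q[:, [1, 2, 0]], 3))
        once = align_runs(ens)
        twice = align_runs(once)
        for a, b in zip(once.runs[3], twice.runs[3]):
            assert np.allclose(a.Q, b.Q)


class TestEvannoDeltaK:
    def ensemble_from_logliks(self, ll_by_k):
        ens = RunEnsemble()
        for K, values in ll_by_k.items():
            for i, v in enumerate(values):
                ens.add(
                    AdmixtureFit(
                        K, ["a", "b"], np.full((2, K), 1.0 / K),
                        np.full((K, 2), 0.5), np.zeros(3), float(v), 1.0, i, 5, 5,
                    )
                )
        return ens

    def test_hand_arithmetic(self):
        # mean L = (-1000, -800, -790, -788); sd(L(2)) = 5
        ll = {
            1: [-1000.0, -1000.0],
            2: [-805.0, -795.0],   # mean -800, sd ~7.07
            3: [-790.0, -790.0],
            4: [-788.0, -788.0],
        }
        tab = self.ensemble_from_logliks(ll)
        delta = evanno_delta_k(tab)
        sd2 = np.std([-805, -795], ddof=1)
        assert delta.loc[2, "second_difference"] == pytest.approx(190.0)
        assert delta.loc[2, "delta_k"] == pytest.approx(190.0 / sd2)
        assert np.isnan(delta.loc[1, "delta_k"])

    def test_flat_likelihood(self):
        ll = {K: [-500.0 + 0.01 * i for i in range(3)] for K in (1, 2, 3)}
        delta = evanno_delta_k(self.ensemble_from_logliks(ll))
        assert delta.loc[2, "second_difference"] == pytest.approx(0.0, abs=1e-9)

    def test_zero_sd_reports_infinite(self):
        ll = {1: [-900.0, -900.0], 2: [-800.0, -800.0], 3: [-795.0, -795.0]}
        delta = evanno_delta_k(self.ensemble_from_logliks(ll))
        assert np.isinf(delta.loc[2, "delta_k"])

    def test_needs_consecutive_k(self):
        ll = {1: [-900.0, -899.0], 3: [-800.0, -801.0]}
        with pytest.raises(ValueError):
            evanno_delta_k(self.ensemble_from_logliks(ll))

    def test_two_population_scan_prefers_k2(self):
        gm, _, _ = two_pop_panel(seed=4, n=40, L=120)
        rng = np.random.default_rng(99)
        ens = RunEnsemble()
        for K in (1, 2, 3, 4):
            for _ in range(3):
                ens.add(fit_admixture(gm, K, burnin=150, reps=300,
                                      seed=int(rng.integers(2**31 - 1))))
        delta = evanno_delta_k(align_runs(ens))
        interior = delta["delta_k"].dropna()
        assert int(interior.idxmax()) == 2


class TestHierarchical:
    def test_homogeneous_population_does_not_split(self, rng):
        from germid.admixture import hierarchical_structure

        p = rng.uniform(0.1, 0.5, 120)
        calls = rng.binomial(2, p, size=(40, 120)).astype(np.int8)
        gm = make_matrix(calls)
        tree = hierarchical_structure(gm, max_depth=1, runs=3,
                                      k_range=range(1, 4), seed=1,
                                      burnin=150, reps=300, min_size=12)
        assert tree.k_chosen == 1 and tree.children == []

    def test_planted_two_level_hierarchy_recovered(self):
        # two macro-populations; the first splits into two close sub-pops
        import collections

        from germid.admixture import hierarchical_structure

        rng = np.random.default_rng(1)
        cfg = SimConfig(seed=1, n_loci=150, species=[SpeciesSpec("X", 5, 0.2)])
        anc, _ = simulate_frequencies(cfg)

        def bn(p, F):
            return rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F)

        m1, m2 = bn(anc, 0.3), bn(anc, 0.3)
        a, b = bn(m1, 0.12), bn(m1, 0.12)
        calls = np.vstack(
            [rng.binomial(2, a, size=(25, 150)),
             rng.binomial(2, b, size=(25, 150)),
             rng.binomial(2, m2, size=(30, 150))]
        ).astype(np.int8)
        gm = make_matrix(calls)
        tree = hierarchical_structure(gm, max_depth=2, runs=2,
                                      k_range=range(1, 5), seed=8,
                                      burnin=150, reps=300, min_size=12)
        assert tree.k_chosen == 2
        leaves = tree.leaves
        assert len(leaves) == 3
        truth = ["A"] * 25 + ["B"] * 25 + ["C"] * 30
        correct = 0
        for leaf in leaves:
            members = [truth[int(s[1:])] for s in leaf.sample_ids]
            correct += collections.Counter(members).most_common(1)[0][1]
        assert correct / len(truth) >= 0.95


class TestCoreMembers:
    def make_fit(self, Q):
        n, K = Q.shape
        return AdmixtureFit(K, [f"s{i}" for i in range(n)], Q,
                            np.full((K, 2), 0.5), np.zeros(3), -1.0, 0.1, 0, 5, 5)

    def test_threshold_rule(self):
        fit = self.make_fit(np.array([[0.95, 0.05], [0.6, 0.4], [0.2, 0.8]]))
        core = select_core_members(fit, 0.80)
        assert core[0] == ["s0"]
        assert core[1] == []
        assert core["admixed"] == ["s1", "s2"]

    def test_strictly_above(self):
        fit = self.make_fit(np.array([[0.80, 0.20]]))
        core = select_core_members(fit, 0.80)
        assert core["admixed"] == ["s0"]

    def test_planted_admixture_excluded(self):
        rng = np.random.default_rng(0)
        pure = np.zeros((90, 2))
        pure[:45, 0] = rng.uniform(0.9, 1.0, 45)
        pure[:45, 1] = 1 - pure[:45, 0]
        pure[45:, 1] = rng.uniform(0.9, 1.0, 45)
        pure[45:, 0] = 1 - pure[45:, 1]
        hybrids = np.tile([0.5, 0.5], (10, 1))
        fit = self.make_fit(np.vstack([pure, hybrids]))
        core = select_core_members(fit)
        kept = set(core[0]) | set(core[1])
        assert len(kept) == 90
        assert all(f"s{i}" in core["admixed"] for i in range(90, 100))


class TestSimulateReference:
    def test_panel_shape_and_labels(self):
        freqs = {"A": np.full(30, 0.2), "B": np.full(30, 0.8)}
        gm, labels = simulate_reference(freqs, n_per_species=50, seed=1)
        assert gm.shape == (100, 30)
        assert labels.count("A") == labels.count("B") == 50

    def test_zero_frequencies(self):
        gm, _ = simulate_reference({"A": np.zeros(10)}, n_per_species=5, seed=0)
        assert (gm.calls == 0).all()

    def test_frequency_recovery(self, rng):
        p = rng.uniform(0.1, 0.9, 100)
        gm, _ = simulate_reference({"A": p}, n_per_species=400, seed=7)
        p_hat = gm.calls.mean(axis=0) / 2
        se = np.sqrt(p * (1 - p) / (2 * 400))
        assert (np.abs(p_hat - p) < 4 * se).mean() > 0.98


@pytest.fixture(scope="module")
def reference():
    cfg = SimConfig(seed=21, n_loci=150,
                    species=[SpeciesSpec("A", 10, 0.25),
                             SpeciesSpec("B", 10, 0.25)])
    _, freqs = simulate_frequencies(cfg)
    ref_gm, labels = simulate_reference(freqs, n_per_species=60, seed=22)
    return ref_gm, labels, freqs


class TestAssignment:
    def test_pure_query_assigned(self, reference):
        ref_gm, labels, freqs = reference
        rng = np.random.default_rng(5)
        q = make_matrix(rng.binomial(2, freqs["A"], size=(3, 150)).astype(np.int8),
                        prefix="q")
        q.locus_ids = list(ref_gm.locus_ids)
        res = assign_unknowns(ref_gm, labels, q, runs=2, burnin=150, reps=300,
                              seed=9)
        assert (res.calls["inferred"] == "A").all()
        assert (res.calls["top_q"] > 0.8).all()

    def test_f1_hybrid_called(self, reference):
        ref_gm, labels, freqs = reference
        rng = np.random.default_rng(6)
        f1 = (rng.binomial(1, freqs["A"], size=(2, 150))
              + rng.binomial(1, freqs["B"], size=(2, 150))).astype(np.int8)
        q = make_matrix(f1, prefix="q")
        q.locus_ids = list(ref_gm.locus_ids)
        res = assign_unknowns(ref_gm, labels, q, runs=2, burnin=150, reps=300,
                              seed=10)
        assert all(HYBRID_LABEL in v for v in res.calls["inferred"])
        assert {"A", "B"} == set(
            res.calls.iloc[0][["top_species", "second_species"]]
        )

    def test_reference_individual_recovered(self, reference):
        ref_gm, labels, _ = reference
        q = ref_gm.subset(samples=[0])
        q.sample_ids = ["query0"]
        res = assign_unknowns(ref_gm, labels, q, runs=2, burnin=150, reps=300,
                              seed=11)
        assert res.calls.iloc[0]["inferred"] == labels[0]
        assert res.calls.iloc[0]["top_q"] > 0.9

    def test_mismatched_loci_rejected(self, reference):
        ref_gm, labels, _ = reference
        q = make_matrix(np.zeros((1, 3), dtype=np.int8), prefix="q")
        with pytest.raises(ValueError, match="loci"):
            assign_unknowns(ref_gm, labels, q, runs=1, burnin=10, reps=10)

    def test_consistency_with_more_loci(self, reference):
        # mean true-species Q non-decreasing (on average) as loci grow
        ref_gm, labels, freqs = reference
        rng = np.random.default_rng(12)
        q_full = make_matrix(
            rng.binomial(2, freqs["A"], size=(4, 150)).astype(np.int8), prefix="q"
        )
        q_full.locus_ids = list(ref_gm.locus_ids)
        means = []
        for n_loci in (30, 150):
            cols = list(range(n_loci))
            res = assign_unknowns(
                ref_gm.subset(loci=cols), labels, q_full.subset(loci=cols),
                runs=2, burnin=150, reps=300, seed=13,
            )
            means.append(res.mean_q[:, res.species.index("A")].mean())
        assert means[1] >= means[0] - 0.05


class TestFlagMislabels:
    def make_assignment(self, rows):
        ids = [r[0] for r in rows]
        calls = pd.DataFrame(
            [
                {
                    "sample_id": sid,
                    "inferred": inf,
                    "inferred_species": inf_sp,
                    "top_species": inf_sp if inf_sp != HYBRID_LABEL else "A",
                    "top_q": q,
                    "second_species": "B",
                    "second_q": 1 - q,
                }
                for sid, inf, inf_sp, q in rows
            ]
        ).set_index("sample_id", drop=False)
        return AssignmentResult(ids, ["A", "B"], np.zeros((len(ids), 2)),
                                calls, 0.8)

    def test_rules(self):
        res = self.make_assignment(
            [
                ("c1", "B", "B", 0.97),              # recorded A -> mislabel
                ("c2", "A", "A", 0.95),              # agrees -> ok
                ("c3", "A", "A", 0.99),              # recorded unknown -> clarification
                ("c4", HYBRID_LABEL, HYBRID_LABEL, 0.6),  # recorded A -> admixed
            ]
        )
        pp = make_passport(
            ["c1", "c2", "c3", "c4"], species=["A", "A", "unknown", "A"]
        )
        flags = flag_mislabels(res, pp).set_index("sample_id")
        assert flags.loc["c1", "status"] == "mislabel"
        assert flags.loc["c2", "status"] == "ok"
        assert flags.loc["c3", "status"] == "clarification"
        assert flags.loc["c4", "status"] == "admixed"
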