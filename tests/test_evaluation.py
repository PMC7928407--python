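"""Pedigree/genomic relationship machinery and the MME solver, validated
against independent dense-algebra oracles."""

import numpy as np
import pandas as pd
import pytest

from dairyopt.evaluation import (
    ConvergenceError,
    ModelSpec,
    PedigreeError,
    TrainingPopulation,
    build_A_inverse,
    build_G,
    build_H_inverse,
    inbreeding,
    pedigree_A22,
    pedigree_A22_flow,
    solve_mme,
    tune_and_blend_G,
)
from dairyopt.fixtures import (
    dense_mme_solution,
    make_toy_mixed_model,
    make_toy_pedigree,
    tabular_A,
)

# 5-animal toy pedigree: 2 founders, 3 descendants incl. full sibs + their cross
SIRE5 = np.array([-1, -1, 0, 0, 2])
DAM5 = np.array([-1, -1, 1, 1, 3])


class TestAInverse:
    def test_five_animal_pedigree_matches_dense_inverse(self):
        A = tabular_A(SIRE5, DAM5)
        a_inv, _ = build_A_inverse(SIRE5, DAM5)
        np.testing.assert_allclose(a_inv.toarray(), np.linalg.inv(A), atol=1e-10)

    def test_founders_only_identity(self):
        a_inv, F = build_A_inverse(np.full(4, -1), np.full(4, -1))
        np.testing.assert_allclose(a_inv.toarray(), np.eye(4), atol=1e-12)
        assert np.all(F == 0)

    def test_inbreeding_matches_tabular_recursion(self):
        # chain of full-sib matings, depth 3
        sire = np.array([-1, -1, 0, 0, 2, 2, 4, 4, 6])
        dam = np.array([-1, -1, 1, 1, 3, 3, 5, 5, 7])
        A = tabular_A(sire, dam)
        F = inbreeding(sire, dam)
        np.testing.assert_allclose(F, np.diag(A) - 1.0, atol=1e-12)
        assert F[-1] > 0.3  # repeated full-sib mating accumulates inbreeding

    def test_random_toy_pedigrees_match_oracle(self):
        for seed in range(5):
            toy = make_toy_pedigree(depth=3, seed=seed)
            a_inv, _ = build_A_inverse(toy.sire, toy.dam)
            np.testing.assert_allclose(
                a_inv.toarray(), np.linalg.inv(toy.A), atol=1e-8
            )

    def test_unordered_pedigree_raises(self):
        with pytest.raises(PedigreeError):
            build_A_inverse(np.array([1, -1]), np.array([-1, -1]))

    def test_female_sire_raises(self):
        with pytest.raises(PedigreeError):
            build_A_inverse(
                np.array([-1, -1, 0]), np.array([-1, -1, 1]),
                sex=np.array([0, 0, 1]),
            )


class TestA22:
    def test_splu_and_flow_methods_agree_with_dense(self):
        toy = make_toy_pedigree(depth=3, seed=4)
        idx = np.array([2, 5, len(toy.sire) - 1])
        a_inv, F = build_A_inverse(toy.sire, toy.dam)
        expected = toy.A[np.ix_(idx, idx)]
        np.testing.assert_allclose(pedigree_A22(a_inv, idx), expected, atol=1e-9)
        np.testing.assert_allclose(
            pedigree_A22_flow(toy.sire, toy.dam, F, idx), expected, atol=1e-9
        )


class TestG:
    def _panel(self, n=40, m=400, seed=0):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.1, 0.9, m)
        dos = rng.binomial(2, p, size=(n, m)).astype(float)
        return dos, p

    def test_unrelated_diagonal_near_one_offdiag_near_zero(self):
        dos, p = self._panel(n=60, m=2000)
        G = build_G(dos, p)
        assert G.diagonal().mean() == pytest.approx(1.0, abs=0.05)
        off = G[~np.eye(60, dtype=bool)]
        assert abs(off.mean()) < 0.02

    def test_identical_twins_offdiagonal_equals_diagonal(self):
        dos, p = self._panel(n=10)
        dos[1] = dos[0]
        G = build_G(dos, p)
        assert G[0, 1] == pytest.approx(G[0, 0])

    def test_monomorphic_panel_raises(self):
        with pytest.raises(ValueError):
            build_G(np.zeros((5, 10)), np.zeros(10))

    def test_tuning_matches_a22_moments(self):
        dos, p = self._panel(n=20)
        G = build_G(dos, p)
        A22 = np.eye(20) * 1.02 + 0.05
        Gt = tune_and_blend_G(G, A22, blend=0.05)
        off = ~np.eye(20, dtype=bool)
        assert Gt.diagonal().mean() == pytest.approx(A22.diagonal().mean(), abs=0.01)
        assert Gt[off].mean() == pytest.approx(A22[off].mean(), abs=0.01)
        np.linalg.cholesky(Gt)  # must be PD


class TestHInverse:
    def test_empty_genotyped_set_reduces_to_pedigree(self):
        a_inv, _ = build_A_inverse(SIRE5, DAM5)
        h_inv = build_H_inverse(a_inv, np.empty((0, 0)), np.array([], dtype=int))
        assert (h_inv != a_inv).nnz == 0

    def test_g_equal_a22_cancels_exactly(self):
        toy = make_toy_pedigree(depth=2, seed=1)
        a_inv, _ = build_A_inverse(toy.sire, toy.dam)
        idx = np.array([0, 3, len(toy.sire) - 1])
        a22 = toy.A[np.ix_(idx, idx)]
        h_inv = build_H_inverse(a_inv, a22.copy(), idx, A22=a22)
        np.testing.assert_allclose(h_inv.toarray(), a_inv.toarray(), atol=1e-9)

    def test_joint_dense_oracle(self):
        """EBVs from H^-1 match a brute-force dense joint H computation."""
        rng = np.random.default_rng(8)
        toy = make_toy_mixed_model(n_animals=8, n_records=16, seed=5)
        idx = np.array([2, 5, 7])
        m = 40
        p = rng.uniform(0.2, 0.8, m)
        dos = rng.binomial(2, p, size=(3, m)).astype(float)
        a22 = toy.A[np.ix_(idx, idx)]
        G = tune_and_blend_G(build_G(dos, p), a22)

        # dense oracle: H assembled directly, then dense MME
        H = toy.A.copy()
        H_inv_dense = np.linalg.inv(toy.A)
        delta = np.linalg.inv(G) - np.linalg.inv(a22)
        H_inv_dense[np.ix_(idx, idx)] += delta
        H = np.linalg.inv(H_inv_dense)
        oracle = dense_mme_solution(toy.records, H, **toy.sigma2)

        a_inv, _ = build_A_inverse(toy.sire, toy.dam)
        h_inv = build_H_inverse(a_inv, G, idx)
        res = solve_mme(toy.records, 8, h_inv, ModelSpec(), model="single-step")
        np.testing.assert_allclose(res.ebv, oracle, atol=1e-8)

    def test_singular_g_raises_with_hint(self):
        a_inv, _ = build_A_inverse(SIRE5, DAM5)
        G = np.ones((2, 2))  # duplicated genotypes, unblended
        with pytest.raises(np.linalg.LinAlgError, match="blend"):
            build_H_inverse(a_inv, G, np.array([3, 4]))


class TestSolveMme:
    def test_toy_dataset_matches_dense_oracle(self):
        toy = make_toy_mixed_model(n_animals=10, n_records=20, seed=0)
        a_inv, _ = build_A_inverse(toy.sire, toy.dam)
        res = solve_mme(toy.records, 10, a_inv, ModelSpec())
        np.testing.assert_allclose(res.ebv, toy.oracle_ebv, atol=1e-8)

    def test_no_phenotypes_prior_mean_zero(self):
        a_inv, _ = build_A_inverse(SIRE5, DAM5)
        res = solve_mme(pd.DataFrame(columns=["animal", "herd", "year", "y"]),
                        5, a_inv, ModelSpec())
        assert np.all(res.ebv == 0)

    def test_shrinkage_releases_with_more_records(self):
        """An animal's EBV moves toward its (high) record mean as its record
        count grows, against a background of mates holding the year mean."""
        n_animals = 6
        a_inv, _ = build_A_inverse(np.full(n_animals, -1), np.full(n_animals, -1))
        ebvs = []
        for n in (1, 2, 5, 10):
            rows = [{"animal": 0, "herd": 0, "year": 0, "y": 2.0}] * n
            rows += [{"animal": i, "herd": 0, "year": 0, "y": 0.0}
                     for i in range(1, n_animals)]
            res = solve_mme(pd.DataFrame(rows), n_animals, a_inv, ModelSpec())
            ebvs.append(res.ebv[0])
        assert all(b > a for a, b in zip(ebvs, ebvs[1:]))

    def test_weighted_collapse_equals_record_level(self):
        toy = make_toy_mixed_model(n_animals=10, n_records=30, seed=2)
        recs = toy.records.copy()
        # force repeated records in the same cell, then collapse
        recs.loc[:, "herd"] = 0
        recs.loc[:, "year"] = 0
        a_inv, _ = build_A_inverse(toy.sire, toy.dam)
        full = solve_mme(recs, 10, a_inv, ModelSpec())
        coll = (recs.groupby("animal")
                .agg(y=("y", "mean"), weight=("y", "size")).reset_index())
        coll["herd"] = 0
        coll["year"] = 0
        res = solve_mme(coll, 10, a_inv, ModelSpec())
        np.testing.assert_allclose(res.ebv, full.ebv, atol=1e-7)

    def test_reordering_invariance(self):
        toy = make_toy_mixed_model(n_animals=10, n_records=20, seed=7)
        a_inv, _ = build_A_inverse(toy.sire, toy.dam)
        base = solve_mme(toy.records, 10, a_inv, ModelSpec()).ebv
        shuffled = toy.records.sample(frac=1.0, random_state=1)
        again = solve_mme(shuffled, 10, a_inv, ModelSpec()).ebv
        np.testing.assert_allclose(base, again, atol=1e-7)

    def test_nonconvergence_raises(self):
        toy = make_toy_mixed_model(n_animals=10, n_records=20, seed=0)
        a_inv, _ = build_A_inverse(toy.sire, toy.dam)
        with pytest.raises(ConvergenceError):
            solve_mme(toy.records, 10, a_inv, ModelSpec(), max_iter=2)


class TestTrainingPopulation:
    def test_cap_drops_oldest_first(self):
        tp = TrainingPopulation(cap=25_000, ids=list(range(24_900)),
                                geno_years=[1] * 100 + [2] * 24_800)
        dropped = tp.update(range(30_000, 30_400), year=5)
        assert tp.size == 25_000
        assert len(dropped) == 300
        # all 100 oldest-genotyped go first, then earliest ids of year 2
        assert dropped[:100] == list(range(100))

    def test_phenotypes_untouched_by_design(self):
        tp = TrainingPopulation(cap=2, ids=[1, 2], geno_years=[1, 1])
        dropped = tp.update([3], year=2)
        assert dropped == [1]
        assert tp.ids == [2, 3]  # genotype list only; no phenotype store here
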