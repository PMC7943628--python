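"""Distances, trees, PCA and admixture: closed-form cases plus external oracles."""

import io

import numpy as np
import pytest

from snpanel.popgen import (
    DegenerateInputError,
    DistanceMatrix,
    ParameterError,
    UndefinedDistanceError,
    admixture_fit,
    align_q_to_truth,
    cv_error_over_k,
    distance_matrix,
    nj_tree,
    pair_distance,
    pca,
)
from snpanel.synthetic_data import PopulationModel, inject_duplicates, simulate_panel
from snpanel.variant_io import MISSING, GenotypeMatrix, to_dosage

from conftest import marker


def dosage_gm(dosage: np.ndarray, prefix: str = "a") -> GenotypeMatrix:
    n, loci = dosage.shape
    markers = [marker(i) for i in range(loci)]
    return GenotypeMatrix(
        [f"{prefix}{i + 1}" for i in range(n)], markers, dosage.astype(np.int8)
    )


class TestPairDistance:
    def test_published_scoring_example(self):
        # identical homs 0, het vs hom 0.5, opposite homs 1, het vs het 0.5
        x = np.array([0, 0, 0, 1])
        y = np.array([0, 1, 2, 1])
        d, n = pair_distance(x, y)
        assert n == 4
        assert d == pytest.approx((0 + 0.5 + 1 + 0.5) / 4)  # = 0.5

    def test_homozygous_identity_and_opposition(self):
        assert pair_distance(np.array([0]), np.array([0])) == (0.0, 1)
        assert pair_distance(np.array([0]), np.array([2])) == (1.0, 1)
        assert pair_distance(np.array([2]), np.array([0])) == (1.0, 1)

    def test_any_het_scores_half(self):
        for other in (0, 1, 2):
            d, _ = pair_distance(np.array([1]), np.array([other]))
            assert d == 0.5

    def test_missing_loci_excluded_from_denominator(self):
        x = np.array([0, MISSING, 2])
        y = np.array([0, 0, MISSING])
        d, n = pair_distance(x, y)
        assert (d, n) == (0.0, 1)

    def test_no_shared_loci_raises(self):
        with pytest.raises(UndefinedDistanceError):
            pair_distance(np.array([MISSING, 0]), np.array([0, MISSING]))


class TestDistanceMatrix:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(31)
        dosage = rng.integers(0, 3, size=(10, 20))
        dosage[rng.random(dosage.shape) < 0.1] = MISSING
        gm = dosage_gm(dosage)
        dm = distance_matrix(gm)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0.0)
        for i in range(10):
            for j in range(i + 1, 10):
                d, n = pair_distance(dosage[i], dosage[j])
                assert dm.values[i, j] == pytest.approx(d)
                assert dm.n_compared[i, j] == n

    def test_exact_duplicate_has_zero_distance(self, homozygous_gm):
        gm, _ = inject_duplicates(homozygous_gm, {"a2": 1}, error_rate=0.0)
        dm = distance_matrix(gm)
        i = gm.accession_index("a2")
        j = gm.accession_index("a2_dup1")
        assert dm.values[i, j] == 0.0
        assert dm.min_overlap == gm.n_loci

    def test_single_accession_rejected(self, homozygous_gm):
        solo = homozygous_gm.subset(["a1"])
        with pytest.raises(ParameterError):
            distance_matrix(solo)


class TestNeighborJoining:
    @staticmethod
    def dm(names, values):
        v = np.asarray(values, dtype=float)
        return DistanceMatrix(names, v, np.full(v.shape, 100, dtype=int))

    def test_three_taxon_exact_branches(self):
        # d(A,B)=2, d(A,C)=3, d(B,C)=4 -> branches 0.5, 1.5, 2.5
        dm = self.dm(["A", "B", "C"], [[0, 2, 3], [2, 0, 4], [3, 4, 0]])
        tree = nj_tree(dm)
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert lengths == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})

    def test_additive_distance_recovery(self):
        # distances generated from a known tree are recovered exactly
        # ((A:1,B:2):1.5,(C:0.5,D:3):1)
        names = ["A", "B", "C", "D"]
        d = {
            ("A", "B"): 3.0, ("A", "C"): 4.0, ("A", "D"): 6.5,
            ("B", "C"): 5.0, ("B", "D"): 7.5, ("C", "D"): 3.5,
        }
        v = np.zeros((4, 4))
        for (a, b), val in d.items():
            i, j = names.index(a), names.index(b)
            v[i, j] = v[j, i] = val
        tree = nj_tree(self.dm(names, v))
        paths = tree.path_length_matrix()
        for (a, b), val in d.items():
            assert paths.loc[a, b] == pytest.approx(val)

    def test_matches_external_implementation(self):
        import skbio

        rng = np.random.default_rng(41)
        dosage = rng.integers(0, 3, size=(8, 60))
        gm = dosage_gm(dosage)
        dm = distance_matrix(gm)
        tree = nj_tree(dm)
        ours = tree.path_length_matrix()

        sk_dm = skbio.DistanceMatrix(dm.values, ids=dm.accessions)
        sk_tree = skbio.tree.nj(sk_dm)
        for a in dm.accessions:
            for b in dm.accessions:
                if a == b:
                    continue
                theirs = sk_tree.find(a).distance(sk_tree.find(b))
                assert ours.loc[a, b] == pytest.approx(theirs, abs=1e-8)

    def test_leaf_set_and_newick_parse(self):
        import dendropy

        rng = np.random.default_rng(43)
        gm = dosage_gm(rng.integers(0, 3, size=(6, 40)))
        tree = nj_tree(distance_matrix(gm))
        newick = tree.to_newick()
        parsed = dendropy.Tree.get(data=newick, schema="newick")
        assert {t.label for t in parsed.taxon_namespace} == set(gm.accessions)

    def test_label_permutation_gives_same_path_lengths(self):
        rng = np.random.default_rng(47)
        dosage = rng.integers(0, 3, size=(7, 50))
        gm1 = dosage_gm(dosage)
        perm = rng.permutation(7)
        gm2 = GenotypeMatrix(
            [gm1.accessions[k] for k in perm], list(gm1.markers),
            dosage[perm].astype(np.int8),
        )
        p1 = nj_tree(distance_matrix(gm1)).path_length_matrix()
        p2 = nj_tree(distance_matrix(gm2)).path_length_matrix()
        names = gm1.accessions
        assert np.allclose(
            p1.loc[names, names].values, p2.loc[names, names].values, atol=1e-9
        )


class TestPca:
    def test_separates_two_populations(self):
        m = PopulationModel(
            n_populations=2, fst=0.5, dirichlet_alpha=(0.05, 0.05),
            n_accessions=60, n_loci=400, missing_rate=0.0, seed=17,
        )
        gm, truth = simulate_panel(m)
        res = pca(to_dosage(gm), n_components=2)
        # accessions dominated by population 1 vs population 2 split on PC1
        major = truth.admixture_q.argmax(axis=1)
        pc1 = res.scores[:, 0]
        means = [pc1[major == k].mean() for k in (0, 1)]
        spread = pc1.std()
        assert abs(means[0] - means[1]) > spread

    def test_explained_percentages_sum_to_100(self):
        rng = np.random.default_rng(19)
        gm = dosage_gm(rng.integers(0, 3, size=(12, 30)))
        res = pca(to_dosage(gm), n_components=3)
        assert res.all_explained_pct.sum() == pytest.approx(100.0)
        assert (res.explained_variance_pct[:-1] >= res.explained_variance_pct[1:]).all()

    def test_constant_matrix_rejected(self):
        gm = dosage_gm(np.ones((5, 10), dtype=np.int8))
        with pytest.raises(DegenerateInputError):
            pca(to_dosage(gm))

    def test_handles_missing_by_mean_imputation(self):
        rng = np.random.default_rng(23)
        dosage = rng.integers(0, 3, size=(10, 25))
        dosage[0, 0] = MISSING
        res = pca(to_dosage(dosage_gm(dosage)), n_components=2)
        assert np.isfinite(res.scores).all()


class TestAdmixture:
    def test_k1_matches_allele_frequencies(self):
        rng = np.random.default_rng(29)
        dosage = rng.integers(0, 3, size=(20, 50))
        dm = to_dosage(dosage_gm(dosage))
        fit = admixture_fit(dm, K=1)
        assert np.allclose(fit.Q, 1.0)
        assert np.allclose(fit.F[0], dosage.mean(axis=0) / 2.0, atol=1e-6)

    def test_loglik_monotone_nondecreasing(self):
        m = PopulationModel(
            n_populations=2, fst=0.4, dirichlet_alpha=(0.3, 0.3),
            n_accessions=40, n_loci=200, missing_rate=0.05, seed=37,
        )
        gm, _ = simulate_panel(m)
        fit = admixture_fit(to_dosage(gm), K=2, seed=1, max_iter=100)
        trace = np.array(fit.loglik_trace)
        assert (np.diff(trace) >= -1e-6).all()
        assert fit.loglik == pytest.approx(trace[-1])

    def test_recovers_strong_structure(self):
        m = PopulationModel(
            n_populations=2, fst=0.5, dirichlet_alpha=(0.1, 0.1),
            n_accessions=80, n_loci=600, missing_rate=0.0, seed=53,
        )
        gm, truth = simulate_panel(m)
        fit = admixture_fit(to_dosage(gm), K=2, seed=2, max_iter=300)
        aligned = align_q_to_truth(fit.Q, truth.admixture_q)
        assert np.abs(aligned - truth.admixture_q).mean() < 0.1

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(59)
        dm = to_dosage(dosage_gm(rng.integers(0, 3, size=(15, 40))))
        fit = admixture_fit(dm, K=3, seed=0, max_iter=50)
        assert np.allclose(fit.Q.sum(axis=1), 1.0)
        assert fit.F.min() > 0 and fit.F.max() < 1

    def test_k_larger_than_samples_rejected(self):
        rng = np.random.default_rng(61)
        dm = to_dosage(dosage_gm(rng.integers(0, 3, size=(4, 10))))
        with pytest.raises(ParameterError):
            admixture_fit(dm, K=5)


class TestCrossValidation:
    def test_errors_nonnegative_and_deterministic(self):
        m = PopulationModel(
            n_populations=2, fst=0.4, dirichlet_alpha=(0.3, 0.3),
            n_accessions=30, n_loci=120, missing_rate=0.0, seed=67,
        )
        gm, _ = simulate_panel(m)
        dm = to_dosage(gm)
        cv1 = cv_error_over_k(dm, [1, 2], seed=5, n_folds=2, max_iter=60)
        cv2 = cv_error_over_k(dm, [1, 2], seed=5, n_folds=2, max_iter=60)
        assert cv1 == cv2
        assert all(v >= 0 for v in cv1.values())
        assert set(cv1) == {1, 2}

    def test_structure_prefers_k2_over_k1(self):
        m = PopulationModel(
            n_populations=2, fst=0.5, dirichlet_alpha=(0.05, 0.05),
            n_accessions=60, n_loci=300, missing_rate=0.0, seed=71,
        )
        gm, _ = simulate_panel(m)
        cv = cv_error_over_k(to_dosage(gm), [1, 2], seed=7, n_folds=2, max_iter=150)
        assert cv[2] < cv[1]
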