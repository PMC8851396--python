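import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import silhouette_score

from phenomet import (
    SynthConfig,
    ValidationError,
    generate_ground_truth,
    generate_metabolome,
    opls_da_fit,
    permutation_test,
    presence_filter,
    q2y,
    select_discriminant,
    vip_scores,
    ward_hca,
)
from phenomet.multivariate import cv_anova
from tests.conftest import make_feature_table

# ---------------------------------------------------------------------------
# Ward HCA oracles
# ---------------------------------------------------------------------------


def centroid_ward_oracle(X):
    """Squared-euclidean Ward via explicit centroid merge costs."""
    X = np.asarray(X, dtype=float)
    clusters = {i: [i] for i in range(len(X))}
    next_id = len(X)
    merges = []
    while len(clusters) > 1:
        best = None
        ids = sorted(clusters)
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                i, j = ids[a], ids[b]
                ca, cb = X[clusters[i]].mean(0), X[clusters[j]].mean(0)
                na, nb = len(clusters[i]), len(clusters[j])
                d = 2.0 * na * nb / (na + nb) * float(((ca - cb) ** 2).sum())
                if best is None or (d, i, j) < best:
                    best = (d, i, j)
        d, i, j = best
        merges.append((i, j, d, len(clusters[i]) + len(clusters[j])))
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        next_id += 1
    return np.array(merges)


def recursive_lw_oracle(X, metric):
    """Lazy-recursive Lance-Williams Ward agglomerator (independent path)."""
    D0 = squareform(pdist(X, metric))
    n = len(D0)
    memo = {(i, j): float(D0[i, j]) for i in range(n) for j in range(i + 1, n)}
    children, size = {}, {i: 1 for i in range(n)}

    def dist(a, b):
        if a > b:
            a, b = b, a
        if (a, b) in memo:
            return memo[(a, b)]
        i, j = children[b]
        ni, nj, na = size[i], size[j], size[a]
        d = (
            (ni + na) * dist(a, i) + (nj + na) * dist(a, j) - na * dist(i, j)
        ) / (ni + nj + na)
        memo[(a, b)] = d
        return d

    active, nid, merges = list(range(n)), n, []
    while len(active) > 1:
        best = None
        for x in range(len(active)):
            for y in range(x + 1, len(active)):
                a, b = sorted((active[x], active[y]))
                cand = (dist(a, b), a, b)
                if best is None or cand < best:
                    best = cand
        d, a, b = best
        children[nid] = (a, b)
        size[nid] = size[a] + size[b]
        merges.append((a, b, d, size[nid]))
        active = [z for z in active if z not in (a, b)] + [nid]
        nid += 1
    return np.array(merges)


METRIC_MAP = {"euclidean": "euclidean", "squared_euclidean": "sqeuclidean", "manhattan": "cityblock"}


class TestWardHca:
    def test_two_well_separated_pairs(self):
        d = ward_hca(np.array([[0.0], [1.0], [10.0], [11.0]]), "euclidean")
        first_two = {tuple(sorted(m[:2].astype(int))) for m in d.merges[:2]}
        assert first_two == {(0, 1), (2, 3)}

    def test_n_two_single_merge(self):
        d = ward_hca(np.array([[0.0, 0.0], [3.0, 4.0]]), "euclidean")
        assert d.merges.shape == (1, 4)
        assert d.merges[0, 2] == pytest.approx(5.0)

    @pytest.mark.parametrize("distance", sorted(METRIC_MAP))
    def test_matches_recursive_oracle(self, distance):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(3, 9))
            X = rng.normal(size=(n, 3))
            ours = ward_hca(X, distance).merges
            oracle = recursive_lw_oracle(X, METRIC_MAP[distance])
            np.testing.assert_allclose(ours, oracle, rtol=1e-10, atol=1e-12)

    def test_squared_euclidean_matches_centroid_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            X = rng.normal(size=(int(rng.integers(3, 9)), 4))
            ours = ward_hca(X, "squared_euclidean").merges
            oracle = centroid_ward_oracle(X)
            np.testing.assert_allclose(ours, oracle, rtol=1e-9, atol=1e-12)

    def test_squared_euclidean_matches_scipy_heights(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 3))
        ours = ward_hca(X, "squared_euclidean")
        sp = linkage(X, method="ward")
        np.testing.assert_allclose(np.sort(ours.merges[:, 2]), np.sort(sp[:, 2] ** 2), rtol=1e-9)

    def test_row_permutation_isomorphic(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(7, 3))
        perm = rng.permutation(7)
        a = ward_hca(X, "euclidean").cophenetic_matrix()
        b = ward_hca(X[perm], "euclidean").cophenetic_matrix()
        np.testing.assert_allclose(a[np.ix_(perm, perm)], b, rtol=1e-10)

    def test_heights_monotone_for_euclidean(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            X = rng.normal(size=(8, 4))
            h = ward_hca(X, "euclidean").merges[:, 2]
            assert np.all(np.diff(h) >= -1e-12)

    def test_nan_rejected(self):
        X = np.array([[0.0, np.nan], [1.0, 2.0]])
        with pytest.raises(ValidationError):
            ward_hca(X, "euclidean")

    def test_newick_well_formed(self):
        d = ward_hca(np.arange(8.0).reshape(4, 2), "euclidean", labels=list("abcd"))
        nwk = d.to_newick()
        assert nwk.endswith(";") and nwk.count("(") == 3


# ---------------------------------------------------------------------------
# presence filter
# ---------------------------------------------------------------------------


class TestPresenceFilter:
    def _table(self):
        groups = ["A_control"] * 4 + ["B_control"] * 4
        vals = np.ones((8, 3))
        # c00: 3/4 in A, absent in B -> retained at 0.75
        vals[3, 0] = np.nan
        vals[4:, 0] = np.nan
        # c01: 2/4 in each group -> removed at 0.75
        vals[[2, 3, 6, 7], 1] = np.nan
        # c02: full -> retained
        return make_feature_table(vals, groups)

    def test_seventy_five_percent_rule(self):
        kept = presence_filter(self._table(), 0.75)
        assert list(kept.compounds) == ["c00", "c02"]

    def test_abundances_unchanged(self):
        table = self._table()
        kept = presence_filter(table, 0.75)
        assert kept.abundance.equals(table.abundance[kept.compounds])

    def test_vanishing_fraction_keeps_any_observation(self):
        kept = presence_filter(self._table(), 1e-9)
        assert list(kept.compounds) == ["c00", "c01", "c02"]

    def test_bad_fraction(self):
        with pytest.raises(ValidationError):
            presence_filter(self._table(), 0.0)


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------


def _two_class(rng, n=24, p=10, shift=1.5):
    classes = np.repeat(["a", "b"], n // 2)
    X = rng.normal(size=(n, p))
    X[classes == "a", 0] += shift
    return X, classes


class TestOplsDaFit:
    def test_perfect_separation_r2y_one(self):
        X = np.zeros((10, 3))
        X[:5, 0], X[5:, 0] = 1.0, -1.0
        X[:, 1:] = np.random.default_rng(0).normal(size=(10, 2)) * 1e-9
        m = opls_da_fit(X, ["x"] * 5 + ["y"] * 5, scaling="none", n_pred=1)
        assert m.r2y == pytest.approx(1.0, abs=1e-6)

    def test_plsda_oracle_two_class(self):
        rng = np.random.default_rng(0)
        X, classes = _two_class(rng)
        Y = (classes[:, None] == np.unique(classes)[None, :]).astype(float)
        for k in (1, 2):
            skl = PLSRegression(n_components=k, scale=False, tol=1e-12).fit(X, Y)
            m = opls_da_fit(X, classes, n_ortho=0, scaling="none", n_pred=k)
            assert np.abs(skl.predict(X) - m.predict_y(X)).max() < 1e-8

    def test_plsda_oracle_three_class(self):
        rng = np.random.default_rng(1)
        classes = np.repeat(["a", "b", "c"], 10)
        X = rng.normal(size=(30, 12))
        X[classes == "a", 0] += 2
        X[classes == "b", 1] += 2
        Y = (classes[:, None] == np.unique(classes)[None, :]).astype(float)
        skl = PLSRegression(n_components=2, scale=False, tol=1e-20, max_iter=100000).fit(X, Y)
        m = opls_da_fit(X, classes, n_ortho=0, scaling="none", n_pred=2)
        assert np.abs(skl.predict(X) - m.predict_y(X)).max() < 1e-8

    def test_discriminant_direction_recovery(self):
        rng = np.random.default_rng(7)
        n, p, snr = 40, 15, 5.0
        d = rng.normal(size=p)
        d /= np.linalg.norm(d)
        y = np.repeat([1.0, -1.0], n // 2)
        X = np.outer(y, d) * snr + rng.normal(size=(n, p))
        m = opls_da_fit(X, np.repeat(["a", "b"], n // 2), scaling="none", n_pred=1)
        corr = abs(float(np.corrcoef(m.weights[:, 0], d)[0, 1]))
        assert corr >= 0.95

    def test_score_orthogonality(self):
        rng = np.random.default_rng(2)
        X, classes = _two_class(rng)
        m = opls_da_fit(X, classes, n_ortho=3, scaling="uv")
        assert np.abs(m.scores.T @ m.ortho_scores).max() < 1e-8

    def test_r2y_nondecreasing_in_n_ortho(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X, classes = _two_class(rng)
            r2 = [opls_da_fit(X, classes, n_ortho=a).r2y for a in range(4)]
            assert np.all(np.diff(r2) >= -1e-10)

    def test_constant_column_named(self):
        rng = np.random.default_rng(3)
        X, classes = _two_class(rng)
        X[:, 4] = 2.0
        with pytest.raises(ValidationError, match="4"):
            opls_da_fit(X, classes, scaling="uv")

    def test_single_class_rejected(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(8, 3))
        with pytest.raises(ValidationError):
            opls_da_fit(X, ["a"] * 8)


class TestVip:
    def test_single_variable(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 1))
        classes = np.where(X[:, 0] > 0, "a", "b")
        m = opls_da_fit(X, classes, scaling="none")
        assert m.vip == pytest.approx([1.0])

    def test_normalisation_identity(self):
        rng = np.random.default_rng(1)
        for p in (3, 8, 20):
            X, classes = _two_class(rng, p=p)
            m = opls_da_fit(X, classes, n_ortho=1)
            assert float((m.vip**2).sum()) == pytest.approx(p, abs=1e-8)

    def test_informative_variable_ranks_first(self):
        hits = 0
        n_runs = 20
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            classes = np.repeat(["a", "b"], 10)
            X = rng.normal(size=(20, 8))
            X[classes == "a", 0] += 3.0
            m = opls_da_fit(X, classes)
            hits += int(np.argmax(m.vip) == 0)
        assert hits >= int(0.95 * n_runs)

    def test_unfitted_model_rejected(self):
        rng = np.random.default_rng(2)
        X, classes = _two_class(rng)
        m = opls_da_fit(X, classes)
        m.weights = np.zeros((X.shape[1], 0))
        with pytest.raises(ValidationError):
            vip_scores(m)


class TestSelectDiscriminant:
    def test_strict_filter(self):
        assert select_discriminant([1.3, 1.1, 0.9], 1.2) == [0]

    def test_boundary_strictness(self):
        assert select_discriminant([1.3, 1.1, 0.9], 1.1) == [0]

    def test_zero_threshold_admits_all(self):
        assert set(select_discriminant([1.3, 1.1, 0.9], 0.0)) == {0, 1, 2}

    def test_sorted_by_descending_vip(self):
        assert select_discriminant([0.5, 2.0, 1.5], 0.4, ids=["x", "y", "z"]) == ["y", "z", "x"]


class TestQ2y:
    def test_noiseless_separable(self):
        rng = np.random.default_rng(0)
        classes = np.repeat(["a", "b"], 8)
        X = rng.normal(size=(16, 5)) * 0.05
        X[classes == "a", 0] += 3.0
        assert q2y(X, classes, folds=4, seed=0, scaling="none") > 0.9

    def test_null_labels_nonpositive(self):
        neg = 0
        n_runs = 20
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(20, 8))
            classes = rng.permutation(np.repeat(["a", "b"], 10))
            neg += int(q2y(X, classes, folds=5, seed=seed) <= 0)
        assert neg >= int(0.9 * n_runs)

    def test_q2_not_exceeding_r2(self):
        ok = 0
        n_runs = 50
        for seed in range(n_runs):
            rng = np.random.default_rng(100 + seed)
            X, classes = _two_class(rng, shift=float(rng.uniform(0, 2)))
            r2 = opls_da_fit(X, classes).r2y
            ok += int(q2y(X, classes, folds=4, seed=seed) <= r2 + 1e-12)
        # empirical regularity, not a theorem
        assert ok >= int(0.9 * n_runs)

    def test_folds_reduced_with_warning(self):
        rng = np.random.default_rng(1)
        classes = np.repeat(["a", "b"], 3)
        X = rng.normal(size=(6, 4))
        with pytest.warns(UserWarning, match="reducing folds"):
            q2y(X, classes, folds=7, seed=0)


class TestPermutationTest:
    def test_determinism(self):
        rng = np.random.default_rng(0)
        X, classes = _two_class(rng, shift=2.0)
        a = permutation_test(X, classes, n_perm=30, seed=5, folds=4)
        b = permutation_test(X, classes, n_perm=30, seed=5, folds=4)
        assert a.permutation_p == b.permutation_p
        np.testing.assert_array_equal(a.perm_q2, b.perm_q2)

    def test_minimal_p_with_strong_signal(self):
        rng = np.random.default_rng(1)
        X, classes = _two_class(rng, shift=6.0)
        rep = permutation_test(X, classes, n_perm=39, seed=0, folds=4)
        assert rep.permutation_p == pytest.approx(1 / 40)

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(16, 6))
        rep = permutation_test(X, np.repeat(["a", "b"], 8), n_perm=20, seed=0, folds=4)
        assert 0.0 < rep.permutation_p <= 1.0


class TestCvAnova:
    def test_perfect_prediction_tiny_p(self):
        rng = np.random.default_rng(0)
        classes = np.repeat(["a", "b"], 10)
        X = rng.normal(size=(20, 4)) * 1e-4
        X[classes == "a", 0] += 5.0
        res = cv_anova(X, classes, folds=5, seed=0)
        assert res.p < 1e-6

    def test_null_labels_rarely_significant(self):
        sig = 0
        n_runs = 20
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(20, 6))
            classes = rng.permutation(np.repeat(["a", "b"], 10))
            sig += int(cv_anova(X, classes, folds=5, seed=seed).p <= 0.05)
        assert n_runs - sig >= int(0.9 * n_runs)

    def test_probability_contract(self):
        rng = np.random.default_rng(3)
        for seed in range(10):
            X, classes = _two_class(rng, shift=float(rng.uniform(0, 3)))
            res = cv_anova(X, classes, folds=4, seed=seed)
            assert 0.0 <= res.p <= 1.0


class TestScoreSpacePattern:
    def test_planted_substances_separate_from_controls(self):
        """Best/worst substances separate in score space; silhouette > 0."""
        hits = 0
        n_runs = 10
        for seed in range(n_runs):
            cfg = SynthConfig(crop="lettuce", seed=seed, n_reps=4, n_compounds=80,
                              conditions=("control",))
            truth = generate_ground_truth(cfg)
            loadings = truth.treatment_loadings.copy()
            loadings.loc[:, :] = 0.0
            for s, scale in (("H", 3.0), ("B", -3.0)):
                loadings.loc[(s, "control")] = scale
            truth.treatment_loadings = loadings
            ft = generate_metabolome(cfg, truth)
            X = np.log(ft.abundance.to_numpy(float))
            m = opls_da_fit(X, ft.samples["substance"].to_numpy(), scaling="pareto", n_pred=2)
            groups = ft.samples["substance"].map(
                lambda s: s if s in ("H", "B") else "rest"
            )
            hits += int(silhouette_score(m.scores, groups.to_numpy()) > 0)
        assert hits >= int(0.9 * n_runs)
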