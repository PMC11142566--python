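import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clusterbalance import (
    GeneratorConfig,
    ResampleConfig,
    clean,
    enn_clean,
    generate,
    knn_clean,
    knn_query,
    nearmiss,
    smote,
    smote_enn,
    smote_knn,
    standardize,
)
from clusterbalance.resamplers import ResampleError

from _oracles import brute_edit, brute_knn, brute_nearmiss
from conftest import make_table


class TestKnnQuery:
    def test_line_points_nearest(self):
        X = np.array([[0.0], [1.0], [3.0]])
        nn = knn_query(X, X[:1], k=1, exclude_self=True)
        assert nn.indices[0, 0] == 1

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 4))
        nn = knn_query(X, X, k=5, exclude_self=True)
        np.testing.assert_array_equal(nn.indices, brute_knn(X, X, 5, exclude_self=True))

    def test_equidistant_tie_takes_lower_index(self):
        X = np.array([[0.0], [1.0], [-1.0]])
        nn = knn_query(X, X[:1], k=2, exclude_self=True)
        assert nn.indices[0].tolist() == [1, 2]

    def test_k_too_large_names_available_count(self):
        X = np.zeros((3, 2))
        with pytest.raises(ResampleError, match="available"):
            knn_query(X, X, k=3, exclude_self=True)


class TestSmote:
    def test_equalizes_reference_counts(self):
        table = clean(generate(GeneratorConfig(n_majority=5340, n_minority=192, seed=2)))
        (ts,), _ = standardize(table)
        out = smote(ts, ResampleConfig(seed=2))
        assert out.class_counts == (5340, 5340)

    def test_balanced_input_unchanged(self, toy_imbalanced):
        sub = toy_imbalanced.subset(np.r_[0:20, 180:200])  # 20 vs 20
        assert smote(sub, ResampleConfig(seed=0)).equals(sub)

    def test_two_point_minority_interpolates_segment(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]] + [[5.0, 5.0]] * 6)
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0])
        out = smote(make_table(X, y), ResampleConfig(k_neighbors1=1, seed=3))
        syn = out.X[8:]
        assert out.class_counts == (6, 6)
        # on the segment between (0,0) and (1,1): equal coordinates in [0,1)
        np.testing.assert_allclose(syn[:, 0], syn[:, 1], atol=1e-12)
        assert ((syn[:, 0] >= 0) & (syn[:, 0] < 1)).all()

    def test_original_rows_pass_through_verbatim(self, toy_imbalanced):
        out = smote(toy_imbalanced, ResampleConfig(seed=5))
        np.testing.assert_array_equal(out.X[:200], toy_imbalanced.X)
        np.testing.assert_array_equal(out.y[:200], toy_imbalanced.y)

    def test_minority_below_two_errors(self):
        X = np.zeros((5, 2))
        table = make_table(X, [0, 0, 0, 0, 1])
        with pytest.raises(ResampleError, match="interpolate"):
            smote(table, ResampleConfig(seed=0))

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000), n_min=st.integers(3, 12))
    def test_geometry_property(self, seed, n_min):
        """Every synthetic row lies on a segment between its recorded parents."""
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(size=(30, 3)), rng.normal(2.0, 1.0, (n_min, 3))])
        y = np.array([0] * 30 + [1] * n_min)
        table = make_table(X, y)
        out, prov = smote(table, ResampleConfig(seed=seed), return_provenance=True)
        syn = out.X[table.n :]
        A = table.X[prov.parent_a]
        B = table.X[prov.parent_b]
        np.testing.assert_allclose(syn, A + prov.lam[:, None] * (B - A), atol=1e-10)
        assert ((prov.lam >= 0) & (prov.lam < 1)).all()

    def test_deterministic_under_seed(self, toy_imbalanced):
        a = smote(toy_imbalanced, ResampleConfig(seed=11))
        b = smote(toy_imbalanced, ResampleConfig(seed=11))
        assert a.equals(b)


class TestEditing:
    def test_single_class_unchanged(self):
        table = make_table(np.random.default_rng(0).normal(size=(10, 2)), [1] * 10)
        assert enn_clean(table).equals(table)

    def test_hand_vote_removes_isolated_minority(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0], [1.5]])
        y = np.array([0, 0, 0, 0, 1])
        out = enn_clean(make_table(X, y))
        assert out.class_counts == (4, 0)
        np.testing.assert_array_equal(out.X[:, 0], [0.0, 1.0, 2.0, 10.0])

    def test_knn_clean_hand_vote_six_points(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0], [10.0], [1.5]])
        y = np.array([0, 0, 0, 0, 0, 1])
        out = knn_clean(make_table(X, y))  # k=5: the lone class-1 row goes
        assert out.class_counts == (5, 0)

    def test_same_k_same_result(self, toy_imbalanced):
        a = enn_clean(toy_imbalanced, ResampleConfig(k_neighbors2=4))
        b = knn_clean(toy_imbalanced, ResampleConfig(k_neighbors2=4))
        assert a.equals(b)

    @pytest.mark.parametrize("k", [3, 5])
    def test_matches_exhaustive_reference(self, k):
        rng = np.random.default_rng(k)
        X = rng.normal(size=(200, 3))
        y = (rng.random(200) < 0.4).astype(int)
        table = make_table(X, y)
        out = _apply_edit(table, k)
        kept = brute_edit(X, y, k)
        np.testing.assert_array_equal(out.X, X[kept])

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_anti_extensive(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(40, 2))
        y = rng.integers(0, 2, 40)
        table = make_table(X, y)
        out = enn_clean(table)
        # every output row appears in the input
        rows_in = {tuple(r) for r in np.column_stack([X, y])}
        rows_out = [tuple(r) for r in np.column_stack([out.X, out.y])]
        assert all(r in rows_in for r in rows_out)
        assert out.n <= table.n


def _apply_edit(table, k):
    return enn_clean(table, ResampleConfig(k_neighbors2=k))


class TestNearMiss:
    def test_reference_counts(self):
        table = clean(generate(GeneratorConfig(n_majority=5340, n_minority=192, seed=2)))
        (ts,), _ = standardize(table)
        out = nearmiss(ts, ResampleConfig(seed=2))
        assert out.class_counts == (192, 192)

    def test_balanced_input_unchanged(self):
        rng = np.random.default_rng(1)
        table = make_table(rng.normal(size=(20, 2)), [0] * 10 + [1] * 10)
        assert nearmiss(table).equals(table)

    def test_matches_exhaustive_scoring(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 2))
        y = np.array([0] * 15 + [1] * 5)
        table = make_table(X, y)
        out = nearmiss(table)
        kept_maj = brute_nearmiss(X, y)
        expected = np.sort(np.concatenate([kept_maj, np.arange(15, 20)]))
        np.testing.assert_array_equal(out.X, X[expected])


class TestHybrids:
    def test_equals_manual_composition(self, toy_imbalanced):
        cfg = ResampleConfig(seed=13)
        assert smote_enn(toy_imbalanced, cfg).equals(enn_clean(smote(toy_imbalanced, cfg), cfg))
        assert smote_knn(toy_imbalanced, cfg).equals(knn_clean(smote(toy_imbalanced, cfg), cfg))

    def test_separated_clusters_barely_edited(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 0.3, (60, 2)), rng.normal(10, 0.3, (15, 2))])
        y = np.array([0] * 60 + [1] * 15)
        out = smote_enn(make_table(X, y), ResampleConfig(seed=3))
        c0, c1 = out.class_counts
        assert c0 == 60 and c1 >= 58  # editing removes ~0 rows

    def test_label_noise_shrinks_both_classes(self):
        table = clean(
            generate(GeneratorConfig(n_majority=900, n_minority=100, label_noise_frac=0.10, seed=6))
        )
        (ts,), _ = standardize(table)
        post_smote = smote(ts, ResampleConfig(seed=6)).class_counts
        for hybrid in (smote_enn, smote_knn):
            c0, c1 = hybrid(ts, ResampleConfig(seed=6)).class_counts
            assert c0 < post_smote[0] and c1 < post_smote[1]
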