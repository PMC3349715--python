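"""Subtype discovery (consensus clustering) and nearest-centroid prediction."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from ladomics import subtyping
from ladomics.containers import SUBTYPES
from ladomics.synthetic import default_config, simulate_cohort


def _frame(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


# ---------------------------------------------------------------------------
# median centering and gene selection

def test_median_center_examples():
    m = _frame([[1, 2, 3]])
    out = subtyping.median_center(m)
    assert out.iloc[0].tolist() == [-1.0, 0.0, 1.0]
    # idempotence
    pd.testing.assert_frame_equal(subtyping.median_center(out), out)


def test_median_center_preserves_missing():
    m = _frame([[1, np.nan, 3]])
    out = subtyping.median_center(m)
    assert np.isnan(out.iloc[0, 1])
    assert out.iloc[0, 0] == -1.0


def test_median_center_all_missing_gene_rejected():
    m = _frame([[np.nan, np.nan]])
    with pytest.raises(ValueError):
        subtyping.median_center(m)


def test_select_variable_genes_fraction_one_returns_all():
    m = _frame(np.random.default_rng(0).normal(size=(8, 5)))
    assert sorted(subtyping.select_variable_genes(m, 1.0)) == sorted(m.index)


def test_select_variable_genes_top_quarter():
    rng = np.random.default_rng(1)
    base = rng.normal(size=(8, 20))
    base[2] *= 10.0
    base[5] *= 10.0
    m = _frame(base)
    assert set(subtyping.select_variable_genes(m, 0.25)) == {"g2", "g5"}


def test_injected_high_variance_genes_always_selected():
    rng = np.random.default_rng(2)
    values = rng.normal(size=(100, 30))
    spiked = [f"g{i}" for i in range(0, 100, 10)]
    m = _frame(values)
    m.loc[spiked] *= 5.0
    chosen = subtyping.select_variable_genes(m, 0.25)
    assert set(spiked) <= set(chosen)


# ---------------------------------------------------------------------------
# consensus clustering

def _blobs(n_per=20, n_genes=40, shift=4.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, size=(n_genes, n_per))
    b = rng.normal(0, 1, size=(n_genes, n_per))
    a[: n_genes // 2] += shift
    b[n_genes // 2:] += shift
    return _frame(np.hstack([a, b])), [0] * n_per + [1] * n_per


def test_consensus_two_blobs_block_structure():
    m, truth = _blobs()
    res = subtyping.consensus_cluster(m, k_range=(2, 3), n_reps=100, seed=1)
    cons = res.consensus[2].to_numpy()
    truth = np.asarray(truth)
    same = truth[:, None] == truth[None, :]
    within = cons[same & ~np.eye(len(truth), dtype=bool)]
    between = cons[~same]
    assert within.mean() >= 0.95
    assert between.mean() <= 0.05
    assert adjusted_rand_score(truth, res.labels[2]) == 1.0


def test_consensus_matrix_symmetric_unit_diagonal():
    m, _ = _blobs(seed=3)
    res = subtyping.consensus_cluster(m, k_range=(2, 3), n_reps=50, seed=2)
    for k, cons in res.consensus.items():
        arr = cons.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 1.0)
        assert arr.min() >= 0.0 and arr.max() <= 1.0


def test_consensus_seeded_determinism():
    m, _ = _blobs(seed=4)
    r1 = subtyping.consensus_cluster(m, k_range=(2, 3), n_reps=50, seed=9)
    r2 = subtyping.consensus_cluster(m, k_range=(2, 3), n_reps=50, seed=9)
    assert r1.chosen_k == r2.chosen_k
    for k in r1.consensus:
        pd.testing.assert_frame_equal(r1.consensus[k], r2.consensus[k])


def test_consensus_repeatability_improves_with_reps():
    """Run-to-run variance of consensus entries shrinks with more reps."""
    # unstructured data: consensus entries are genuinely stochastic
    m, _ = _blobs(n_per=15, shift=0.0, seed=5)

    def spread(n_reps):
        mats = [
            subtyping.consensus_cluster(
                m, k_range=(2,), n_reps=n_reps, seed=s
            ).consensus[2].to_numpy()
            for s in range(4)
        ]
        return np.std(np.stack(mats), axis=0).mean()

    assert spread(120) < spread(15)


# ---------------------------------------------------------------------------
# centroid predictor

def _three_class_data(n_per=10, n_genes=30, shift=3.0, seed=0):
    rng = np.random.default_rng(seed)
    blocks = []
    labels = []
    for i, subtype in enumerate(SUBTYPES):
        x = rng.normal(size=(n_genes, n_per))
        x[i * (n_genes // 3): (i + 1) * (n_genes // 3)] += shift
        blocks.append(x)
        labels += [subtype] * n_per
    m = _frame(np.hstack(blocks))
    return m, pd.Series(labels, index=m.columns)


def test_predictor_reclassifies_separable_training_data():
    m, labels = _three_class_data()
    model = subtyping.train_centroid_predictor(m, labels, n_genes=15)
    pred = subtyping.predict_subtype(model, m)
    assert (pred["subtype"] == labels).all()


def test_predictor_all_genes_centroids_are_class_means():
    m, labels = _three_class_data()
    model = subtyping.train_centroid_predictor(m, labels, n_genes=len(m))
    centered = subtyping.median_center(m)
    for subtype in SUBTYPES:
        expected = centered[labels.index[labels == subtype]].mean(axis=1)
        got = model.centroids[subtype].reindex(expected.index)
        assert np.allclose(got, expected)


def test_single_marker_gene_ranks_first():
    rng = np.random.default_rng(6)
    m = _frame(rng.normal(size=(20, 30)))
    labels = pd.Series(
        [SUBTYPES[i // 10] for i in range(30)], index=m.columns
    )
    m.loc["g7", labels == "Magnoid"] += 10.0
    model = subtyping.train_centroid_predictor(m, labels, n_genes=3)
    assert "g7" in model.gene_ids


def test_predict_sample_equal_to_centroid():
    m, labels = _three_class_data()
    model = subtyping.train_centroid_predictor(m, labels, n_genes=15)
    probe = model.centroids.rename(
        columns={s: f"probe_{s}" for s in SUBTYPES}
    )
    pred = subtyping.predict_subtype(model, probe)
    for s in SUBTYPES:
        assert pred.loc[f"probe_{s}", "subtype"] == s


def test_predict_invariant_to_gene_row_order():
    m, labels = _three_class_data(seed=7)
    model = subtyping.train_centroid_predictor(m, labels, n_genes=12)
    p1 = subtyping.predict_subtype(model, m)
    shuffled = m.sample(frac=1.0, random_state=0)
    p2 = subtyping.predict_subtype(model, shuffled)
    assert (p1["subtype"] == p2["subtype"]).all()


def test_predict_requires_half_model_genes():
    m, labels = _three_class_data()
    model = subtyping.train_centroid_predictor(m, labels, n_genes=20)
    small = m.iloc[:5]
    with pytest.raises(ValueError, match="model genes"):
        subtyping.predict_subtype(model, small)


def test_model_tsv_round_trip(tmp_path):
    m, labels = _three_class_data()
    model = subtyping.train_centroid_predictor(m, labels, n_genes=9)
    model.save(tmp_path / "genes.tsv", tmp_path / "centroids.tsv")
    back = subtyping.SubtypeModel.load(
        tmp_path / "genes.tsv", tmp_path / "centroids.tsv"
    )
    assert back.gene_ids == model.gene_ids
    assert np.allclose(back.centroids, model.centroids)


def test_train_rejects_too_many_genes():
    m, labels = _three_class_data()
    with pytest.raises(ValueError):
        subtyping.train_centroid_predictor(m, labels, n_genes=1000)


# ---------------------------------------------------------------------------
# parameter recovery on the synthetic cohort

def test_consensus_recovery_on_synthetic_cohort(small_cohort):
    cohort, truth = small_cohort
    tumors = list(truth.subtype.index)
    expr = subtyping.median_center(cohort.expression[tumors])
    genes = subtyping.select_variable_genes(expr, 0.25)
    res = subtyping.consensus_cluster(
        expr.loc[genes], k_range=(2, 3, 4), n_reps=150, seed=0
    )
    assert res.chosen_k == 3
    assert adjusted_rand_score(truth.subtype[tumors], res.labels[3][tumors]) >= 0.9


def test_held_out_prediction_accuracy(small_cohort):
    cohort, truth = small_cohort
    tumors = list(truth.subtype.index)
    model = subtyping.train_centroid_predictor(
        cohort.expression[tumors], truth.subtype
    )
    held, held_truth = simulate_cohort(default_config(), seed=77, prefix="H")
    held_tumors = list(held_truth.subtype.index)
    pred = subtyping.predict_subtype(model, held.expression[held_tumors])
    acc = (pred["subtype"] == held_truth.subtype[pred.index]).mean()
    assert acc >= 0.9
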