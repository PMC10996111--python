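"""Imputation, standardization and SMOTE contracts, with sklearn cross-checks."""

import numpy as np
import pandas as pd
import pytest
from sklearn.impute import KNNImputer

from daebls import (
    ConfigError,
    DataError,
    PreprocessConfig,
    SchemaError,
    SmoteParams,
    SynthSpec,
    fit_imputer,
    generate_table,
    knn_impute,
    preprocess_pipeline,
    smote_oversample,
    zscore_fit,
    zscore_transform,
)
from conftest import make_table


# ---------------------------------------------------------------------------
# KNN imputation
# ---------------------------------------------------------------------------
def test_impute_nearest_single_neighbor():
    # row 2 is far away; the nearest co-observed row supplies the value 5
    t = make_table([[1, 1, np.nan], [1, 1, 5], [10, 10, 9]])
    out = knn_impute(t, fit_imputer(t, k=1))
    assert out.features()[0, 2] == 5.0


def test_impute_mean_of_two_neighbors():
    t = make_table([[0, np.nan], [0, 2], [0, 4]])
    out = knn_impute(t, fit_imputer(t, k=2))
    assert out.features()[0, 1] == pytest.approx(3.0)


def test_impute_no_missing_is_identity(tiny_labelled):
    out = knn_impute(tiny_labelled, fit_imputer(tiny_labelled, k=2))
    assert out.X.equals(tiny_labelled.X)


def test_impute_never_alters_observed_cells_and_stays_in_range():
    t = generate_table(SynthSpec(n_samples=80, n_features=5,
                                 missing_rate=0.15, seed=4))
    out = knn_impute(t, fit_imputer(t, k=5))
    obs = ~t.missing_mask().to_numpy()
    np.testing.assert_array_equal(out.features()[obs], t.features()[obs])
    assert out.n_missing() == 0
    lo = np.nanmin(t.features(), axis=0)
    hi = np.nanmax(t.features(), axis=0)
    filled = out.features()[~obs]
    cols = np.nonzero(~obs)[1]
    assert np.all(filled >= lo[cols] - 1e-12)
    assert np.all(filled <= hi[cols] + 1e-12)


def test_impute_all_missing_row_rejected():
    t = make_table([[np.nan, np.nan], [1, 2], [3, 4]])
    with pytest.raises(DataError, match="0"):
        knn_impute(t, fit_imputer(t, k=1))


def test_impute_matches_sklearn_on_plentiful_donors():
    # where no fallback triggers, donor choice and the neighbour mean agree
    # with sklearn's KNNImputer (nan-euclidean distance is a monotone
    # transform of ours, so the k nearest donors coincide)
    rng = np.random.default_rng(11)
    X = rng.standard_normal((60, 4))
    mask = rng.random(X.shape) < 0.08
    mask[:, 0] &= False  # keep one always-observed column
    Xm = X.copy()
    Xm[mask] = np.nan
    t = make_table(Xm)
    ours = knn_impute(t, fit_imputer(t, k=3)).features()
    theirs = KNNImputer(n_neighbors=3).fit_transform(Xm)
    np.testing.assert_allclose(ours, theirs, atol=1e-12)


def test_impute_falls_back_to_global_mean_when_donors_scarce(caplog):
    # only one reference row observes f1, but k=2 donors are required
    t = make_table([[0.0, np.nan], [0.1, np.nan], [0.2, np.nan], [5.0, 7.0]])
    with caplog.at_level("WARNING"):
        out = knn_impute(t, fit_imputer(t, k=2))
    assert np.all(out.features()[:3, 1] == 7.0)  # global mean of f1
    assert any("global mean" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# z-score
# ---------------------------------------------------------------------------
def test_zscore_closed_form():
    t = make_table([[1.0], [2.0], [3.0]])
    params = zscore_fit(t)
    assert params.mu[0] == pytest.approx(2.0)
    assert params.sigma[0] == pytest.approx(0.81650, abs=1e-5)
    z = zscore_transform(t, params).features()[:, 0]
    np.testing.assert_allclose(z, [-1.22474, 0.0, 1.22474], atol=1e-5)


def test_zscore_constant_column_maps_to_zero():
    t = make_table([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
    params = zscore_fit(t)
    assert params.sigma[0] == 0.0
    z = zscore_transform(t, params).features()
    assert np.all(z[:, 0] == 0.0)


def test_zscore_idempotent_on_standardized_data(rng):
    X = rng.standard_normal((100, 3))
    X = (X - X.mean(0)) / X.std(0)
    t = make_table(X)
    z = zscore_transform(t, zscore_fit(t)).features()
    np.testing.assert_allclose(z, X, atol=1e-9)


def test_zscore_self_transform_is_mean0_sd1(rng):
    t = make_table(rng.gamma(2.0, 3.0, size=(50, 4)))
    z = zscore_transform(t, zscore_fit(t)).features()
    assert np.all(np.abs(z.mean(0)) < 1e-9)
    assert np.all(np.abs(z.std(0) - 1) < 1e-9)


def test_zscore_requires_complete_table_and_matching_schema():
    with pytest.raises(DataError):
        zscore_fit(make_table([[1.0, np.nan], [2.0, 3.0]]))
    t = make_table([[1.0], [2.0]])
    params = zscore_fit(t)
    other = make_table([[1.0]], columns=["other"])
    with pytest.raises(SchemaError):
        zscore_transform(other, params)


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------
def test_smote_count_arithmetic():
    X = np.vstack([np.random.default_rng(0).normal(0, 1, (10, 2)),
                   np.random.default_rng(1).normal(5, 1, (4, 2))])
    t = make_table(X, y=[0] * 10 + [1] * 4)
    out = smote_oversample(t, SmoteParams(k_neighbors=2, target_ratio=1.0, seed=0))
    assert out.n_samples == 20  # 6 synthetics appended
    counts = np.unique(out.labels(), return_counts=True)[1]
    assert list(counts) == [10, 10]


def test_smote_synthetic_rows_lie_on_minority_segments():
    rng = np.random.default_rng(5)
    X = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(4, 1, (8, 3))])
    t = make_table(X, y=[0] * 30 + [1] * 8)
    out = smote_oversample(t, SmoteParams(k_neighbors=3, seed=2))
    originals = out.features()[: t.n_samples]
    np.testing.assert_array_equal(originals, t.features())  # untouched, in order
    minority = t.features()[np.asarray(t.labels()) == 1]
    for s in out.features()[t.n_samples:]:
        assert _on_some_segment(s, minority, tol=1e-9)
        # synthetics carry the minority label
    assert np.all(out.labels()[t.n_samples:] == 1)


def _on_some_segment(point, anchors, tol):
    for i in range(len(anchors)):
        d = anchors - anchors[i]
        v = point - anchors[i]
        with np.errstate(invalid="ignore", divide="ignore"):
            g = (d @ v) / (d * d).sum(axis=1)
        proj = anchors[i] + np.clip(np.nan_to_num(g), 0, 1)[:, None] * d
        if np.min(np.linalg.norm(proj - point, axis=1)) < tol:
            return True
    return False


def test_smote_balanced_input_is_noop(tiny_labelled):
    out = smote_oversample(tiny_labelled, SmoteParams(k_neighbors=1, seed=0))
    assert out.n_samples == tiny_labelled.n_samples


def test_smote_reproducible_and_validated():
    rng = np.random.default_rng(7)
    t = make_table(np.vstack([rng.normal(0, 1, (9, 2)), rng.normal(3, 1, (3, 2))]),
                   y=[0] * 9 + [1] * 3)
    a = smote_oversample(t, SmoteParams(k_neighbors=2, seed=1))
    b = smote_oversample(t, SmoteParams(k_neighbors=2, seed=1))
    assert a.X.equals(b.X)
    with pytest.raises(ConfigError):
        smote_oversample(t, SmoteParams(k_neighbors=3, seed=1))  # k >= minority
    t1 = make_table([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]], y=[0, 0, 1])
    with pytest.raises(DataError):
        smote_oversample(t1, SmoteParams(k_neighbors=1, seed=1))  # minority < 2


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------
def test_pipeline_output_complete_and_balanced():
    table = generate_table(SynthSpec(n_samples=300, n_features=6,
                                     minority_fraction=0.2, missing_rate=0.1,
                                     seed=8))
    half = table.n_samples // 2
    train, test = table.select_rows(range(half)), table.select_rows(range(half, table.n_samples))
    train_p, test_p, scaler = preprocess_pipeline(train, test, PreprocessConfig(seed=0))
    assert train_p.n_missing() == 0 and test_p.n_missing() == 0
    counts = np.unique(train_p.labels(), return_counts=True)[1]
    assert counts.min() == counts.max()  # exact balance at target_ratio 1
    assert test_p.n_samples == test.n_samples  # SMOTE never touches test


def test_pipeline_is_leakage_safe():
    # imputing a test cell must use train statistics only: a pathological test
    # row cannot change its own imputed value by changing its unseen cells
    train = make_table([[0.0, 0.0], [0.0, 2.0], [0.0, 4.0], [1.0, 6.0]],
                       y=[0, 0, 1, 1])
    test_a = make_table([[0.0, np.nan], [100.0, 100.0]], y=[0, 1])
    test_b = make_table([[0.0, np.nan], [-100.0, -100.0]], y=[0, 1])
    cfg = PreprocessConfig(impute_k=2, smote=False)
    _, out_a, scaler_a = preprocess_pipeline(train, test_a, cfg)
    _, out_b, scaler_b = preprocess_pipeline(train, test_b, cfg)
    assert out_a.features()[0, 1] == out_b.features()[0, 1]
    np.testing.assert_array_equal(scaler_a.mu, scaler_b.mu)


def test_pipeline_clean_balanced_reduces_to_standardization(tiny_labelled):
    train_p, _, scaler = preprocess_pipeline(tiny_labelled, None,
                                             PreprocessConfig(smote_k=1))
    assert train_p.n_samples == tiny_labelled.n_samples
    z = train_p.features()
    assert np.all(np.abs(z.mean(0)) < 1e-9)
    assert np.all(np.abs(z.std(0) - 1) < 1e-9)
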