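"""Feature assembly, PCA, confusion metrics and the three classifiers."""

import numpy as np
import pandas as pd
import pytest

from usdot.classify import (
    ClassifyError,
    DenseHingeNet,
    build_features,
    classification_metrics,
    pca_embed,
    train_eval,
    _standardize,
)

WAVES = [635.0, 670.0, 685.0, 785.0, 905.0, 930.0, 975.0, 1060.0]


def _toy_fits(n, rng, shift=0.0):
    fits, labels = {}, {}
    for i in range(n):
        malignant = i % 2 == 0
        base = 0.015 if malignant else 0.008
        fits[i] = {
            lam: (base * rng.uniform(0.9, 1.1) + shift, 1.0 * rng.uniform(0.9, 1.1))
            for lam in WAVES
        }
        labels[i] = "malignant" if malignant else "benign"
    return fits, labels


def test_metrics_direct_arithmetic():
    m = classification_metrics(85, 80, 15, 20)
    assert m["accuracy"] == pytest.approx(0.825)
    assert m["precision"] == pytest.approx(0.85)
    assert m["recall"] == pytest.approx(0.8095, abs=1e-4)
    assert m["f1"] == pytest.approx(2 * 0.85 * 0.8095 / (0.85 + 0.8095), abs=1e-4)


def test_metrics_perfect_and_degenerate():
    perfect = classification_metrics(10, 10, 0, 0)
    assert all(perfect[k] == 1.0 for k in ("accuracy", "precision", "recall", "f1"))
    # all-benign predictor on a balanced set: no positive calls
    allb = classification_metrics(0, 10, 0, 10)
    assert allb["recall"] == 0.0
    assert allb["precision"] is None  # undefined, not zero
    assert allb["f1"] is None
    with pytest.raises(ClassifyError):
        classification_metrics(0, 0, 0, 0)


def test_feature_table_shape_log_and_exclusions():
    rng = np.random.default_rng(0)
    fits, labels = _toy_fits(20, rng)
    fits[3][WAVES[2]] = (-0.001, 1.0)  # non-positive coefficient: cannot log
    table = build_features(fits, labels)
    assert table.shape[0] == 19
    feat_cols = [c for c in table.columns if c.startswith(("mua_", "musp_"))]
    assert len(feat_cols) == 16
    assert table.attrs["excluded"] == [3]
    assert table.loc[0, "mua_635"] == pytest.approx(np.log(fits[0][635.0][0]))


def test_standardization_contract():
    rng = np.random.default_rng(1)
    train = rng.normal(3.0, 2.0, size=(50, 4))
    train[:, 2] = 7.0  # constant column maps to zero, not NaN
    test = rng.normal(3.0, 2.0, size=(20, 4))
    tr, te = _standardize(train, test)
    assert np.allclose(tr.mean(axis=0), 0.0, atol=1e-12)
    assert np.allclose(tr[:, 2], 0.0)
    assert not np.allclose(te.mean(axis=0), 0.0, atol=1e-3)


def test_pca_orthogonal_ordered_isotropic():
    rng = np.random.default_rng(2)
    fits, labels = _toy_fits(60, rng)
    table = build_features(fits, labels)
    scores, pca = pca_embed(table, n_components=3)
    assert scores.shape == (60, 3)
    comps = pca.components_
    gram = comps @ comps.T
    assert np.allclose(gram, np.eye(3), atol=1e-8)
    ev = pca.explained_variance_
    assert np.all(np.diff(ev) <= 1e-12)

    # isotropic 3D data: all explained variances comparable
    white = rng.standard_normal((500, 3))
    df = pd.DataFrame(white, columns=["mua_1", "mua_2", "mua_3"])
    df["label"] = ["benign", "malignant"] * 250
    _, p = pca_embed(df, n_components=3)
    ev = p.explained_variance_ratio_
    assert ev.max() / ev.min() < 1.3


@pytest.mark.parametrize("method", ["logreg", "svm", "fcn"])
def test_separable_classes_are_perfectly_classified(method):
    rng = np.random.default_rng(3)
    fits, labels = _toy_fits(120, rng)  # disjoint mu_a ranges: separable
    table = build_features(fits, labels)
    report = train_eval(table, method, rng_seed=0)
    assert report.accuracy == 1.0
    # metrics recomputable from confusion counts
    assert report.metrics == classification_metrics(report.tm, report.tb,
                                                    report.fm, report.fb)


def test_label_permutation_destroys_accuracy():
    rng = np.random.default_rng(4)
    fits, labels = _toy_fits(300, rng)
    ids = sorted(labels)
    vals = [labels[i] for i in ids]
    rng.shuffle(vals)
    shuffled = dict(zip(ids, vals))
    table = build_features(fits, shuffled)
    accs = [train_eval(table, "logreg", rng_seed=s).accuracy for s in range(3)]
    assert abs(np.mean(accs) - 0.5) < 0.1


def test_single_class_table_raises():
    rng = np.random.default_rng(5)
    fits, labels = _toy_fits(10, rng)
    labels = {k: "benign" for k in labels}
    with pytest.raises(ClassifyError):
        train_eval(build_features(fits, labels), "logreg")


def test_dense_net_learns_xor_style_boundary():
    """The small dense net handles a non-linearly-separable layout."""
    rng = np.random.default_rng(6)
    x = rng.uniform(-1, 1, size=(400, 16))
    y = ((x[:, 0] > 0) ^ (x[:, 1] > 0)).astype(int)
    net = DenseHingeNet(n_in=16, seed=0, max_epochs=300)
    net.fit(x[:300], y[:300], x[300:], y[300:])
    acc = (net.predict(x[300:]) == y[300:]).mean()
    # far above the ~0.5 ceiling of any linear separator on this layout
    assert acc >= 0.75
    s = net.decision(x[:10])
    assert np.all((s > -1) & (s < 1))
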