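"""Benign/malignant classification of per-wavelength lesion spectra.

Each lesion contributes 16 features: the inclusion absorption and reduced
scattering at the 8 wavelengths.  Features are log-transformed (spectral
contrasts are multiplicative) and z-scored with training-split statistics.
Three classifiers are compared: logistic regression, a kernel SVM
(model-selected over Gaussian/polynomial/sigmoid kernels and C in [0.5, 5]),
and a small fully connected network (dense widths 16/32/16/1, ReLU hidden
activations, sigmoid output, hinge loss, minibatch SGD with early stopping).
Performance is summarized by accuracy, precision, recall and F1 computed
from the malignant/benign confusion counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.svm import SVC

__all__ = [
    "FEATURE_COLUMNS",
    "ClassReport",
    "build_features",
    "pca_embed",
    "classification_metrics",
    "train_eval",
    "DenseHingeNet",
]


class ClassifyError(ValueError):
    pass


def feature_columns(wavelengths: np.ndarray) -> list[str]:
    lams = [int(round(l)) for l in wavelengths]
    return [f"mua_{l}" for l in lams] + [f"musp_{l}" for l in lams]


#: the default 16 feature names at the standard 8 wavelengths
FEATURE_COLUMNS = feature_columns(np.array([635, 670, 685, 785, 905, 930, 975, 1060]))


@dataclass
class ClassReport:
    """Confusion counts and derived metrics for one method on one split."""

    method: str
    tm: int  # true malignant
    tb: int  # true benign
    fm: int  # false malignant (benign called malignant)
    fb: int  # false benign (malignant called benign)
    split: str = ""
    metrics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.metrics:
            self.metrics = classification_metrics(self.tm, self.tb, self.fm, self.fb)

    @property
    def accuracy(self) -> float:
        return self.metrics["accuracy"]


def classification_metrics(tm: int, tb: int, fm: int, fb: int) -> dict:
    """Accuracy, precision, recall, F1 from malignant/benign confusion counts.

    Denominator-free cases are reported as None (undefined), never as 0.
    """
    if min(tm, tb, fm, fb) < 0 or tm + tb + fm + fb == 0:
        raise ClassifyError("confusion counts must be non-negative with positive total")
    total = tm + tb + fm + fb
    acc = (tm + tb) / total
    prec = tm / (tm + fm) if tm + fm > 0 else None
    rec = tm / (tm + fb) if tm + fb > 0 else None
    if prec is not None and rec is not None and prec + rec > 0:
        f1 = 2.0 * prec * rec / (prec + rec)
    else:
        f1 = None
    return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1}


def build_features(
    fits: dict,
    labels: dict,
    provenance: str = "recon_gt_prior",
    wavelengths: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble the 16-feature lesion table from per-wavelength fit results.

    ``fits`` maps lesion id -> {wavelength -> (mua_in, musp_in) or FitResult};
    ``labels`` maps lesion id -> "benign" | "malignant".  Lesions with any
    missing wavelength, non-converged fit or non-positive coefficient are
    excluded (they cannot be log-transformed); exclusions are recorded in
    ``df.attrs["excluded"]``.  Values are stored as log-coefficients;
    z-scoring with training statistics happens inside :func:`train_eval`.
    """
    rows = []
    excluded = []
    for lesion, perlam in fits.items():
        lams = sorted(perlam)
        mua, musp, ok = [], [], True
        for lam in lams:
            entry = perlam[lam]
            if hasattr(entry, "params"):
                if not getattr(entry, "converged", True):
                    ok = False
                    break
                mua.append(entry.params.mua_in)
                musp.append(entry.params.musp_in)
            else:
                mua.append(entry[0])
                musp.append(entry[1])
        vals = np.array(mua + musp, dtype=float)
        if not ok or vals.size != 2 * len(lams) or np.any(vals <= 0):
            excluded.append(lesion)
            continue
        cols = feature_columns(np.array(lams))
        rows.append({"lesion": lesion, "label": labels[lesion],
                     **dict(zip(cols, np.log(vals)))})
    if not rows:
        raise ClassifyError("no usable lesions")
    df = pd.DataFrame(rows).set_index("lesion")
    df["provenance"] = provenance
    df.attrs["excluded"] = excluded
    return df


def _xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    cols = [c for c in table.columns if c.startswith(("mua_", "musp_"))]
    x = table[cols].to_numpy(dtype=float)
    y = (table["label"].to_numpy() == "malignant").astype(int)
    return x, y


def _standardize(train: np.ndarray, *others: np.ndarray) -> tuple[np.ndarray, ...]:
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return tuple((a - mean) / sd for a in (train, *others))


def pca_embed(table: pd.DataFrame, n_components: int = 3) -> tuple[np.ndarray, PCA]:
    """PCA scores of the standardized feature table (for separability plots)."""
    x, _ = _xy(table)
    if x.shape[1] < n_components or x.shape[0] < n_components:
        raise ClassifyError("fewer features/samples than requested components")
    (xs,) = _standardize(x)
    pca = PCA(n_components=n_components)
    return pca.fit_transform(xs), pca


class DenseHingeNet:
    """Small fully connected network: dense widths 16/32/16/1.

    ReLU hidden activations, sigmoid output mapped to [-1, 1], hinge loss on
    +-1 labels, minibatch SGD with momentum, early stopping on validation
    hinge loss.  Deterministic given the seed.
    """

    def __init__(self, n_in: int = 16, widths: tuple[int, ...] = (16, 32, 16, 1),
                 lr: float = 0.05, momentum: float = 0.9, batch_size: int = 32,
                 max_epochs: int = 500, patience: int = 25, seed: int = 0):
        self.widths = widths
        self.lr = lr
        self.momentum = momentum
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        rng = np.random.default_rng(seed)
        dims = [n_in, *widths]
        self.W = [rng.normal(0, np.sqrt(2.0 / dims[i]), (dims[i], dims[i + 1]))
                  for i in range(len(widths))]
        self.b = [np.zeros(d) for d in widths]
        self._vw = [np.zeros_like(w) for w in self.W]
        self._vb = [np.zeros_like(b) for b in self.b]
        self._rng = rng

    def _forward(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        acts = [x]
        h = x
        for k in range(len(self.W) - 1):
            h = np.maximum(h @ self.W[k] + self.b[k], 0.0)
            acts.append(h)
        z = h @ self.W[-1] + self.b[-1]
        o = 1.0 / (1.0 + np.exp(-z))
        acts.append(o)
        return o.ravel(), acts

    def decision(self, x: np.ndarray) -> np.ndarray:
        """Score in (-1, 1); threshold at 0."""
        o, _ = self._forward(x)
        return 2.0 * o - 1.0

    def predict(self, x: np.ndarray) -> np.ndarray:
        return (self.decision(x) > 0).astype(int)

    def hinge_loss(self, x: np.ndarray, y_pm: np.ndarray) -> float:
        return float(np.mean(np.maximum(0.0, 1.0 - y_pm * self.decision(x))))

    def _step(self, x: np.ndarray, y_pm: np.ndarray) -> None:
        n = len(x)
        o, acts = self._forward(x)
        s = 2.0 * o - 1.0
        active = (1.0 - y_pm * s) > 0
        # d loss / d z  (z = logit): ds/dz = 2 o (1-o)
        dz = np.where(active, -y_pm * 2.0 * o * (1.0 - o), 0.0)[:, None] / n
        grads_w, grads_b = [], []
        delta = dz
        for k in range(len(self.W) - 1, -1, -1):
            a_prev = acts[k]
            grads_w.append(a_prev.T @ delta)
            grads_b.append(delta.sum(axis=0))
            if k > 0:
                delta = (delta @ self.W[k].T) * (acts[k] > 0)
        grads_w.reverse()
        grads_b.reverse()
        for k in range(len(self.W)):
            self._vw[k] = self.momentum * self._vw[k] - self.lr * grads_w[k]
            self._vb[k] = self.momentum * self._vb[k] - self.lr * grads_b[k]
            self.W[k] += self._vw[k]
            self.b[k] += self._vb[k]

    def fit(self, x: np.ndarray, y: np.ndarray,
            x_val: np.ndarray | None = None, y_val: np.ndarray | None = None) -> "DenseHingeNet":
        y_pm = 2.0 * np.asarray(y, dtype=float) - 1.0
        yv_pm = 2.0 * np.asarray(y_val, dtype=float) - 1.0 if y_val is not None else None
        best = np.inf
        best_state = None
        stale = 0
        n = len(x)
        for _ in range(self.max_epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, self.batch_size):
                sel = order[start : start + self.batch_size]
                self._step(x[sel], y_pm[sel])
            monitor = (self.hinge_loss(x_val, yv_pm) if x_val is not None
                       else self.hinge_loss(x, y_pm))
            if monitor < best - 1e-6:
                best = monitor
                best_state = ([w.copy() for w in self.W], [b.copy() for b in self.b])
                stale = 0
            else:
                stale += 1
                if stale >= self.patience:
                    break
        if best_state is not None:
            self.W, self.b = best_state
        return self


#: SVM model-selection grid: kernels and regularization per the study design
SVM_GRID = {"kernel": ["rbf", "poly", "sigmoid"], "C": [0.5, 1.0, 2.0, 3.0, 4.0, 5.0]}


def train_eval(
    table: pd.DataFrame,
    method: str = "svm",
    rng_seed: int = 0,
    split: tuple[float, ...] | None = None,
) -> ClassReport:
    """Train one classifier on a stratified split and score the held-out test.

    Splits: 60:40 train:test for logistic regression and the SVM; 60:20:20
    train:validation:test for the FCN (the validation part drives early
    stopping).  Standardization statistics come from the training split only.
    """
    if method not in ("logreg", "svm", "fcn"):
        raise ClassifyError(f"unknown method {method!r}")
    x, y = _xy(table)
    if len(np.unique(y)) < 2:
        raise ClassifyError("both classes must be present")

    if method == "fcn":
        frac = split or (0.6, 0.2, 0.2)
        x_tr, x_rest, y_tr, y_rest = train_test_split(
            x, y, train_size=frac[0], stratify=y, random_state=rng_seed)
        rel = frac[1] / (frac[1] + frac[2])
        x_val, x_te, y_val, y_te = train_test_split(
            x_rest, y_rest, train_size=rel, stratify=y_rest, random_state=rng_seed)
        x_tr, x_val, x_te = _standardize(x_tr, x_val, x_te)
        net = DenseHingeNet(n_in=x.shape[1], seed=rng_seed)
        net.fit(x_tr, y_tr, x_val, y_val)
        y_hat = net.predict(x_te)
        split_desc = "60:20:20 stratified"
    else:
        frac = split or (0.6, 0.4)
        x_tr, x_te, y_tr, y_te = train_test_split(
            x, y, train_size=frac[0], stratify=y, random_state=rng_seed)
        x_tr, x_te = _standardize(x_tr, x_te)
        if method == "logreg":
            clf = LogisticRegression(max_iter=2000)
        else:
            cv = min(5, int(np.min(np.bincount(y_tr))))
            clf = GridSearchCV(SVC(), SVM_GRID, scoring="accuracy", cv=max(cv, 2))
        clf.fit(x_tr, y_tr)
        y_hat = clf.predict(x_te)
        split_desc = "60:40 stratified"

    tm = int(np.sum((y_hat == 1) & (y_te == 1)))
    tb = int(np.sum((y_hat == 0) & (y_te == 0)))
    fm = int(np.sum((y_hat == 1) & (y_te == 0)))
    fb = int(np.sum((y_hat == 0) & (y_te == 1)))
    return ClassReport(method=method, tm=tm, tb=tb, fm=fm, fb=fb, split=split_desc)
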