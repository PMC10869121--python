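"""Canonical discriminant analysis of burn severity.

Observations are (subject, burn class, time since injury T in seconds, and the
ROI means of CHbT, StO2, StMet).  The three burn classes — scald exposure at
70 C, 78 C and 98 C, modeling superficial dermal, deep dermal and deep
(full-thickness) burns — are coded 1/2/3.  Predictors are the four features
plus their second-order terms (squares and pairwise products, 14 columns),
z-standardized.  CDA finds the linear projections maximizing between-class to
within-class scatter: solving B v = lambda W v gives at most g-1 = 2 canonical
axes, scaled so canonical scores have unit pooled within-class variance.
Classification is nearest class centroid in canonical score space; separation
strength is summarized by Wilks' lambda with Bartlett's chi-square
approximation; generalization by leave-one-out cross-validation and one-vs-
rest ROC curves.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "CLASS_CODES", "TIME_POINTS_S", "SampleTable", "PredictorMatrix",
    "CDAModel", "ROCCurve", "expand_predictors", "fit_cda", "canonical_scores",
    "wilks_lambda", "classify", "loocv", "one_vs_rest_roc",
]

#: Burn classes in ascending scald temperature: 1 = 70 C (superficial dermal),
#: 2 = 78 C (deep dermal), 3 = 98 C (deep / full thickness).
CLASS_CODES = {1: "70C", 2: "78C", 3: "98C"}

#: Acquisition times: 5 min, 24 h, 48 h, 72 h post-burn, in seconds.
TIME_POINTS_S = (300.0, 86_400.0, 172_800.0, 259_200.0)

FEATURES = ("t_s", "chbt", "sto2", "stmet")


@dataclass
class SampleTable:
    """Per-observation records feeding the discriminant analysis."""

    frame: pd.DataFrame   # columns: subject, class, t_s, chbt, sto2, stmet

    REQUIRED = ("subject", "class", "t_s", "chbt", "sto2", "stmet")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"sample table missing column(s): {missing}")
        if self.frame[list(self.REQUIRED[2:])].isna().any().any():
            raise ValueError("sample table has missing feature values")
        if (self.frame["t_s"] < 0).any():
            raise ValueError("time since injury must be non-negative")
        counts = self.frame["class"].value_counts()
        if (counts < 2).any():
            raise ValueError("every class needs at least 2 records")

    def __len__(self):
        return len(self.frame)

    @property
    def labels(self) -> np.ndarray:
        return self.frame["class"].to_numpy(dtype=int)

    @property
    def features(self) -> np.ndarray:
        return self.frame[list(FEATURES)].to_numpy(dtype=float)

    @classmethod
    def from_csv(cls, path) -> "SampleTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path):
        self.frame.to_csv(path, index=False)


def _expand_raw(x: np.ndarray, squares_only: bool = False) -> tuple[np.ndarray, list]:
    """Second-order expansion of feature rows (..., 4) -> (..., 14) or (..., 8)."""
    names = list(FEATURES)
    cols = [x[..., i] for i in range(4)]
    for i in range(4):
        cols.append(x[..., i] ** 2)
        names.append(f"{FEATURES[i]}^2")
    if not squares_only:
        for i in range(4):
            for j in range(i + 1, 4):
                cols.append(x[..., i] * x[..., j])
                names.append(f"{FEATURES[i]}*{FEATURES[j]}")
    return np.stack(cols, axis=-1), names


@dataclass
class PredictorMatrix:
    """Standardized second-order design matrix with reusable statistics."""

    data: np.ndarray          # (n, p) standardized
    names: list
    mean: np.ndarray          # per-column standardization parameters
    sd: np.ndarray
    dropped: list             # zero-variance columns removed, by name
    squares_only: bool = False

    def transform(self, features: np.ndarray) -> np.ndarray:
        """Apply the stored expansion + standardization to new feature rows."""
        raw, names = _expand_raw(np.asarray(features, dtype=float), self.squares_only)
        keep = [i for i, nm in enumerate(names) if nm not in self.dropped]
        return (raw[..., keep] - self.mean) / self.sd


def expand_predictors(table: SampleTable, squares_only: bool = False) -> PredictorMatrix:
    """Build the standardized quadratic predictor matrix from a sample table.

    The full quadratic expansion has 14 columns: 4 linear terms, 4 squares and
    6 pairwise products (``squares_only`` restricts to the first 8).  Columns
    are z-standardized with training statistics stored for reuse; raw T is in
    seconds and spans ~1e2-1e5, so unstandardized scatter matrices would be
    dominated by it.  Zero-variance columns are dropped with a warning.
    """
    raw, names = _expand_raw(table.features, squares_only)
    sd = raw.std(axis=0, ddof=0)
    dropped = [names[i] for i in np.where(sd == 0)[0]]
    if dropped:
        warnings.warn(f"dropping zero-variance predictor column(s): {dropped}")
    keep = sd > 0
    raw = raw[:, keep]
    mean = raw.mean(axis=0)
    sdk = sd[keep]
    return PredictorMatrix(data=(raw - mean) / sdk,
                           names=[n for n, k in zip(names, keep) if k],
                           mean=mean, sd=sdk, dropped=dropped,
                           squares_only=squares_only)


@dataclass
class CDAModel:
    """Fitted canonical discriminant model."""

    axes: np.ndarray          # (p, k) canonical coefficient vectors
    eigenvalues: np.ndarray   # (k,) descending, >= 0
    centroids: dict           # class code -> (k,) canonical-space centroid
    class_codes: list
    predictor: PredictorMatrix
    n_samples: int
    n_features: int
    within_scatter: np.ndarray
    between_scatter: np.ndarray
    ridge: float = 0.0
    metadata: dict = field(default_factory=dict)

    def to_json(self, path):
        obj = {
            "axes": self.axes.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "centroids": {str(k): v.tolist() for k, v in self.centroids.items()},
            "class_codes": self.class_codes,
            "predictor": {
                "names": self.predictor.names,
                "mean": self.predictor.mean.tolist(),
                "sd": self.predictor.sd.tolist(),
                "dropped": self.predictor.dropped,
                "squares_only": self.predictor.squares_only,
            },
            "n_samples": self.n_samples,
            "n_features": self.n_features,
            "within_scatter": self.within_scatter.tolist(),
            "between_scatter": self.between_scatter.tolist(),
            "ridge": self.ridge,
            "metadata": self.metadata,
        }
        with open(path, "w") as f:
            json.dump(obj, f, indent=1)

    @classmethod
    def from_json(cls, path) -> "CDAModel":
        with open(path) as f:
            o = json.load(f)
        pred = PredictorMatrix(data=np.empty((0, len(o["predictor"]["names"]))),
                               names=o["predictor"]["names"],
                               mean=np.array(o["predictor"]["mean"]),
                               sd=np.array(o["predictor"]["sd"]),
                               dropped=o["predictor"]["dropped"],
                               squares_only=o["predictor"]["squares_only"])
        return cls(axes=np.array(o["axes"]), eigenvalues=np.array(o["eigenvalues"]),
                   centroids={int(k): np.array(v) for k, v in o["centroids"].items()},
                   class_codes=o["class_codes"], predictor=pred,
                   n_samples=o["n_samples"], n_features=o["n_features"],
                   within_scatter=np.array(o["within_scatter"]),
                   between_scatter=np.array(o["between_scatter"]),
                   ridge=o["ridge"], metadata=o.get("metadata", {}))


def _scatter_matrices(x: np.ndarray, labels: np.ndarray):
    classes = np.unique(labels)
    grand = x.mean(axis=0)
    p = x.shape[1]
    w = np.zeros((p, p))
    b = np.zeros((p, p))
    means = {}
    for c in classes:
        xc = x[labels == c]
        mc = xc.mean(axis=0)
        means[int(c)] = mc
        d = xc - mc
        w += d.T @ d
        db = (mc - grand)[:, None]
        b += len(xc) * (db @ db.T)
    return w, b, means, classes


def fit_cda(predictors: PredictorMatrix, labels) -> CDAModel:
    """Fit canonical discriminant axes from a standardized predictor matrix.

    Solves the generalized symmetric eigenproblem B v = lambda W v on the
    within/between scatter matrices and keeps the top min(g-1, rank(B)) axes,
    scaled so canonical scores have unit pooled within-class variance
    (v' W v = n - g).  A singular W falls back to ridge regularization
    W + eps*I with eps = 1e-8 tr(W)/p.  Axis signs are fixed so the largest-
    magnitude coefficient of each axis is positive, making fits reproducible.
    """
    x = predictors.data
    labels = np.asarray(labels, dtype=int)
    if x.shape[0] != labels.shape[0]:
        raise ValueError("predictor rows and labels must align")
    classes = np.unique(labels)
    g = len(classes)
    if g < 2:
        raise ValueError("need at least 2 classes")
    n, p = x.shape
    w, b, means, _ = _scatter_matrices(x, labels)

    ridge = 0.0
    try:
        evals, evecs = linalg.eigh(b, w)
    except linalg.LinAlgError:
        ridge = 1e-8 * np.trace(w) / p
        try:
            evals, evecs = linalg.eigh(b, w + ridge * np.eye(p))
        except linalg.LinAlgError as err:
            raise linalg.LinAlgError(
                "within-class scatter singular even after ridge") from err

    order = np.argsort(evals)[::-1]
    n_axes = min(g - 1, int(np.sum(evals[order] > 1e-10 * max(evals.max(), 1.0))))
    n_axes = max(n_axes, 1)
    idx = order[:n_axes]
    vecs = evecs[:, idx]                       # v' W v = 1 from eigh
    vecs = vecs * np.sqrt(n - g)               # unit pooled within-class variance
    sign = np.sign(vecs[np.argmax(np.abs(vecs), axis=0), np.arange(n_axes)])
    vecs = vecs * np.where(sign == 0, 1.0, sign)

    centroids = {c: means[int(c)] @ vecs for c in map(int, classes)}
    return CDAModel(axes=vecs, eigenvalues=np.maximum(evals[idx], 0.0),
                    centroids=centroids, class_codes=[int(c) for c in classes],
                    predictor=predictors, n_samples=n, n_features=p,
                    within_scatter=w, between_scatter=b, ridge=ridge)


def canonical_scores(model: CDAModel, standardized_rows) -> np.ndarray:
    """Project standardized predictor rows (..., p) onto the canonical axes."""
    z = np.asarray(standardized_rows, dtype=float)
    if z.shape[-1] != model.n_features:
        raise ValueError(f"expected {model.n_features} predictor columns, got {z.shape[-1]}")
    return z @ model.axes


def wilks_lambda(model: CDAModel) -> dict:
    """Wilks' lambda with Bartlett's chi-square significance approximation.

    Lambda = prod_k 1/(1 + lambda_k) over the canonical eigenvalues; the
    Bartlett statistic is -(n - 1 - (p + g)/2) ln Lambda on p(g-1) degrees of
    freedom.
    """
    lam = float(np.prod(1.0 / (1.0 + model.eigenvalues)))
    n = model.n_samples
    p = model.n_features
    g = len(model.class_codes)
    chi2 = -(n - 1 - (p + g) / 2.0) * np.log(lam) if lam > 0 else np.inf
    df = p * (g - 1)
    pval = float(stats.chi2.sf(chi2, df)) if np.isfinite(chi2) else 0.0
    return {"lambda": lam, "chi2": float(chi2), "df": int(df), "p": pval}


def classify(model: CDAModel, standardized_rows) -> np.ndarray:
    """Nearest-centroid class codes in canonical space; ties break toward the
    lowest class code."""
    scores = canonical_scores(model, standardized_rows)
    codes = sorted(model.class_codes)
    d2 = np.stack([np.sum((scores - model.centroids[c]) ** 2, axis=-1) for c in codes],
                  axis=-1)
    return np.asarray(codes, dtype=int)[np.argmin(d2, axis=-1)]


def classify_features(model: CDAModel, features) -> np.ndarray:
    """Convenience: classify raw (T, CHbT, StO2, StMet) rows."""
    return classify(model, model.predictor.transform(features))


def loocv(table: SampleTable, squares_only: bool = False,
          group_by_subject: bool = False) -> dict:
    """Leave-one-out cross-validation of the full expand/standardize/fit chain.

    Each observation is classified by a model refitted without it; with
    ``group_by_subject`` the fold leaves out every observation of the held
    sample's subject (the stricter variant when subjects contribute several
    time points).  A fold whose refit fails is excluded with a warning.
    Returns the confusion matrix (rows = true class, columns = predicted),
    per-class and overall percent correct.
    """
    labels = table.labels
    feats = table.features
    subjects = table.frame["subject"].to_numpy()
    classes = sorted(int(c) for c in np.unique(labels))
    if min(np.bincount(labels)[np.bincount(labels) > 0]) < 3:
        raise ValueError("LOOCV needs at least 3 samples per class")
    n = len(table)
    idx = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    failed = []
    for i in range(n):
        mask = (subjects != subjects[i]) if group_by_subject \
            else np.arange(n) != i
        sub = SampleTable(table.frame.iloc[mask].reset_index(drop=True))
        try:
            pm = expand_predictors(sub, squares_only=squares_only)
            model = fit_cda(pm, sub.labels)
        except Exception as err:   # refit failure: record and skip the fold
            warnings.warn(f"LOOCV fold {i} failed: {err}")
            failed.append(i)
            continue
        pred = int(classify(model, pm.transform(feats[i]))[()])
        confusion[idx[labels[i]], idx[pred]] += 1
    per_class = {
        c: 100.0 * confusion[idx[c], idx[c]] / max(confusion[idx[c]].sum(), 1)
        for c in classes
    }
    total = confusion.sum()
    overall = 100.0 * np.trace(confusion) / max(total, 1)
    return {"confusion": confusion, "classes": classes, "per_class_pct": per_class,
            "overall_pct": overall, "failed_folds": failed}


@dataclass(frozen=True)
class ROCCurve:
    """One-vs-rest ROC curve in (FPR, TPR) coordinates with trapezoid AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    positive_class: int
    score_definition: str


def centroid_margin_scores(model: CDAModel, standardized_rows, positive_class: int) -> np.ndarray:
    """Per-row score: (min distance to any negative centroid) - (distance to
    the positive centroid); larger means more positive-class-like."""
    scores = canonical_scores(model, standardized_rows)
    d = {c: np.sqrt(np.sum((scores - model.centroids[c]) ** 2, axis=-1))
         for c in model.class_codes}
    neg = [c for c in model.class_codes if c != positive_class]
    if not neg:
        raise ValueError("need at least one negative class")
    return np.min([d[c] for c in neg], axis=0) - d[positive_class]


def one_vs_rest_roc(model: CDAModel, table: SampleTable, positive_class: int) -> ROCCurve:
    """ROC of the centroid-margin score for one class against the rest.

    The curve sweeps every distinct score threshold; ties are grouped so the
    trapezoid AUC equals the Mann-Whitney statistic with tie correction.
    """
    if positive_class not in model.class_codes:
        raise ValueError(f"class {positive_class} not in model")
    labels = table.labels
    y = labels == positive_class
    if y.all() or not y.any():
        raise ValueError("need both positive and negative samples")
    z = model.predictor.transform(table.features)
    s = centroid_margin_scores(model, z, positive_class)

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # group ties: cumulative counts at each distinct threshold
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(~y_sorted)[distinct]
    tpr = np.r_[0.0, tp / y.sum()]
    fpr = np.r_[0.0, fp / (~y).sum()]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, auc=auc, positive_class=positive_class,
                    score_definition="min_negative_centroid_distance - positive_centroid_distance")
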