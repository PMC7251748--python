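"""Bagged decision-tree detector, repeated k-fold evaluation, significance.

PF (pharyngeal fricative) is the positive class throughout: sensitivity is
the PF recall (missed-diagnosis rate complement), specificity the NS recall.
Vote ties over an even ensemble resolve to NS, i.e. toward "no disorder".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .bandsplit import significance_flag
from .errors import ConfigError, DegenerateTrainingError, ShapeError
from scipy import stats

log = logging.getLogger(__name__)

POSITIVE = "PF"
NEGATIVE = "NS"


@dataclass
class FeatureMatrix:
    """Per-token feature rows with labels and consonant types."""

    X: np.ndarray  # (n_tokens, n_features)
    labels: np.ndarray  # (n_tokens,) of {"PF", "NS"}
    consonants: np.ndarray  # (n_tokens,)
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        self.consonants = np.asarray(self.consonants)
        if self.X.ndim != 2:
            raise ShapeError("X must be 2-D")
        if not (len(self.labels) == len(self.consonants) == self.X.shape[0]):
            raise ShapeError("labels/consonants length must match X rows")
        if not self.feature_names:
            self.feature_names = [f"f_{j + 1}" for j in range(self.X.shape[1])]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def y(self) -> np.ndarray:
        """Boolean target, True for the positive (PF) class."""
        return self.labels == POSITIVE

    @staticmethod
    def combine(a: "FeatureMatrix", b: "FeatureMatrix") -> "FeatureMatrix":
        if a.X.shape[0] != b.X.shape[0]:
            raise ShapeError("cannot combine matrices with different row counts")
        if not np.array_equal(a.labels, b.labels):
            raise ShapeError("cannot combine matrices with different labels")
        return FeatureMatrix(
            X=np.hstack([a.X, b.X]),
            labels=a.labels.copy(),
            consonants=a.consonants.copy(),
            feature_names=a.feature_names + b.feature_names,
        )

    def to_frame(self, source_ids=None) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "consonant", self.consonants)
        df.insert(0, "source_id", source_ids if source_ids is not None
                  else np.arange(len(self.labels)).astype(str))
        return df

    @staticmethod
    def from_frame(df: pd.DataFrame, prefix: str | None = None) -> "FeatureMatrix":
        meta = {"source_id", "consonant", "label"}
        cols = [c for c in df.columns if c not in meta]
        if prefix is not None:
            cols = [c for c in cols if c.startswith(prefix)]
        return FeatureMatrix(
            X=df[cols].to_numpy(dtype=np.float64),
            labels=df["label"].to_numpy(),
            consonants=df["consonant"].to_numpy(),
            feature_names=cols,
        )


@dataclass
class EnsembleModel:
    trees: list
    T: int
    seed: int | None
    n_features: int


@dataclass
class Metric:
    mean: float
    sd: float

    def to_dict(self) -> dict:
        return {"mean": round(self.mean, 3), "sd": round(self.sd, 3)}


@dataclass
class CVResult:
    """Repeated-CV metrics in percent, mean +/- SD over repeats."""

    accuracy: Metric
    sensitivity: Metric
    specificity: Metric
    auc: Metric
    per_consonant: dict
    k: int
    repeats: int
    n_trees: int
    n_rows: int
    raw: dict = field(default_factory=dict)  # per-repeat metric lists

    def to_dict(self) -> dict:
        return {
            "overall": {
                "accuracy": self.accuracy.to_dict(),
                "sensitivity": self.sensitivity.to_dict(),
                "specificity": self.specificity.to_dict(),
                "auc": self.auc.to_dict(),
            },
            "per_consonant": {
                cons: {name: m.to_dict() for name, m in mm.items()}
                for cons, mm in self.per_consonant.items()
            },
            "protocol": {
                "k": self.k,
                "repeats": self.repeats,
                "n_trees": self.n_trees,
                "n_rows": self.n_rows,
                "spread": "sd over repeats",
            },
        }


def _as_xy(data, y=None):
    if isinstance(data, FeatureMatrix):
        return data.X, data.y
    return np.asarray(data, dtype=np.float64), np.asarray(y, dtype=bool)


def fit_bagging(
    data,
    y=None,
    T: int = 30,
    seed: int | None = None,
    bootstrap: bool = True,
) -> EnsembleModel:
    """Fit ``T`` decision trees, each on a bootstrap resample of the rows.

    Trees use Gini impurity and unlimited depth (the reference protocol
    leaves tree hyperparameters unstated).  With ``bootstrap=False`` every
    tree sees the full training set (useful only for degenerate T=1 checks).
    """
    X, yy = _as_xy(data, y)
    if X.shape[0] < 2 or len(np.unique(yy)) < 2:
        raise DegenerateTrainingError("training data must contain both classes")
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(T):
        idx = (rng.integers(0, X.shape[0], X.shape[0]) if bootstrap
               else np.arange(X.shape[0]))
        tree = DecisionTreeClassifier(
            criterion="gini", random_state=int(rng.integers(2**31))
        )
        tree.fit(X[idx], yy[idx])
        trees.append(tree)
    return EnsembleModel(trees=trees, T=T, seed=seed, n_features=X.shape[1])


def predict(model: EnsembleModel, data):
    """Majority-vote labels and the PF vote fraction per row.

    Returns ``(labels, vote_frac)``; a row with vote fraction exactly 0.5
    is labelled NS (the tie-break favours "no disorder").
    """
    X = data.X if isinstance(data, FeatureMatrix) else np.asarray(data, float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ShapeError(
            f"expected {model.n_features} features, got shape {X.shape}"
        )
    votes = np.zeros(X.shape[0])
    for tree in model.trees:
        votes += tree.predict(X).astype(float)
    frac = votes / model.T
    labels = np.where(frac > 0.5, POSITIVE, NEGATIVE)
    return labels, frac


def _confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    tp = np.sum(y_true & y_pred)
    tn = np.sum(~y_true & ~y_pred)
    fp = np.sum(~y_true & y_pred)
    fn = np.sum(y_true & ~y_pred)
    out = {"accuracy": 100.0 * (tp + tn) / max(len(y_true), 1)}
    out["sensitivity"] = 100.0 * tp / (tp + fn) if tp + fn else np.nan
    out["specificity"] = 100.0 * tn / (tn + fp) if tn + fp else np.nan
    return out


def cross_validate(
    fm: FeatureMatrix,
    k: int = 10,
    repeats: int = 10,
    T: int = 30,
    seed: int | None = None,
) -> CVResult:
    """Repeated stratified k-fold CV of the bagged ensemble.

    Each repeat reshuffles the folds; metrics are computed per repeat from
    the pooled out-of-fold predictions (AUC from pooled vote fractions) and
    then averaged, reported as mean +/- SD over repeats.  Per-repeat seeds
    derive deterministically from ``seed``, so repeat 1 of a longer run
    matches a ``repeats=1`` run with the same master seed.
    """
    y = fm.y
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if min(n_pos, n_neg) < k:
        raise ConfigError(
            f"each class needs >= k={k} rows (have {n_pos} PF / {n_neg} NS)"
        )
    rep_seeds = np.random.SeedSequence(seed).generate_state(repeats)
    per_rep = {m: [] for m in ("accuracy", "sensitivity", "specificity", "auc")}
    cons_types = sorted(set(fm.consonants.tolist()))
    per_cons_rep = {c: {m: [] for m in per_rep} for c in cons_types}

    for r in range(repeats):
        rs = int(rep_seeds[r] % (2**31))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
        pred = np.zeros(len(y), dtype=bool)
        score = np.zeros(len(y))
        for fold, (tr, te) in enumerate(skf.split(fm.X, y)):
            model = fit_bagging(fm.X[tr], y[tr], T=T, seed=rs + fold)
            labels, frac = predict(model, fm.X[te])
            pred[te] = labels == POSITIVE
            score[te] = frac
        m = _confusion_metrics(y, pred)
        m["auc"] = 100.0 * roc_auc_score(y, score)
        for name, val in m.items():
            per_rep[name].append(val)
        for cons in cons_types:
            sel = fm.consonants == cons
            mc = _confusion_metrics(y[sel], pred[sel])
            if len(np.unique(y[sel])) == 2:
                mc["auc"] = 100.0 * roc_auc_score(y[sel], score[sel])
            else:
                mc["auc"] = np.nan
            for name, val in mc.items():
                per_cons_rep[cons][name].append(val)

    def summarize(vals) -> Metric:
        arr = np.asarray(vals, dtype=np.float64)
        arr = arr[np.isfinite(arr)]
        if arr.size == 0:
            return Metric(np.nan, np.nan)
        return Metric(float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0)

    per_cons = {
        c: {name: summarize(v) for name, v in mm.items()}
        for c, mm in per_cons_rep.items()
    }
    return CVResult(
        accuracy=summarize(per_rep["accuracy"]),
        sensitivity=summarize(per_rep["sensitivity"]),
        specificity=summarize(per_rep["specificity"]),
        auc=summarize(per_rep["auc"]),
        per_consonant=per_cons,
        k=k, repeats=repeats, n_trees=T, n_rows=len(y),
        raw=per_rep,
    )


def feature_significance(
    fm: FeatureMatrix,
    alpha: float = 0.01,
    method: str = "welch",
    per_consonant: bool = True,
) -> list[dict]:
    """Two-sample test of pooled per-frame feature values, PF vs NS.

    One report row per stratum (consonant type, or a single pooled "all"
    stratum): the consonant, the p-value and the H decision at ``alpha``.
    Strata missing a class are skipped with a warning.
    """
    strata = sorted(set(fm.consonants.tolist())) if per_consonant else ["all"]
    out = []
    for cons in strata:
        sel = np.ones(len(fm.labels), bool) if cons == "all" else fm.consonants == cons
        pf = fm.X[sel & fm.y].ravel()
        ns = fm.X[sel & ~fm.y].ravel()
        if pf.size < 2 or ns.size < 2:
            log.warning("stratum %r lacks both classes; skipped", cons)
            continue
        if method == "welch":
            p = float(stats.ttest_ind(pf, ns, equal_var=False).pvalue)
        else:
            p = float(stats.mannwhitneyu(pf, ns, alternative="two-sided").pvalue)
        h = significance_flag(pf, ns, alpha=alpha, method=method)
        out.append({"consonant": cons, "p": p, "H": h, "alpha": alpha})
    return out
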