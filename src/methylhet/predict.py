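"""Prediction of CGI hypermethylation susceptibility.

Eight features per CGI — H3K4me3, H3K27me3, H3K36me3 and DNase enrichment
(log(RPKM + 0.001) z-scores), CpG density, normalized CpG density
(observed/expected), GC fraction and starting (control) methylation —
feed a random-forest classifier (100 trees, class weights 1 : nneg/npos)
evaluated with stratified five-fold cross-validation.  Performance is read
off the pooled out-of-fold precision-recall curve; the headline number is
the recall achievable at 5% false discovery rate, i.e. at precision >=
0.95.  Leave-one-feature-out ablation re-runs the same folds without each
feature in turn and ranks features by the drop in PR performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, precision_recall_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.tree import DecisionTreeClassifier

FEATURE_COLUMNS = ["h3k4me3", "h3k27me3", "h3k36me3", "dnase", "cpg_density",
                   "normalized_cpg_density", "gc_fraction",
                   "control_methylation"]

TRACK_COLUMNS = ["h3k4me3", "h3k27me3", "h3k36me3", "dnase"]

METHODS = ("random_forest", "logistic", "naive_bayes", "decision_tree",
           "gradient_boosting")

LOG_PSEUDOCOUNT = 0.001
METH_CUTOFF = 0.2
RPKM_PERCENTILE = 99.0
PRECISION_AT_FDR5 = 0.95


def build_feature_matrix(
    cgi_features: pd.DataFrame,
    track_rpkms: pd.DataFrame,
    control_methylation: pd.DataFrame,
    log_base: str = "natural",
) -> pd.DataFrame:
    """Assemble and normalise the per-CGI predictor table.

    ``cgi_features`` carries cgi_id, cpg_density, normalized_cpg_density,
    gc_fraction (from the genome annotation); ``track_rpkms`` carries
    cgi_id plus raw RPKM columns h3k4me3/h3k27me3/h3k36me3/dnase;
    ``control_methylation`` carries cgi_id and control_methylation, and
    optionally a label column.  Per track, CGIs above that track's own 99th
    RPKM percentile are dropped, the rest log(RPKM + 0.001)-transformed and
    z-scored over the retained set; CGIs with starting methylation >= 0.2
    are then removed so the table describes canonical unmethylated CGIs.
    """
    if log_base not in ("natural", "log10"):
        raise ValueError("log_base must be 'natural' or 'log10'")
    df = cgi_features.merge(track_rpkms, on="cgi_id", how="inner")
    df = df.merge(control_methylation, on="cgi_id", how="inner")
    n_missing = len(cgi_features) - len(df)
    df.attrs["n_missing_track"] = n_missing
    for col in TRACK_COLUMNS:
        cutoff = np.percentile(df[col], RPKM_PERCENTILE)
        df = df.loc[df[col] <= cutoff]
    df = df.loc[df["control_methylation"] < METH_CUTOFF].copy()
    # normalise over the retained set (filter first, then z-score)
    log = np.log if log_base == "natural" else np.log10
    for col in TRACK_COLUMNS:
        x = log(df[col] + LOG_PSEUDOCOUNT)
        sd = x.std(ddof=0)
        df[col] = (x - x.mean()) / sd if sd > 0 else 0.0
    return df.reset_index(drop=True)


def _class_weight_ratio(y: np.ndarray) -> float:
    npos = int(y.sum())
    nneg = int(y.size - npos)
    if npos == 0 or nneg == 0:
        raise ValueError("both classes must be present")
    return nneg / npos


def train_classifier(X, y, method: str = "random_forest", seed: int = 0):
    """Fit one of the five susceptibility classifiers.

    The random forest uses 100 trees with class weights {neg: 1, pos:
    nneg/npos}; gradient boosting uses depth 10, 10 rounds, subsample 0.7
    and positive-class weight nneg/npos; logistic regression, naive Bayes
    and the decision tree run at library defaults.  All fitted models
    expose ``predict_proba``.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    ratio = _class_weight_ratio(y)
    if method == "random_forest":
        model = RandomForestClassifier(
            n_estimators=100, class_weight={0: 1.0, 1: ratio},
            random_state=seed)
    elif method == "logistic":
        # unpenalised, like a plain GLM fit
        model = LogisticRegression(C=np.inf, max_iter=1000)
    elif method == "naive_bayes":
        model = GaussianNB()
    elif method == "decision_tree":
        model = DecisionTreeClassifier(random_state=seed)
    elif method == "gradient_boosting":
        from xgboost import XGBClassifier

        model = XGBClassifier(
            objective="binary:logistic", max_depth=10, n_estimators=10,
            scale_pos_weight=ratio, subsample=0.7, random_state=seed)
    else:
        raise ValueError(f"unknown method '{method}'")
    model.fit(X, y)
    return model


@dataclass
class PrCurve:
    """Pooled out-of-fold precision-recall curve and its summaries."""

    precision: np.ndarray
    recall: np.ndarray
    thresholds: np.ndarray
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)
    auc_pr: float = float("nan")
    recall_at_fdr5: float = float("nan")


def _summarize(scores: np.ndarray, labels: np.ndarray) -> PrCurve:
    precision, recall, thresholds = precision_recall_curve(labels, scores)
    at = precision >= PRECISION_AT_FDR5
    recall_at = float(recall[at].max()) if at.any() else 0.0
    return PrCurve(
        precision=precision, recall=recall, thresholds=thresholds,
        scores=scores, labels=labels,
        auc_pr=float(average_precision_score(labels, scores)),
        recall_at_fdr5=recall_at,
    )


def make_folds(y, k: int = 5, seed: int = 0):
    """Stratified fold assignments, shared across ablations for pairing."""
    y = np.asarray(y, int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(y), y))


def cross_validated_pr(
    X, y,
    method: str = "random_forest",
    k: int = 5,
    seed: int = 0,
    folds=None,
) -> PrCurve:
    """Out-of-fold PR curve of a classifier under stratified k-fold CV.

    Predicted positive-class probabilities of every held-out fold are
    pooled into a single curve.  ``recall_at_fdr5`` is the largest recall
    at precision >= 0.95 (0 when the curve never reaches it).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        small = int(np.argmin(counts))
        raise ValueError(
            f"class {small} has only {counts[small]} members; cannot "
            f"stratify into {k} folds")
    if folds is None:
        folds = make_folds(y, k=k, seed=seed)
    scores = np.zeros(y.size)
    for train, test in folds:
        model = train_classifier(X[train], y[train], method=method,
                                 seed=seed)
        scores[test] = model.predict_proba(X[test])[:, 1]
    return _summarize(scores, y)


def feature_ablation(
    features: pd.DataFrame,
    label_column: str = "label",
    feature_columns=None,
    method: str = "random_forest",
    k: int = 5,
    seed: int = 0,
):
    """Leave-one-feature-out ablation on common folds.

    Returns ``(full_curve, ablation_table)``: the all-features PR curve
    plus one row per ablated feature with its AUC-PR, recall at 5% FDR and
    the deltas versus the full model, ranked by AUC-PR drop (largest drop
    first).
    """
    if feature_columns is None:
        feature_columns = [c for c in FEATURE_COLUMNS
                           if c in features.columns]
    if len(feature_columns) < 2:
        raise ValueError("ablation needs at least two features")
    y = features[label_column].to_numpy(int)
    folds = make_folds(y, k=k, seed=seed)
    full = cross_validated_pr(features[feature_columns], y, method=method,
                              k=k, seed=seed, folds=folds)
    rows = []
    for col in feature_columns:
        kept = [c for c in feature_columns if c != col]
        curve = cross_validated_pr(features[kept], y, method=method,
                                   k=k, seed=seed, folds=folds)
        rows.append({
            "feature": col,
            "auc_pr": curve.auc_pr,
            "recall_at_fdr5": curve.recall_at_fdr5,
            "delta_auc_pr": curve.auc_pr - full.auc_pr,
            "delta_recall_at_fdr5":
                curve.recall_at_fdr5 - full.recall_at_fdr5,
        })
    table = pd.DataFrame(rows).sort_values(
        "delta_auc_pr").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return full, table
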