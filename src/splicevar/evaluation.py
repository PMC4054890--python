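"""Benchmark arithmetic and per-feature ranking.

Metrics follow the conventions of the splicing-prediction literature:
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), FPR = FP/(FP+TN),
*accuracy is the mean of sensitivity and specificity* (the field's
headline "accuracy"; the standard (TP+TN)/N is also reported), and the
Matthews correlation coefficient. Feature ranking trains a linear SVM per
feature (or declared feature subset) under stratified 10-fold CV and
compares fold AUCs against a per-example uniform-random control feature
with a Bonferroni-corrected Welch t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("negative confusion count")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValueError("empty confusion matrix")


def confusion(calls, labels, positive: str = "SAV") -> ConfusionCounts:
    """Cross-tabulate predicted calls against true labels."""
    calls, labels = list(calls), list(labels)
    if len(calls) != len(labels):
        raise ValueError("calls and labels differ in length")
    tp = fp = tn = fn = 0
    for c, y in zip(calls, labels):
        if c == positive and y == positive:
            tp += 1
        elif c == positive:
            fp += 1
        elif y == positive:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


@dataclass
class MetricsReport:
    sensitivity_pct: float = None
    specificity_pct: float = None
    fpr_pct: float = None
    accuracy_pct: float = None  # mean of sensitivity and specificity
    accuracy_standard_pct: float = None  # (TP+TN)/N
    mcc: float = None
    auc_pct: float = None
    undefined: tuple = ()

    def rounded(self, ndigits: int = 1) -> dict:
        out = {}
        for k in (
            "sensitivity_pct",
            "specificity_pct",
            "fpr_pct",
            "accuracy_pct",
            "accuracy_standard_pct",
            "auc_pct",
        ):
            v = getattr(self, k)
            out[k] = None if v is None else round(v, ndigits)
        out["mcc"] = None if self.mcc is None else round(self.mcc, 2)
        return out


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Sensitivity/specificity/FPR/accuracy/MCC from a confusion matrix.

    Metrics with zero denominators are left None and listed in
    ``undefined`` instead of raising.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    undefined = []
    rep = MetricsReport()
    if tp + fn > 0:
        rep.sensitivity_pct = 100.0 * tp / (tp + fn)
    else:
        undefined.append("sensitivity")
    if tn + fp > 0:
        rep.specificity_pct = 100.0 * tn / (tn + fp)
        rep.fpr_pct = 100.0 * fp / (fp + tn)
    else:
        undefined.append("specificity")
    if rep.sensitivity_pct is not None and rep.specificity_pct is not None:
        rep.accuracy_pct = (rep.sensitivity_pct + rep.specificity_pct) / 2.0
    rep.accuracy_standard_pct = 100.0 * (tp + tn) / (tp + fp + tn + fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom > 0:
        rep.mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    else:
        undefined.append("mcc")
    rep.undefined = tuple(undefined)
    return rep


def roc_auc(scores, labels, positive: str = "SAV"):
    """ROC curve and AUC (ties get half credit, the Mann-Whitney view).

    Returns (fpr, tpr, auc) with auc in [0,1].
    """
    y = np.array([1 if l == positive else 0 for l in labels])
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise ValueError("both classes must be present for a ROC curve")
    fpr, tpr, _ = roc_curve(y, s)
    return fpr, tpr, float(roc_auc_score(y, s))


def _fold_aucs(col: np.ndarray, y: np.ndarray, folds: int, seed: int):
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for train, test in skf.split(col, y):
        clf = make_pipeline(StandardScaler(), LinearSVC())
        clf.fit(col[train], y[train])
        dec = clf.decision_function(col[test])
        aucs.append(roc_auc_score(y[test], dec))
    return np.array(aucs)


def rank_features(
    features: pd.DataFrame,
    labels: pd.Series,
    groups: dict = None,
    folds: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Single-feature(-subset) linear-SVM ranking with a random control.

    ``groups`` maps a rank name to a list of columns (default: each column
    alone). A uniform-random control feature is ranked identically; each
    group's fold AUCs are compared to the control's by Welch's t-test with
    Bonferroni correction over the number of ranked groups. Constant
    groups record AUC 0.5 and skip the test.
    """
    y = labels.reindex(features.index).to_numpy()
    if groups is None:
        groups = {c: [c] for c in features.columns}
    rng = np.random.default_rng(seed)
    control = rng.uniform(size=len(features)).reshape(-1, 1)
    control_aucs = _fold_aucs(control, y, folds, seed)
    rows = []
    n_tests = len(groups)
    for name, cols in groups.items():
        X = features[cols].to_numpy(dtype=float)
        if np.allclose(X.std(axis=0), 0):
            rows.append(
                {
                    "feature": name,
                    "mean_auc": 0.5,
                    "fold_aucs": None,
                    "p_corrected": np.nan,
                    "significant": False,
                }
            )
            continue
        aucs = _fold_aucs(X, y, folds, seed)
        t, p = stats.ttest_ind(aucs, control_aucs, equal_var=False)
        p_corr = min(1.0, float(p) * n_tests)
        rows.append(
            {
                "feature": name,
                "mean_auc": float(aucs.mean()),
                "fold_aucs": aucs,
                "p_corrected": p_corr,
                "significant": bool(p_corr < alpha),
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    out.attrs["control_mean_auc"] = float(control_aucs.mean())
    return out


LABEL_ALIASES = {
    "sav": "SAV",
    "positive": "SAV",
    "pos": "SAV",
    "1": "SAV",
    "snv": "SNV",
    "negative": "SNV",
    "neg": "SNV",
    "0": "SNV",
}


def load_variant_table(path) -> pd.DataFrame:
    """Load a labeled variant TSV (id, contig, pos, ref, alt, label, ...).

    Labels are normalized to SAV/SNV; 1-based positions in the file. Used
    both for training tables and unseen evaluation sets.
    """
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    required = {"contig", "pos", "ref", "alt", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["label"] = (
        df["label"].astype(str).str.strip().str.lower().map(LABEL_ALIASES)
    )
    if df["label"].isna().any():
        raise ValueError(f"{path}: unrecognized labels present")
    if "id" not in df.columns:
        df["id"] = [
            f"{c}:{p}{r}>{a}"
            for c, p, r, a in zip(df.contig, df.pos, df.ref, df.alt)
        ]
    return df
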