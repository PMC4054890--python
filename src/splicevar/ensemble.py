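"""Balanced Random-Forest ensemble and the general score.

Training sets for this problem are heavily imbalanced (few labeled
splice-altering variants, many putatively neutral ones). Rather than
down-weighting, the negatives are partitioned into balanced subsets, one
Random Forest is trained per subset against the full positive set, and a
variant's *general score* is the arithmetic mean of the per-forest
positive-class probabilities. A general score >= 0.60 calls the variant a
SAV (splice-altering variant); anything below is an SNV (splice-neutral).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .sequence_features import FEATURE_NAMES, schema_hash

DEFAULT_THRESHOLD = 0.60
DEFAULT_N_TREES = 500


def partition_negatives(n_pos: int, negative_ids, seed: int, remainder: str = "topup"):
    """Split negative ids into balanced subsets of size ``n_pos``.

    The first floor(n_neg/n_pos) subsets are disjoint and cover negatives
    without replacement; a final remainder subset (if any) is topped up to
    n_pos by sampling without replacement from already-used negatives
    (``remainder='topup'``, default) or dropped (``remainder='drop'``).
    Deterministic given the seed.
    """
    ids = list(negative_ids)
    if n_pos < 1:
        raise ValueError("need at least one positive example")
    if len(ids) < n_pos:
        raise ValueError(
            f"{len(ids)} negatives cannot balance {n_pos} positives"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    n_full = len(ids) // n_pos
    subsets = [shuffled[i * n_pos : (i + 1) * n_pos] for i in range(n_full)]
    rest = shuffled[n_full * n_pos :]
    if rest:
        if remainder == "topup":
            used = shuffled[: n_full * n_pos]
            extra = rng.choice(len(used), size=n_pos - len(rest), replace=False)
            subsets.append(rest + [used[i] for i in extra])
        elif remainder == "drop":
            pass
        else:
            raise ValueError(f"unknown remainder policy {remainder!r}")
    return subsets


@dataclass
class PredictionScore:
    general_score: float
    per_model: tuple
    call: str  # 'SAV' or 'SNV'


@dataclass
class EnsembleModel:
    """One RF per balanced subset; mean probability is the general score."""

    models: list
    subset_ids: list
    seed: int
    feature_schema: str
    threshold: float = DEFAULT_THRESHOLD
    rf_params: dict = field(default_factory=dict)
    train_ids: list = field(default_factory=list)  # per-model training order

    def __post_init__(self):
        if not self.models:
            raise ValueError("ensemble needs at least one base model")

    @property
    def n_models(self) -> int:
        return len(self.models)

    def _check(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != FEATURE_NAMES:
            raise ValueError("feature table does not match the model's schema")
        if self.feature_schema != schema_hash():
            raise ValueError("model was trained under a different feature schema")
        return X.to_numpy(dtype=float)

    def per_model_scores(self, X: pd.DataFrame) -> np.ndarray:
        """(n_models, n_variants) positive-class probabilities."""
        arr = self._check(X)
        out = np.empty((self.n_models, len(arr)))
        for i, m in enumerate(self.models):
            pos_col = list(m.classes_).index(1)
            out[i] = m.predict_proba(arr)[:, pos_col]
        return out

    def general_scores(self, X: pd.DataFrame) -> np.ndarray:
        return self.per_model_scores(X).mean(axis=0)

    def honest_scores(self, X: pd.DataFrame) -> np.ndarray:
        """General scores that avoid training-set memorization.

        For examples that were inside a base model's training set, that
        model contributes its out-of-bag probability instead of the fitted
        one (a fully grown forest reproduces its own training labels, so
        fitted probabilities cannot flag mislabeled training negatives).
        Examples never seen in training get the ordinary general score.
        """
        per = self.per_model_scores(X)
        col_of = {vid: j for j, vid in enumerate(X.index)}
        for i, m in enumerate(self.models):
            if not self.train_ids or not hasattr(m, "oob_decision_function_"):
                continue
            pos_col = list(m.classes_).index(1)
            oob = m.oob_decision_function_
            for row, vid in enumerate(self.train_ids[i]):
                j = col_of.get(vid)
                if j is None:
                    continue
                per[i, j] = oob[row, pos_col]  # may be nan if never oob
        return np.nanmean(per, axis=0)

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        scores = self.general_scores(X)
        calls = np.where(scores >= self.threshold, "SAV", "SNV")
        return pd.DataFrame({"score": scores, "call": calls}, index=X.index)

    def score_one(self, x: pd.Series) -> PredictionScore:
        X = x.to_frame().T[FEATURE_NAMES]
        per = tuple(self.per_model_scores(X)[:, 0])
        g = float(np.mean(per))
        return PredictionScore(g, per, "SAV" if g >= self.threshold else "SNV")

    def save(self, path, extra: dict = None) -> None:
        joblib.dump(
            {
                "kind": "splicevar-ensemble",
                "ensemble": self,
                "schema_hash": self.feature_schema,
                "seed": self.seed,
                "extra": extra or {},
            },
            path,
        )


def load_ensemble(path):
    payload = joblib.load(path)
    if payload.get("kind") != "splicevar-ensemble":
        raise ValueError(f"{path} is not an ensemble archive")
    return payload["ensemble"], payload.get("extra", {})


def train_ensemble(
    features: pd.DataFrame,
    labels: pd.Series,
    seed: int,
    n_trees: int = DEFAULT_N_TREES,
    threshold: float = DEFAULT_THRESHOLD,
    remainder: str = "topup",
    rf_params: dict = None,
) -> EnsembleModel:
    """Train the balanced ensemble.

    ``labels`` is 1 for SAV, 0 for SNV, indexed like ``features``. One
    forest is trained per balanced negative subset; forests get distinct
    but seed-derived random states, so the whole ensemble is reproducible.
    """
    if list(features.columns) != FEATURE_NAMES:
        raise ValueError("feature table does not match the current schema")
    labels = labels.reindex(features.index)
    pos_ids = list(labels.index[labels == 1])
    neg_ids = list(labels.index[labels == 0])
    if not pos_ids or not neg_ids:
        raise ValueError("both classes must be present")
    # balance the majority class against the minority, whichever way the
    # imbalance runs (self-training can leave positives in the majority)
    if len(neg_ids) >= len(pos_ids):
        subsets = partition_negatives(len(pos_ids), neg_ids, seed, remainder)
        fixed, fixed_label, subset_label = pos_ids, 1, 0
    else:
        subsets = partition_negatives(len(neg_ids), pos_ids, seed, remainder)
        fixed, fixed_label, subset_label = neg_ids, 0, 1
    params = dict(rf_params or {})
    params.setdefault("n_estimators", n_trees)
    params.setdefault("n_jobs", 1)
    params.setdefault("oob_score", True)  # enables honest training scores
    # the design matrix is dominated by sparse k-mer counts: give each
    # split a larger feature budget than the sqrt heuristic, and keep
    # leaves >= 3 examples so tree votes are graded rather than 0/1
    params.setdefault("max_features", 0.1)
    params.setdefault("min_samples_leaf", 3)
    models = []
    train_ids = []
    for i, subset in enumerate(subsets):
        idx = fixed + subset
        X = features.loc[idx].to_numpy(dtype=float)
        y = np.array([fixed_label] * len(fixed) + [subset_label] * len(subset))
        rf = RandomForestClassifier(random_state=(seed + 1000 * (i + 1)) % 2**31, **params)
        rf.fit(X, y)
        models.append(rf)
        train_ids.append(list(idx))
    return EnsembleModel(
        models=models,
        subset_ids=subsets,
        seed=seed,
        feature_schema=schema_hash(),
        threshold=threshold,
        rf_params=params,
        train_ids=train_ids,
    )
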