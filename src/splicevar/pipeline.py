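"""Three-iteration training regimen and splicing-mechanism hypotheses.

The labeled negative sets for this problem are noisy: a sizeable minority
of "neutral" disease-derived variants in fact disrupt splicing. The
regimen therefore runs three iterations:

  Iter. 1  train the balanced ensemble on the initial sets;
  Iter. 2  drop negatives the Iter.1 model scores at or above the removal
           threshold (default 0.80) and retrain;
  Iter. 3  self-training: score the unlabeled pool with the Iter.2 model,
           add examples scoring >= 0.90 as positives and <= 0.10 as
           negatives, retrain.

Every removal/addition is journalled with the score that justified it, so
the final sets are replayable from the Iter.1 sets plus the ledger.

For a predicted SAV, mechanism hypotheses compare four splicing properties
against their distributions over predicted-neutral variants via Z scores:
natural-site loss (lower tail of the site-strength delta), cryptic-site
activation (upper tail of the best cryptic score), exon skipping (upper
tail of the ESE-loss + ESS-gain burden) and exon retention (upper tail of
the ESS-loss + ESE-gain burden, emitted only for non-constitutive target
exons). A one-sided normal P < 0.05 marks a hypothesis confident.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble import DEFAULT_N_TREES, DEFAULT_THRESHOLD, EnsembleModel, train_ensemble

MECHANISMS = (
    "natural splice site loss",
    "cryptic splice site activation",
    "exon skipping",
    "exon retention",
)

# property name -> tail of the disruption direction
_PROPERTY_TAIL = {
    "natural splice site loss": ("delta_natural_site_prop", "lower"),
    "cryptic splice site activation": ("max_cryptic_prop", "upper"),
    "exon skipping": ("skipping_burden", "upper"),
    "exon retention": ("retention_burden", "upper"),
}

PROPERTY_NAMES = (
    "delta_natural_site_prop",
    "max_cryptic_prop",
    "skipping_burden",
    "retention_burden",
)


def mechanism_properties(features: pd.DataFrame) -> pd.DataFrame:
    """Derive the four mechanism-linked properties from feature vectors.

    Burdens are count-weighted ESR-HS scores: each transition count is
    multiplied by the variant's ESR-HS feature for that transition type.
    """
    return pd.DataFrame(
        {
            "delta_natural_site_prop": features["delta_natural_site"],
            "max_cryptic_prop": features["max_cryptic_score"],
            "skipping_burden": (
                features["esr_ese_loss"] * features["esrhs_ese_loss"]
                + features["esr_ess_gain"] * features["esrhs_ess_gain"]
                + features["esr_ese_to_ess"]
                * (features["esrhs_ese_loss"] + features["esrhs_ess_gain"])
            ),
            "retention_burden": (
                features["esr_ess_loss"] * features["esrhs_ess_loss"]
                + features["esr_ese_gain"] * features["esrhs_ese_gain"]
                + features["esr_ess_to_ese"]
                * (features["esrhs_ess_loss"] + features["esrhs_ese_gain"])
            ),
        },
        index=features.index,
    )


@dataclass
class ReferenceDistributions:
    """Mean/sd of each mechanism property over predicted-neutral variants."""

    stats: dict  # name -> (mean, sd)
    n: int

    def __post_init__(self):
        if self.n < 30:
            raise ValueError(
                f"need >= 30 predicted-neutral variants, got {self.n}"
            )
        for name, (_, sd) in self.stats.items():
            if not sd > 0:
                raise ValueError(f"zero-variance reference property {name}")

    def z(self, name: str, value: float) -> float:
        mean, sd = self.stats[name]
        return (value - mean) / sd


def build_reference_distributions(
    neutral_features: pd.DataFrame,
) -> ReferenceDistributions:
    props = mechanism_properties(neutral_features)
    return ReferenceDistributions(
        stats={
            name: (float(props[name].mean()), float(props[name].std(ddof=1)))
            for name in PROPERTY_NAMES
        },
        n=len(props),
    )


@dataclass
class MechanismHypothesis:
    mechanism: str
    z: float
    p: float
    confident: bool


def hypothesize_mechanism(
    feature_row: pd.Series,
    prediction,
    refdist: ReferenceDistributions,
    constitutive_exon: bool,
    alpha: float = 0.05,
):
    """All mechanism hypotheses for one predicted SAV, ascending P.

    The exon-retention hypothesis is only evaluated when the target exon is
    non-constitutive (retention of an exon present in every isoform is not
    a coherent outcome).
    """
    if getattr(prediction, "call", prediction) != "SAV":
        raise ValueError("mechanism hypotheses are generated for predicted SAVs only")
    props = mechanism_properties(feature_row.to_frame().T).iloc[0]
    out = []
    for mech in MECHANISMS:
        prop, tail = _PROPERTY_TAIL[mech]
        if mech == "exon retention" and constitutive_exon:
            continue
        z = refdist.z(prop, float(props[prop]))
        p = stats.norm.cdf(z) if tail == "lower" else stats.norm.sf(z)
        p = float(min(max(p, np.nextafter(0, 1)), 1.0 - 1e-16))
        out.append(MechanismHypothesis(mech, float(z), p, p < alpha))
    out.sort(key=lambda h: h.p)
    return out


@dataclass
class IterationConfig:
    seed: int
    removal_threshold: float = 0.80
    positive_threshold: float = 0.90
    negative_threshold: float = 0.10
    max_added_per_class: int = None
    n_trees: int = DEFAULT_N_TREES
    threshold: float = DEFAULT_THRESHOLD
    rf_params: dict = None

    def __post_init__(self):
        if not 0.5 < self.removal_threshold <= 1.0:
            raise ValueError("removal threshold must lie in (0.5, 1]")
        if not self.negative_threshold < 0.5 < self.positive_threshold:
            raise ValueError(
                "self-labeling thresholds must straddle 0.5 "
                "(negative < 0.5 < positive)"
            )


@dataclass
class IterationState:
    models: dict  # iteration -> EnsembleModel
    pos_ids: dict  # iteration -> list of ids
    neg_ids: dict
    removal_ledger: pd.DataFrame  # id, score (Iter.2 removals)
    addition_ledger: pd.DataFrame  # id, score, label (Iter.3 additions)
    warnings: list = field(default_factory=list)

    def final_model(self) -> EnsembleModel:
        return self.models[max(self.models)]


def run_iterations(
    pos_features: pd.DataFrame,
    neg_features: pd.DataFrame,
    unlabeled_features: pd.DataFrame,
    config: IterationConfig,
) -> IterationState:
    """Run the full three-iteration regimen over featurized sets."""
    warnings = []

    def _train(pos_ids, neg_ids, seed):
        X = pd.concat([pos_features.loc[pos_ids], neg_features_all.loc[neg_ids]])
        y = pd.Series(
            [1] * len(pos_ids) + [0] * len(neg_ids), index=X.index
        )
        return train_ensemble(
            X,
            y,
            seed=seed,
            n_trees=config.n_trees,
            threshold=config.threshold,
            rf_params=config.rf_params,
        )

    # Iter.3 may add unlabeled examples to either class; keep one lookup
    # table per role so ledger replay stays trivial.
    pos_features = pos_features.copy()
    neg_features_all = pd.concat([neg_features, unlabeled_features])
    pos1 = list(pos_features.index)
    neg1 = list(neg_features.index)

    model1 = _train(pos1, neg1, config.seed)

    # Iter.2: clean the negative set. Honest (out-of-model / out-of-bag)
    # scores are used because a fitted forest reproduces its own training
    # labels, which would make this step a no-op by construction.
    neg_scores = pd.Series(
        model1.honest_scores(neg_features.loc[neg1]), index=neg1
    )
    removed = neg_scores[neg_scores >= config.removal_threshold]
    neg2 = [i for i in neg1 if i not in set(removed.index)]
    if not neg2:
        raise ValueError("removal threshold eliminated every negative example")
    removal_ledger = pd.DataFrame(
        {"id": removed.index, "score": removed.values, "iteration": 2}
    )
    model2 = _train(pos1, neg2, config.seed + 1)

    # Iter.3: self-training from the unlabeled pool
    pos3, neg3 = list(pos1), list(neg2)
    additions = []
    if len(unlabeled_features) == 0:
        warnings.append("empty unlabeled pool: Iter.3 equals Iter.2")
        model3 = model2
    else:
        u_scores = pd.Series(
            model2.general_scores(unlabeled_features), index=unlabeled_features.index
        )
        new_pos = u_scores[u_scores >= config.positive_threshold].sort_values(
            ascending=False
        )
        new_neg = u_scores[u_scores <= config.negative_threshold].sort_values()
        if config.max_added_per_class is not None:
            new_pos = new_pos.iloc[: config.max_added_per_class]
            new_neg = new_neg.iloc[: config.max_added_per_class]
        for i, s in new_pos.items():
            additions.append({"id": i, "score": s, "label": "SAV", "iteration": 3})
        for i, s in new_neg.items():
            additions.append({"id": i, "score": s, "label": "SNV", "iteration": 3})
        pos_features = pd.concat(
            [pos_features, unlabeled_features.loc[new_pos.index]]
        )
        pos3 = pos3 + list(new_pos.index)
        neg3 = neg3 + list(new_neg.index)
        if not additions:
            warnings.append("no confident unlabeled examples at Iter.3")
        model3 = _train(pos3, neg3, config.seed + 2)

    return IterationState(
        models={1: model1, 2: model2, 3: model3},
        pos_ids={1: pos1, 2: pos1, 3: pos3},
        neg_ids={1: neg1, 2: neg2, 3: neg3},
        removal_ledger=removal_ledger,
        addition_ledger=pd.DataFrame(
            additions, columns=["id", "score", "label", "iteration"]
        ),
        warnings=warnings,
    )


def replay_ledgers(
    pos1, neg1, removal_ledger: pd.DataFrame, addition_ledger: pd.DataFrame
):
    """Reconstruct the Iter.3 sets from the Iter.1 sets plus the ledgers."""
    removed = set(removal_ledger["id"])
    neg3 = [i for i in neg1 if i not in removed]
    pos3 = list(pos1)
    for _, row in addition_ledger.iterrows():
        if row["label"] == "SAV":
            pos3.append(row["id"])
        else:
            neg3.append(row["id"])
    return pos3, neg3
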