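"""Decision rule recommending PWM or APFA from sample features.

Each TFBS sample becomes one training instance: its six-feature vector
and a binary label derived from the nested-CV comparison (1 when
Cohen's D >= 0.4, i.e. the APFA clearly outperformed; 0 otherwise).  A
depth-limited Gini decision tree is fit on these instances and exported
as an explicit, JSON-serialisable rule whose splits read
"feature >= threshold goes to the APFA-leaning right branch" — the
same inclusive convention as the D >= 0.4 label itself.

Shipping note: the default rule bundled with :func:`default_rule` was
retrained on this package's synthetic corpus and its thresholds are
synthetic-data values, not published ones; retrain on your own labeled
corpus for production use.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.tree import DecisionTreeClassifier

from .dependency_features import FEATURE_NAMES, FeatureVector, extract_features
from .evaluation import CVConfig, ModelComparison, outer_cv
from .negatives import generate_nonpositive
from .sequence_io import NullModel

LABEL_NAMES = {0: "PWM", 1: "APFA"}


@dataclass
class LabeledFeatureTable:
    features: list[FeatureVector]
    labels: np.ndarray  # 0 = PWM-preferred, 1 = APFA-preferred
    comparisons: list[ModelComparison] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.features) != self.labels.size:
            raise ValueError("features and labels must have equal length")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary (0 = PWM, 1 = APFA)")

    def X(self) -> np.ndarray:
        return np.vstack([f.as_array() for f in self.features])


@dataclass(frozen=True)
class DecisionRule:
    """Explicit decision tree: nested dicts of splits ending in leaves.

    A split node is {"feature", "threshold", "left", "right"}; samples
    with feature >= threshold go right.  A leaf is {"leaf": "APFA"|"PWM"}.
    """

    root: dict
    max_depth: int = 3

    def to_json(self) -> str:
        return json.dumps({"max_depth": self.max_depth, "root": self.root}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DecisionRule":
        obj = json.loads(text)
        return cls(root=obj["root"], max_depth=obj["max_depth"])


def _export_node(tree, node: int) -> dict:
    if tree.children_left[node] == -1:  # leaf
        counts = tree.value[node][0]
        return {"leaf": LABEL_NAMES[int(np.argmax(counts))]}
    return {
        "feature": FEATURE_NAMES[tree.feature[node]],
        "threshold": float(tree.threshold[node]),
        "left": _export_node(tree, tree.children_left[node]),
        "right": _export_node(tree, tree.children_right[node]),
    }


def train_tree(
    table: LabeledFeatureTable,
    max_depth: int = 3,
    seed: int = 11,
) -> tuple[DecisionRule, dict[str, float], tuple[float, float]]:
    """Fit the preference tree and estimate its accuracy.

    Returns the exported rule, the per-feature Gini importances
    (summing to 1) and the stratified k-fold CV accuracy as
    (mean, standard deviation).  The fold count comes from the caller's
    corpus size: 10 folds by default, reduced (with a warning) when the
    rarer class has fewer members than folds.
    """
    y = table.labels
    classes, class_counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both preference classes must be present to train")
    X = table.X()
    clf = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
    n_splits = 10
    min_class = int(class_counts.min())
    if min_class < n_splits:
        warnings.warn(
            f"reducing stratified CV folds from {n_splits} to {min_class} "
            "(rarer class too small)",
            stacklevel=2,
        )
        n_splits = min_class
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    accs = cross_val_score(
        DecisionTreeClassifier(max_depth=max_depth, random_state=seed), X, y, cv=cv
    )
    clf.fit(X, y)
    importances = dict(zip(FEATURE_NAMES, clf.feature_importances_.tolist()))
    rule = DecisionRule(root=_export_node(clf.tree_, 0), max_depth=max_depth)
    return rule, importances, (float(accs.mean()), float(accs.std()))


def apply_rule(features: FeatureVector, rule: DecisionRule) -> str:
    """Follow the rule's splits for one feature vector; returns "APFA" or "PWM"."""
    node = rule.root
    while "leaf" not in node:
        value = getattr(features, node["feature"], None)
        if value is None:
            raise ValueError(f"feature vector lacks {node['feature']!r}")
        node = node["right"] if value >= node["threshold"] else node["left"]
    return node["leaf"]


def build_labeled_corpus(
    samples,
    genomes,
    cfg: CVConfig,
    null: NullModel,
    **negatives_kwargs,
) -> LabeledFeatureTable:
    """Run the full labeling pipeline over a collection of samples.

    ``genomes`` is either one background genome (shared) or a sequence
    of genomes matched to ``samples``.  For each sample the features are
    extracted, non-positives generated, the nested CV run, and the label
    assigned by the D >= 0.4 rule.  Extra keyword arguments (e.g.
    ``n_fragments``) are forwarded to :func:`generate_nonpositive`.
    """
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError("corpus needs at least 2 samples")
    if isinstance(genomes, str) or not hasattr(genomes, "__len__"):
        genomes = [genomes] * len(samples)
    if len(genomes) != len(samples):
        raise ValueError("genomes must be one genome or one per sample")
    feats, labels, comps = [], [], []
    for sample, genome in zip(samples, genomes):
        feats.append(extract_features(sample, null))
        negs = generate_nonpositive(
            genome, sample.l, sample.n, seed=cfg.seed, **negatives_kwargs
        )
        mc = outer_cv(sample, negs, cfg, null)
        comps.append(mc)
        labels.append(1 if mc.preferred == "APFA" else 0)
    return LabeledFeatureTable(features=feats, labels=np.array(labels), comparisons=comps)


#: Depth-3 rule retrained on a 40-sample synthetic corpus (seed 11,
#: half with a deterministic position coupling).  The threshold is a
#: synthetic-data value — retrain for real data.
_DEFAULT_RULE_JSON = """
{
  "max_depth": 3,
  "root": {
    "feature": "max_theils_u",
    "threshold": 0.5540059581398964,
    "left": {"leaf": "PWM"},
    "right": {"leaf": "APFA"}
  }
}
"""


def default_rule() -> DecisionRule:
    """The bundled synthetic-corpus rule (see module docstring caveat)."""
    return DecisionRule.from_json(_DEFAULT_RULE_JSON)
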