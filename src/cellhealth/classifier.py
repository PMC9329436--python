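"""Cell Health Index (CHI) classifier and the eight-endpoint fingerprint.

A two-class ("yes" = expectation of high cell stress vs "no") logistic
model is trained on a labelled compound library of 24-feature phenotypes.
The CHI for a test compound is the fitted probability of "yes"-class
membership.  Alongside the full 24-feature model, eight lower-dimensional
sub-classifiers are trained on channel subsets mapped to cell-stress
endpoints (e.g. cell morphology (CM) uses only forward and side scatter),
yielding a "biological fingerprint" of endpoint probabilities.

Model selection operationalises "most parsimonious model with maximum
class separation" as elastic-net-regularised logistic regression whose
penalty is chosen by repeated stratified cross-validation on held-out
log-likelihood, preferring the most-regularised model within one standard
error of the best (the 1-SE rule).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .errors import DegenerateTrainingError, SchemaError
from .qf import MAX_RATE, RANGE, PhenotypeVector, channel_feature_names

LABEL_YES = "yes"
LABEL_NO = "no"

ENDPOINT_ORDER = ("CM", "CMI", "ROS", "GSH", "NMI1", "CC", "NMI2", "MMP")

#: endpoint code → channels whose (max-rate, range) feature pairs feed the
#: sub-classifier.  CM = {FSC, SSC} is fixed by the assay design; the rest
#: is the package's documented interpretation and is plain configuration.
DEFAULT_ENDPOINT_CHANNELS: dict[str, tuple[str, ...]] = {
    "CM": ("FSC", "SSC"),                       # cell morphology
    "CMI": ("CalceinAM", "SYTOXRed"),           # cell membrane integrity
    "ROS": ("MitoSOXRed",),                     # reactive superoxide species
    "GSH": ("Monobromobimane",),                # glutathione
    "NMI1": ("DCV_W",),                         # nuclear membrane integrity 1
    "CC": ("DCV",),                             # cell cycle
    "NMI2": ("PI",),                            # nuclear membrane integrity 2
    "MMP": ("JC9_green", "JC9_red"),            # mitochondrial depolarization
}


@dataclass(frozen=True)
class EndpointSpec:
    code: str
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.channels:
            raise SchemaError(f"endpoint {self.code!r} has no mapped channels")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return channel_feature_names(list(self.channels))


def default_endpoint_specs() -> list[EndpointSpec]:
    return [EndpointSpec(code=c, channels=DEFAULT_ENDPOINT_CHANNELS[c])
            for c in ENDPOINT_ORDER]


@dataclass(frozen=True)
class TrainingExample:
    compound_id: str
    phenotype: PhenotypeVector
    label: str

    def __post_init__(self) -> None:
        if self.label not in (LABEL_YES, LABEL_NO):
            raise SchemaError(f"label must be {LABEL_YES!r} or {LABEL_NO!r}")


class CellHealthClassifier(BaseEstimator, ClassifierMixin):
    """Elastic-net logistic risk classifier with 1-SE parsimony selection.

    Parameters
    ----------
    Cs : tuple of float
        Inverse regularisation strengths searched (glmnet-style grid).
    l1_ratios : tuple of float
        Elastic-net mixing values searched (1.0 = pure lasso).
    cv_folds, cv_repeats : int
        Repeated stratified K-fold used for model selection.
    class_weight : "balanced" or None
        Class-weighted likelihood; prevalence of the two outcome classes
        in a curated library is arbitrary, so "balanced" is the default.
    random_state : int or None
        Controls fold assignment and the saga solver; mandatory for
        reproducible training in pipeline use.

    Fitted attributes: ``coef_``, ``intercept_`` (standardised-feature
    space), ``scaler_``, ``classes_``, ``best_params_``, ``cv_results_``.
    """

    def __init__(self, Cs=(0.01, 0.0316, 0.1, 0.316, 1.0, 3.16, 10.0),
                 l1_ratios=(0.5, 1.0), cv_folds=5, cv_repeats=10,
                 class_weight="balanced", max_iter=5000, random_state=None):
        self.Cs = Cs
        self.l1_ratios = l1_ratios
        self.cv_folds = cv_folds
        self.cv_repeats = cv_repeats
        self.class_weight = class_weight
        self.max_iter = max_iter
        self.random_state = random_state

    def _make_base(self, C, l1_ratio):
        return LogisticRegression(
            solver="saga", C=C, l1_ratio=l1_ratio,
            class_weight=self.class_weight, max_iter=self.max_iter,
            random_state=self.random_state, tol=1e-4)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D and aligned with y")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise DegenerateTrainingError(
                "training requires both outcome classes; got only "
                f"{classes.tolist()}")
        if counts.min() < 2:
            raise DegenerateTrainingError("need at least 2 examples per class")

        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)

        cv = RepeatedStratifiedKFold(
            n_splits=self.cv_folds, n_repeats=self.cv_repeats,
            random_state=self.random_state)
        splits = list(cv.split(Xs, y))

        records = []
        for C in self.Cs:
            for l1 in self.l1_ratios:
                scores = []
                for tr, te in splits:
                    m = self._make_base(C, l1).fit(Xs[tr], y[tr])
                    p = m.predict_proba(Xs[te])
                    scores.append(-log_loss(y[te], p, labels=m.classes_))
                scores = np.asarray(scores)
                records.append({
                    "C": C, "l1_ratio": l1,
                    "mean_score": float(scores.mean()),
                    "se_score": float(scores.std(ddof=1) / np.sqrt(len(scores))),
                })
        self.cv_results_ = pd.DataFrame(records)

        best = self.cv_results_.loc[self.cv_results_["mean_score"].idxmax()]
        threshold = best["mean_score"] - best["se_score"]
        eligible = self.cv_results_[self.cv_results_["mean_score"] >= threshold]
        # parsimony: strongest penalty (smallest C), then sparsest mix
        chosen = eligible.sort_values(
            ["C", "l1_ratio"], ascending=[True, False]).iloc[0]
        self.best_params_ = {"C": float(chosen["C"]),
                             "l1_ratio": float(chosen["l1_ratio"])}

        final = self._make_base(**self.best_params_).fit(Xs, y)
        self.model_ = final
        self.classes_ = final.classes_
        self.coef_ = final.coef_
        self.intercept_ = final.intercept_
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self.scaler_.transform(
            np.asarray(X, dtype=float)))

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(self.scaler_.transform(
            np.asarray(X, dtype=float)))

    def prob_yes(self, X):
        """Probability of the high-stress ("yes") class for each row."""
        proba = self.predict_proba(X)
        idx = list(self.classes_).index(LABEL_YES)
        return proba[:, idx]


@dataclass
class RiskModel:
    """Trained CHI model: coefficients, standardisation, CV record."""

    feature_names: tuple[str, ...]
    classifier: CellHealthClassifier
    cv_record: dict
    n_train: int

    def _align(self, phenotype: PhenotypeVector) -> np.ndarray:
        missing = set(self.feature_names) - set(phenotype.feature_names)
        if missing:
            raise SchemaError(f"phenotype features do not match the model; "
                              f"missing {sorted(missing)}")
        order = [phenotype.feature_names.index(n) for n in self.feature_names]
        return phenotype.features[order]

    def score(self, phenotype: PhenotypeVector) -> float:
        return float(self.classifier.prob_yes(self._align(phenotype)[None, :])[0])

    # ---- JSON serialization -------------------------------------------
    def to_json(self, path=None) -> str:
        clf = self.classifier
        payload = {
            "feature_names": list(self.feature_names),
            "params": clf.get_params(),
            "best_params": clf.best_params_,
            "classes": list(clf.classes_),
            "coef": clf.coef_.tolist(),
            "intercept": clf.intercept_.tolist(),
            "scaler_mean": clf.scaler_.mean_.tolist(),
            "scaler_scale": clf.scaler_.scale_.tolist(),
            "cv_record": self.cv_record,
            "n_train": self.n_train,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RiskModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        params = dict(payload["params"])
        for k in ("Cs", "l1_ratios"):
            params[k] = tuple(params[k])
        clf = CellHealthClassifier(**params)
        clf.best_params_ = payload["best_params"]
        inner = clf._make_base(**clf.best_params_)
        inner.classes_ = np.asarray(payload["classes"])
        inner.coef_ = np.asarray(payload["coef"])
        inner.intercept_ = np.asarray(payload["intercept"])
        clf.model_ = inner
        clf.classes_ = inner.classes_
        clf.coef_ = inner.coef_
        clf.intercept_ = inner.intercept_
        scaler = StandardScaler()
        scaler.mean_ = np.asarray(payload["scaler_mean"])
        scaler.scale_ = np.asarray(payload["scaler_scale"])
        scaler.var_ = scaler.scale_ ** 2
        scaler.n_features_in_ = len(scaler.mean_)
        clf.scaler_ = scaler
        clf.n_features_in_ = len(scaler.mean_)
        return cls(feature_names=tuple(payload["feature_names"]),
                   classifier=clf, cv_record=payload["cv_record"],
                   n_train=payload["n_train"])


def _design_matrix(examples: list[TrainingExample],
                   feature_names: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    rows = []
    for ex in examples:
        if set(ex.phenotype.feature_names) < set(feature_names):
            raise SchemaError(
                f"{ex.compound_id}: phenotype lacks required features")
        order = [ex.phenotype.feature_names.index(n) for n in feature_names]
        rows.append(ex.phenotype.features[order])
    X = np.asarray(rows, dtype=float)
    y = np.asarray([ex.label for ex in examples])
    return X, y


def train_risk_model(examples: list[TrainingExample],
                     cv: tuple[int, int] = (5, 10),
                     seed: int | None = None, *,
                     feature_names: tuple[str, ...] | None = None,
                     **clf_kwargs) -> RiskModel:
    """Train the full 24-feature CHI model on a labelled library."""
    if feature_names is None:
        feature_names = examples[0].phenotype.feature_names
    X, y = _design_matrix(examples, feature_names)
    clf = CellHealthClassifier(cv_folds=cv[0], cv_repeats=cv[1],
                               random_state=seed, **clf_kwargs)
    clf.fit(X, y)
    record = {"folds": cv[0], "repeats": cv[1], "seed": seed,
              "selected": clf.best_params_}
    return RiskModel(feature_names=tuple(feature_names), classifier=clf,
                     cv_record=record, n_train=len(examples))


def chi_score(model: RiskModel, phenotype: PhenotypeVector) -> float:
    """Cell Health Index: probability that the phenotype belongs to the
    high-stress ("yes") class of the training library."""
    return model.score(phenotype)


@dataclass(frozen=True)
class Fingerprint:
    """CHI plus the eight endpoint probability scores for one compound."""

    compound_id: str
    chi: float
    endpoint_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.endpoint_scores) != len(ENDPOINT_ORDER):
            raise SchemaError("a fingerprint carries exactly 8 endpoint scores")
        for code, v in list(self.endpoint_scores.items()) + [("CHI", self.chi)]:
            if not 0.0 <= v <= 1.0:
                raise SchemaError(f"{code} score {v} outside [0, 1]")

    def top_endpoint(self) -> str:
        return max(self.endpoint_scores, key=self.endpoint_scores.get)


class EndpointFingerprinter:
    """Full CHI model plus the eight endpoint-restricted sub-models.

    Each sub-model is the same 1-SE elastic-net logistic classifier fit on
    only that endpoint's channel feature pairs (e.g. CM sees the 4 scatter
    features), trained on the same library.
    """

    def __init__(self, endpoint_specs: list[EndpointSpec] | None = None,
                 cv: tuple[int, int] = (5, 10), seed: int | None = None,
                 **clf_kwargs):
        self.endpoint_specs = endpoint_specs or default_endpoint_specs()
        codes = {s.code for s in self.endpoint_specs}
        if codes != set(ENDPOINT_ORDER):
            raise SchemaError(f"endpoint specs must cover {ENDPOINT_ORDER}")
        self.cv = cv
        self.seed = seed
        self.clf_kwargs = clf_kwargs

    def fit(self, examples: list[TrainingExample]) -> "EndpointFingerprinter":
        self.full_model_ = train_risk_model(examples, cv=self.cv,
                                            seed=self.seed, **self.clf_kwargs)
        self.sub_models_ = {}
        for spec in self.endpoint_specs:
            self.sub_models_[spec.code] = train_risk_model(
                examples, cv=self.cv, seed=self.seed,
                feature_names=spec.feature_names, **self.clf_kwargs)
        return self

    def fingerprint(self, phenotype: PhenotypeVector) -> Fingerprint:
        if not hasattr(self, "full_model_"):
            raise RuntimeError("fingerprinter is not fitted; call fit() first")
        scores = {code: m.score(phenotype)
                  for code, m in self.sub_models_.items()}
        return Fingerprint(compound_id=phenotype.compound_id,
                           chi=self.full_model_.score(phenotype),
                           endpoint_scores=scores)


def endpoint_scores(examples: list[TrainingExample],
                    endpoint_specs: list[EndpointSpec] | None,
                    phenotype: PhenotypeVector,
                    seed: int | None = None,
                    cv: tuple[int, int] = (5, 10),
                    **clf_kwargs) -> Fingerprint:
    """Train the fingerprint models and score one phenotype (convenience)."""
    fp = EndpointFingerprinter(endpoint_specs, cv=cv, seed=seed, **clf_kwargs)
    return fp.fit(examples).fingerprint(phenotype)


def classify_compound_table(models: EndpointFingerprinter,
                            phenotypes: list[PhenotypeVector]) -> pd.DataFrame:
    """One row per compound: the eight endpoint scores then CHI, to 2 dp."""
    rows = []
    for p in phenotypes:
        fp = models.fingerprint(p)
        row = {"compound_id": fp.compound_id}
        row.update({c: round(fp.endpoint_scores[c], 2) for c in ENDPOINT_ORDER})
        row["CHI"] = round(fp.chi, 2)
        rows.append(row)
    cols = ["compound_id", *ENDPOINT_ORDER, "CHI"]
    return pd.DataFrame(rows, columns=cols)
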