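"""Whole-image classification: HLAC + morphometric features, random forest.

The estimators follow the scikit-learn contract (``fit`` / ``transform`` /
``predict``, ``get_params`` / ``set_params``, trailing-underscore fitted
attributes) so they compose with sklearn pipelines and model selection.
``X`` is a sequence of 2-D arrays or :class:`~morphoquant.io.Image` objects
rather than a feature matrix — the featurizers turn images into fixed-length
vectors.

Evaluation is stratified k-fold cross-validation (default k=3) with seeded
fold assignment; the :class:`CVReport` stores per-fold accuracies, per-class
recall, the confusion matrix, and the raw out-of-fold predictions, so class
mergers (e.g. pooling the three early-mitotic stages and the two
late-mitotic stages of a seven-stage cell-cycle labelling into a four-class
problem) can be re-scored without re-training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats as sstats
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold

from .io import Image
from .engine import PipelineRecipe, SuggestionContext, default_recipe, run_recipe
from .hlac import hlac_feature_names, hlac_features

__all__ = [
    "HLACFeaturizer", "MorphometricFeaturizer", "ImageClassifier",
    "CVReport", "cross_validate", "merge_classes", "merge_labels",
    "CELL_CYCLE_MERGE", "morphometric_features",
    "morphometric_feature_names",
]

# built-in 7 -> 4 cell-cycle merge: the three early mitotic stages pool into
# one class, the two late mitotic stages into another; others map to
# themselves
CELL_CYCLE_MERGE: Dict[str, str] = {
    "prophase": "early_mitotic",
    "prometaphase": "early_mitotic",
    "metaphase": "early_mitotic",
    "anaphase": "late_mitotic",
    "telophase": "late_mitotic",
}


def _as_array(image: Union[Image, np.ndarray]) -> np.ndarray:
    return image.pixels if isinstance(image, Image) else np.asarray(image, float)


# ---------------------------------------------------------------------------
# featurizers

class HLACFeaturizer(BaseEstimator, TransformerMixin):
    """Transform images into higher-order local autocorrelation vectors.

    Parameters
    ----------
    d : int, default 1
        Window half-width; 25 features at d=1.
    max_order : int, default 2
        Highest autocorrelation order (products of max_order+1 pixels).
    binary : bool, default False
        Use the classical binary HLAC variant (midpoint threshold first).
    """

    def __init__(self, d: int = 1, max_order: int = 2, binary: bool = False):
        self.d = d
        self.max_order = max_order
        self.binary = binary

    def fit(self, X, y=None):
        self.feature_names_ = list(hlac_feature_names(self.d, self.max_order))
        self.n_features_out_ = len(self.feature_names_)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "feature_names_"):
            self.fit(X)
        rows = [hlac_features(_as_array(img), d=self.d,
                              max_order=self.max_order, binary=self.binary)
                for img in X]
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_)


_MORPHO_PARTICLE_FEATURES = ("area_px", "roundness", "solidity",
                             "major_axis", "minor_axis")


def morphometric_feature_names() -> List[str]:
    names = ["intensity_mean", "intensity_sd", "intensity_skew",
             "intensity_kurtosis", "intensity_q10", "intensity_q25",
             "intensity_q50", "intensity_q75", "intensity_q90",
             "foreground_fraction", "particle_count", "particles_valid"]
    for feat in _MORPHO_PARTICLE_FEATURES:
        names += [f"{feat}_mean", f"{feat}_sd"]
    return names


def morphometric_features(image: Union[Image, np.ndarray],
                          measurement_recipe: Optional[PipelineRecipe] = None
                          ) -> np.ndarray:
    """A fixed-length whole-image morphometric descriptor bundle.

    Global intensity statistics (mean, sd, skewness, kurtosis, five
    quantiles), the foreground fraction after the recipe's binarisation,
    the particle count, and mean/sd of area, roundness, solidity and the
    ellipse axes over detected particles.  Images with no detected
    particles get zeros for the per-particle statistics plus a validity
    flag of 0 (1 otherwise), keeping the schema fixed.
    """
    if measurement_recipe is None:
        measurement_recipe = default_recipe(
            SuggestionContext("fluorescence", "other"))
    img = image if isinstance(image, Image) else Image(np.asarray(image, float))
    arr = img.pixels
    flat = arr.ravel()
    sd = float(flat.std(ddof=0))
    # near-constant images: higher moments are numerically meaningless
    varied = sd > 1e-12 * max(1.0, abs(float(flat.mean())))
    skew = float(sstats.skew(flat)) if varied else 0.0
    kurt = float(sstats.kurtosis(flat)) if varied else 0.0
    q10, q25, q50, q75, q90 = np.quantile(flat, [0.1, 0.25, 0.5, 0.75, 0.9])
    labels, table = run_recipe(img, measurement_recipe)
    fg_fraction = float((labels.pixels > 0).mean())
    n = len(table)
    values = [float(flat.mean()), sd, skew, kurt,
              float(q10), float(q25), float(q50), float(q75), float(q90),
              fg_fraction, float(n), 1.0 if n > 0 else 0.0]
    for feat in _MORPHO_PARTICLE_FEATURES:
        if n > 0:
            col = table[feat].to_numpy(float)
            values += [float(col.mean()),
                       float(col.std(ddof=1)) if n > 1 else 0.0]
        else:
            values += [0.0, 0.0]  # sentinel; particles_valid flags it
    return np.asarray(values, dtype=np.float64)


class MorphometricFeaturizer(BaseEstimator, TransformerMixin):
    """Transform images into whole-image morphometric feature vectors.

    ``recipe`` is the measurement :class:`PipelineRecipe` used to detect
    particles (default: the headless fluorescence recipe).
    """

    def __init__(self, recipe: Optional[PipelineRecipe] = None):
        self.recipe = recipe

    def fit(self, X, y=None):
        self.feature_names_ = morphometric_feature_names()
        self.n_features_out_ = len(self.feature_names_)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "feature_names_"):
            self.fit(X)
        return np.vstack([morphometric_features(img, self.recipe) for img in X])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_)


# ---------------------------------------------------------------------------
# classifier

class ImageClassifier(BaseEstimator, ClassifierMixin):
    """Random-forest image classifier over HLAC + morphometric features.

    Defaults: 500 trees, sqrt(#features) candidate features per split, no
    depth cap — all recorded in CV reports.  Either feature family can be
    disabled; by default both are extracted and concatenated.

    Parameters
    ----------
    use_hlac, use_morphometric : bool
        Which feature families to extract.
    n_trees : int, default 500
        Forest size.
    hlac_d : int, default 1
        HLAC window half-width.
    recipe : PipelineRecipe, optional
        Measurement recipe behind the morphometric features.
    random_state : int, default 0
        Seed for forest training (deterministic predictions given data+seed).

    Attributes
    ----------
    classes_ : ndarray of class labels.
    feature_names_ : list of str, concatenated feature schema.
    forest_ : the fitted RandomForestClassifier.
    """

    def __init__(self, use_hlac: bool = True, use_morphometric: bool = True,
                 n_trees: int = 500, hlac_d: int = 1,
                 recipe: Optional[PipelineRecipe] = None,
                 random_state: int = 0):
        self.use_hlac = use_hlac
        self.use_morphometric = use_morphometric
        self.n_trees = n_trees
        self.hlac_d = hlac_d
        self.recipe = recipe
        self.random_state = random_state

    def _featurizers(self):
        fs = []
        if self.use_hlac:
            fs.append(HLACFeaturizer(d=self.hlac_d))
        if self.use_morphometric:
            fs.append(MorphometricFeaturizer(recipe=self.recipe))
        if not fs:
            raise ValueError("at least one feature family must be enabled")
        return fs

    def extract_features(self, X) -> np.ndarray:
        fs = self._featurizers()
        blocks = [f.fit(X).transform(X) for f in fs]
        self.feature_names_ = sum((list(f.feature_names_) for f in fs), [])
        return np.hstack(blocks)

    def fit(self, X, y):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training needs at least two classes")
        F = self.extract_features(X)
        if not np.all(np.isfinite(F)):
            raise ValueError("non-finite feature values")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees, max_features="sqrt", max_depth=None,
            random_state=self.random_state)
        self.forest_.fit(F, y)
        self.classes_ = self.forest_.classes_
        return self

    def fit_features(self, F: np.ndarray, y, feature_names=None):
        """Fit directly on a precomputed feature matrix."""
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training needs at least two classes")
        self.feature_names_ = (list(feature_names) if feature_names is not None
                               else [f"f{i}" for i in range(F.shape[1])])
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees, max_features="sqrt", max_depth=None,
            random_state=self.random_state)
        self.forest_.fit(F, y)
        self.classes_ = self.forest_.classes_
        return self

    def predict(self, X):
        return self.forest_.predict(self.extract_features_like_fit(X))

    def predict_features(self, F: np.ndarray):
        return self.forest_.predict(np.asarray(F, float))

    def extract_features_like_fit(self, X) -> np.ndarray:
        fs = self._featurizers()
        return np.hstack([f.fit(X).transform(X) for f in fs])

    def save(self, path) -> None:
        """Persist the trained model with its feature-name schema."""
        import pickle

        payload = {"schema_version": 1,
                   "feature_names": list(self.feature_names_),
                   "params": self.get_params(deep=False),
                   "forest": self.forest_}
        # recipe objects are not JSON; pickle keeps the whole bundle
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "ImageClassifier":
        import pickle

        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        model = cls(**payload["params"])
        model.forest_ = payload["forest"]
        model.feature_names_ = payload["feature_names"]
        model.classes_ = model.forest_.classes_
        return model


# ---------------------------------------------------------------------------
# cross-validation and class merging

@dataclass
class CVReport:
    """Stratified k-fold cross-validation record.

    ``mean_accuracy`` is the mean of the per-fold accuracies; per-class
    accuracy is recall (confusion-matrix diagonal over row sum).  The raw
    out-of-fold truths and predictions are stored so mergers can re-score
    without re-training.
    """

    k: int
    seed: int
    classes: List[str]
    fold_accuracies: List[float]
    per_class_accuracy: Dict[str, float]
    confusion: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    fold_of: np.ndarray
    model_params: Dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "classes": list(self.classes),
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": self.mean_accuracy,
            "per_class_accuracy": {k: float(v)
                                   for k, v in self.per_class_accuracy.items()},
            "confusion_matrix": self.confusion.tolist(),
            "model_params": {k: v for k, v in self.model_params.items()
                             if isinstance(v, (int, float, str, bool, type(None)))},
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)

    def summary_text(self) -> str:
        lines = [f"{self.k}-fold stratified cross-validation (seed {self.seed})",
                 f"mean accuracy: {self.mean_accuracy:.4f}",
                 "per-fold: " + ", ".join(f"{a:.4f}" for a in self.fold_accuracies),
                 "per-class recall:"]
        for cls in self.classes:
            lines.append(f"  {cls}: {self.per_class_accuracy[cls]:.4f}")
        return "\n".join(lines)


def _score_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                       fold_of: np.ndarray, k: int, seed: int,
                       model_params: Dict) -> CVReport:
    classes = sorted(np.unique(y_true).tolist())
    fold_acc = [float(np.mean(y_pred[fold_of == f] == y_true[fold_of == f]))
                for f in range(k)]
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    per_class = {}
    for i, cls in enumerate(classes):
        row = cm[i].sum()
        per_class[cls] = float(cm[i, i] / row) if row else float("nan")
    return CVReport(k=k, seed=seed, classes=classes,
                    fold_accuracies=fold_acc, per_class_accuracy=per_class,
                    confusion=cm, y_true=y_true, y_pred=y_pred,
                    fold_of=fold_of, model_params=model_params)


def cross_validate(X, y, k: int = 3, seed: int = 0,
                   model: Optional[ImageClassifier] = None,
                   precomputed_features: Optional[np.ndarray] = None
                   ) -> CVReport:
    """Stratified k-fold cross-validation of the image classifier.

    Features are extracted once for the whole dataset (they are per-image
    pure functions, so no information leaks across folds); each fold trains
    a fresh forest on the remaining folds and predicts the held-out one.

    Raises
    ------
    ValueError
        If ``k < 2`` or any class has fewer than ``k`` members (the error
        names the offending class).
    """
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("cross-validation needs at least two classes")
    for cls, cnt in zip(classes, counts):
        if cnt < k:
            raise ValueError(
                f"class {cls!r} has only {cnt} members; {k}-fold CV needs >= {k}")
    model = model if model is not None else ImageClassifier(random_state=seed)

    if precomputed_features is not None:
        F = np.asarray(precomputed_features, float)
    else:
        F = model.extract_features(X)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    fold_of = np.empty(len(y), dtype=int)
    for f, (train, test) in enumerate(skf.split(F, y)):
        fold_model = ImageClassifier(**model.get_params(deep=False))
        fold_model.random_state = seed + f
        fold_model.fit_features(F[train], y[train])
        y_pred[test] = fold_model.predict_features(F[test])
        fold_of[test] = f
    params = {**model.get_params(deep=False), "recipe": None}
    return _score_predictions(y, y_pred, fold_of, k, seed, params)


def merge_labels(labels: Sequence[str],
                 mapping: Optional[Mapping[str, str]] = None) -> np.ndarray:
    """Apply a class merge map to a label sequence.

    With the default ``mapping=None`` the built-in cell-cycle merge
    (:data:`CELL_CYCLE_MERGE`) is used and classes absent from it map to
    themselves, turning a seven-stage labelling into four classes.  An
    explicitly supplied mapping must be total on the observed classes;
    an unmapped observed class raises ``ValueError``.
    """
    if mapping is None:
        return np.asarray([CELL_CYCLE_MERGE.get(str(lab), str(lab))
                           for lab in labels])
    mapping = {str(k): str(v) for k, v in mapping.items()}
    observed = {str(lab) for lab in labels}
    unmapped = sorted(observed - set(mapping))
    if unmapped:
        raise ValueError(f"merge mapping is not total: unmapped classes {unmapped}")
    return np.asarray([mapping[str(lab)] for lab in labels])


def merge_classes(report_or_labels,
                  mapping: Optional[Mapping[str, str]] = None):
    """Merge classes of a label sequence or re-score a CV report.

    Applied to a :class:`CVReport`, the stored out-of-fold predictions are
    relabelled and accuracy re-computed *without re-training*; merging can
    only turn mismatches into matches, never the reverse, so accuracy never
    decreases.
    """
    if isinstance(report_or_labels, CVReport):
        rep = report_or_labels
        y_true = merge_labels(rep.y_true, mapping)
        y_pred = merge_labels(rep.y_pred, mapping)
        return _score_predictions(y_true, y_pred, rep.fold_of, rep.k,
                                  rep.seed, dict(rep.model_params))
    return merge_labels(report_or_labels, mapping)
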