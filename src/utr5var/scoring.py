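"""Random-forest prioritization of uORF-affecting variants.

A 17-feature vector is assembled per annotation record: 5' UTR context
(5' UTR length, uAUG-to-mAUG distance, cap-to-uAUG distance, uORF rank,
uORF length in nt and aa), uORF characteristics (type, uStop codon, uKozak
strength), evolutionary conservation (phyloP and PhastCons at the uAUG),
gene constraint (pLI and LOEUF), ribosome-profiling evidence, main-CDS
Kozak strength, per-transcript uORF count, and the variant consequence
(one-hot over the five uORF categories; mKozak-only and splice-derived
records are excluded from training and scoring and receive an NA score).

Continuous missing values are imputed with training-set medians only.
Categorical features are label encoded with a fixed alphabetical ordering
persisted with the model; unseen levels at scoring time map to a reserved
code. Class imbalance is corrected with SMOTE (synthetic minority
oversampling: convex combinations of k=5 minority nearest neighbors) before
fitting. The positive-class probability is the prioritization score in
[0, 1]; the default high/low threshold is 0.74.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

NUMERIC_FEATURES = [
    "5UTR_LENGTH", "uSTART_mSTART_DIST", "uSTART_CAP_DIST", "uORF_rank",
    "uORF_LENGTH", "uORF_AA_LENGTH", "uSTART_PHYLOP", "uSTART_PHASTCONS",
    "pLI", "LOEUF", "uORF_count",
]
CATEGORICAL_FEATURES = ["uORF_TYPE", "uSTOP_CODON", "uKOZAK_STRENGTH", "Ribo_seq", "mKOZAK_STRENGTH"]
CSQ_LEVELS = ["uStart_gain", "uStart_loss", "uStop_gain", "uStop_loss", "uKozak"]
#: The 17 model features (CSQ counts as one feature, one-hot encoded).
FEATURES = NUMERIC_FEATURES + CATEGORICAL_FEATURES + ["CSQ"]

DEFAULT_HYPERPARAMS = dict(
    n_estimators=500,
    class_weight="balanced",
    max_depth=None,
    max_features=None,
    min_samples_leaf=2,
    min_samples_split=2,
)
DEFAULT_THRESHOLD = 0.74
UNKNOWN_CODE = -1


def _encode_categorical(series: pd.Series, levels: list[str]) -> np.ndarray:
    mapping = {lvl: i for i, lvl in enumerate(levels)}
    return series.map(lambda v: mapping.get(v, UNKNOWN_CODE)).to_numpy(dtype=float)


def fit_encoders(records: pd.DataFrame) -> dict[str, list[str]]:
    """Fixed alphabetical label-encoding levels per categorical feature."""
    return {
        col: sorted(str(v) for v in records[col].dropna().unique())
        for col in CATEGORICAL_FEATURES
    }


def assemble_features(
    records: pd.DataFrame,
    training_medians: Optional[pd.Series] = None,
    encoders: Optional[dict[str, list[str]]] = None,
) -> tuple[pd.DataFrame, pd.Series, dict[str, list[str]]]:
    """Build the numeric feature matrix from annotation records.

    Records whose CSQ is not one of the five uORF categories are rejected.
    When ``training_medians`` is None the medians are fitted from ``records``
    (training mode); otherwise they are applied as-is (scoring mode) so that
    no test-set statistics leak into imputation.
    """
    bad = set(records["CSQ"].unique()) - set(CSQ_LEVELS)
    if bad:
        raise ValueError(f"records contain non-uORF consequence categories: {sorted(bad)}")
    records = records.mask(records == "NA")
    X = pd.DataFrame(index=records.index)
    for col in NUMERIC_FEATURES:
        X[col] = pd.to_numeric(records[col], errors="coerce")
    if encoders is None:
        encoders = fit_encoders(records)
    for col in CATEGORICAL_FEATURES:
        X[col] = _encode_categorical(records[col].astype(str), encoders[col])
    for lvl in CSQ_LEVELS:
        X[f"CSQ_{lvl}"] = (records["CSQ"] == lvl).astype(float)
    if training_medians is None:
        training_medians = X[NUMERIC_FEATURES].median()
    X[NUMERIC_FEATURES] = X[NUMERIC_FEATURES].fillna(training_medians)
    X = X.fillna(0.0)
    return X, training_medians, encoders


def balance_classes(
    X: np.ndarray, y: np.ndarray, seed: int, k: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE: equalize class sizes by interpolating minority samples.

    Each synthetic point is a convex combination of a minority sample and
    one of its ``k`` nearest minority neighbors, so every synthetic value
    lies within the per-feature minority bounding box.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("balance_classes expects exactly two classes")
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    if n_needed == 0:
        return X, y
    X_min = X[y == minority]
    if len(X_min) < 2:
        raise ValueError("minority class has fewer than 2 samples; more data needed")
    rng = np.random.default_rng(seed)
    k_eff = min(k, len(X_min) - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X_min)
    _, neigh = nn.kneighbors(X_min)
    idx = rng.integers(0, len(X_min), size=n_needed)
    jdx = neigh[idx, rng.integers(1, k_eff + 1, size=n_needed)]
    gap = rng.random((n_needed, 1))
    synth = X_min[idx] + gap * (X_min[jdx] - X_min[idx])
    Xb = np.vstack([X, synth])
    yb = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return Xb, yb


@dataclass
class ScoreModel:
    classifier: RandomForestClassifier
    feature_names: list[str]
    training_medians: pd.Series
    encoders: dict[str, list[str]]
    hyperparams: dict
    cv_metrics: list[dict]
    threshold: float = DEFAULT_THRESHOLD

    @property
    def mean_cv_auc(self) -> float:
        return float(np.mean([m["auc"] for m in self.cv_metrics]))

    def save(self, path: str) -> None:
        joblib.dump(self, path)
        sidecar = {
            "feature_names": self.feature_names,
            "hyperparams": {k: v for k, v in self.hyperparams.items()},
            "encoders": self.encoders,
            "training_medians": {k: float(v) for k, v in self.training_medians.items()},
            "threshold": self.threshold,
            "cv_metrics": self.cv_metrics,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "ScoreModel":
        return joblib.load(path)


def train_model(
    X: pd.DataFrame,
    y,
    hyperparams: Optional[dict] = None,
    seed: int = 42,
    training_medians: Optional[pd.Series] = None,
    encoders: Optional[dict] = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> ScoreModel:
    """Train the random-forest score with SMOTE balancing and 5-fold
    stratified cross-validation metrics."""
    y = np.asarray(y)
    if len(y) < 20 or len(np.unique(y)) < 2:
        raise ValueError("need >= 20 labeled samples with both classes")
    hp = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        hp.update(hyperparams)
    Xv = X.to_numpy(dtype=float)

    cv_metrics = []
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    for fold, (tr, te) in enumerate(skf.split(Xv, y)):
        Xb, yb = balance_classes(Xv[tr], y[tr], seed=seed + fold)
        clf = RandomForestClassifier(random_state=seed, **hp).fit(Xb, yb)
        proba = clf.predict_proba(Xv[te])[:, 1]
        acc = float(np.mean((proba >= threshold).astype(int) == y[te]))
        auc = float(roc_auc_score(y[te], proba)) if len(np.unique(y[te])) == 2 else float("nan")
        cv_metrics.append({"fold": fold, "accuracy": acc, "auc": auc})

    Xb, yb = balance_classes(Xv, y, seed=seed)
    clf = RandomForestClassifier(random_state=seed, **hp).fit(Xb, yb)
    if training_medians is None:
        training_medians = pd.Series(np.median(Xv, axis=0), index=list(X.columns))
    return ScoreModel(
        classifier=clf,
        feature_names=list(X.columns),
        training_medians=training_medians,
        encoders=encoders or {},
        hyperparams=hp,
        cv_metrics=cv_metrics,
        threshold=threshold,
    )


def score(model: ScoreModel, X: pd.DataFrame) -> np.ndarray:
    """Positive-class probability in [0, 1] per row of ``X``."""
    Xv = X[model.feature_names].to_numpy(dtype=float)
    return model.classifier.predict_proba(Xv)[:, 1]


def feature_importance(model: ScoreModel) -> list[tuple[str, float]]:
    """Impurity-based importances, non-negative, summing to 1, descending."""
    imp = model.classifier.feature_importances_
    pairs = sorted(zip(model.feature_names, imp), key=lambda t: -t[1])
    return [(name, float(v)) for name, v in pairs]


def score_records(records: pd.DataFrame, model: ScoreModel) -> pd.DataFrame:
    """Fill the score column of an annotation table in place.

    Only the five uORF consequence categories are scored; mKozak and
    splice-derived records keep an NA score (they are outside the training
    domain).
    """
    records = records.copy()
    mask = records["CSQ"].isin(CSQ_LEVELS) & (records["Splicing_CSQ"] == "NA")
    if mask.any():
        X, _, _ = assemble_features(
            records.loc[mask], model.training_medians, model.encoders
        )
        records.loc[mask, "5ULTRA_Score"] = [f"{s:.3f}" for s in score(model, X)]
    return records
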