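"""Random-forest hit expansion on circular (Morgan) fingerprints.

Screen-labeled compounds are featurized as folded binary Morgan
fingerprints (radius 2, 2048 bits by default), a random forest with
balanced class weights is trained on the activity labels, and unscreened
library compounds are ranked by predicted probability of activity.
Compounds seen in training are always excluded from the prediction set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from rdkit.Chem import rdFingerprintGenerator
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_score, recall_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .exceptions import ConfigError, DataError, DegenerateLabelsError
from .library import CompoundLibrary

logger = logging.getLogger(__name__)


@dataclass
class FingerprintMatrix:
    """Binary fingerprint rows aligned to compound ids."""

    bits: np.ndarray
    radius: int
    n_bits: int
    compound_ids: list[str]
    n_skipped: int = 0


@dataclass(frozen=True)
class RFConfig:
    n_trees: int = 500
    radius: int = 2
    n_bits: int = 2048
    class_weight: str | None = "balanced"
    cv_folds: int = 5
    threshold: float = 0.5


@dataclass
class ActivityModel:
    """Fitted forest plus the training configuration and CV metrics."""

    forest: RandomForestClassifier
    config: RFConfig
    train_ids: list[str]
    cv_metrics: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.forest, path / "forest.joblib")
        (path / "config.json").write_text(
            json.dumps(
                {
                    "config": self.config.__dict__,
                    "train_ids": self.train_ids,
                    "cv_metrics": self.cv_metrics,
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "ActivityModel":
        path = Path(path)
        meta = json.loads((path / "config.json").read_text())
        return cls(
            forest=joblib.load(path / "forest.joblib"),
            config=RFConfig(**meta["config"]),
            train_ids=meta["train_ids"],
            cv_metrics=meta["cv_metrics"],
        )


@dataclass
class PredictionSet:
    """Ranked activity predictions for non-training compounds."""

    predictions: pd.DataFrame  # compound_id, probability, predicted_active
    threshold: float

    def top(self, n: int) -> pd.DataFrame:
        return self.predictions.head(n)


def featurize_morgan(
    library: CompoundLibrary, radius: int = 2, n_bits: int = 2048
) -> FingerprintMatrix:
    """Folded binary Morgan fingerprints; unparsable structures skipped."""
    ids, mols = library.parsed()
    n_skipped = len(library) - len(mols)
    if not mols:
        raise DataError("no parsable structures to featurize")
    if n_skipped:
        logger.warning("featurize_morgan: skipped %d unparsable structures", n_skipped)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bits = np.zeros((len(mols), n_bits), dtype=np.uint8)
    for i, mol in enumerate(mols):
        bits[i] = gen.GetFingerprintAsNumPy(mol)
    return FingerprintMatrix(
        bits=bits, radius=radius, n_bits=n_bits, compound_ids=ids, n_skipped=n_skipped
    )


def train_rf(
    X: FingerprintMatrix,
    y,
    config: RFConfig | None = None,
    seed: int = 0,
) -> ActivityModel:
    """Train the activity forest with stratified cross-validated metrics.

    ``y`` is aligned to the rows of ``X``; both classes must be present.
    Out-of-bag scoring is enabled; CV AUROC/precision/recall are computed
    with stratified k-fold predicted probabilities.
    """
    config = config or RFConfig()
    y = np.asarray(y, dtype=int)
    if y.shape[0] != X.bits.shape[0]:
        raise DataError("label vector length must match fingerprint rows")
    if np.unique(y).size < 2:
        raise DegenerateLabelsError("training requires both activity classes")
    if (X.radius, X.n_bits) != (config.radius, config.n_bits):
        raise ConfigError("fingerprint matrix does not match the model's fingerprint config")

    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        class_weight=config.class_weight,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    metrics = {}
    if config.cv_folds and config.cv_folds > 1:
        cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
        proba = cross_val_predict(forest, X.bits, y, cv=cv, method="predict_proba")[:, 1]
        pred = (proba >= config.threshold).astype(int)
        metrics = {
            "auroc": float(roc_auc_score(y, proba)),
            "precision": float(precision_score(y, pred, zero_division=0)),
            "recall": float(recall_score(y, pred, zero_division=0)),
        }
    forest.fit(X.bits, y)
    metrics["oob_score"] = float(forest.oob_score_)
    return ActivityModel(
        forest=forest, config=config, train_ids=list(X.compound_ids), cv_metrics=metrics
    )


def predict_actives(
    model: ActivityModel,
    library: CompoundLibrary | FingerprintMatrix,
    threshold: float | None = None,
) -> PredictionSet:
    """Rank non-training library compounds by predicted activity.

    Accepts a library (featurized with the model's own fingerprint config)
    or a precomputed matrix, which must match that config.  Training
    compounds are removed; rows sort by probability descending, ties by id.
    """
    threshold = model.config.threshold if threshold is None else float(threshold)
    if isinstance(library, FingerprintMatrix):
        fps = library
        if (fps.radius, fps.n_bits) != (model.config.radius, model.config.n_bits):
            raise ConfigError("fingerprint matrix does not match the model's fingerprint config")
    else:
        fps = featurize_morgan(library, radius=model.config.radius, n_bits=model.config.n_bits)
    train = set(model.train_ids)
    keep = [i for i, cid in enumerate(fps.compound_ids) if cid not in train]
    if not keep:
        frame = pd.DataFrame(columns=["compound_id", "probability", "predicted_active"])
        return PredictionSet(predictions=frame, threshold=threshold)
    proba = model.forest.predict_proba(fps.bits[keep])[:, 1]
    frame = pd.DataFrame(
        {
            "compound_id": [fps.compound_ids[i] for i in keep],
            "probability": proba,
        }
    )
    frame["predicted_active"] = frame["probability"] >= threshold
    frame = frame.sort_values(
        ["probability", "compound_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return PredictionSet(predictions=frame, threshold=threshold)
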