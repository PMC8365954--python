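"""Stages 2-3: gradient-boosted-tree classifiers on extracted sequence
features, and the end-to-end "from open chromatin" genome-wide predictor.

The frozen stage-1 extractor converts each anchor pair into four blocks of
kernel activations (plus, optionally, the raw anchor distance in bp — trees
are invariant to monotone transforms, so no log scaling is applied). XGBoost
supplies the boosting; gain-based feature importances are mapped back through
the block structure so that each importance record names its anchor side,
orientation and kernel — the basis of the convergent-orientation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb

from .dataset_builder import (
    DEFAULT_EXTENSION,
    DEFAULT_MAX_SPAN,
    DEFAULT_MERGE_DISTANCE,
    build_anchors_from_open_chromatin,
    enumerate_and_label_pairs,
)
from .genome_io import AnchorPair, GenomeSequence, GenomicInterval
from .sequence_model import ConvFeatureExtractor, extract_feature_matrix

__all__ = [
    "PredictionRecord",
    "ImportanceRecord",
    "GBModel",
    "DEFAULT_GB_PARAMS",
    "train_gb",
    "predict_pairs",
    "feature_importance_report",
    "predict_from_open_chromatin",
]

DEFAULT_GB_PARAMS: dict = {
    "objective": "binary:logistic",
    "max_depth": 6,
    "eta": 0.05,
    "subsample": 0.8,
    "eval_metric": "aucpr",
    "tree_method": "hist",
    "nthread": 1,
}
DEFAULT_NUM_ROUNDS = 500
DEFAULT_EARLY_STOPPING = 50


@dataclass(frozen=True)
class PredictionRecord:
    pair: AnchorPair
    score: float
    model_id: str = ""
    predicted: bool | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")


@dataclass(frozen=True)
class ImportanceRecord:
    feature_index: int
    feature_name: str
    block: str  # left_F / left_RC / right_F / right_RC / distance
    kernel: int | None
    importance: float


class GBModel:
    """A trained booster plus its feature-name manifest and training log."""

    def __init__(
        self,
        booster: xgb.Booster,
        feature_names: list[str],
        stage: str,
        params: dict,
        eval_log: pd.DataFrame | None = None,
    ):
        self.booster = booster
        self.feature_names = list(feature_names)
        self.stage = stage
        self.params = dict(params)
        self.eval_log = eval_log

    def predict(self, X) -> np.ndarray:
        X = self._validate(X)
        dm = xgb.DMatrix(X, feature_names=self.feature_names, nthread=1)
        return self.booster.predict(dm)

    def _validate(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if list(X.columns) != self.feature_names:
                raise ValueError(
                    "feature manifest mismatch: model expects "
                    f"{self.feature_names[:3]}... got {list(X.columns)[:3]}..."
                )
            X = X.to_numpy()
        X = np.asarray(X, dtype=np.float32)
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"feature manifest mismatch: expected {len(self.feature_names)} "
                f"features, got {X.shape[1]}"
            )
        return X

    def save(self, path: str | Path) -> None:
        self.booster.set_attr(
            chromloop_features="\t".join(self.feature_names),
            chromloop_stage=self.stage,
        )
        self.booster.save_model(str(path))

    @classmethod
    def load(cls, path: str | Path) -> "GBModel":
        booster = xgb.Booster()
        booster.load_model(str(path))
        names = booster.attr("chromloop_features").split("\t")
        stage = booster.attr("chromloop_stage") or "unknown"
        return cls(booster, names, stage, {})


def _check_features(X: pd.DataFrame | np.ndarray, names: list[str]) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        arr = X.to_numpy(dtype=np.float32)
    else:
        arr = np.asarray(X, dtype=np.float32)
    bad = np.nonzero(~np.isfinite(arr).all(axis=0))[0]
    if bad.size:
        raise ValueError(f"non-finite values in feature column(s) {[names[i] for i in bad]}")
    return arr


def train_gb(
    X,
    labels,
    feature_names: list[str] | None = None,
    seed: int = 0,
    stage: str = "extended",
    params: Mapping | None = None,
    num_rounds: int = DEFAULT_NUM_ROUNDS,
    early_stopping_rounds: int | None = DEFAULT_EARLY_STOPPING,
    eval_set: tuple | None = None,
) -> GBModel:
    """Train a gradient-boosted-tree classifier.

    Single-threaded and seeded, hence deterministic. ``eval_set`` is an
    optional ``(X_val, y_val)`` used for the per-round validation metric
    (aucpr) and early stopping; without it the model trains for the full
    ``num_rounds``.
    """
    if isinstance(X, pd.DataFrame) and feature_names is None:
        feature_names = list(X.columns)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(np.asarray(X).shape[1])]
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    arr = _check_features(X, feature_names)
    full_params = dict(DEFAULT_GB_PARAMS)
    if params:
        full_params.update(params)
    full_params["seed"] = seed
    dtrain = xgb.DMatrix(arr, label=y, feature_names=feature_names, nthread=1)
    evals = [(dtrain, "train")]
    if eval_set is not None:
        Xv, yv = eval_set
        dval = xgb.DMatrix(
            _check_features(Xv, feature_names),
            label=np.asarray(yv, dtype=int),
            feature_names=feature_names,
            nthread=1,
        )
        evals.append((dval, "validation"))
    history: dict = {}
    booster = xgb.train(
        full_params,
        dtrain,
        num_boost_round=num_rounds,
        evals=evals,
        evals_result=history,
        early_stopping_rounds=(
            early_stopping_rounds if eval_set is not None else None
        ),
        verbose_eval=False,
    )
    log = pd.DataFrame(
        {f"{split}_{metric}": vals
         for split, metrics in history.items()
         for metric, vals in metrics.items()}
    )
    return GBModel(booster, feature_names, stage, full_params, log)


def predict_pairs(
    model: GBModel,
    extractor: ConvFeatureExtractor,
    pairs: Sequence[AnchorPair],
    genome: GenomeSequence,
    include_distance: bool = False,
    batch_size: int = 256,
    model_id: str = "",
) -> list[PredictionRecord]:
    """Score anchor pairs: fetch sequences, run the frozen extractor, apply
    the booster. Scores are batch-order invariant."""
    if include_distance != (model.feature_names[-1] == "distance"):
        raise ValueError(
            "feature manifest mismatch: model "
            + ("includes" if model.feature_names[-1] == "distance" else "lacks")
            + " a distance feature"
        )
    left = [genome.fetch(p.left) for p in pairs]
    right = [genome.fetch(p.right) for p in pairs]
    feats = extract_feature_matrix(extractor, left, right, batch_size)
    if include_distance:
        d = np.array([[p.distance] for p in pairs], dtype=np.float32)
        feats = np.hstack([feats, d])
    scores = model.predict(feats)
    return [
        PredictionRecord(p, float(s), model_id) for p, s in zip(pairs, scores)
    ]


_BLOCK_NAMES = ("left_F", "left_RC", "right_F", "right_RC")


def feature_importance_report(model: GBModel) -> list[ImportanceRecord]:
    """Gain-based importance for every feature of the model (absent from all
    splits → 0), mapped to (anchor side, orientation, kernel) or distance."""
    gains = model.booster.get_score(importance_type="gain")
    records: list[ImportanceRecord] = []
    for i, name in enumerate(model.feature_names):
        if name == "distance":
            block, kernel = "distance", None
        else:
            block, _, k = name.rpartition("_k")
            if block in _BLOCK_NAMES and k.isdigit():
                kernel = int(k)
            else:
                block, kernel = name, None
        records.append(
            ImportanceRecord(i, name, block, kernel, float(gains.get(name, 0.0)))
        )
    return records


def predict_from_open_chromatin(
    peaks: Sequence[GenomicInterval],
    genome: GenomeSequence,
    extractor: ConvFeatureExtractor,
    model: GBModel,
    merge_distance: int = DEFAULT_MERGE_DISTANCE,
    extension: int = DEFAULT_EXTENSION,
    max_span: int = DEFAULT_MAX_SPAN,
    threshold: float = 0.5,
    include_distance: bool = False,
    model_id: str = "from_open",
) -> list[PredictionRecord]:
    """Genome-wide prediction from open-chromatin peaks alone.

    Pipeline: merge-and-extend peaks into anchors → enumerate all
    same-chromosome anchor pairs within ``max_span`` → extract sequence
    features with the frozen extractor → score with the boosted model.
    Every enumerated pair is returned with its score; ``predicted`` flags
    those at or above ``threshold``.
    """
    if not peaks:
        return []
    anchors = build_anchors_from_open_chromatin(
        peaks, merge_distance, extension, genome.chrom_lengths
    )
    pairs = enumerate_and_label_pairs(anchors, [], max_span=max_span)
    pairs = [p.with_label("unknown") for p in pairs]
    records = predict_pairs(
        model, extractor, pairs, genome, include_distance, model_id=model_id
    )
    return [
        PredictionRecord(r.pair, r.score, r.model_id, r.score >= threshold)
        for r in records
    ]
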