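"""Random-forest training, scoring, importances and model persistence.

The score of an SV is the fraction of decision trees voting pathogenic, in
[0, 1]. Default hyperparameters: max depth 10, one feature considered per
split, minimum 2 samples per leaf, minimum 4 samples to split, 1000 trees,
no out-of-bag scoring. At inference any SV larger than 3 Mb is scored
exactly 1.0 regardless of its features (benign SVs of that size are
essentially unobserved); training rejects such SVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from svforest.features import BOOLEAN_FEATURES, FEATURE_NAMES, FeatureVector, features_to_frame

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1
LARGE_SV_BP = 3_000_000
POSITIVE_LABEL = "pathogenic"


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest hyperparameters (defaults are the production settings)."""

    max_depth: int | None = 10
    max_features_per_split: int = 1
    min_samples_leaf: int = 2
    min_samples_split: int = 4
    n_trees: int = 1000
    use_oob: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("max_features_per_split", "min_samples_leaf", "min_samples_split", "n_trees"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be positive or None")

    def to_sklearn(self) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            max_depth=self.max_depth,
            max_features=self.max_features_per_split,
            min_samples_leaf=self.min_samples_leaf,
            min_samples_split=self.min_samples_split,
            oob_score=self.use_oob,
            random_state=self.seed,
            n_jobs=1,
        )


@dataclass
class TrainedModel:
    """A fitted forest plus everything needed to reproduce its inputs."""

    forest: RandomForestClassifier
    feature_order: tuple[str, ...]
    medians: dict[str, float]
    config: ForestConfig
    label_counts: dict[str, int] = field(default_factory=dict)
    format_version: int = MODEL_FORMAT_VERSION


def _as_frame(
    features: Sequence[FeatureVector] | pd.DataFrame,
) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        missing = set(FEATURE_NAMES) - set(features.columns)
        if missing:
            raise ValueError(f"feature frame lacks columns: {sorted(missing)}")
        return features[list(FEATURE_NAMES)].astype(float)
    return features_to_frame(features)


def compute_frame_medians(df: pd.DataFrame) -> dict[str, float]:
    """Median (majority for booleans, ties to 0) per feature, ignoring NaN."""
    out = {}
    for name in FEATURE_NAMES:
        col = df[name].dropna()
        if col.empty:
            out[name] = 0.0
        elif name in BOOLEAN_FEATURES:
            out[name] = 1.0 if col.mean() > 0.5 else 0.0
        else:
            out[name] = float(col.median())
    return out


def train(
    features: Sequence[FeatureVector] | pd.DataFrame,
    labels: Sequence[str],
    cfg: ForestConfig | None = None,
    sizes: Sequence[int] | None = None,
) -> TrainedModel:
    """Fit the forest on labeled feature vectors.

    Missing values (NaN / None) are imputed with medians computed from the
    training set itself; those medians are stored on the model for inference.
    Records larger than 3 Mb are excluded from training (with a logged count)
    when ``sizes`` is supplied. Fixed seed gives bit-reproducible models.
    """
    cfg = cfg or ForestConfig()
    df = _as_frame(features).reset_index(drop=True)
    y = pd.Series(list(labels), name="label")
    if len(df) != len(y):
        raise ValueError("features and labels differ in length")
    if sizes is not None:
        keep = np.asarray(sizes) <= LARGE_SV_BP
        if (~keep).any():
            logger.info("excluding %d SVs > 3 Mb from training", int((~keep).sum()))
        df, y = df[keep].reset_index(drop=True), y[keep].reset_index(drop=True)
    counts = y.value_counts().to_dict()
    if len(counts) < 2 or min(counts.values()) < 2:
        raise ValueError(f"need >= 2 examples of each label, got {counts}")
    medians = compute_frame_medians(df)
    X = df.fillna(pd.Series(medians)).to_numpy()
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values after imputation")
    forest = cfg.to_sklearn()
    forest.fit(X, (y == POSITIVE_LABEL).to_numpy())
    return TrainedModel(
        forest=forest,
        feature_order=tuple(FEATURE_NAMES),
        medians=medians,
        config=cfg,
        label_counts={str(k): int(v) for k, v in counts.items()},
    )


def predict(
    model: TrainedModel,
    features: Sequence[FeatureVector] | pd.DataFrame,
    sizes: Sequence[int] | None = None,
) -> np.ndarray:
    """Score SVs: fraction of trees voting pathogenic, in [0, 1].

    Missing values are imputed with the model's training medians. When
    ``sizes`` is given, any SV larger than 3 Mb receives score exactly 1.0.
    """
    df = _as_frame(features)
    if tuple(df.columns) != tuple(model.feature_order):
        raise ValueError("feature order does not match the trained model")
    X = df.fillna(pd.Series(model.medians)).to_numpy()
    pathogenic_col = list(model.forest.classes_).index(True)
    scores = model.forest.predict_proba(X)[:, pathogenic_col]
    if sizes is not None:
        if len(sizes) != len(scores):
            raise ValueError("sizes and features differ in length")
        scores = np.where(np.asarray(sizes) > LARGE_SV_BP, 1.0, scores)
    return scores


def gini_importances(model: TrainedModel) -> pd.Series:
    """Mean-decrease-in-impurity importance per feature; sums to 1."""
    if not hasattr(model.forest, "feature_importances_"):
        raise ValueError("model is not fitted")
    return pd.Series(model.forest.feature_importances_, index=list(model.feature_order))


def importance_confidence_intervals(
    features: Sequence[FeatureVector] | pd.DataFrame,
    labels: Sequence[str],
    cfg: ForestConfig | None = None,
    n_replicates: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """95% CIs on Gini importances from refitting with fresh forest seeds.

    Returns a frame (mean, low, high) per feature; ``n_replicates`` forests
    are trained with seeds derived from ``seed``.
    """
    cfg = cfg or ForestConfig()
    reps = []
    for r in range(n_replicates):
        m = train(features, labels, replace(cfg, seed=seed + r))
        reps.append(gini_importances(m))
    mat = pd.concat(reps, axis=1)
    return pd.DataFrame(
        {
            "mean": mat.mean(axis=1),
            "low": mat.quantile(0.025, axis=1),
            "high": mat.quantile(0.975, axis=1),
        }
    )


def grid_search(
    features: pd.DataFrame,
    labels: Sequence[str],
    chroms: Sequence[str],
    param_grid: Mapping[str, Sequence],
    validation_mask: Sequence[bool] | None = None,
    seed: int = 0,
) -> tuple[ForestConfig, pd.DataFrame]:
    """Hyperparameter search by leave-one-chromosome-out cross validation.

    Every combination in ``param_grid`` (keys are ForestConfig field names)
    is scored by the mean validation AUC across LOCO folds; validation is
    restricted to records where ``validation_mask`` is true (e.g. the
    curated-database subset). Folds whose validation subset is single-class
    are skipped with a warning. Returns the best config and the full table.
    """
    from itertools import product

    from svforest.evaluation import roc_auc

    df = _as_frame(features).reset_index(drop=True)
    y = np.asarray([lab == POSITIVE_LABEL for lab in labels])
    chroms = np.asarray(chroms)
    vmask = np.ones(len(df), dtype=bool) if validation_mask is None else np.asarray(validation_mask)
    keys = list(param_grid)
    rows = []
    best: tuple[float, ForestConfig] | None = None
    for combo in product(*(param_grid[k] for k in keys)):
        cfg = ForestConfig(**dict(zip(keys, combo)), seed=seed)
        aucs = []
        for chrom in sorted(set(chroms)):
            test = (chroms == chrom) & vmask
            tr = chroms != chrom
            if test.sum() == 0 or len(set(y[test])) < 2:
                logger.warning("fold %s skipped: validation subset single-class/empty", chrom)
                continue
            model = train(df[tr], ["pathogenic" if v else "benign" for v in y[tr]], cfg)
            scores = predict(model, df[test])
            aucs.append(roc_auc(scores, y[test]).auc)
        mean_auc = float(np.mean(aucs)) if aucs else float("nan")
        rows.append({**dict(zip(keys, combo)), "mean_auc": mean_auc, "n_folds": len(aucs)})
        if aucs and (best is None or mean_auc > best[0]):
            best = (mean_auc, cfg)
    if best is None:
        raise ValueError("no grid point could be evaluated")
    return best[1], pd.DataFrame(rows)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a model (forest, feature order, medians, config) to one file."""
    joblib.dump(
        {
            "format_version": model.format_version,
            "forest": model.forest,
            "feature_order": model.feature_order,
            "medians": model.medians,
            "config": asdict(model.config),
            "label_counts": model.label_counts,
        },
        path,
    )


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {version} unsupported (expected {MODEL_FORMAT_VERSION})"
        )
    return TrainedModel(
        forest=payload["forest"],
        feature_order=tuple(payload["feature_order"]),
        medians=dict(payload["medians"]),
        config=ForestConfig(**payload["config"]),
        label_counts=dict(payload["label_counts"]),
        format_version=version,
    )
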