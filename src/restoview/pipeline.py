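"""End-to-end pipeline: images + ratings -> features, scores, models, predictions.

Stage order mirrors the study's analysis: extract visual properties, score
and aggregate ratings, inspect the greenery correlations, prune collinear
indicators, hold out test photos, select the lasso penalty by
cross-validation, and evaluate.  Every intermediate is persisted as CSV/JSON
and the resolved configuration is written next to the outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from restoview.config import RunConfig
from restoview.exceptions import ValidationError
from restoview.images import FEATURE_NAMES, RasterImage, extract_features, feature_frame
from restoview.modeling import RestorativenessLasso, sqrt_greenery_correlations
from restoview.psychometrics import (
    ScaleDefinition,
    aggregate_by_photo,
    default_scale,
    score_ratings_table,
)

__all__ = ["extract_directory", "run_full_pipeline"]

log = logging.getLogger("restoview")

OUTCOMES = ("overall", "being_away", "fascination", "extent")
IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")


def extract_directory(images_dir, config: RunConfig) -> pd.DataFrame:
    """Extract the 19-indicator table for every PNG/JPEG in a directory."""
    paths = sorted(
        p for p in Path(images_dir).iterdir() if p.suffix.lower() in IMAGE_SUFFIXES
    )
    if not paths:
        raise ValidationError(f"no PNG/JPEG images found in {images_dir}")
    vectors = []
    for p in paths:
        img = RasterImage.from_file(p, source_id=p.stem)
        try:
            vectors.append(extract_features(img, config.extraction))
        except Exception as exc:
            raise type(exc)(f"extract failed for {p.name}: {exc}") from exc
    return feature_frame(vectors)


def run_full_pipeline(
    images_dir,
    ratings_file,
    out_dir,
    seed: int,
    config: RunConfig | None = None,
    scale: ScaleDefinition | None = None,
) -> dict:
    """Run extract -> score -> correlate -> prune -> split -> cv-lasso -> evaluate.

    Returns a dict of the in-memory artifacts; persists everything under
    ``out_dir``.  Stage failures abort with the stage name attached.
    """
    if config is None:
        config = RunConfig()
    if scale is None:
        scale = default_scale()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "run_config.json")
    log.info("config digest %s, seed %d", config.digest(), seed)

    features = extract_directory(images_dir, config)
    features.index.name = "source_id"
    features.to_csv(out / "features.csv")
    log.info("extract: %d photos x %d indicators", len(features), len(FEATURE_NAMES))

    ratings = pd.read_csv(ratings_file)
    unknown = set(ratings["photo_id"].unique()) - set(features.index)
    if unknown:
        raise ValidationError(f"ratings reference unknown photo ids: {sorted(unknown)[:5]}")
    scores = score_ratings_table(ratings, scale)
    photo_scores = aggregate_by_photo(scores)
    photo_scores.to_csv(out / "photo_scores.csv", index=False)
    log.info("score: %d ratings -> %d photos", len(ratings), len(photo_scores))

    correlations = sqrt_greenery_correlations(features, photo_scores)
    correlations.to_csv(out / "correlations.csv")

    results = {}
    for outcome in OUTCOMES:
        model = RestorativenessLasso(
            features[list(FEATURE_NAMES)],
            photo_scores,
            outcome=outcome,
            protected=config.protected,
            vif_threshold=config.vif_threshold,
            n_test=config.n_test,
            n_folds=config.n_folds,
        )
        res = model.fit(seed=seed)
        res.model_spec.to_json(out / f"model_{outcome}.json")
        res.cv_result.curve_frame().to_csv(out / f"cv_curve_{outcome}.csv", index=False)
        res.vif_report.trace_frame().to_csv(out / f"vif_trace_{outcome}.csv", index=False)
        res.predict(features[list(FEATURE_NAMES)]).to_csv(out / f"predictions_{outcome}.csv")
        results[outcome] = res
        log.info(
            "fit %s: lambda_1se=%.4f selected=%s rmse train/test %.3f/%.3f",
            outcome, res.cv_result.lambda_1se, res.selected_features,
            res.rmse_train, res.rmse_test,
        )
    return {
        "features": features,
        "photo_scores": photo_scores,
        "correlations": correlations,
        "results": results,
    }
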