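"""End-to-end orchestration: simulate → calibrate → extract → measure →
analyze, with CSV outputs and a machine-readable run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import consensus as consensus_mod
from . import fixtures, variation
from .calibration import (
    SIDECAR_COLUMNS,
    VIEWS,
    load_scene,
    save_image,
    save_mask,
)
from .extraction import ExtractionConfig, extract_pattern
from .measures import SymmetrySearchGrid, measure_all

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.12g"  # CSV float serialization, 12 significant digits


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of the pipeline in one place."""

    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    symmetry_grid: SymmetrySearchGrid = field(default_factory=SymmetrySearchGrid)
    calibration_target: float = 0.18
    cv_normalization: str = "pair_mean"
    taus: tuple[float, ...] = variation.DEFAULT_SENSITIVITY_TAUS
    baseline_tau: float = variation.DEFAULT_BASELINE_TAU
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "extraction" in d:
            d["extraction"] = ExtractionConfig(**d["extraction"])
        if "symmetry_grid" in d:
            d["symmetry_grid"] = SymmetrySearchGrid(**d["symmetry_grid"])
        if "taus" in d:
            d["taus"] = tuple(d["taus"])
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def run_pipeline(
    config: PipelineConfig,
    manifest: pd.DataFrame,
    out_dir,
    survey=None,
    image_root=None,
    save_previews: bool = False,
) -> dict:
    """Run the full analysis over an image manifest.

    ``manifest`` follows the sidecar schema (one row per photograph:
    image_path, turtle_id, view, replicate, source, card box and edge
    length). Per-image failures are logged and skipped; the run fails only
    if no image succeeds. Outputs (measures.csv, cv.csv, tests.csv,
    sensitivity.csv, consensus outputs when a survey is supplied, and
    run_manifest.json recording config hash and per-image status) are
    written under ``out_dir``. Returns the result bundle as a dict of
    DataFrames.
    """
    if isinstance(manifest, (str, os.PathLike)):
        manifest = pd.read_csv(manifest)
    missing = [c for c in SIDECAR_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if manifest.empty:
        raise ValueError("empty manifest")
    os.makedirs(out_dir, exist_ok=True)

    records, statuses, items = [], [], []
    for _, row in manifest.iterrows():
        tag = f"{row['turtle_id']}/{row['view']}/r{row['replicate']}"
        try:
            image, mask = load_scene(row, root=image_root)
            pattern = extract_pattern(image, mask, config.extraction)
            ms = measure_all(image, mask, pattern, config.symmetry_grid)
            records.extend(ms.to_records())
            items.append((image, mask))
            statuses.append({"image": tag, "status": "ok"})
            if save_previews:
                base = f"{row['turtle_id']}_{row['view']}_r{row['replicate']}"
                save_image(os.path.join(out_dir, base + "_calibrated.png"), image.pixels)
                save_mask(os.path.join(out_dir, base + "_pattern.png"), pattern.pattern)
        except Exception as exc:  # per-image failures are survivable
            logger.warning("image %s failed: %s", tag, exc)
            statuses.append({"image": tag, "status": f"error: {exc}"})
    if not records:
        raise RuntimeError("no image in the manifest could be processed")

    measures = pd.DataFrame(records)
    _write_csv(measures, os.path.join(out_dir, "measures.csv"))
    bundle: dict = {"measures": measures}

    # repeatability
    try:
        w_view, w_meas = variation.within_individual_cv(
            measures, normalization=config.cv_normalization
        )
        a_view, a_meas = variation.across_individual_cv(measures)
        cv = variation.noise_ratio(w_meas, a_meas)
        _write_csv(cv, os.path.join(out_dir, "cv.csv"))
        _write_csv(w_view.merge(a_view, on=["measure", "view"]),
                   os.path.join(out_dir, "cv_by_view.csv"))
        bundle["cv"] = cv
    except ValueError as exc:
        logger.warning("CV analysis skipped: %s", exc)

    # museum vs field
    if measures["source"].nunique() == 2:
        tests = variation.group_comparison(measures, group_key="source")
        if not tests.empty:
            _write_csv(tests, os.path.join(out_dir, "tests.csv"))
            bundle["tests"] = tests

    # threshold sensitivity
    sens = variation.threshold_sensitivity(
        items, taus=config.taus, baseline=config.baseline_tau, config=config.extraction
    )
    _write_csv(sens, os.path.join(out_dir, "sensitivity.csv"))
    bundle["sensitivity"] = sens

    # consensus
    if survey is not None:
        result = consensus_mod.consensus_table(survey)
        _write_csv(result.per_turtle, os.path.join(out_dir, "consensus.csv"))
        corr = consensus_mod.correlate_measures(result, measures)
        _write_csv(corr, os.path.join(out_dir, "correlations.csv"))
        bundle["consensus"] = result
        bundle["correlations"] = corr

    run_manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_images": int(len(manifest)),
        "images": statuses,
    }
    with open(os.path.join(out_dir, "run_manifest.json"), "w") as fh:
        json.dump(run_manifest, fh, indent=2, sort_keys=True)
    bundle["run_manifest"] = run_manifest
    return bundle


def simulate_dataset(
    out_dir,
    n_turtles: int = 3,
    replicates: int = 2,
    seed: int = 0,
    views=VIEWS,
    n_volunteers: int = 0,
    image_size=(240, 320),
    field_fraction: float = 0.2,
) -> pd.DataFrame:
    """Write a synthetic photo set: PNG images, sidecar manifest,
    ground_truth.csv, and (optionally) a survey.csv.

    Each turtle gets one scene per view with a turtle-specific object
    layout, photographed ``replicates`` times under the default replicate
    jitter. The last ``field_fraction`` of turtles are labeled source=field
    (slightly brighter objects, emulating live animals), the rest museum.
    Returns the sidecar manifest DataFrame.
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows, gt_rows = [], []
    n_field = int(round(field_fraction * n_turtles))
    for i in range(n_turtles):
        tid = f"t{i:03d}"
        source = "field" if i >= n_turtles - n_field else "museum"
        for view in views:
            spec = fixtures.random_disc_scene(
                seed=int(rng.integers(2**31)), image_size=image_size
            )
            if source == "field":  # livelier colors in the field
                spec = dataclasses.replace(
                    spec,
                    objects=tuple(
                        dataclasses.replace(
                            o, rgb=tuple(min(1.0, v * 1.15) for v in o.rgb)
                        )
                        for o in spec.objects
                    ),
                )
            jitter = fixtures.ReplicateJitterSpec(
                n_replicates=replicates, seed=int(rng.integers(2**31))
            )
            for k, (img, gt) in enumerate(fixtures.generate_replicates(spec, jitter), start=1):
                name = f"{tid}_{view}_r{k}.png"
                save_image(os.path.join(out_dir, name), img)
                r, c, h, w = spec.card_rect
                rows.append(
                    {
                        "image_path": name,
                        "turtle_id": tid,
                        "view": view,
                        "replicate": k,
                        "source": source,
                        "card_x": c,
                        "card_y": r,
                        "card_w": w,
                        "card_h": h,
                        "card_edge_px": spec.card_edge_px,
                    }
                )
                gt_rows.append(
                    {
                        "turtle_id": tid,
                        "view": view,
                        "replicate": k,
                        "n_objects": gt.n_objects,
                        "fractional_area": gt.fractional_area,
                        "scute_interior_px": gt.scute_interior_px,
                        "mm_per_pixel": gt.mm_per_pixel,
                    }
                )
    manifest = pd.DataFrame(rows)
    _write_csv(manifest, os.path.join(out_dir, "sidecar.csv"))
    _write_csv(pd.DataFrame(gt_rows), os.path.join(out_dir, "ground_truth.csv"))
    if n_volunteers:
        probs = rng.uniform(0.05, 0.95, size=len(fixtures.SURVEY_CATEGORIES))
        survey = fixtures.generate_survey(
            n_turtles, n_volunteers, probs, seed=int(rng.integers(2**31))
        )
        _write_csv(survey, os.path.join(out_dir, "survey.csv"))
    return manifest
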