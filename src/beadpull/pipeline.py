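"""End-to-end pipelines tying the stages together.

Two modes:

* ``beads`` — simulate (or load) bead scenes, detect beads, draw and
  score radial profiles, apply the SD-vs-mean QC filter, and write the
  per-bead table plus exclusion report;
* ``condensates`` — simulate (or load) a condensate time series, apply
  rolling-ball background correction, count condensates per time point,
  and compute the reference-vs-probe colocalization fraction.

Every run writes the fully resolved config and a log of parameters,
seeds, and exclusions next to its outputs; re-running from that config
reproduces the outputs bitwise.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import beads as bq
from . import condensates as cq
from .io import RunConfig, load_config, write_scene
from .scene import ImageScene, SceneTruth
from .synth import (
    BeadSceneSpec,
    BeadSpec,
    CondensateSceneSpec,
    generate_bead_scene,
    generate_condensate_series,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "build_bead_scene_spec", "build_condensate_spec"]


def build_bead_scene_spec(block: dict, seed: int) -> BeadSceneSpec:
    """Build a :class:`BeadSceneSpec` from a config ``simulate`` block."""
    beads = [
        BeadSpec(
            center=tuple(b["center"]),
            radius=float(b["radius"]),
            rim_thickness=float(b.get("rim_thickness", 3.0)),
            rim_intensity=dict(b.get("rim_intensity", {})),
            core_intensity=dict(b.get("core_intensity", {})),
        )
        for b in block.get("beads", [])
    ]
    return BeadSceneSpec(
        image_shape=tuple(block["image_shape"]),
        beads=beads,
        background_level=dict(block.get("background_level", {})),
        noise_sd=float(block.get("noise_sd", 0.0)),
        blur_sigma=float(block.get("blur_sigma", 0.0)),
        allow_adjacent=bool(block.get("allow_adjacent", False)),
        seed=seed,
    )


def build_condensate_spec(block: dict, seed: int) -> CondensateSceneSpec:
    """Build a :class:`CondensateSceneSpec` from a config ``simulate`` block."""
    kwargs = {k: v for k, v in block.items() if k != "kind"}
    kwargs["image_shape"] = tuple(kwargs["image_shape"])
    return CondensateSceneSpec(seed=seed, **kwargs)


def _setup_run_logging(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    root = logging.getLogger("beadpull")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    return handler


def run_pipeline(config: RunConfig | dict | str | Path) -> Path:
    """Execute the configured pipeline; returns the output directory.

    Any stage error aborts with the stage name and the input identifier
    attached, so batch users can tell which image failed.
    """
    cfg = config if isinstance(config, RunConfig) else load_config(config)
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(out_dir)
    try:
        cfg.dump(out_dir / "resolved_config.yaml")
        logger.info("run start: mode=%s seed=%d", cfg.mode, cfg.seed)
        if cfg.mode == "beads":
            _run_beads(cfg, out_dir)
        else:
            _run_condensates(cfg, out_dir)
        logger.info("run complete: outputs in %s", out_dir)
    finally:
        logging.getLogger("beadpull").removeHandler(handler)
        handler.close()
    return out_dir


def _load_or_simulate_bead_scenes(
    cfg: RunConfig, out_dir: Path
) -> list[tuple[str, ImageScene, SceneTruth | None]]:
    from .io import read_scene  # local to keep module import light

    if cfg.simulate is not None:
        spec = build_bead_scene_spec(cfg.simulate, cfg.seed)
        scene, truth = generate_bead_scene(spec)
        write_scene(scene, out_dir / "scene_pos0.tif")
        truth.objects.to_csv(out_dir / "scene_truth.csv", index=False)
        return [("simulated:pos0", scene, truth)]
    return [
        (str(p), read_scene(p), None) for p in cfg.images
    ]


def _run_beads(cfg: RunConfig, out_dir: Path) -> None:
    try:
        scenes = _load_or_simulate_bead_scenes(cfg, out_dir)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate/load' failed: {exc}") from exc

    tables = []
    for image_id, scene, _truth in scenes:
        try:
            table, _profiles = bq.quantify_scene(
                scene.channel(cfg.channel),
                n_lines=cfg.n_lines,
                extension_frac=cfg.extension_frac,
                step=cfg.step,
                min_radius=cfg.min_radius,
                well_id=cfg.well_id,
                replicate_id=cfg.replicate_id,
                condition=cfg.condition,
            )
        except Exception as exc:
            raise RuntimeError(
                f"stage 'bead-quantify' failed on {image_id!r}: {exc}"
            ) from exc
        table.insert(0, "image_id", image_id)
        tables.append(table)
    per_bead = pd.concat(tables, ignore_index=True)
    per_bead.to_csv(out_dir / "beads.csv", index=False)

    measured = per_bead[per_bead["exclusion_reason"] == ""]
    keep = measured["sd_score"] < measured["mean_score"] / 2.0
    retained = measured[keep]
    excluded = per_bead[~per_bead.index.isin(retained.index)]
    retained.to_csv(out_dir / "beads_qc_retained.csv", index=False)
    excluded.to_csv(out_dir / "beads_qc_excluded.csv", index=False)
    logger.info(
        "QC: %d/%d beads retained (sd < mean/2)", len(retained), len(per_bead)
    )


def _run_condensates(cfg: RunConfig, out_dir: Path) -> None:
    from .io import read_scene

    try:
        if cfg.simulate is not None:
            spec = build_condensate_spec(cfg.simulate, cfg.seed)
            series, truth = generate_condensate_series(spec)
            truth.objects.to_csv(out_dir / "scene_truth.csv", index=False)
            for i, scene in enumerate(series):
                write_scene(scene, out_dir / f"scene_t{i}.tif")
        else:
            series = [read_scene(p) for p in cfg.images]
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate/load' failed: {exc}") from exc

    try:
        kinetics = cq.condensate_kinetics(
            series,
            channel=cfg.ref_channel,
            threshold_policy=cfg.threshold_policy,
            min_area=cfg.min_area,
            rolling_ball_radius=cfg.rolling_ball_radius,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'kinetics' failed: {exc}") from exc
    kinetics.to_csv(out_dir / "kinetics.csv", index=False)

    coloc_rows = []
    spot_tables = []
    for i, scene in enumerate(series):
        try:
            ref_img = cq.rolling_ball_subtract(
                scene.channel(cfg.ref_channel), cfg.rolling_ball_radius
            )
            cset = cq.count_condensates(
                ref_img,
                threshold_policy=cfg.threshold_policy,
                min_area=cfg.min_area,
                image_id=str(i),
                time_point=float(scene.metadata.get("time_point", i)),
                extra_channels={cfg.probe_channel: scene.channel(cfg.probe_channel)},
            )
            res = cq.colocalization_fraction(
                cset, scene.channel(cfg.probe_channel), k=cfg.coloc_k
            )
        except Exception as exc:
            raise RuntimeError(
                f"stage 'coloc' failed on scene {i}: {exc}"
            ) from exc
        spots = cset.spots.copy()
        spots.insert(0, "time_point", cset.time_point)
        spot_tables.append(spots)
        coloc_rows.append(
            {
                "time_point": cset.time_point,
                "n_ref": res.n_ref,
                "n_positive": res.n_positive,
                "fraction": res.fraction,
                "k": res.k,
                "empty_reference": res.empty_reference,
            }
        )
    non_empty = [t for t in spot_tables if len(t)]
    spots_out = (
        pd.concat(non_empty, ignore_index=True) if non_empty else spot_tables[0]
    )
    spots_out.to_csv(out_dir / "spots.csv", index=False)
    pd.DataFrame(coloc_rows).to_csv(out_dir / "coloc.csv", index=False)
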