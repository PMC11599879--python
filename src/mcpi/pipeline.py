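"""End-to-end pipeline: simulate -> sample -> index -> trend -> cena -> validate.

A single YAML config drives every stage; one global seed deterministically
derives per-stage seeds (stage-name hashing), so adding a stage never
perturbs the randomness of earlier ones.  Every output file is listed in a
JSON-lines manifest with a content hash; identical config + seed yields an
identical manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cena as cena_mod
from . import storms as storms_mod
from .index import IndexConstants, enrich_records
from .scene import (
    SceneConfig,
    generate_scene,
    generate_storms,
    scene_to_dir,
    storms_to_geojson,
    with_ndvi_damage,
)
from .transects import extract_regions, frame_to_records, records_to_frame
from .trends import trend_table

__all__ = ["RunConfig", "run_pipeline", "PipelineError", "stage_seed"]

log = logging.getLogger("mcpi")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed below 2**31 from the global seed."""
    digest = hashlib.blake2s(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; see ``RunConfig.from_yaml``."""

    out_dir: Path
    seed: int = 0
    scene: SceneConfig = field(
        default_factory=lambda: SceneConfig(
            n_cols=240,
            n_rows=80,
            width_m=(600.0, 1100.0, 1500.0, 450.0, 900.0, 1300.0),
            height_m=(3.0, 6.0, 9.0, 2.0, 11.0, 7.0),
            ndvi=(0.55, 0.65, 0.75, 0.5, 0.8, 0.7),
            n_regions=6,
        )
    )
    epochs: list[dict] = field(
        default_factory=lambda: [
            {"year": 2007, "width_factor": 1.0, "height_factor": 1.0, "ndvi_factor": 1.0},
            {"year": 2019, "width_factor": 1.0, "height_factor": 0.8, "ndvi_factor": 1.0},
        ]
    )
    sampling: dict = field(
        default_factory=lambda: {"spacing": 500.0, "length": 6000.0, "include_empty_transects": False}
    )
    constants: IndexConstants = field(default_factory=IndexConstants)
    trend: dict = field(default_factory=lambda: {"alpha": 0.05})
    cena: dict = field(default_factory=lambda: {"k": 4, "bootstrap": 50, "metric": "one_minus_cos"})
    validation: dict = field(
        default_factory=lambda: {
            "n_storms": 8,
            "wind_range": [50.0, 130.0],
            "wind_threshold_kn": 64.0,
            "buffer_m": 500.0,
            "base_drop": 0.3,
            "noise_sd": 0.03,
        }
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        kwargs["out_dir"] = Path(raw.get("out_dir", "mcpi_run"))
        kwargs["seed"] = int(raw.get("seed", 0))
        if "scene" in raw:
            kwargs["scene"] = SceneConfig(**raw["scene"])
        if "epochs" in raw:
            kwargs["epochs"] = raw["epochs"]
        if "index" in raw:
            kwargs["constants"] = IndexConstants(**raw["index"])
        for key in ("sampling", "trend", "cena", "validation"):
            if key in raw:
                base = cls.__dataclass_fields__[key].default_factory()  # type: ignore[misc]
                base.update(raw[key])
                kwargs[key] = base
        return cls(**kwargs)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _epoch_config(base: SceneConfig, epoch: dict) -> SceneConfig:
    from .scene import _per_region

    n = base.n_regions
    return replace(
        base,
        width_m=_per_region(base.width_m, n, "width_m") * _per_region(epoch.get("width_factor", 1.0), n, "width_factor"),
        height_m=_per_region(base.height_m, n, "height_m") * _per_region(epoch.get("height_factor", 1.0), n, "height_factor"),
        ndvi=_per_region(base.ndvi, n, "ndvi") * _per_region(epoch.get("ndvi_factor", 1.0), n, "ndvi_factor"),
    )


def run_pipeline(config: RunConfig) -> list[dict]:
    """Execute every stage and return the output manifest.

    Stages consume and produce only files under ``config.out_dir`` (plus
    in-memory hand-off), so each can be rerun independently from the
    intermediates on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    years = [int(e["year"]) for e in config.epochs]

    def run_stage(name, fn):
        log.info("[%s] starting", name)
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        log.info("[%s] done", name)
        return result

    # -- simulate ---------------------------------------------------------
    def simulate():
        seed = stage_seed(config.seed, "simulate")
        scenes = {}
        for epoch in config.epochs:
            cfg = _epoch_config(config.scene, epoch)
            scene = generate_scene(cfg, seed=seed, epoch=int(epoch["year"]))
            d = out / "scenes" / str(epoch["year"])
            scene_to_dir(scene, d)
            artifacts.extend(sorted(d.iterdir()))
            scenes[int(epoch["year"])] = scene
        v = config.validation
        tracks = generate_storms(
            int(v["n_storms"]), tuple(v["wind_range"]), scenes[years[-1]],
            seed=stage_seed(config.seed, "storms"),
        )
        storms_to_geojson(tracks, out / "storms.geojson")
        artifacts.append(out / "storms.geojson")
        return scenes, tracks

    scenes, tracks = run_stage("simulate", simulate)

    # -- sample -----------------------------------------------------------
    def sample():
        frames = []
        for year in years:
            recs = extract_regions(
                scenes[year],
                spacing=float(config.sampling["spacing"]),
                length=float(config.sampling["length"]),
                include_empty_transects=bool(config.sampling["include_empty_transects"]),
            )
            frames.append(records_to_frame(recs))
        df = pd.concat(frames, ignore_index=True)
        df.to_csv(out / "records.csv", index=False)
        artifacts.append(out / "records.csv")
        return df

    records_df = run_stage("sample", sample)

    # -- index ------------------------------------------------------------
    def index_stage():
        frames = []
        for year in years:
            recs = frame_to_records(records_df[records_df["epoch"] == year])
            frames.append(records_to_frame(enrich_records(recs, config.constants)))
        df = pd.concat(frames, ignore_index=True)
        df.to_csv(out / "records_indexed.csv", index=False)
        artifacts.append(out / "records_indexed.csv")
        return df

    indexed_df = run_stage("index", index_stage)

    # -- trend ------------------------------------------------------------
    def trend():
        if len(years) < 3:
            log.info("[trend] fewer than 3 epochs: stage writes an empty table")
            df = pd.DataFrame()
        else:
            series = indexed_df.rename(columns={"region_id": "unit_id", "epoch": "year"})[
                ["unit_id", "year", "amw_m"]
            ]
            df = trend_table(series, alpha=float(config.trend["alpha"]))
        df.to_csv(out / "trend.csv", index=False)
        artifacts.append(out / "trend.csv")
        return df

    run_stage("trend", trend)

    # -- cena -------------------------------------------------------------
    def run_cena():
        ya, yb = years[0], years[-1]
        sub = indexed_df[indexed_df["epoch"].isin([ya, yb])]
        # exchange analysis needs the common region set in both epochs
        common = set(sub[sub["epoch"] == ya]["region_id"]) & set(sub[sub["epoch"] == yb]["region_id"])
        sub = sub[sub["region_id"].isin(common)]
        recs = frame_to_records(sub)
        X = cena_mod.normalize_features(recs)
        k = int(config.cena["k"])
        model = cena_mod.cluster_cells(X, k=k, metric=str(config.cena["metric"]))
        labels_df = pd.DataFrame(
            {"region_id": X.region_ids, "epoch": X.epochs, "cluster": model.labels}
        )
        labels_df.to_csv(out / "cena_labels.csv", index=False)
        membership = cena_mod.bootstrap_membership(
            X, model, reps=int(config.cena["bootstrap"]), seed=stage_seed(config.seed, "cena")
        )
        pd.DataFrame(
            membership.probabilities, columns=[f"cluster_{c}" for c in range(1, k + 1)]
        ).assign(region_id=X.region_ids, epoch=X.epochs).to_csv(
            out / "cena_membership.csv", index=False
        )
        ex = cena_mod.exchange_matrix(
            cena_mod.labels_by_epoch(X, model, ya),
            cena_mod.labels_by_epoch(X, model, yb),
            k=k, epoch_a=ya, epoch_b=yb,
        )
        ex.to_frame().to_csv(out / "cena_exchange.csv")
        ex.edges().to_csv(out / "cena_edges.csv", index=False)
        artifacts.extend(
            out / f for f in ("cena_labels.csv", "cena_membership.csv", "cena_exchange.csv", "cena_edges.csv")
        )

    run_stage("cena", run_cena)

    # -- validate ---------------------------------------------------------
    def validate():
        v = config.validation
        yb = years[-1]
        scene = scenes[yb]
        recs = frame_to_records(indexed_df[indexed_df["epoch"] == yb])
        severe = storms_mod.select_severe(tracks, scene.coastline, float(v["wind_threshold_kn"]))
        zones = storms_mod.impact_zones(severe, scene, buffer_m=float(v["buffer_m"]))
        rng = np.random.default_rng(stage_seed(config.seed, "validate"))
        mcpi_of = {r.region_id: r.mcpi for r in recs}
        deltas = [
            -float(v["base_drop"])
            * (1.0 - (np.mean([mcpi_of.get(r, 0.0) for r in z.region_ids]) if z.region_ids else 0.0)
               / config.constants.scale)
            + rng.normal(0.0, float(v["noise_sd"]))
            for z in zones
        ]
        damaged = with_ndvi_damage(scene, [z.polygon for z in zones], deltas)
        responses = []
        for z in zones:
            responses.extend(storms_mod.ndvi_response(scene, damaged, z, recs))
        df = pd.DataFrame(
            [
                {
                    "region_id": r.region_id,
                    "storm_id": r.storm_id,
                    "mcpi": r.mcpi,
                    "ndvi_before": r.ndvi_before,
                    "ndvi_after": r.ndvi_after,
                    "delta_ndvi": r.delta_ndvi,
                }
                for r in responses
            ]
        )
        df.to_csv(out / "storm_responses.csv", index=False)
        artifacts.append(out / "storm_responses.csv")
        if len(df) >= 3 and df["mcpi"].nunique() > 1 and df["delta_ndvi"].nunique() > 1:
            rho, p = storms_mod.spearman(df["mcpi"], df["delta_ndvi"])
        else:
            rho, p = float("nan"), float("nan")
        summary = {"rho": rho, "p_value": p, "n": int(len(df))}
        with open(out / "validation_summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, allow_nan=True)
        artifacts.append(out / "validation_summary.json")

    run_stage("validate", validate)

    # -- manifest ---------------------------------------------------------
    manifest = [
        {"path": str(p.relative_to(out)), "sha256": _hash_file(p)}
        for p in sorted(set(artifacts))
    ]
    with open(out / "manifest.jsonl", "w") as fh:
        for entry in manifest:
            fh.write(json.dumps(entry) + "\n")
    return manifest
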