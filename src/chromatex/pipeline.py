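"""End-to-end pipeline runs driven by a YAML config.

A run either simulates scenes (one of the three generator kinds) or loads
image files, then executes the requested stages in dependency order —
simulate → segment → texture / foci / quantify → compare — writing CSV and
JSON artifacts under ``{output_dir}/{stage}/`` plus a ``manifest.json`` at
the run root (config echo, package version, per-stage record counts).
Runs are deterministic given the configured seed; re-running overwrites
outputs with byte-identical files.

Config schema (YAML)::

    seed: 1
    output_dir: runs/demo
    stages: [simulate, segment, texture, compare]
    simulate:
      kind: texture            # texture | foci | tma
      n_samples_per_arm: 5
      arms:                    # texture kind only; per-arm SceneSpec overrides
        control: {texture_regime: control, clumpiness: 0.0}
        treated: {texture_regime: treated, clumpiness: 0.4}
      spec: {height: 256, width: 256, n_nuclei: 12}   # shared overrides
    glcm: {levels: 32, distance: 1}
    segmentation: {smoothing_sigma: 2.0, min_area: 100}
    foci: {positivity_cutpoint: 5}
    compare: {method: mann_whitney}
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_io import TEXTURE_TABLE_COLUMNS, read_image, write_table
from .foci import FociParams, detect_foci
from .quantify import exclude_low_epithelium, score_core
from .segment import SegmentationParams, compartment_masks, segment_nuclei
from .stats import compare_texture_groups
from .synth import SceneSpec, generate_foci_scene, generate_texture_scene, generate_tma_scene, write_scene
from .texture import GLCMParams, interpret_chromatin_pattern, nucleus_texture_profile, percent_change

__all__ = ["RunConfig", "ConfigError", "load_config", "run_pipeline"]

log = logging.getLogger("chromatex")

VALID_STAGES = ("simulate", "segment", "texture", "foci", "quantify", "compare")


class ConfigError(ValueError):
    """Invalid run configuration; message lists the offending keys."""


@dataclasses.dataclass
class RunConfig:
    seed: int
    output_dir: Path
    stages: list[str]
    simulate: dict | None = None
    inputs: list[Path] | None = None
    glcm: GLCMParams = GLCMParams()
    segmentation: SegmentationParams = SegmentationParams()
    foci: FociParams = FociParams()
    compare: dict = dataclasses.field(default_factory=lambda: {"method": "mann_whitney"})
    log_level: str = "info"
    raw: dict = dataclasses.field(default_factory=dict)


def _build(cls, block: dict | None, name: str):
    block = dict(block or {})
    valid = {f.name for f in dataclasses.fields(cls)}
    bad = set(block) - valid
    if bad:
        raise ConfigError(f"unknown keys in '{name}' block: {sorted(bad)}")
    try:
        return cls(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{name}' block: {exc}") from exc


def load_config(source: str | Path | dict) -> RunConfig:
    """Parse and validate a YAML config file (or pre-parsed dict)."""
    if isinstance(source, dict):
        raw = dict(source)
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
    bad_keys = set(raw) - {"seed", "output_dir", "stages", "simulate", "inputs",
                           "glcm", "segmentation", "foci", "compare", "log_level"}
    if bad_keys:
        raise ConfigError(f"unknown config keys: {sorted(bad_keys)}")
    if "output_dir" not in raw:
        raise ConfigError("missing required key: output_dir")
    has_sim = raw.get("simulate") is not None
    has_inputs = raw.get("inputs") is not None
    if has_sim == has_inputs:
        raise ConfigError("exactly one of 'simulate' or 'inputs' must be given")
    if has_inputs:
        missing = [p for p in raw["inputs"] if not Path(p).exists()]
        if missing:
            raise ConfigError(f"input files not found: {missing}")
    stages = list(raw.get("stages") or (("simulate",) if has_sim else ()) )
    bad_stages = set(stages) - set(VALID_STAGES)
    if bad_stages:
        raise ConfigError(f"unknown stages: {sorted(bad_stages)}")
    tuple_fix = dict(raw.get("glcm") or {})
    if "angles" in tuple_fix:
        tuple_fix["angles"] = tuple(tuple_fix["angles"])
    if "nucleus_radius_range" in (raw.get("simulate") or {}).get("spec", {}):
        raw["simulate"]["spec"]["nucleus_radius_range"] = tuple(
            raw["simulate"]["spec"]["nucleus_radius_range"])
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        output_dir=Path(raw["output_dir"]),
        stages=stages,
        simulate=raw.get("simulate"),
        inputs=[Path(p) for p in raw["inputs"]] if has_inputs else None,
        glcm=_build(GLCMParams, tuple_fix, "glcm"),
        segmentation=_build(SegmentationParams, raw.get("segmentation"), "segmentation"),
        foci=_build(FociParams, raw.get("foci"), "foci"),
        compare=dict(raw.get("compare") or {"method": "mann_whitney"}),
        log_level=str(raw.get("log_level", "info")),
        raw=raw,
    )


def _scene_spec(sim: dict, overrides: dict, seed: int) -> SceneSpec:
    block = dict(sim.get("spec") or {})
    block.update(overrides)
    if "nucleus_radius_range" in block:
        block["nucleus_radius_range"] = tuple(block["nucleus_radius_range"])
    spec = _build(SceneSpec, block, "simulate.spec")
    return replace(spec, seed=seed)


def _json_dump(obj: Any, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
    log.info("wrote %s", path)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_pipeline(config: RunConfig | str | Path | dict) -> dict:
    """Execute the configured stages and return the run manifest."""
    cfg = config if isinstance(config, RunConfig) else load_config(config)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO),
                        format="[%(name)s] %(levelname)s %(message)s")
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"config": cfg.raw, "version": __version__,
                                "seed": cfg.seed, "stages": {}, "artifacts": []}

    scenes: list[tuple[str, str, Any]] = []  # (sample_id, group, SyntheticScene)
    kind = (cfg.simulate or {}).get("kind", "texture")

    if cfg.simulate is not None:
        sim = cfg.simulate
        n = int(sim.get("n_samples_per_arm", sim.get("n_samples", 3)))
        arms = sim.get("arms") or {"default": {}}
        gen = {"texture": generate_texture_scene, "foci": generate_foci_scene,
               "tma": generate_tma_scene}
        if kind not in gen:
            raise ConfigError(f"unknown simulate.kind: {kind}")
        for a_idx, (arm, overrides) in enumerate(sorted(arms.items())):
            for k in range(n):
                spec = _scene_spec(sim, overrides or {}, cfg.seed + 10_000 * a_idx + k)
                scenes.append((f"{arm}_{k}", arm, gen[kind](spec)))
        if "simulate" in cfg.stages:
            for sample_id, _, scene in scenes:
                write_scene(scene, out / "simulate", sample_id)
                manifest["artifacts"].append(str(out / "simulate" / f"{sample_id}.tif"))
            manifest["stages"]["simulate"] = {"n_scenes": len(scenes), "kind": kind}

    masks: dict[str, Any] = {}
    if "segment" in cfg.stages:
        import tifffile

        seg_dir = out / "segment"
        seg_dir.mkdir(parents=True, exist_ok=True)
        counts = {}
        for sample_id, _, scene in scenes:
            mask = segment_nuclei(scene.channels["dapi"], cfg.segmentation)
            masks[sample_id] = mask
            tifffile.imwrite(seg_dir / f"{sample_id}_nuclei.tif",
                             mask.labels.astype(np.uint16))
            counts[sample_id] = mask.n_labels
        manifest["stages"]["segment"] = {"n_nuclei": counts}
        manifest["artifacts"].append(str(seg_dir))

    def _mask_for(sample_id, scene):
        return masks.get(sample_id) or scene.truth_nuclei

    per_sample_means: list[dict] = []
    if "texture" in cfg.stages:
        tables = []
        for sample_id, group, scene in scenes:
            table, means = nucleus_texture_profile(scene.channels["dapi"],
                                                   _mask_for(sample_id, scene),
                                                   cfg.glcm, sample_id=sample_id, group=group)
            tables.append(table)
            per_sample_means.append(means)
        all_rows = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(
            columns=TEXTURE_TABLE_COLUMNS)
        write_table(all_rows, out / "texture" / "per_nucleus.csv", TEXTURE_TABLE_COLUMNS)
        write_table(pd.DataFrame(per_sample_means), out / "texture" / "per_sample_means.csv")
        manifest["stages"]["texture"] = {"n_nuclei_rows": len(all_rows),
                                         "n_samples": len(per_sample_means),
                                         "glcm": dataclasses.asdict(cfg.glcm)}
        manifest["artifacts"] += [str(out / "texture" / "per_nucleus.csv"),
                                  str(out / "texture" / "per_sample_means.csv")]

    if "foci" in cfg.stages:
        rows, summaries = [], {}
        for sample_id, group, scene in scenes:
            channel = scene.channels.get("foci") or scene.channels["dapi"]
            result = detect_foci(channel, _mask_for(sample_id, scene), cfg.foci)
            for lab, count in result.counts.items():
                rows.append({"sample_id": sample_id, "group": group, "nucleus_id": lab,
                             "foci_count": count,
                             "positive": count > cfg.foci.positivity_cutpoint})
            summaries[sample_id] = {"fraction_positive": result.fraction_positive,
                                    "histogram": result.histogram,
                                    "cutpoint": cfg.foci.positivity_cutpoint}
        write_table(rows, out / "foci" / "per_nucleus.csv",
                    ["sample_id", "group", "nucleus_id", "foci_count", "positive"])
        _json_dump(summaries, out / "foci" / "summary.json")
        manifest["stages"]["foci"] = {"n_rows": len(rows)}
        manifest["artifacts"] += [str(out / "foci" / "per_nucleus.csv"),
                                  str(out / "foci" / "summary.json")]

    if "quantify" in cfg.stages:
        scores = []
        for sample_id, group, scene in scenes:
            if scene.truth_compartments is not None and not masks:
                comp = scene.truth_compartments
            else:
                comp = compartment_masks(scene.channels["dapi"],
                                         scene.channels.get("cytokeratin", scene.channels["dapi"]),
                                         cfg.segmentation)
            s = score_core(scene.channels.get("target", scene.channels["dapi"]), comp,
                           core_mask=scene.truth_core, core_id=sample_id)
            scores.append(s)
        kept, report = exclude_low_epithelium(scores)
        write_table([dataclasses.asdict(s) for s in scores], out / "quantify" / "per_core.csv",
                    ["core_id", "nuclear_score", "cytoplasmic_score",
                     "epithelium_fraction", "included"])
        _json_dump(report, out / "quantify" / "exclusions.json")
        manifest["stages"]["quantify"] = {"n_cores": len(scores), "n_kept": len(kept)}
        manifest["artifacts"] += [str(out / "quantify" / "per_core.csv"),
                                  str(out / "quantify" / "exclusions.json")]

    if "compare" in cfg.stages:
        df = pd.DataFrame(per_sample_means)
        if df.empty or "group" not in df or df["group"].nunique() != 2:
            raise ConfigError("compare stage needs a texture stage with exactly two arms")
        groups = sorted(df["group"].unique())
        control_df = df[df["group"] == groups[0]]
        treated_df = df[df["group"] == groups[1]]
        comparisons = compare_texture_groups(control_df, treated_df,
                                             method=cfg.compare.get("method", "mann_whitney"))
        feats = ("asm", "contrast", "correlation", "idm", "entropy")
        means = {g: {f: float(np.nanmean(d[f].to_numpy(dtype=float))) for f in feats}
                 for g, d in (("control", control_df), ("treated", treated_df))}
        changes = percent_change(means["treated"], means["control"])
        pattern = interpret_chromatin_pattern(changes)
        write_table([dataclasses.asdict(c) for c in comparisons],
                    out / "compare" / "comparisons.csv",
                    ["parameter", "statistic", "p_value", "method", "n_a", "n_b", "notes"])
        _json_dump({"feature_means": means, "percent_change": changes,
                    "pattern": dataclasses.asdict(pattern)},
                   out / "compare" / "summary.json")
        manifest["stages"]["compare"] = {"n_comparisons": len(comparisons),
                                         "arms": groups}
        manifest["artifacts"] += [str(out / "compare" / "comparisons.csv"),
                                  str(out / "compare" / "summary.json")]

    _json_dump(manifest, out / "manifest.json")
    return manifest
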