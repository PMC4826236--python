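"""Multi-scene study workflows built on the analysis modules.

These functions script the common experiment shapes: a treated-vs-control
chromatin texture comparison over many simulated coverslips, and recovery
benchmarks of the segmentation / foci / quantification modules against the
generator's ground truth. They are the building blocks of the pipeline
runner, the examples and the acceptance checks.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import ImageGrid, LabelMask
from .foci import FociParams, classify_positive, detect_foci
from .quantify import CompartmentScore, exclude_low_epithelium, score_core
from .segment import SegmentationParams, compartment_masks, segment_nuclei
from .stats import GroupComparison, compare_texture_groups
from .synth import SceneSpec, generate_foci_scene, generate_texture_scene, generate_tma_scene
from .texture import (GLCMParams, PatternCall, interpret_chromatin_pattern,
                      nucleus_texture_profile, percent_change)

__all__ = [
    "texture_arm_study",
    "match_nuclei",
    "segmentation_recovery",
    "foci_recovery",
    "tma_recovery",
]


def _sample_means_table(means_list: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(means_list)


def texture_arm_study(n_seeds: int = 20, seed: int = 0,
                      control_spec: SceneSpec | None = None,
                      treated_spec: SceneSpec | None = None,
                      glcm: GLCMParams = GLCMParams(),
                      seg: SegmentationParams = SegmentationParams(),
                      use_truth_masks: bool = False) -> dict:
    """Simulate control and treated coverslips and compare their texture.

    Each seed yields one sample (coverslip) per arm; per-sample feature
    means are computed over the sample's nuclei, percent changes compare
    arm-level means, and a two-tailed Mann-Whitney U test compares the two
    arms per feature. Set ``use_truth_masks`` to bypass segmentation and
    measure texture inside the generator's own nucleus masks.
    """
    if control_spec is None:
        control_spec = SceneSpec(texture_regime="control", clumpiness=0.0)
    if treated_spec is None:
        treated_spec = SceneSpec(texture_regime="treated", clumpiness=0.4)
    arms: dict[str, pd.DataFrame] = {}
    for group, spec in (("control", control_spec), ("treated", treated_spec)):
        means_rows = []
        for k in range(n_seeds):
            scene_spec = replace(spec, seed=seed + 10_000 * (group == "treated") + k)
            scene = generate_texture_scene(scene_spec)
            dapi = scene.channels["dapi"]
            nuclei = scene.truth_nuclei if use_truth_masks else segment_nuclei(dapi, seg)
            _, means = nucleus_texture_profile(dapi, nuclei, glcm,
                                               sample_id=f"{group}_{k}", group=group)
            means_rows.append(means)
        arms[group] = _sample_means_table(means_rows)
    arm_means = {g: {f: float(np.nanmean(df[f].to_numpy(dtype=float)))
                     for f in ("asm", "contrast", "correlation", "idm", "entropy")}
                 for g, df in arms.items()}
    changes = percent_change(arm_means["treated"], arm_means["control"])
    pattern = interpret_chromatin_pattern(changes)
    comparisons = compare_texture_groups(arms["control"], arms["treated"])
    return {
        "per_sample": arms,
        "arm_means": arm_means,
        "percent_change": changes,
        "pattern": pattern,
        "comparisons": comparisons,
    }


def match_nuclei(predicted: LabelMask, truth: LabelMask,
                 iou_threshold: float = 0.5) -> dict:
    """Greedy max-overlap matching of predicted to truth nuclei.

    Returns per-match IoU plus detection precision and recall at the given
    IoU threshold.
    """
    pred_ids = list(predicted.label_ids())
    true_ids = list(truth.label_ids())
    pairs = []
    for t in true_ids:
        tmask = truth.labels == t
        overlaps = np.bincount(predicted.labels[tmask].ravel(),
                               minlength=predicted.labels.max() + 1)
        overlaps[0] = 0
        if overlaps.max() == 0:
            continue
        p = int(overlaps.argmax())
        inter = overlaps[p]
        union = tmask.sum() + (predicted.labels == p).sum() - inter
        pairs.append((int(t), p, float(inter / union)))
    matched = [(t, p, iou) for t, p, iou in pairs if iou >= iou_threshold]
    # one predicted label may match at most one truth label
    seen: dict[int, tuple[int, int, float]] = {}
    for t, p, iou in matched:
        if p not in seen or iou > seen[p][2]:
            seen[p] = (t, p, iou)
    matched = list(seen.values())
    n_match = len(matched)
    precision = n_match / len(pred_ids) if pred_ids else 0.0
    recall = n_match / len(true_ids) if true_ids else 0.0
    ious = [iou for _, _, iou in matched]
    return {"n_true": len(true_ids), "n_pred": len(pred_ids), "n_matched": n_match,
            "precision": precision, "recall": recall, "ious": ious,
            "min_iou": min(ious) if ious else 0.0,
            "mean_iou": float(np.mean(ious)) if ious else 0.0}


def segmentation_recovery(n_seeds: int = 20, seed: int = 0,
                          spec: SceneSpec | None = None,
                          seg: SegmentationParams = SegmentationParams()) -> dict:
    """Precision/recall/IoU of nucleus segmentation on generator scenes."""
    if spec is None:
        spec = SceneSpec()
    stats = []
    for k in range(n_seeds):
        scene = generate_texture_scene(replace(spec, seed=seed + k))
        pred = segment_nuclei(scene.channels["dapi"], seg)
        stats.append(match_nuclei(pred, scene.truth_nuclei))
    n_true = sum(s["n_true"] for s in stats)
    n_pred = sum(s["n_pred"] for s in stats)
    n_match = sum(s["n_matched"] for s in stats)
    all_ious = [iou for s in stats for iou in s["ious"]]
    return {
        "n_scenes": n_seeds,
        "precision": n_match / n_pred if n_pred else 0.0,
        "recall": n_match / n_true if n_true else 0.0,
        "min_iou": min(all_ious) if all_ious else 0.0,
        "mean_iou": float(np.mean(all_ious)) if all_ious else 0.0,
    }


def foci_recovery(n_seeds: int = 20, seed: int = 0,
                  spec: SceneSpec | None = None,
                  params: FociParams = FociParams(),
                  counts_range: tuple[int, int] = (0, 12)) -> dict:
    """Fraction of nuclei whose detected focus count equals the planted count.

    Per scene, the per-nucleus planted count is drawn uniformly from
    ``counts_range`` (one scene per draw so each scene has one planted count,
    cycling through the range across seeds); detection runs on the
    generator's truth masks so the benchmark isolates the detector.
    """
    rng = np.random.default_rng(seed)
    lo, hi = counts_range
    n_exact = 0
    n_total = 0
    n_correct_class = 0
    for k in range(n_seeds):
        planted = int(rng.integers(lo, hi + 1))
        scene_spec = (SceneSpec() if spec is None else spec)
        scene_spec = replace(scene_spec, foci_per_nucleus=planted, seed=seed + 500 + k)
        scene = generate_foci_scene(scene_spec)
        result = detect_foci(scene.channels["foci"], scene.truth_nuclei, params)
        for lab, count in result.counts.items():
            n_total += 1
            if count == planted:
                n_exact += 1
            if classify_positive(count, params.positivity_cutpoint) == classify_positive(
                    planted, params.positivity_cutpoint):
                n_correct_class += 1
    return {"n_nuclei": n_total,
            "exact_fraction": n_exact / n_total if n_total else 0.0,
            "classification_fraction": n_correct_class / n_total if n_total else 0.0}


def tma_recovery(n_seeds: int = 10, seed: int = 0,
                 spec: SceneSpec | None = None,
                 seg: SegmentationParams = SegmentationParams(),
                 use_truth_masks: bool = True) -> dict:
    """Mean absolute error of compartment scores against generator levels."""
    if spec is None:
        spec = SceneSpec()
    nuc_err, cyt_err, scores = [], [], []
    for k in range(n_seeds):
        scene = generate_tma_scene(replace(spec, seed=seed + 900 + k))
        comp = (scene.truth_compartments if use_truth_masks
                else compartment_masks(scene.channels["dapi"], scene.channels["cytokeratin"], seg))
        s = score_core(scene.channels["target"], comp, core_mask=scene.truth_core,
                       core_id=f"core_{k}")
        scores.append(s)
        if not np.isnan(s.nuclear_score):
            nuc_err.append(abs(s.nuclear_score - spec.target_level_nuclear))
        if not np.isnan(s.cytoplasmic_score):
            cyt_err.append(abs(s.cytoplasmic_score - spec.target_level_cytoplasmic))
    kept, report = exclude_low_epithelium(scores)
    return {"scores": scores, "kept": kept, "exclusion_report": report,
            "nuclear_mae": float(np.mean(nuc_err)) if nuc_err else float("nan"),
            "cytoplasmic_mae": float(np.mean(cyt_err)) if cyt_err else float("nan")}
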