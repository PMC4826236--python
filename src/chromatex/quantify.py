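"""Compartment-based immunofluorescence quantification of TMA cores.

For each core, the target channel is scored within molecularly defined
compartments: the nuclear compartment (DAPI within epithelium) and the
cytoplasmic compartment (cytokeratin-positive epithelium minus nuclei).
The score of a compartment is its mean target intensity (total intensity /
pixel count), in arbitrary units (Au). Cores whose epithelium occupies
less than 5% of the core area are excluded as non-representative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import ImageGrid, LabelMask
from .segment import COMPARTMENT_CYTOPLASMIC, COMPARTMENT_NUCLEAR

__all__ = [
    "CompartmentScore",
    "score_core",
    "exclude_low_epithelium",
    "EPITHELIUM_FRACTION_THRESHOLD",
]

EPITHELIUM_FRACTION_THRESHOLD = 0.05


@dataclass(frozen=True)
class CompartmentScore:
    """Per-core compartment scores; NaN marks an empty (undefined) compartment."""

    core_id: str
    nuclear_score: float
    cytoplasmic_score: float
    epithelium_fraction: float
    included: bool

    def __post_init__(self) -> None:
        for v in (self.nuclear_score, self.cytoplasmic_score):
            if not math.isnan(v) and v < 0:
                raise ValueError("compartment scores must be ≥ 0")
        if not 0.0 <= self.epithelium_fraction <= 1.0:
            raise ValueError("epithelium_fraction must lie in [0, 1]")


def score_core(target: ImageGrid, compartments: LabelMask,
               core_mask: np.ndarray | None = None,
               core_id: str = "core",
               threshold: float = EPITHELIUM_FRACTION_THRESHOLD) -> CompartmentScore:
    """Mean target intensity per compartment plus the epithelium fraction.

    ``core_mask`` delimits the tissue core; per-core TMA images are usually
    cropped to the core, so it defaults to the whole frame. The epithelium
    fraction is epithelial pixels / core pixels, and ``included`` applies
    the <threshold exclusion rule (fraction exactly at the threshold is
    kept). Background (label 0) pixel values never influence the scores.
    """
    if target.values.shape != compartments.labels.shape:
        raise ValueError("target channel and compartment mask dimensions differ")
    img = target.values.astype(np.float64)
    labels = compartments.labels
    if core_mask is None:
        core_pixels = labels.size
    else:
        core_mask = np.asarray(core_mask, dtype=bool)
        if core_mask.shape != labels.shape:
            raise ValueError("core mask dimensions differ from compartments")
        core_pixels = int(core_mask.sum())
    nuc = labels == COMPARTMENT_NUCLEAR
    cyt = labels == COMPARTMENT_CYTOPLASMIC
    nuclear_score = float(img[nuc].mean()) if nuc.any() else float("nan")
    cyto_score = float(img[cyt].mean()) if cyt.any() else float("nan")
    epith_pixels = int(nuc.sum() + cyt.sum())
    fraction = epith_pixels / core_pixels if core_pixels else 0.0
    fraction = min(fraction, 1.0)
    return CompartmentScore(core_id=core_id, nuclear_score=nuclear_score,
                            cytoplasmic_score=cyto_score,
                            epithelium_fraction=fraction,
                            included=fraction >= threshold)


def exclude_low_epithelium(scores: Sequence[CompartmentScore],
                           threshold: float = EPITHELIUM_FRACTION_THRESHOLD,
                           ) -> tuple[list[CompartmentScore], dict]:
    """Drop cores whose epithelium fraction is strictly below ``threshold``.

    Returns (kept scores, report). The report lists excluded core ids and
    the threshold; kept + excluded partition the input, and applying the
    filter twice changes nothing (idempotent).
    """
    kept = [s for s in scores if s.epithelium_fraction >= threshold]
    excluded = [s.core_id for s in scores if s.epithelium_fraction < threshold]
    report = {"threshold": threshold, "n_input": len(scores),
              "n_excluded": len(excluded), "excluded_core_ids": excluded}
    return kept, report
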