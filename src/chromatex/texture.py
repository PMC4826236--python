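"""Grey-level co-occurrence texture analysis of nuclear chromatin.

The second-order statistics implemented here quantify the spatial
arrangement of chromatin staining inside a nucleus. An 8-bit image is
quantized to G grey levels; for each ROI a grey-level co-occurrence matrix
(GLCM) counts ordered pixel pairs at a fixed offset (distance d, angle θ),
normalised to a joint probability p(i, j). Five scalar features summarise
the matrix:

    ASM         Σ p(i,j)²                         uniformity / smoothness
    contrast    Σ (i−j)² p(i,j)                   local intensity variation
    correlation Σ (i−μx)(j−μy) p(i,j) / (σx σy)   grey-level linear dependency
    IDM         Σ p(i,j) / (1 + (i−j)²)           local homogeneity
    entropy     −Σ p(i,j) log₂ p(i,j)             pattern disorder (bits)

Homogeneous (euchromatin-rich) nuclei score high ASM/IDM and low
entropy/contrast; clumped, heterochromatin-rich nuclei shift every feature
the opposite way. Correlation is undefined when a marginal standard
deviation is zero (e.g. a constant ROI) and is then flagged rather than
coerced.

Pairs are only counted when both endpoints lie inside the ROI mask, so
background around an irregular nucleus never leaks into the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import ImageGrid, LabelMask, TEXTURE_TABLE_COLUMNS

__all__ = [
    "GLCMParams",
    "GLCMatrix",
    "TextureFeatures",
    "PatternCall",
    "ANGLES",
    "PATTERN_ASSOCIATIONS",
    "quantize",
    "compute_glcm",
    "haralick_features",
    "nucleus_texture_profile",
    "percent_change",
    "interpret_chromatin_pattern",
]

#: Pixel offsets (drow, dcol) per angle, for unit distance; multiplied by d.
#: 0° scans rightwards along a row; 45°, 90°, 135° rotate counter-clockwise
#: in image coordinates (row axis pointing down).
ANGLES: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}

MASKED_SENTINEL = -1


@dataclass(frozen=True)
class GLCMParams:
    """Quantization and co-occurrence geometry.

    levels: grey-level count G after quantization (default 32 — raw 8-bit
    matrices are sparse on small nuclear ROIs and make correlation
    unstable). distance in pixels; angles a subset of {0, 45, 90, 135}
    degrees; symmetric counts each ordered pair in both directions;
    average_over_angles averages the five features (not the matrices)
    across angles.
    """

    levels: int = 32
    distance: int = 1
    angles: tuple[int, ...] = (0, 45, 90, 135)
    symmetric: bool = True
    average_over_angles: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be ≥ 2")
        if self.distance < 1:
            raise ValueError("distance must be ≥ 1")
        if not self.angles:
            raise ValueError("at least one angle required")
        bad = set(self.angles) - set(ANGLES)
        if bad:
            raise ValueError(f"unsupported angles {sorted(bad)}; allowed {sorted(ANGLES)}")


@dataclass(frozen=True)
class GLCMatrix:
    """Normalised co-occurrence probabilities for one ROI and one offset."""

    p: np.ndarray
    params: GLCMParams
    angle: int
    n_pairs: int

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=np.float64)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("GLCM must be square")
        if self.n_pairs > 0 and not np.isclose(p.sum(), 1.0):
            raise ValueError("GLCM probabilities must sum to 1")
        if (p < 0).any():
            raise ValueError("GLCM probabilities must be non-negative")
        object.__setattr__(self, "p", p)


@dataclass(frozen=True)
class TextureFeatures:
    """The five per-ROI texture values; correlation may be undefined."""

    asm: float
    contrast: float
    correlation: float  # NaN when undefined
    idm: float
    entropy: float
    correlation_defined: bool

    def as_dict(self) -> dict[str, float]:
        return {
            "asm": self.asm,
            "contrast": self.contrast,
            "correlation": self.correlation,
            "idm": self.idm,
            "entropy": self.entropy,
        }


@dataclass(frozen=True)
class PatternCall:
    """Direction of change of the three chromatin patterns.

    Each of homogeneity / heterogeneity / contrast_pattern is one of
    {increased, decreased, unchanged, indeterminate}; ``votes`` records the
    per-feature contribution behind each call.
    """

    homogeneity: str
    heterogeneity: str
    contrast_pattern: str
    votes: dict[str, dict[str, str]]


def quantize(image: ImageGrid | np.ndarray, mask: np.ndarray | None, levels: int) -> np.ndarray:
    """Uniformly bin an 8-bit image into ``levels`` grey levels.

    Bin edges split [0, 256) into G equal-width bins (level = v·G // 256),
    so G = 256 is the identity. Pixels outside ``mask`` are set to the
    sentinel −1 and never contribute co-occurrence pairs.
    """
    if isinstance(image, ImageGrid):
        if image.bit_depth != 8:
            raise ValueError("quantize expects an 8-bit image; convert with to_8bit first")
        vals = image.values
    else:
        vals = np.asarray(image)
    if levels < 2 or levels > 256:
        raise ValueError("levels must be in [2, 256]")
    if mask is None:
        mask = np.ones(vals.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vals.shape:
        raise ValueError("mask shape must match image shape")
    if not mask.any():
        raise ValueError("empty mask: ROI has no usable pixels")
    out = (vals.astype(np.int64) * levels) // 256
    out = out.astype(np.int32)
    out[~mask] = MASKED_SENTINEL
    return out


def compute_glcm(levelled: np.ndarray, params: GLCMParams,
                 mask: np.ndarray | None = None) -> list[GLCMatrix]:
    """Build one normalised GLCM per requested angle.

    ``levelled`` is the output of :func:`quantize` (sentinel −1 marks
    excluded pixels); an additional boolean ``mask`` may restrict it
    further. Ordered pairs (p, p+offset) are counted when both endpoints
    are valid; symmetric mode also counts the reversed pair.
    """
    lev = np.asarray(levelled)
    valid = lev != MASKED_SENTINEL
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    g = params.levels
    if valid.any() and lev[valid].max() >= g:
        raise ValueError("levelled grid contains values ≥ params.levels")
    d = params.distance
    out: list[GLCMatrix] = []
    for angle in params.angles:
        dr, dc = ANGLES[angle]
        dr, dc = dr * d, dc * d
        h, w = lev.shape
        # Crop the two co-registered views shifted by (dr, dc).
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        if r0 >= r1 or c0 >= c1:
            raise ValueError(f"ROI too small for offset at angle {angle}°")
        src = lev[r0:r1, c0:c1]
        dst = lev[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        ok = valid[r0:r1, c0:c1] & valid[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        i, j = src[ok].ravel(), dst[ok].ravel()
        counts = np.zeros((g, g), dtype=np.float64)
        np.add.at(counts, (i, j), 1.0)
        if params.symmetric:
            counts = counts + counts.T
        n_pairs = int(counts.sum())
        if n_pairs == 0:
            raise ValueError(f"no valid pixel pairs for angle {angle}°: ROI too small for the offset")
        out.append(GLCMatrix(counts / n_pairs, params, angle, n_pairs))
    return out


def _features_single(glcm: GLCMatrix) -> TextureFeatures:
    p = glcm.p
    g = p.shape[0]
    idx = np.arange(g, dtype=np.float64)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    asm = float((p**2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((idx * px).sum())
    mu_y = float((idx * py).sum())
    sd_x = float(np.sqrt(((idx - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((idx - mu_y) ** 2 * py).sum()))
    if sd_x == 0.0 or sd_y == 0.0:
        return TextureFeatures(asm, contrast, float("nan"), idm, entropy, False)
    corr = float((((ii - mu_x) * (jj - mu_y) * p).sum()) / (sd_x * sd_y))
    corr = min(1.0, max(-1.0, corr))
    return TextureFeatures(asm, contrast, corr, idm, entropy, True)


def haralick_features(glcm: GLCMatrix | Sequence[GLCMatrix]) -> TextureFeatures:
    """Compute the five texture features from one GLCM or a per-angle set.

    For a per-angle set the features (not the matrices) are averaged with
    equal weight; correlation is averaged only over angles where it is
    defined, and is undefined only when no angle defines it.
    """
    if isinstance(glcm, GLCMatrix):
        return _features_single(glcm)
    per_angle = [_features_single(m) for m in glcm]
    if not per_angle:
        raise ValueError("empty GLCM set")
    if len(per_angle) == 1:
        return per_angle[0]
    asm = float(np.mean([f.asm for f in per_angle]))
    contrast = float(np.mean([f.contrast for f in per_angle]))
    idm = float(np.mean([f.idm for f in per_angle]))
    entropy = float(np.mean([f.entropy for f in per_angle]))
    corrs = [f.correlation for f in per_angle if f.correlation_defined]
    if corrs:
        return TextureFeatures(asm, contrast, float(np.mean(corrs)), idm, entropy, True)
    return TextureFeatures(asm, contrast, float("nan"), idm, entropy, False)


def roi_texture(image: ImageGrid, mask: np.ndarray, params: GLCMParams) -> TextureFeatures:
    """Texture features of a single masked ROI (quantize → GLCM → features)."""
    lev = quantize(image, mask, params.levels)
    glcms = compute_glcm(lev, params)
    if params.average_over_angles:
        return haralick_features(glcms)
    return haralick_features(glcms[0])


FEATURES = ["asm", "contrast", "correlation", "idm", "entropy"]


def nucleus_texture_profile(image: ImageGrid, nuclei: LabelMask, params: GLCMParams,
                            sample_id: str = "", group: str = "",
                            boundary_erosion_px: int = 1) -> tuple[pd.DataFrame, dict]:
    """Per-nucleus texture table plus per-sample feature means.

    One row per nucleus, pairs restricted to that nucleus's own pixels.
    Each mask is first eroded by ``boundary_erosion_px`` (skipped if that
    would empty it): segmentation boundaries overshoot the true nuclear
    outline by a pixel or so, and the dark rim of background pixels this
    drags in would otherwise dominate every second-order statistic.
    Sample means average over nuclei; undefined correlations are excluded
    from the correlation mean and counted in ``n_correlation_undefined``.
    Nuclei too small to yield any pixel pair are skipped.
    """
    if image.values.shape != nuclei.labels.shape:
        raise ValueError("image and nucleus mask dimensions differ")
    img8 = image if image.bit_depth == 8 else None
    if img8 is None:
        from .core_io import to_8bit

        img8 = to_8bit(image)
    rows = []
    for lab in nuclei.label_ids():
        mask = nuclei.labels == lab
        if boundary_erosion_px > 0:
            from scipy import ndimage as ndi

            eroded = ndi.binary_erosion(mask, iterations=boundary_erosion_px)
            if eroded.any():
                mask = eroded
        try:
            feats = roi_texture(img8, mask, params)
        except ValueError:
            continue  # ROI too small for the offset
        rows.append({
            "sample_id": sample_id,
            "group": group,
            "nucleus_id": int(lab),
            "area_px": int(mask.sum()),
            **feats.as_dict(),
            "correlation_defined": feats.correlation_defined,
        })
    table = pd.DataFrame(rows, columns=TEXTURE_TABLE_COLUMNS)
    means: dict[str, float | int | str | None] = {"sample_id": sample_id, "group": group,
                                                  "n_nuclei": len(table)}
    if table.empty:
        for f in FEATURES:
            means[f] = None
        means["n_correlation_undefined"] = 0
        return table, means
    for f in FEATURES:
        vals = table[f].to_numpy(dtype=np.float64)
        vals = vals[~np.isnan(vals)]
        means[f] = float(vals.mean()) if vals.size else None
    means["n_correlation_undefined"] = int((~table["correlation_defined"]).sum())
    return table, means


def percent_change(treated_means: Mapping[str, float], control_means: Mapping[str, float],
                   features: Sequence[str] = tuple(FEATURES)) -> dict[str, float]:
    """Per-feature percent change of the treated group over the control group.

    100 × (treated − control) / control. A feature undefined in either group,
    or with control mean 0, yields NaN (flagged, not an exception).
    """
    out: dict[str, float] = {}
    for f in features:
        t = treated_means.get(f)
        c = control_means.get(f)
        if t is None or c is None or np.isnan(t) or np.isnan(c) or c == 0.0:
            out[f] = float("nan")
        else:
            out[f] = 100.0 * (t - c) / c
    return out


#: Signed association of each texture feature with each chromatin pattern:
#: +1 means the feature rises when the pattern increases, −1 the opposite.
#: ASM/entropy/IDM↔homogeneity and correlation/entropy↔heterogeneity follow
#: the usual reading of these statistics; the remaining entries complete the
#: map so every pattern has at least two voters.
PATTERN_ASSOCIATIONS: dict[str, dict[str, int]] = {
    "homogeneity": {"asm": +1, "entropy": -1, "idm": +1},
    "heterogeneity": {"correlation": -1, "entropy": +1},
    "contrast": {"contrast": +1, "idm": -1},
}

VOTE_THRESHOLD_DEFAULT = 5.0  # percent


def interpret_chromatin_pattern(changes: Mapping[str, float],
                                threshold: float = VOTE_THRESHOLD_DEFAULT) -> PatternCall:
    """Translate per-feature percent changes into chromatin-pattern calls.

    Each feature whose |change| ≥ threshold votes, via its signed
    association, on the patterns it informs. Unanimous non-zero votes call
    the pattern increased/decreased; all voters below threshold call it
    unchanged; conflicting votes give indeterminate.
    """
    defined = {f: v for f, v in changes.items() if v is not None and not np.isnan(v)}
    if not defined:
        raise ValueError("no defined feature changes to interpret")
    calls: dict[str, str] = {}
    votes: dict[str, dict[str, str]] = {}
    for pattern, assoc in PATTERN_ASSOCIATIONS.items():
        pattern_votes: dict[str, str] = {}
        directions = set()
        for feat, sign in assoc.items():
            if feat not in defined:
                continue
            change = defined[feat]
            if abs(change) < threshold:
                pattern_votes[feat] = "below_threshold"
                continue
            direction = "increased" if change * sign > 0 else "decreased"
            pattern_votes[feat] = direction
            directions.add(direction)
        votes[pattern] = pattern_votes
        if not pattern_votes:
            calls[pattern] = "indeterminate"
        elif not directions:
            calls[pattern] = "unchanged"
        elif len(directions) == 1:
            calls[pattern] = directions.pop()
        else:
            calls[pattern] = "indeterminate"
    return PatternCall(homogeneity=calls["homogeneity"],
                       heterogeneity=calls["heterogeneity"],
                       contrast_pattern=calls["contrast"],
                       votes=votes)
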