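"""Synthetic fluorescence-microscopy scenes with full ground truth.

Three scene classes emulate the image types the analysis modules consume:

* chromatin-texture scenes — DAPI-stained elliptical nuclei whose interior
  is a smooth correlated intensity field (control regime) or additionally
  carries bright heterochromatin-like clumps on a dimmed background
  (treated regime). Clumps change the spatial pattern while the nuclear
  mean intensity is conserved, so texture statistics respond to pattern,
  not to gain.
* foci scenes — a punctate channel with Gaussian spots planted at known
  in-nucleus positions, for validating spot detection and counting.
* TMA-core scenes — a circular tissue core with an epithelium region
  (cytokeratin channel), nuclei inside the epithelium (DAPI) and a target
  channel with distinct nuclear and cytoplasmic levels, for validating
  compartment-based quantification.

Every stochastic draw flows through one numpy Generator seeded from
``SceneSpec.seed``; equal (spec, seed) gives bit-identical scenes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .core_io import ImageGrid, LabelMask, write_image

__all__ = [
    "SceneSpec",
    "SyntheticScene",
    "GenerationError",
    "generate_texture_scene",
    "generate_foci_scene",
    "generate_tma_scene",
    "write_scene",
]


class GenerationError(RuntimeError):
    """Scene could not be generated under the geometric constraints."""


@dataclass(frozen=True)
class SceneSpec:
    """All knobs of the scene generator; one integer seed drives everything.

    Intensity units are raw 8-bit grey levels. ``clumpiness`` is the area
    fraction of the nuclear interior covered by heterochromatin-like clumps
    (0 in the control regime); ``clump_gain`` the multiplicative brightness
    of a clump relative to ``base_level``; ``field_sd`` the amplitude of the
    smooth intra-nuclear field present in both regimes. Radii are mean
    nucleus radii in pixels; ellipse eccentricity is drawn in [1.0, 1.6].
    Clump radii (``clump_radius_range``) are small relative to the nucleus:
    condensed-chromatin granules decorrelate neighbouring pixels, which is
    what drives the correlation feature down in the treated regime.
    """

    height: int = 256
    width: int = 256
    n_nuclei: int = 12
    nucleus_radius_range: tuple[float, float] = (12.0, 18.0)
    texture_regime: str = "control"  # control | treated
    clumpiness: float = 0.0
    clump_gain: float = 1.2
    clump_radius_range: tuple[float, float] = (1.0, 2.0)
    base_level: float = 120.0
    field_sd: float = 10.0
    noise_sd: float = 5.0
    foci_per_nucleus: int = 0
    focus_sigma: float = 1.0
    focus_amplitude: float = 150.0
    epithelium_fraction: float = 0.5
    target_level_nuclear: float = 200.0
    target_level_cytoplasmic: float = 50.0
    allow_border_nuclei: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.texture_regime not in ("control", "treated"):
            raise ValueError("texture_regime must be 'control' or 'treated'")
        if self.texture_regime == "control" and self.clumpiness != 0.0:
            raise ValueError("clumpiness must be 0 in the control regime")
        if not 0.0 <= self.clumpiness <= 1.0:
            raise ValueError("clumpiness must lie in [0, 1]")
        if self.clump_gain < 1.0:
            raise ValueError("clump_gain must be ≥ 1")
        lo, hi = self.nucleus_radius_range
        if lo < 2.0 or hi < lo:
            raise ValueError("nucleus radii must be ≥ 2 px with min ≤ max")
        for name in ("base_level", "field_sd", "noise_sd", "focus_sigma",
                     "focus_amplitude", "target_level_nuclear", "target_level_cytoplasmic"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.foci_per_nucleus < 0:
            raise ValueError("foci_per_nucleus must be non-negative")
        if not 0.0 <= self.epithelium_fraction <= 1.0:
            raise ValueError("epithelium_fraction must lie in [0, 1]")


def treated_spec(**overrides) -> SceneSpec:
    """Convenience: the default treated-arm spec (clumpiness 0.4)."""
    overrides.setdefault("texture_regime", "treated")
    overrides.setdefault("clumpiness", 0.4)
    return SceneSpec(**overrides)


@dataclass(frozen=True)
class SyntheticScene:
    """Generated channels plus full ground truth."""

    channels: dict[str, ImageGrid]
    truth_nuclei: LabelMask
    truth_foci: list[tuple[int, int, int]]  # (nucleus label, row, col)
    truth_compartments: LabelMask | None
    truth_core: np.ndarray | None  # boolean core mask for TMA scenes
    spec: SceneSpec


# ---------------------------------------------------------------------------
# geometry helpers

def _place_ellipses(spec: SceneSpec, rng: np.random.Generator,
                    region: np.ndarray | None = None,
                    max_tries: int = 2000) -> LabelMask:
    """Place n_nuclei non-overlapping ellipses; raises GenerationError on failure.

    ``region`` optionally restricts centres (and full footprints) to a mask.
    A 2-px clearance ring keeps neighbouring nuclei from touching.
    """
    h, w = spec.height, spec.width
    labels = np.zeros((h, w), dtype=np.int32)
    occupied = np.zeros((h, w), dtype=bool)
    lo, hi = spec.nucleus_radius_range
    region_coords = np.argwhere(region) if region is not None else None
    if region_coords is not None and len(region_coords) == 0:
        raise GenerationError("placement region is empty")
    placed = 0
    tries = 0
    while placed < spec.n_nuclei:
        tries += 1
        if tries > max_tries:
            raise GenerationError(
                f"placed only {placed}/{spec.n_nuclei} nuclei after {max_tries} tries; "
                "use a larger canvas or fewer/smaller nuclei")
        r_mean = rng.uniform(lo, hi)
        ecc = rng.uniform(1.0, 1.6)
        a, b = r_mean * np.sqrt(ecc), r_mean / np.sqrt(ecc)
        theta = rng.uniform(0, np.pi)
        if region_coords is not None:
            cy, cx = region_coords[rng.integers(len(region_coords))].astype(float)
        else:
            margin = 0 if spec.allow_border_nuclei else int(np.ceil(a)) + 2
            if h - margin <= margin or w - margin <= margin:
                raise GenerationError("canvas too small for the requested nucleus radii")
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
        # evaluate the ellipse on its bounding box only
        ext = int(np.ceil(a)) + 3
        r0, r1 = max(0, int(cy) - ext), min(h, int(cy) + ext + 1)
        c0, c1 = max(0, int(cx) - ext), min(w, int(cx) + ext + 1)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        ct, st = np.cos(theta), np.sin(theta)
        u = (rr - cy) * ct + (cc - cx) * st
        v = -(rr - cy) * st + (cc - cx) * ct
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        if not spec.allow_border_nuclei and (inside[0, :].any() or inside[-1, :].any()
                                             or inside[:, 0].any() or inside[:, -1].any()):
            continue
        dilated = (u / (a + 2)) ** 2 + (v / (b + 2)) ** 2 <= 1.0
        if (dilated & occupied[r0:r1, c0:c1]).any():
            continue
        if region is not None and (inside & ~region[r0:r1, c0:c1]).any():
            continue
        placed += 1
        labels[r0:r1, c0:c1][inside] = placed
        occupied[r0:r1, c0:c1] |= dilated
    return LabelMask(labels)


def _smooth_field(shape: tuple[int, int], sigma: float, sd: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian random field with correlation length ≈ sigma and sd ``sd``."""
    white = rng.standard_normal(shape)
    smooth = ndi.gaussian_filter(white, sigma, mode="reflect")
    s = smooth.std()
    if s == 0:
        return np.zeros(shape)
    return smooth * (sd / s)


def _to_grid(arr: np.ndarray, bit_depth: int = 8) -> ImageGrid:
    top = 2**bit_depth - 1
    return ImageGrid(np.clip(np.round(arr), 0, top), bit_depth=bit_depth)


# ---------------------------------------------------------------------------
# scene generators

def generate_texture_scene(spec: SceneSpec) -> SyntheticScene:
    """DAPI chromatin-texture scene: control (smooth) vs treated (clumped).

    Control nuclei: interior = base_level + smooth correlated field
    (correlation length ≈ mean radius / 4). Treated nuclei additionally get
    disk-shaped granules covering ≈ ``clumpiness`` of the nuclear area,
    half condensed (bright, base_level × clump_gain) and half depleted
    (dark, base_level × (2 − clump_gain)); the symmetric bright/dark split
    conserves the nuclear mean exactly, so texture changes reflect pattern,
    not gain. Read noise of sd ``noise_sd`` is added everywhere.
    """
    rng = np.random.default_rng(spec.seed)
    nuclei = _place_ellipses(spec, rng)
    h, w = spec.height, spec.width
    dapi = np.zeros((h, w), dtype=np.float64)
    mean_radius = float(np.mean(spec.nucleus_radius_range))
    field = _smooth_field((h, w), mean_radius / 4.0, spec.field_sd, rng)
    f, gain = spec.clumpiness, spec.clump_gain
    if gain > 2.0:
        raise GenerationError("clump_gain must be ≤ 2 so the depleted level stays non-negative")
    for lab in nuclei.label_ids():
        mask = nuclei.labels == lab
        levels = np.full(mask.shape, spec.base_level)
        if spec.texture_regime == "treated" and f > 0:
            area = int(mask.sum())
            bright = _plant_clumps(mask, round(f / 2 * area), rng, spec.clump_radius_range)
            dark = _plant_clumps(mask & ~bright, round(f / 2 * area), rng,
                                 spec.clump_radius_range)
            levels[bright] = spec.base_level * gain
            levels[dark] = spec.base_level * (2.0 - gain)
        dapi[mask] = levels[mask] + field[mask]
    dapi += rng.normal(0.0, spec.noise_sd, size=(h, w)) if spec.noise_sd > 0 else 0.0
    return SyntheticScene(channels={"dapi": _to_grid(dapi)},
                         truth_nuclei=nuclei, truth_foci=[],
                         truth_compartments=None, truth_core=None, spec=spec)


def _plant_clumps(mask: np.ndarray, target_px: float, rng: np.random.Generator,
                  clump_radius_range: tuple[float, float] = (1.0, 2.0),
                  max_tries: int = 6000) -> np.ndarray:
    """Disk-shaped clumps inside ``mask`` totalling ≈ ``target_px`` pixels."""
    clumps = np.zeros_like(mask)
    coords = np.argwhere(mask)
    if len(coords) == 0 or target_px <= 0:
        return clumps
    h, w = mask.shape
    rr, cc = np.mgrid[0:h, 0:w]
    tries = 0
    while clumps.sum() < target_px and tries < max_tries:
        tries += 1
        cy, cx = coords[rng.integers(len(coords))]
        rad = rng.uniform(*clump_radius_range)
        disk = (rr - cy) ** 2 + (cc - cx) ** 2 <= rad**2
        clumps |= disk & mask
    return clumps


def _pack_spots(coords: np.ndarray, count: int, min_sep: float,
                rng: np.random.Generator, max_attempts: int = 50) -> list[tuple[int, int]] | None:
    """Greedy packing of ``count`` points with pairwise distance ≥ min_sep.

    Each attempt scans a fresh random permutation of the candidate pixels
    and keeps every point far enough from those already kept (random
    sequential adsorption); returns None when no attempt fits ``count``.
    """
    if count == 0:
        return []
    if len(coords) == 0:
        return None
    sep2 = min_sep**2
    for _ in range(max_attempts):
        order = rng.permutation(len(coords))
        placed: list[tuple[int, int]] = []
        for idx in order:
            y, x = coords[idx]
            if all((y - py) ** 2 + (x - px) ** 2 >= sep2 for py, px in placed):
                placed.append((int(y), int(x)))
                if len(placed) == count:
                    return placed
    return None


def generate_foci_scene(spec: SceneSpec) -> SyntheticScene:
    """Punctate foci channel over DAPI nuclei, with every spot recorded.

    Spots are isotropic Gaussians (sd ``focus_sigma``, peak
    ``focus_amplitude``) at uniformly drawn in-nucleus positions with
    pairwise separation ≥ 4·focus_sigma; centres keep 2·focus_sigma
    clearance from the nuclear boundary so each spot is resolvable within
    its nucleus. Background is low-level noise.
    """
    rng = np.random.default_rng(spec.seed)
    nuclei = _place_ellipses(spec, rng)
    h, w = spec.height, spec.width
    foci_img = np.zeros((h, w), dtype=np.float64)
    min_sep = 4.0 * spec.focus_sigma
    erode_iter = max(1, int(round(2.0 * spec.focus_sigma)))
    truth: list[tuple[int, int, int]] = []
    rr, cc = np.mgrid[0:h, 0:w]
    for lab in nuclei.label_ids():
        mask = nuclei.labels == lab
        interior = ndi.binary_erosion(mask, iterations=erode_iter)
        coords = np.argwhere(interior if interior.any() else mask)
        placed = _pack_spots(coords, spec.foci_per_nucleus, min_sep, rng)
        if placed is None:
            raise GenerationError(
                f"cannot place {spec.foci_per_nucleus} foci at separation "
                f"{min_sep:.1f}px inside nucleus {lab}")
        truth.extend((int(lab), y, x) for y, x in placed)
        for (y, x) in placed:
            foci_img += spec.focus_amplitude * np.exp(
                -((rr - y) ** 2 + (cc - x) ** 2) / (2.0 * spec.focus_sigma**2))
    # faint DAPI rendering so the scene also carries a nuclear channel
    dapi = np.where(nuclei.labels > 0, spec.base_level, 0.0)
    dapi += rng.normal(0.0, spec.noise_sd, size=(h, w)) if spec.noise_sd > 0 else 0.0
    foci_img += rng.normal(0.0, spec.noise_sd, size=(h, w)) if spec.noise_sd > 0 else 0.0
    return SyntheticScene(channels={"dapi": _to_grid(dapi), "foci": _to_grid(foci_img)},
                         truth_nuclei=nuclei, truth_foci=truth,
                         truth_compartments=None, truth_core=None, spec=spec)


def generate_tma_scene(spec: SceneSpec) -> SyntheticScene:
    """TMA-core scene: circular core, epithelium blob, nuclei, target channel.

    The epithelium occupies ``epithelium_fraction`` of the core area (set by
    thresholding a smooth random field at the matching quantile, so the
    realised fraction tracks the request to within discretisation). Nuclei
    are placed inside the epithelium; the target channel carries
    ``target_level_nuclear`` on nuclear pixels and
    ``target_level_cytoplasmic`` on the remaining epithelial pixels.
    truth_compartments uses {0 background, 1 cytoplasmic, 2 nuclear}.
    """
    if spec.epithelium_fraction > 0.95:
        raise ValueError("epithelium_fraction must be ≤ 0.95")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    rr, cc = np.mgrid[0:h, 0:w]
    radius = 0.45 * min(h, w)
    core = (rr - h / 2.0) ** 2 + (cc - w / 2.0) ** 2 <= radius**2
    frac = spec.epithelium_fraction
    if frac <= 0:
        epith = np.zeros((h, w), dtype=bool)
    else:
        fld = _smooth_field((h, w), 0.15 * min(h, w), 1.0, rng)
        cut = np.quantile(fld[core], 1.0 - frac)
        epith = core & (fld >= cut)
        epith = ndi.binary_closing(epith, iterations=2) & core
    nuclei = LabelMask(np.zeros((h, w), dtype=np.int32))
    if epith.any() and spec.n_nuclei > 0:
        eroded = ndi.binary_erosion(epith, iterations=3)
        region = eroded if eroded.any() else epith
        try:
            nuclei = _place_ellipses(replace(spec, allow_border_nuclei=True), rng, region=region)
        except GenerationError:
            # dense epithelium with little room: accept however many fitted
            nuclei = _best_effort_ellipses(spec, rng, region)
    nuclear = nuclei.labels > 0
    cyto = epith & ~nuclear
    compartments = np.zeros((h, w), dtype=np.int32)
    compartments[cyto] = 1
    compartments[nuclear] = 2
    noise = (lambda: rng.normal(0.0, spec.noise_sd, size=(h, w))) if spec.noise_sd > 0 else (lambda: 0.0)
    dapi = np.where(nuclear, spec.base_level, 0.0) + noise()
    ck = np.where(cyto, spec.base_level, 0.0) + noise()
    target = np.where(nuclear, spec.target_level_nuclear,
                      np.where(cyto, spec.target_level_cytoplasmic, 0.0)) + noise()
    return SyntheticScene(
        channels={"dapi": _to_grid(dapi), "cytokeratin": _to_grid(ck), "target": _to_grid(target)},
        truth_nuclei=nuclei, truth_foci=[],
        truth_compartments=LabelMask(compartments), truth_core=core, spec=spec)


def _best_effort_ellipses(spec: SceneSpec, rng: np.random.Generator,
                          region: np.ndarray) -> LabelMask:
    """Place as many nuclei as fit in ``region`` (used for crowded TMA cores)."""
    for n in range(spec.n_nuclei, 0, -1):
        try:
            return _place_ellipses(replace(spec, n_nuclei=n, allow_border_nuclei=True),
                                   rng, region=region)
        except GenerationError:
            continue
    return LabelMask(np.zeros((spec.height, spec.width), dtype=np.int32))


# ---------------------------------------------------------------------------
# persistence

def write_scene(scene: SyntheticScene, directory: str | Path, name: str = "scene") -> dict:
    """Write a scene as multichannel TIFF + JSON ground-truth sidecar.

    Returns the sidecar dict ({channels, nuclei label stats, foci list,
    spec parameters}).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    order = list(scene.channels)
    write_image(directory / f"{name}.tif", [scene.channels[k] for k in order])
    import tifffile

    tifffile.imwrite(directory / f"{name}_nuclei.tif", scene.truth_nuclei.labels.astype(np.uint16))
    if scene.truth_compartments is not None:
        tifffile.imwrite(directory / f"{name}_compartments.tif",
                         scene.truth_compartments.labels.astype(np.uint16))
    areas = {int(l): int((scene.truth_nuclei.labels == l).sum())
             for l in scene.truth_nuclei.label_ids()}
    sidecar = {
        "channels": order,
        "nuclei": {"count": len(areas), "areas_px": areas},
        "foci": [list(t) for t in scene.truth_foci],
        "spec": asdict(scene.spec),
    }
    with open(directory / f"{name}_truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
    return sidecar
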