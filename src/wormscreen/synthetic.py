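"""Synthetic plates, cohorts and qPCR tables with planted ground truth.

The generators emulate the study conditions of the screen: wells of ~dozens
of animals imaged in bright-field and GFP channels (four tiles per well),
per-condition multiplicative GFP induction/suppression with replicate noise,
Weibull lifespans scored on an alternate-day grid with right-censoring, and
Ct tables that encode a known expression fold change against a reference
gene.  Every generator is a pure function of its spec and seed, so each
downstream stage can be validated against exactly known truth without any
raw-data download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import morphology

from .imaging import split_tiles
from .types import (GroundTruth, PlateCondition, SurvivalCohort,
                    SurvivalSimSpec, WellImage, WormShapeSpec)

__all__ = [
    "RenderParams",
    "PlateImageParams",
    "simulate_worm_shapes",
    "render_well_image",
    "simulate_screen_plate",
    "simulate_survival_cohort",
    "simulate_qpcr_plate",
]


class OvercrowdedWellError(ValueError):
    """Raised when worms cannot be placed at the requested separation."""


@dataclass
class RenderParams:
    """Intensity model for rendered wells (16-bit-style arbitrary units).

    Bright field: dark surround outside the well, bright well interior, worms
    and debris darker than the interior (they absorb light), plus an optional
    smooth illumination gradient.  GFP: flat background everywhere, worm
    pixels at background + base_gfp * induction * suppression.  Additive
    Gaussian noise with SD ``noise_sd`` on both channels; the noiseless limit
    is exact so fold changes are exactly recoverable by construction.
    """

    bf_outside: float = 2000.0
    bf_well: float = 30000.0
    bf_worm_contrast: float = 12000.0
    bf_gradient_amplitude: float = 1500.0
    gfp_background: float = 500.0
    base_gfp: float = 1000.0
    n_debris: int = 8
    debris_radius: int = 4  # area ~50 px^2, below the default size_min


@dataclass
class PlateImageParams:
    worm_spec: WormShapeSpec = field(default_factory=WormShapeSpec)
    well_radius: float = 200.0
    noise_sd: float = 0.0
    render: RenderParams = field(default_factory=RenderParams)


def _image_shape(well_radius: float, pad: int = 12) -> tuple[int, int]:
    half = int(np.ceil(well_radius)) + pad
    size = 2 * half  # even, so a 2x2 tiling is exact
    return (size, size)


def _random_backbone(rng: np.random.Generator, spec: WormShapeSpec,
                     center: np.ndarray, heading: float) -> np.ndarray:
    """Smoothly curved backbone: a heading random walk with bounded turning."""
    n_seg = max(int(spec.backbone_length // 2), 4)
    ds = spec.backbone_length / n_seg
    pts = [center.astype(float)]
    h = heading
    for _ in range(n_seg):
        h += spec.curvature * rng.uniform(-1.0, 1.0)
        pts.append(pts[-1] + ds * np.array([np.sin(h), np.cos(h)]))
    pts = np.asarray(pts)
    # densify so the rasterized backbone is 8-connected
    dense = []
    for a, b in zip(pts[:-1], pts[1:]):
        steps = max(int(np.ceil(np.linalg.norm(b - a) / 0.5)), 1)
        t = np.linspace(0, 1, steps, endpoint=False)[:, None]
        dense.append(a + t * (b - a))
    dense.append(pts[-1:])
    return np.concatenate(dense)


def simulate_worm_shapes(spec: WormShapeSpec, well_radius: float,
                         seed: int, max_retries: int = 500) -> GroundTruth:
    """Place ``spec.count`` non-overlapping worm tubes inside the well disk.

    Each worm is a randomly curved backbone dilated to ``body_width``;
    placement retries until worms keep ``min_separation`` from each other and
    lie fully inside the well, raising :class:`OvercrowdedWellError` after
    bounded retries.  Deterministic for a fixed (spec, seed).
    """
    rng = np.random.default_rng(seed)
    shape = _image_shape(well_radius)
    cy = cx = shape[0] / 2.0
    yy, xx = np.ogrid[:shape[0], :shape[1]]
    well_disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= (well_radius - 2.0) ** 2

    labels = np.zeros(shape, dtype=np.int32)
    truth = GroundTruth(worm_mask=labels, well_center=(cy, cx),
                        well_radius=float(well_radius))
    if spec.count == 0:
        return truth

    tube_r = max(1, int(round((spec.body_width - 1) / 2)))
    tube_fp = morphology.disk(tube_r)
    sep_iter = max(int(np.ceil(spec.min_separation)), 0)
    occupied = np.zeros(shape, dtype=bool)
    if spec.backbone_length / 2.0 + spec.body_width >= well_radius:
        raise OvercrowdedWellError(
            "well_radius too small for the requested worm geometry")

    center = np.array([cy, cx])
    max_r = well_radius - 2.0 - tube_r  # backbone containment radius
    start_margin = spec.body_width + 2.0
    for worm_id in range(1, spec.count + 1):
        placed = False
        for _ in range(max_retries):
            r = (well_radius - start_margin) * np.sqrt(rng.random())
            ang = rng.uniform(0, 2 * np.pi)
            start = center + r * np.array([np.sin(ang), np.cos(ang)])
            # bias the initial heading inward so long backbones rarely
            # escape the disk; curvature still randomizes the course
            inward = np.arctan2(cy - start[0], cx - start[1])
            pts = _random_backbone(rng, spec, start,
                                   inward + rng.uniform(-1.2, 1.2))
            if (np.linalg.norm(pts - center, axis=1) > max_r).any():
                continue
            ij = np.round(pts).astype(int)
            pad = tube_r + sep_iter + 1
            i0, i1 = ij[:, 0].min() - pad, ij[:, 0].max() + pad + 1
            j0, j1 = ij[:, 1].min() - pad, ij[:, 1].max() + pad + 1
            i0, j0 = max(i0, 0), max(j0, 0)
            i1, j1 = min(i1, shape[0]), min(j1, shape[1])
            box = (slice(i0, i1), slice(j0, j1))
            local = np.zeros((i1 - i0, j1 - j0), dtype=bool)
            local[ij[:, 0] - i0, ij[:, 1] - j0] = True
            tube = ndi.binary_dilation(local, structure=tube_fp)
            halo = ndi.binary_dilation(tube, iterations=sep_iter) if sep_iter else tube
            if (halo & occupied[box]).any():
                continue
            labels[box][tube] = worm_id
            occupied[box] |= tube
            placed = True
            break
        if not placed:
            raise OvercrowdedWellError(
                f"could not place worm {worm_id} of {spec.count} "
                f"after {max_retries} retries")
    truth.worm_mask = labels
    return truth


def render_well_image(truth: GroundTruth, condition: PlateCondition,
                      noise_sd: float = 0.0, seed: int = 0,
                      params: RenderParams | None = None,
                      tile_grid: tuple[int, int] = (2, 2)) -> WellImage:
    """Render bright-field + GFP channels for one well and split into tiles.

    Worm GFP intensity is ``background + base_gfp * induction * suppression``
    plus Gaussian noise; ``truth.per_worm_mean_gfp`` and
    ``truth.background_level`` are filled in as a side effect.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    p = params or RenderParams()
    rng = np.random.default_rng(seed)
    shape = truth.worm_mask.shape
    cy, cx = truth.well_center
    yy, xx = np.ogrid[:shape[0], :shape[1]]
    well_disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= truth.well_radius ** 2
    worms = truth.worm_mask > 0

    bf = np.full(shape, p.bf_outside, dtype=float)
    bf[well_disk] = p.bf_well
    if p.bf_gradient_amplitude:
        ramp = p.bf_gradient_amplitude * (xx + yy) / (shape[0] + shape[1])
        bf += np.broadcast_to(ramp, shape) * well_disk
    bf[worms] -= p.bf_worm_contrast
    if p.n_debris:
        fp = morphology.disk(p.debris_radius)
        debris = np.zeros(shape, dtype=bool)
        centers: list[tuple[int, int]] = []
        placed = 0
        attempts = 0
        # keep debris disks disjoint (from each other and from worms) so each
        # stays below the size filter
        min_gap = 2 * p.debris_radius + 3
        worm_halo = ndi.binary_dilation(worms, iterations=p.debris_radius + 2) \
            if worms.any() else worms
        while placed < p.n_debris and attempts < 50 * p.n_debris:
            attempts += 1
            r = (truth.well_radius - 3 * p.debris_radius) * np.sqrt(rng.random())
            ang = rng.uniform(0, 2 * np.pi)
            iy, ix = int(cy + r * np.sin(ang)), int(cx + r * np.cos(ang))
            if worm_halo.size and worm_halo[iy, ix]:
                continue
            if any((iy - y) ** 2 + (ix - x) ** 2 < min_gap ** 2
                   for y, x in centers):
                continue
            centers.append((iy, ix))
            debris[iy, ix] = True
            placed += 1
        debris = ndi.binary_dilation(debris, structure=fp) & well_disk & ~worms
        bf[debris] -= p.bf_worm_contrast

    worm_gfp = p.gfp_background + p.base_gfp * condition.intensity_factor
    gfp = np.full(shape, p.gfp_background, dtype=float)
    gfp[worms] = worm_gfp

    if noise_sd > 0:
        bf = bf + rng.normal(0.0, noise_sd, shape)
        gfp = gfp + rng.normal(0.0, noise_sd, shape)

    truth.background_level = p.gfp_background
    n_worms = truth.n_worms
    truth.per_worm_mean_gfp = [
        float(gfp[truth.worm_mask == i].mean()) for i in range(1, n_worms + 1)
    ]
    return WellImage(brightfield=bf, gfp=gfp,
                     bf_tiles=split_tiles(bf, tile_grid),
                     gfp_tiles=split_tiles(gfp, tile_grid),
                     condition=condition)


def simulate_screen_plate(conditions: list[PlateCondition],
                          image_params: PlateImageParams | None = None,
                          seed: int = 0
                          ) -> tuple[list[tuple[WellImage, GroundTruth]], pd.DataFrame]:
    """One image set per replicate per condition, plus a truth manifest.

    The manifest records, per well, the planted intensity factor and the true
    fold decrease versus the matching vector control (``rnai_clone ==
    'vector'`` with the same strain and treatment), which by construction is
    ``1 / suppression_factor``.
    """
    if not conditions:
        raise ValueError("need at least one condition")
    keys = [c.key for c in conditions]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (strain, rnai, treatment) conditions")
    ip = image_params or PlateImageParams()
    rng = np.random.default_rng(seed)

    controls = {(c.strain, c.treatment): c for c in conditions
                if c.rnai_clone == "vector"}
    wells: list[tuple[WellImage, GroundTruth]] = []
    rows = []
    for cond in conditions:
        ctrl = controls.get((cond.strain, cond.treatment))
        true_fold = (ctrl.intensity_factor / cond.intensity_factor
                     if ctrl is not None else 1.0 / cond.suppression_factor)
        for rep in range(cond.replicates):
            wseed = int(rng.integers(2 ** 31))
            truth = simulate_worm_shapes(ip.worm_spec, ip.well_radius, wseed)
            well = render_well_image(truth, cond, noise_sd=ip.noise_sd,
                                     seed=wseed + 1, params=ip.render)
            well.replicate = rep
            wells.append((well, truth))
            rows.append({"strain": cond.strain, "rnai": cond.rnai_clone,
                         "treatment": cond.treatment, "replicate": rep,
                         "intensity_factor": cond.intensity_factor,
                         "true_fold": true_fold, "seed": wseed})
    return wells, pd.DataFrame(rows)


def simulate_survival_cohort(spec: SurvivalSimSpec) -> SurvivalCohort:
    """Weibull lifespans snapped to the alternate-day scoring grid.

    Event times are Weibull(scale * strain_multiplier * rnai_multiplier,
    shape); deaths are observed at the next even scoring day, and a fraction
    ``censor_prob`` of animals is right-censored at a uniform time before
    death (snapped to the same grid).  Ties at scoring days exercise the
    product-limit estimator's tie handling downstream.
    """
    rng = np.random.default_rng(spec.seed)
    scale = spec.baseline_scale * spec.strain_multiplier * spec.rnai_multiplier
    raw = scale * rng.weibull(spec.baseline_shape, size=spec.n_animals)
    days = np.maximum(2.0, 2.0 * np.ceil(raw / 2.0))
    status = np.ones(spec.n_animals, dtype=int)
    censored = rng.random(spec.n_animals) < spec.censor_prob
    if censored.any():
        u = rng.uniform(0.0, 1.0, size=spec.n_animals)
        ctime = np.maximum(2.0, 2.0 * np.ceil(u * raw / 2.0))
        days = np.where(censored, ctime, days)
        status[censored] = 0
    return SurvivalCohort(times=days, status=status)


def simulate_qpcr_plate(true_fold: float, ref_ct: float = 15.0,
                        noise_sd: float = 0.2, replicates: int = 4,
                        seed: int = 0, target_offset: float = 4.0) -> pd.DataFrame:
    """Ct table encoding a known fold change against the reference gene.

    Treated target Ct = (ref_ct + target_offset) - log2(true_fold) + noise;
    control target Ct sits at the anchor; the reference gene is constant up
    to noise in both groups.  With noise_sd = 0 the ddCt computation recovers
    ``true_fold`` exactly.
    """
    if true_fold <= 0:
        raise ValueError("true_fold must be > 0")
    if replicates < 2:
        raise ValueError("need >= 2 replicates for the downstream t-test")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    anchor = ref_ct + target_offset
    rows = []
    for group, shift in (("control", 0.0), ("treated", -np.log2(true_fold))):
        for rep in range(replicates):
            rows.append({
                "group": group, "replicate": rep,
                "target_ct": anchor + shift + rng.normal(0, noise_sd) if noise_sd else anchor + shift,
                "reference_ct": ref_ct + rng.normal(0, noise_sd) if noise_sd else ref_ct,
            })
    return pd.DataFrame(rows)
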