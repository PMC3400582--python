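"""Shared domain containers for the screen pipeline.

These are deliberately thin: plain dataclasses holding numpy arrays and
labels, so that every pipeline stage can be driven either from synthetic
plates or from TIFFs + CSV manifests on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PlateCondition:
    """One (strain, RNAi clone, treatment) cell of a screen plate.

    ``induction_factor`` is the multiplicative GFP induction produced by the
    stressor (toxin or genetic trigger) relative to baseline; for RNAi clones
    that suppress the response, ``suppression_factor`` < 1 multiplies on top
    of it.  The planted "true fold decrease" of a suppressed condition versus
    its vector control is therefore 1/suppression_factor.
    """

    strain: str = "N2"
    rnai_clone: str = "vector"
    treatment: str = "none"
    induction_factor: float = 1.0
    suppression_factor: float = 1.0
    replicates: int = 4

    def __post_init__(self) -> None:
        if self.induction_factor <= 0:
            raise ValueError("induction_factor must be > 0")
        if self.suppression_factor <= 0:
            raise ValueError("suppression_factor must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def intensity_factor(self) -> float:
        return self.induction_factor * self.suppression_factor

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.strain, self.rnai_clone, self.treatment)


@dataclass
class WormShapeSpec:
    """Geometry of the synthetic animals placed in a well (pixel units)."""

    count: int = 50  # animals per well in the screen design
    backbone_length: float = 60.0
    body_width: float = 8.0
    curvature: float = 0.25
    min_separation: float = 4.0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.body_width < 2:
            raise ValueError("body_width must be >= 2 px")
        if self.backbone_length <= 0:
            raise ValueError("backbone_length must be > 0")


@dataclass
class GroundTruth:
    """Planted truth for one synthetic well."""

    worm_mask: np.ndarray  # integer label image, 0 = background
    well_center: tuple[float, float] = (0.0, 0.0)
    well_radius: float = 0.0
    background_level: float = 0.0
    per_worm_mean_gfp: list[float] = field(default_factory=list)

    @property
    def n_worms(self) -> int:
        labels = np.unique(self.worm_mask)
        return int((labels > 0).sum())


@dataclass
class WellImage:
    """Stitched bright-field + GFP images for one well, with tile provenance.

    The acquisition device captures four sub-images per well which are tiled
    (row-major 2x2) into the full-well arrays processed downstream.
    """

    brightfield: np.ndarray
    gfp: np.ndarray
    bf_tiles: list[np.ndarray] = field(default_factory=list)
    gfp_tiles: list[np.ndarray] = field(default_factory=list)
    condition: PlateCondition | None = None
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.brightfield.shape != self.gfp.shape:
            raise ValueError("brightfield and gfp must share a shape")


@dataclass
class SurvivalSimSpec:
    """Weibull lifespan simulator settings for one strain x RNAi cohort."""

    baseline_scale: float = 20.0  # days
    baseline_shape: float = 4.0
    strain_multiplier: float = 1.0
    rnai_multiplier: float = 1.0
    n_animals: int = 100
    censor_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.baseline_scale, self.baseline_shape,
               self.strain_multiplier, self.rnai_multiplier) <= 0:
            raise ValueError("scale, shape and multipliers must be > 0")
        if not (0 <= self.censor_prob < 1):
            raise ValueError("censor_prob must be in [0, 1)")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")


@dataclass
class SurvivalCohort:
    """Per-animal event/censor times for one strain x RNAi condition.

    ``status`` is 1 for an observed death, 0 for right-censoring.
    """

    times: np.ndarray
    status: np.ndarray
    strain: str = "N2"
    rnai_clone: str = "vector"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.status = np.asarray(self.status, dtype=int)
        if self.times.shape != self.status.shape:
            raise ValueError("times and status must align")
        if self.times.size and self.times.min() <= 0:
            raise ValueError("times must be > 0")

    @property
    def n_events(self) -> int:
        return int(self.status.sum())
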