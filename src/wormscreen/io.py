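"""TIFF and CSV I/O for wells, manifests and cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile

from .imaging import stitch_tiles
from .types import SurvivalCohort, WellImage


def write_well_tiff(path: str, well: WellImage) -> None:
    """Write a well as an 8-page TIFF: 4 bright-field tiles then 4 GFP tiles,
    row-major 2x2 order."""
    pages = [t.astype(np.float32) for t in well.bf_tiles + well.gfp_tiles]
    tifffile.imwrite(path, np.stack(pages))


def read_well_tiff(path: str) -> WellImage:
    """Read a well TIFF written by :func:`write_well_tiff`, re-stitching tiles."""
    pages = list(tifffile.imread(path))
    if len(pages) == 8:
        bf_tiles, gfp_tiles = pages[:4], pages[4:]
    elif len(pages) == 2:  # already-stitched bf + gfp
        return WellImage(brightfield=pages[0], gfp=pages[1])
    else:
        raise ValueError(f"expected 8 tile pages or 2 stitched pages, got {len(pages)}")
    return WellImage(brightfield=stitch_tiles(bf_tiles),
                     gfp=stitch_tiles(gfp_tiles),
                     bf_tiles=bf_tiles, gfp_tiles=gfp_tiles)


def write_cohorts_csv(path: str, cohorts: list[SurvivalCohort]) -> None:
    rows = []
    for c in cohorts:
        for i, (t, s) in enumerate(zip(c.times, c.status)):
            rows.append({"strain": c.strain, "rnai": c.rnai_clone,
                         "animal_id": i, "day": t, "status": int(s)})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohorts_csv(path: str) -> list[SurvivalCohort]:
    df = pd.read_csv(path)
    cohorts = []
    for (strain, rnai), grp in df.groupby(["strain", "rnai"], sort=False):
        cohorts.append(SurvivalCohort(times=grp["day"].to_numpy(),
                                      status=grp["status"].to_numpy(),
                                      strain=strain, rnai_clone=rnai))
    return cohorts
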