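"""Ground-truth generators: determinism, geometry, planted effects."""

import numpy as np
import pytest

from wormscreen import imaging, screen, synthetic
from wormscreen.synthetic import (OvercrowdedWellError, PlateImageParams,
                                  RenderParams, simulate_qpcr_plate,
                                  simulate_screen_plate,
                                  simulate_survival_cohort,
                                  simulate_worm_shapes)
from wormscreen.types import (PlateCondition, SurvivalSimSpec, WormShapeSpec)

from conftest import SMALL_RADIUS, SMALL_SPEC


# ----------------------------------------------------------- worm shapes

def test_zero_count_gives_empty_mask():
    truth = simulate_worm_shapes(WormShapeSpec(count=0), 80, seed=0)
    assert truth.n_worms == 0
    assert not truth.worm_mask.any()


def test_same_seed_reproduces_mask():
    a = simulate_worm_shapes(SMALL_SPEC, SMALL_RADIUS, seed=5)
    b = simulate_worm_shapes(SMALL_SPEC, SMALL_RADIUS, seed=5)
    np.testing.assert_array_equal(a.worm_mask, b.worm_mask)


def test_fifty_worms_labels_and_areas():
    spec = WormShapeSpec(count=50, backbone_length=60, body_width=8)
    truth = simulate_worm_shapes(spec, 200, seed=7)
    labels = np.unique(truth.worm_mask)
    assert truth.n_worms == 50
    target = spec.backbone_length * spec.body_width
    for i in labels[labels > 0]:
        area = (truth.worm_mask == i).sum()
        assert 0.5 * target <= area <= 1.5 * target


def test_worms_stay_inside_well_disk():
    truth = simulate_worm_shapes(SMALL_SPEC, SMALL_RADIUS, seed=9)
    yy, xx = np.indices(truth.worm_mask.shape)
    cy, cx = truth.well_center
    r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    assert r[truth.worm_mask > 0].max() <= truth.well_radius


def test_overcrowded_well_raises():
    with pytest.raises(OvercrowdedWellError):
        simulate_worm_shapes(WormShapeSpec(count=100, backbone_length=60), 45, seed=0)


# ------------------------------------------------------------- rendering

def test_noiseless_induction_ratio_exact(small_truth):
    a = synthetic.render_well_image(
        small_truth, PlateCondition(induction_factor=1.0), noise_sd=0.0, seed=1)
    b = synthetic.render_well_image(
        small_truth, PlateCondition(induction_factor=10.0), noise_sd=0.0, seed=1)
    worms = small_truth.worm_mask > 0
    bg = small_truth.background_level
    ratio = (b.gfp[worms] - bg).mean() / (a.gfp[worms] - bg).mean()
    assert ratio == pytest.approx(10.0)


def test_zero_worm_render_is_background_only():
    truth = simulate_worm_shapes(WormShapeSpec(count=0), 60, seed=2)
    well = synthetic.render_well_image(
        truth, PlateCondition(), noise_sd=0.0, seed=0,
        params=RenderParams(n_debris=0))
    assert (well.gfp == truth.background_level).all()


def test_tiles_restitch_exactly(small_truth, induced_condition):
    well = synthetic.render_well_image(small_truth, induced_condition,
                                       noise_sd=10.0, seed=3)
    np.testing.assert_array_equal(imaging.stitch_tiles(well.bf_tiles),
                                  well.brightfield)
    np.testing.assert_array_equal(imaging.stitch_tiles(well.gfp_tiles),
                                  well.gfp)


def test_negative_noise_rejected(small_truth, induced_condition):
    with pytest.raises(ValueError):
        synthetic.render_well_image(small_truth, induced_condition,
                                    noise_sd=-1.0, seed=0)


# ----------------------------------------------------------- whole plate

def _small_plate_params(noise_sd=0.0):
    return PlateImageParams(worm_spec=SMALL_SPEC, well_radius=SMALL_RADIUS,
                            noise_sd=noise_sd)


def test_plate_well_count_and_manifest():
    conds = [PlateCondition(rnai_clone="vector", treatment="tox",
                            induction_factor=8, replicates=4),
             PlateCondition(rnai_clone="geneX", treatment="tox",
                            induction_factor=8, suppression_factor=0.25,
                            replicates=4)]
    wells, manifest = simulate_screen_plate(conds, _small_plate_params(), seed=1)
    assert len(wells) == 8 and len(manifest) == 8
    assert (manifest.loc[manifest.rnai == "geneX", "true_fold"] == 4.0).all()
    assert (manifest.loc[manifest.rnai == "vector", "true_fold"] == 1.0).all()


def test_duplicate_conditions_rejected():
    c = PlateCondition(rnai_clone="geneX")
    with pytest.raises(ValueError):
        simulate_screen_plate([c, PlateCondition(rnai_clone="geneX")], seed=0)


def test_noiseless_plate_fold_recovered_by_pipeline():
    """End to end: quantified fold equals the manifest fold (noiseless)."""
    conds = [PlateCondition(rnai_clone="vector", treatment="tox",
                            induction_factor=10, replicates=4),
             PlateCondition(rnai_clone="geneX", treatment="tox",
                            induction_factor=10, suppression_factor=0.2,
                            replicates=4)]
    wells, manifest = simulate_screen_plate(conds, _small_plate_params(), seed=2)
    values = {}
    for well, _ in wells:
        m = imaging.quantify_well(well)
        values.setdefault(well.condition.rnai_clone, []).append(
            m.median_worm_fluorescence)
    fold = np.mean(values["vector"]) / np.mean(values["geneX"])
    true = manifest.loc[manifest.rnai == "geneX", "true_fold"].iloc[0]
    assert fold == pytest.approx(true, rel=0.02)


# -------------------------------------------------------------- survival

def test_cohort_determinism():
    spec = SurvivalSimSpec(n_animals=50, seed=8)
    a, b = simulate_survival_cohort(spec), simulate_survival_cohort(spec)
    np.testing.assert_array_equal(a.times, b.times)
    np.testing.assert_array_equal(a.status, b.status)


def test_times_on_alternate_day_grid():
    c = simulate_survival_cohort(SurvivalSimSpec(n_animals=300, seed=1))
    assert (c.times % 2 == 0).all() and c.times.min() >= 2


def test_matched_multipliers_agree_within_monte_carlo_error():
    from wormscreen import lifespan
    a = simulate_survival_cohort(SurvivalSimSpec(n_animals=1000, seed=11))
    b = simulate_survival_cohort(SurvivalSimSpec(rnai_multiplier=1.0,
                                                 n_animals=1000, seed=12))
    ma = lifespan.mean_lifespan(a)
    mb = lifespan.mean_lifespan(b)
    sd = max(a.times.std(), b.times.std())
    se = sd * np.sqrt(2 / 1000)
    assert abs(ma - mb) <= 3 * se


def test_half_multiplier_shortens_lifespan():
    base = simulate_survival_cohort(SurvivalSimSpec(n_animals=1000, seed=13))
    short = simulate_survival_cohort(SurvivalSimSpec(rnai_multiplier=0.5,
                                                     n_animals=1000, seed=13))
    assert short.times[short.status == 1].mean() < base.times[base.status == 1].mean()


# ------------------------------------------------------------------ qPCR

def test_qpcr_noiseless_inverts_exactly():
    table = simulate_qpcr_plate(true_fold=8.0, noise_sd=0.0, replicates=4, seed=0)
    assert screen.qpcr_fold_change_from_table(table) == pytest.approx(8.0)
    flat = simulate_qpcr_plate(true_fold=1.0, noise_sd=0.0, replicates=4, seed=0)
    assert screen.qpcr_fold_change_from_table(flat) == pytest.approx(1.0)


def test_qpcr_monte_carlo_recovery_within_5_percent():
    folds = [screen.qpcr_fold_change_from_table(
        simulate_qpcr_plate(true_fold=8.0, noise_sd=0.2, replicates=4, seed=s))
        for s in range(200)]
    assert np.mean(folds) == pytest.approx(8.0, rel=0.05)


def test_qpcr_requires_replicates():
    with pytest.raises(ValueError):
        simulate_qpcr_plate(true_fold=2.0, replicates=1, seed=0)
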