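import numpy as np
import pytest

from vocamap import (
    GridSpec,
    StepCountTable,
    all_pairs,
    chi_square_2x2,
    classify_regions,
    density,
    embed,
    segment_regions,
    step_table,
)
from vocamap.step_analysis import _nearest_region

REFERENCE_TABLE = np.array([[3257, 1461], [2073, 2222]])


@pytest.fixture
def grid():
    return GridSpec((-20.0, 20.0), (-20.0, 20.0), n_x=50, n_y=50)


class TestSegmentRegions:
    def test_unimodal_density_single_region(self, grid):
        d = density(np.array([[0.0, 0.0]]), grid=grid, sigma=4.0)
        regions = segment_regions(d)
        assert regions.max() == 1

    def test_two_blobs_two_regions_boundary_near_midline(self, grid):
        pts = np.array([[-10.0, 0.0], [10.0, 0.0]])
        d = density(pts, grid=grid, sigma=2.5)
        regions = segment_regions(d)
        assert regions.max() == 2
        ix, iy = grid.locate(pts)
        r_left, r_right = regions[ix[0], iy[0]], regions[ix[1], iy[1]]
        assert r_left != r_right and r_left > 0 and r_right > 0
        # along the row through the blobs, the label switch happens near x=0
        row = regions[:, iy[0]]
        labeled = np.nonzero(row > 0)[0]
        switch = labeled[np.nonzero(np.diff(row[labeled]))[0]]
        assert abs(grid.x_centers[switch].mean()) < 3.0

    def test_zero_background_floor_assigns_every_cell(self, grid):
        d = density(np.array([[0.0, 0.0], [5.0, 5.0]]), grid=grid, sigma=3.0)
        regions = segment_regions(d, background_mass=0.0)
        assert (regions > 0).all()

    def test_background_floor_masks_low_mass_cells(self, grid):
        d = density(np.array([[0.0, 0.0]]), grid=grid, sigma=2.0)
        regions = segment_regions(d, background_mass=0.01)
        assert (regions == 0).any()

    def test_nearest_region_fill(self):
        rg = np.zeros((5, 5), dtype=int)
        rg[0, 0] = 1
        rg[4, 4] = 2
        filled = _nearest_region(rg)
        assert filled[0, 1] == 1 and filled[4, 3] == 2
        assert (filled > 0).all()


@pytest.fixture(scope="module")
def step_repertoire():
    """4-family repertoire large enough for the map to form real islands."""
    from vocamap import RepertoireConfig, generate_repertoire

    cfg = RepertoireConfig(
        n_individuals_per_group=3,
        calls_per_individual=50,
        step_probability={"WT": 0.7, "HT": 0.2},
        seed=42,
    )
    return generate_repertoire(cfg)


@pytest.fixture(scope="module")
def mapped_repertoire(step_repertoire):
    # sigma is matched to this 300-call map's island scale (span ~50 units);
    # larger maps use proportionally wider smoothing
    sigma = 2.0
    d = all_pairs(step_repertoire)
    rmap = embed(d, seed=0)
    grid = GridSpec.from_points(rmap.coordinates, n_x=80, n_y=80, margin=3 * sigma)
    pooled = density(rmap, grid=grid, sigma=sigma)
    regions = segment_regions(pooled)
    labels = classify_regions(regions, rmap, step_repertoire, grid)
    return rmap, grid, regions, labels


class TestClassifyAndTable:

    def test_label_recovery_against_generating_family(
        self, mapped_repertoire, step_repertoire
    ):
        from vocamap.synthetic_data import template_family

        _, _, _, labels = mapped_repertoire
        agree = np.mean(
            [
                (labels.vocal_labels[c.syllable_id] == "step")
                == (template_family(c) == "step")
                for c in step_repertoire
            ]
        )
        assert agree >= 0.95

    def test_every_vocalization_labeled(self, mapped_repertoire, step_repertoire):
        _, _, _, labels = mapped_repertoire
        assert set(labels.vocal_labels) == {c.syllable_id for c in step_repertoire}

    def test_labels_blind_to_genotype(self, mapped_repertoire, step_repertoire):
        """Permuting group labels changes the table margins, never the labels."""
        from vocamap import ContourCollection, FrequencyContour

        rmap, grid, regions, labels = mapped_repertoire
        swapped = ContourCollection(
            [
                FrequencyContour(
                    c.syllable_id,
                    c.individual_id,
                    {"WT": "HT", "HT": "WT"}[c.group],
                    c.start_time,
                    c.hop,
                    c.frequencies,
                    c.clipped,
                )
                for c in step_repertoire
            ]
        )
        relabeled = classify_regions(regions, rmap, swapped, grid)
        assert relabeled.vocal_labels == labels.vocal_labels
        t0 = step_table(labels, step_repertoire)
        t1 = step_table(relabeled, swapped)
        rows0 = dict(zip(t0.groups, t0.counts.tolist()))
        rows1 = dict(zip(t1.groups, t1.counts.tolist()))
        # the animals formerly labeled WT carry their counts to the HT row
        assert rows1["HT"] == rows0["WT"] and rows1["WT"] == rows0["HT"]

    def test_step_table_totals(self, mapped_repertoire, step_repertoire):
        _, _, _, labels = mapped_repertoire
        t = step_table(labels, step_repertoire)
        assert t.counts.sum() == len(step_repertoire)
        assert t.counts.sum(axis=1).tolist() == [150, 150]

    def test_map_proportions_near_direct_detection(
        self, mapped_repertoire, step_repertoire
    ):
        from vocamap.acoustics import detect_step

        _, _, _, labels = mapped_repertoire
        t = step_table(labels, step_repertoire)
        for g in ("WT", "HT"):
            direct = np.mean([detect_step(c) for c in step_repertoire if c.group == g])
            assert abs(t.step_fractions[g] - direct) < 0.05


class TestChiSquare:
    def test_reference_counts_yates(self):
        t = StepCountTable(counts=REFERENCE_TABLE, groups=["WT", "HT"])
        stat, df, p = chi_square_2x2(t, continuity_correction=True)
        assert df == 1
        assert stat == pytest.approx(400.42, abs=0.05)
        assert p < 1e-4

    def test_uncorrected_matches_closed_form(self):
        a, b = REFERENCE_TABLE[0]
        c, d = REFERENCE_TABLE[1]
        n = REFERENCE_TABLE.sum()
        closed = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        stat, _, _ = chi_square_2x2(REFERENCE_TABLE, continuity_correction=False)
        assert stat == pytest.approx(closed, rel=1e-12)
        corrected, _, _ = chi_square_2x2(REFERENCE_TABLE, continuity_correction=True)
        assert corrected < stat  # Yates shrinks the statistic

    def test_equal_proportions_zero(self):
        stat, _, p = chi_square_2x2(
            np.array([[50, 50], [50, 50]]), continuity_correction=False
        )
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_row_and_column_swap_invariance(self):
        stat0, _, _ = chi_square_2x2(REFERENCE_TABLE)
        swapped = REFERENCE_TABLE[::-1, ::-1]
        stat1, _, _ = chi_square_2x2(swapped)
        assert stat0 == pytest.approx(stat1, rel=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_2x2(np.array([[0, 0], [10, 5]]))


def test_step_fractions_from_reference_counts():
    t = StepCountTable(counts=REFERENCE_TABLE, groups=["WT", "HT"])
    f = t.step_fractions
    assert round(100 * f["WT"]) == 69
    assert round(100 * f["HT"]) == 48
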