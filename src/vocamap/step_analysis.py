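"""Map-based step/non-step labeling and the 2x2 contingency test.

Step ("jump"/"punctuated") syllables contain an abrupt discontinuity in
frequency and occupy their own islands in the repertoire map, separate from
the central body of simple calls.  To count them without inspecting
genotype, the pooled map density is segmented into regions by watershedding
from its local maxima, each region is classified step/non-step by the
majority step status of the contours that fall in it (contour shape only —
never group identity), and every vocalization inherits its region's label.
The per-genotype step counts then go into a 2x2 chi-squared test (Yates
continuity correction by default, which is the variant that reproduces the
reference statistic for the published counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .acoustics import DEFAULT_JUMP_THRESHOLD_KHZ, detect_step
from .contour_core import ContourCollection
from .density_significance import DensityGrid
from .embedding import RepertoireMap

__all__ = [
    "RegionLabels",
    "StepCountTable",
    "segment_regions",
    "classify_regions",
    "step_table",
    "chi_square_2x2",
]


@dataclass
class RegionLabels:
    """Watershed regions with step/non-step classes and per-call labels."""

    region_grid: np.ndarray  # (n_x, n_y) ints; 0 = background
    region_class: dict[int, str]  # region id -> "step" | "non_step"
    vocal_labels: dict[str, str]  # syllable_id -> "step" | "non_step"


@dataclass
class StepCountTable:
    """2x2 step/non-step counts; rows are groups, columns (step, non_step)."""

    counts: np.ndarray  # (2, 2) ints
    groups: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 2) or np.any(self.counts < 0):
            raise ValueError("counts must be a nonnegative 2x2 table")
        if len(self.groups) != 2:
            raise ValueError("exactly two groups required")

    @property
    def step_fractions(self) -> dict[str, float]:
        totals = self.counts.sum(axis=1)
        if np.any(totals == 0):
            raise ValueError("empty group in contingency table")
        return {
            g: float(self.counts[i, 0] / totals[i]) for i, g in enumerate(self.groups)
        }


def segment_regions(
    pooled: DensityGrid,
    background_mass: float = 0.01,
    min_peak_distance: int = 3,
) -> np.ndarray:
    """Watershed segmentation of the pooled map density.

    The negated density is flooded from its local maxima; cells jointly
    holding the lowest ``background_mass`` fraction of probability mass are
    background (region id 0).  With ``background_mass = 0`` every cell is
    assigned to a region.
    """
    if abs(pooled.total_mass - 1.0) > 1e-6:
        raise ValueError("pooled density must be normalized")
    rho = pooled.rho
    if background_mass > 0:
        order = np.argsort(rho, axis=None)
        cum = np.cumsum(rho.ravel()[order]) * pooled.grid.cell_area
        bg_flat = order[cum <= background_mass]
        background = np.zeros(rho.shape, dtype=bool)
        background.ravel()[bg_flat] = True
    else:
        background = np.zeros(rho.shape, dtype=bool)
    mask = ~background
    peaks = peak_local_max(
        rho, min_distance=min_peak_distance, exclude_border=False, labels=mask
    )
    markers = np.zeros(rho.shape, dtype=int)
    for rid, (i, j) in enumerate(peaks, start=1):
        markers[i, j] = rid
    if markers.max() == 0:  # perfectly flat density: one region
        ii, jj = np.nonzero(mask)
        markers[ii[0], jj[0]] = 1
    return watershed(-rho, markers=markers, mask=mask)


def _nearest_region(region_grid: np.ndarray) -> np.ndarray:
    """Grid where background cells take the id of the nearest region cell."""
    if (region_grid > 0).all():
        return region_grid
    _, (inds_x, inds_y) = ndimage.distance_transform_edt(
        region_grid == 0, return_indices=True
    )
    return region_grid[inds_x, inds_y]


def classify_regions(
    region_grid: np.ndarray,
    rmap: RepertoireMap,
    collection: ContourCollection,
    grid,
    jump_threshold: float = DEFAULT_JUMP_THRESHOLD_KHZ,
) -> RegionLabels:
    """Majority-vote step classification of regions; genotype-blind.

    A region is "step" iff more than half of the contours falling in it
    contain a frequency discontinuity >= ``jump_threshold``.  Vocalizations
    landing on background cells are assigned to the nearest region.  Only
    map position and contour shape are used — never group identity.
    """
    coll = collection.non_clipped()
    by_id = {c.syllable_id: c for c in coll}
    missing = [s for s in rmap.syllable_order if s not in by_id]
    if missing:
        raise ValueError(f"map contains unknown syllables, e.g. {missing[0]!r}")
    filled = _nearest_region(region_grid)
    ix, iy = grid.locate(rmap.coordinates)
    regions = filled[ix, iy]

    steps = np.array(
        [detect_step(by_id[s], jump_threshold) for s in rmap.syllable_order]
    )
    region_class: dict[int, str] = {}
    for rid in np.unique(region_grid[region_grid > 0]):
        members = regions == rid
        frac = steps[members].mean() if members.any() else 0.0
        region_class[int(rid)] = "step" if frac > 0.5 else "non_step"
    vocal_labels = {
        sid: region_class[int(rid)]
        for sid, rid in zip(rmap.syllable_order, regions)
    }
    return RegionLabels(
        region_grid=region_grid, region_class=region_class, vocal_labels=vocal_labels
    )


def step_table(labels: RegionLabels, collection: ContourCollection) -> StepCountTable:
    """Cross-tabulate group x (step, non_step) over non-clipped calls."""
    coll = collection.non_clipped()
    groups = coll.groups
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    counts = np.zeros((2, 2), dtype=int)
    for c in coll:
        lab = labels.vocal_labels.get(c.syllable_id)
        if lab is None:
            raise ValueError(f"unlabeled vocalization {c.syllable_id!r}")
        counts[groups.index(c.group), 0 if lab == "step" else 1] += 1
    if np.any(counts.sum(axis=1) == 0):
        raise ValueError("a group has no vocalizations")
    return StepCountTable(counts=counts, groups=groups)


def chi_square_2x2(
    table: StepCountTable | np.ndarray, continuity_correction: bool = True
) -> tuple[float, int, float]:
    """Pearson chi-squared on a 2x2 table; Yates-corrected by default.

    Returns ``(statistic, df=1, p)`` with the upper-tail p-value.
    """
    counts = table.counts if isinstance(table, StepCountTable) else np.asarray(table)
    if counts.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    res = stats.chi2_contingency(counts, correction=continuity_correction)
    return float(res.statistic), 1, float(res.pvalue)
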