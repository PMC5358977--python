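"""Per-syllable acoustic measures and group statistics.

Three simple measures are computed from each frequency contour: duration
(``(n - 1) * hop`` seconds), bandwidth (max - min contour frequency, kHz) and
mean frequency (unweighted mean of the contour samples, kHz).  Group
comparisons follow the standard design for pup vocalization studies: the
unit of analysis is the *individual* — per-syllable measures are averaged
within each animal and a one-way ANOVA is run on the individual means (so a
5 + 6 animal study has df = (1, 9) regardless of how many thousands of calls
were recorded).

``detect_step`` flags syllables containing an abrupt frequency discontinuity
("step"/"jump" syllables): any adjacent-sample change >= ``jump_threshold``
(default 10 kHz, well above the per-sample change of even steep sweeps at a
1 ms hop).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .contour_core import ContourCollection, FrequencyContour

__all__ = [
    "AcousticMeasures",
    "DEFAULT_JUMP_THRESHOLD_KHZ",
    "measure",
    "detect_step",
    "measure_collection",
    "individual_means",
    "anova_oneway",
]

DEFAULT_JUMP_THRESHOLD_KHZ = 10.0


@dataclass(frozen=True)
class AcousticMeasures:
    duration: float  # s
    bandwidth: float  # kHz
    mean_frequency: float  # kHz
    has_step: bool


def measure(
    c: FrequencyContour, jump_threshold: float = DEFAULT_JUMP_THRESHOLD_KHZ
) -> AcousticMeasures:
    """Duration, bandwidth, mean frequency and step flag for one syllable."""
    f = c.frequencies
    return AcousticMeasures(
        duration=c.duration,
        bandwidth=float(f.max() - f.min()),
        mean_frequency=float(f.mean()),
        has_step=detect_step(c, jump_threshold),
    )


def detect_step(
    c: FrequencyContour, jump_threshold: float = DEFAULT_JUMP_THRESHOLD_KHZ
) -> bool:
    """True iff any adjacent-sample |Δf| >= jump_threshold (kHz)."""
    if not (jump_threshold > 0):
        raise ValueError("jump_threshold must be > 0")
    return bool(np.max(np.abs(np.diff(c.frequencies))) >= jump_threshold)


def measure_collection(
    collection: ContourCollection,
    jump_threshold: float = DEFAULT_JUMP_THRESHOLD_KHZ,
    include_clipped: bool = False,
) -> pd.DataFrame:
    """Per-syllable measure table (clipped syllables dropped by default)."""
    rows = []
    for c in collection:
        if c.clipped and not include_clipped:
            continue
        m = measure(c, jump_threshold)
        rows.append(
            (
                c.syllable_id,
                c.individual_id,
                c.group,
                m.duration,
                m.bandwidth,
                m.mean_frequency,
                m.has_step,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "syllable_id",
            "individual_id",
            "group",
            "duration",
            "bandwidth",
            "mean_frequency",
            "has_step",
        ],
    )


def individual_means(
    collection: ContourCollection, measure_name: str
) -> dict[str, float]:
    """Mean of one acoustic measure over each individual's non-clipped calls."""
    df = measure_collection(collection)
    if measure_name not in ("duration", "bandwidth", "mean_frequency"):
        raise ValueError(f"unknown measure {measure_name!r}")
    empty = set(collection.individuals) - set(df["individual_id"])
    if empty:
        raise ValueError(
            f"individual(s) with no analysable contours: {sorted(empty)}"
        )
    return df.groupby("individual_id")[measure_name].mean().to_dict()


def anova_oneway(
    values_by_group: Mapping[str, Sequence[float]],
) -> tuple[float, int, int, float]:
    """One-way ANOVA on per-individual means.

    Returns ``(F, df1, df2, p)`` with ``df1 = groups - 1`` and
    ``df2 = total individuals - groups``.
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    samples = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    for g, s in zip(groups, samples):
        if s.size < 2:
            raise ValueError(f"group {g!r} has < 2 individuals")
    f_stat, p = stats.f_oneway(*samples)
    df1 = len(groups) - 1
    df2 = int(sum(s.size for s in samples)) - len(groups)
    return float(f_stat), df1, df2, float(p)


def group_anovas(collection: ContourCollection) -> pd.DataFrame:
    """ANOVA on individual means for each of the three acoustic measures."""
    ind_group = collection.individuals
    rows = []
    for name in ("duration", "bandwidth", "mean_frequency"):
        means = individual_means(collection, name)
        by_group: dict[str, list[float]] = {}
        for ind, v in means.items():
            by_group.setdefault(ind_group[ind], []).append(v)
        f, df1, df2, p = anova_oneway(by_group)
        rows.append((name, f, df1, df2, p))
    return pd.DataFrame(rows, columns=["measure", "F", "df1", "df2", "p"])
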