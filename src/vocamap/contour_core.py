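"""Frequency-contour data model and interchange I/O.

A mouse ultrasonic vocalization (USV) syllable is represented here by its
*frequency contour*: the uniformly sampled trajectory of its dominant
frequency (kHz) over time, together with metadata identifying the emitting
individual and its genotype group.  Contours are the unit of every
downstream computation — acoustic measures, dynamic-time-warping distances,
and the 2-D repertoire map are all functions of these objects.

Interchange formats
-------------------
* **CSV** (long form): one row per contour sample with columns
  ``syllable_id, individual_id, group, sample_index, time_s, freq_khz,
  clipped``.  Ragged syllable lengths are natural in this layout and any
  tabular reader round-trips it.
* **JSON**: a list of syllable records, each carrying its metadata and a
  frequency array.

Frequencies are stored in kHz and times in seconds.  Contours are uniformly
sampled; ``duration = (n - 1) * hop`` (fence-post convention, 0-based sample
indices).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FrequencyContour",
    "ContourCollection",
    "ContourParseError",
    "read_contours",
    "write_contours",
    "resample_contour",
]

CSV_COLUMNS = [
    "syllable_id",
    "individual_id",
    "group",
    "sample_index",
    "time_s",
    "freq_khz",
    "clipped",
]

#: relative tolerance used when deciding whether two hop values are "the same"
_HOP_RTOL = 1e-6


class ContourParseError(ValueError):
    """Raised when a contour file is malformed."""


@dataclass(frozen=True)
class FrequencyContour:
    """One syllable's uniformly sampled frequency trajectory.

    Parameters
    ----------
    syllable_id, individual_id, group
        Opaque identifiers.  ``group`` is the genotype label (e.g. ``"WT"``,
        ``"HT"``).
    start_time
        Onset of the syllable in the recording, seconds (>= 0).
    hop
        Sampling interval of the contour, seconds (> 0).
    frequencies
        Frequency samples in kHz, length >= 2, all positive and finite.
    clipped
        True if the source waveform exceeded the recorder's amplitude limit;
        clipped syllables are excluded from analysis.
    """

    syllable_id: str
    individual_id: str
    group: str
    start_time: float
    hop: float
    frequencies: np.ndarray
    clipped: bool = False

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", freqs)
        if freqs.ndim != 1 or freqs.size < 2:
            raise ValueError(
                f"contour {self.syllable_id!r}: need >= 2 frequency samples, "
                f"got shape {freqs.shape}"
            )
        if not np.all(np.isfinite(freqs)) or np.any(freqs <= 0):
            raise ValueError(
                f"contour {self.syllable_id!r}: frequencies must be finite and > 0 kHz"
            )
        if not (self.hop > 0):
            raise ValueError(f"contour {self.syllable_id!r}: hop must be > 0")
        if self.start_time < 0:
            raise ValueError(f"contour {self.syllable_id!r}: start_time must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(self.frequencies.size)

    @property
    def duration(self) -> float:
        """Syllable duration in seconds: ``(n - 1) * hop``."""
        return (self.n_samples - 1) * self.hop

    @property
    def times(self) -> np.ndarray:
        """Sample times relative to syllable onset, seconds."""
        return np.arange(self.n_samples) * self.hop

    def __eq__(self, other: object) -> bool:  # dataclass eq chokes on arrays
        if not isinstance(other, FrequencyContour):
            return NotImplemented
        return (
            self.syllable_id == other.syllable_id
            and self.individual_id == other.individual_id
            and self.group == other.group
            and np.isclose(self.start_time, other.start_time)
            and np.isclose(self.hop, other.hop)
            and self.clipped == other.clipped
            and self.frequencies.shape == other.frequencies.shape
            and np.allclose(self.frequencies, other.frequencies)
        )


@dataclass
class ContourCollection:
    """An ordered collection of contours sharing one sampling hop.

    The contour order is stable: row/column ``i`` of any matrix derived from
    the collection refers to ``contours[i]``.  Each individual belongs to
    exactly one group.
    """

    contours: list[FrequencyContour] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: dict[str, str] = {}
        for c in self.contours:
            prev = seen.setdefault(c.individual_id, c.group)
            if prev != c.group:
                raise ValueError(
                    f"individual {c.individual_id!r} appears in groups "
                    f"{prev!r} and {c.group!r}"
                )
        hops = {c.hop for c in self.contours}
        if len(hops) > 1:
            lo, hi = min(hops), max(hops)
            if (hi - lo) / hi > _HOP_RTOL:
                raise ValueError(
                    f"mixed contour hops ({lo:g}..{hi:g} s); resample to a "
                    "common hop first (see resample_contour / auto_resample)"
                )

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.contours)

    def __iter__(self) -> Iterator[FrequencyContour]:
        return iter(self.contours)

    def __getitem__(self, i: int) -> FrequencyContour:
        return self.contours[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContourCollection):
            return NotImplemented
        return len(self) == len(other) and all(
            a == b for a, b in zip(self.contours, other.contours)
        )

    # -- metadata views ------------------------------------------------------
    @property
    def groups(self) -> list[str]:
        """Group labels present, in first-appearance order."""
        out: list[str] = []
        for c in self.contours:
            if c.group not in out:
                out.append(c.group)
        return out

    @property
    def individuals(self) -> dict[str, str]:
        """Mapping individual_id -> group."""
        out: dict[str, str] = {}
        for c in self.contours:
            out.setdefault(c.individual_id, c.group)
        return out

    @property
    def hop(self) -> float:
        if not self.contours:
            raise ValueError("empty collection has no hop")
        return self.contours[0].hop

    def non_clipped(self) -> "ContourCollection":
        """Collection restricted to analysable (non-clipped) contours."""
        return ContourCollection([c for c in self.contours if not c.clipped])

    def subset(self, indices: Sequence[int]) -> "ContourCollection":
        return ContourCollection([self.contours[i] for i in indices])

    def group_indices(self) -> dict[str, np.ndarray]:
        """Per-group integer indices into the collection's contour order."""
        out: dict[str, list[int]] = {g: [] for g in self.groups}
        for i, c in enumerate(self.contours):
            out[c.group].append(i)
        return {g: np.asarray(ix, dtype=int) for g, ix in out.items()}

    def resampled(self, hop: float) -> "ContourCollection":
        return ContourCollection([resample_contour(c, hop) for c in self.contours])


def resample_contour(c: FrequencyContour, hop: float) -> FrequencyContour:
    """Linearly resample a contour onto a new sampling interval.

    Duration is preserved to within one hop: the output has
    ``round(duration / hop) + 1`` samples.  Identity when the hop is
    unchanged.
    """
    if not (hop > 0):
        raise ValueError("hop must be > 0")
    if np.isclose(hop, c.hop, rtol=_HOP_RTOL):
        return c
    n_new = int(round(c.duration / hop)) + 1
    if n_new < 2:
        raise ValueError(
            f"contour {c.syllable_id!r} ({c.duration * 1e3:.2f} ms) too short "
            f"for hop {hop * 1e3:.2f} ms"
        )
    new_times = np.arange(n_new) * hop
    freqs = np.interp(np.clip(new_times, 0.0, c.duration), c.times, c.frequencies)
    return replace(c, hop=hop, frequencies=freqs)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "json" if path.suffix.lower() == ".json" else "csv"


def read_contours(
    path: str | Path,
    format: str | None = None,
    auto_resample: bool = False,
    hop: float | None = None,
) -> ContourCollection:
    """Read a contour collection from CSV (long form) or JSON.

    Parameters
    ----------
    format
        ``"csv"`` or ``"json"``; inferred from the suffix when omitted.
    auto_resample
        If the file mixes hop values, resample everything onto a common hop
        (``hop`` if given, else the smallest present) instead of raising.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        contours = _read_csv(path)
    elif fmt == "json":
        contours = _read_json(path)
    else:
        raise ValueError(f"unknown contour format {fmt!r}")
    if not contours:
        raise ContourParseError(f"{path}: no contours found (empty file?)")

    hops = sorted({c.hop for c in contours})
    if len(hops) > 1 and (hops[-1] - hops[0]) / hops[-1] > _HOP_RTOL:
        if not auto_resample:
            raise ValueError(
                f"{path}: contours have mixed hops {hops[0]:g}..{hops[-1]:g} s; "
                "pass auto_resample=True or resample explicitly"
            )
        target = hop if hop is not None else hops[0]
        contours = [resample_contour(c, target) for c in contours]
    return ContourCollection(contours)


def _read_csv(path: Path) -> list[FrequencyContour]:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ContourParseError(f"{path}: empty file") from None
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ContourParseError(f"{path}: missing required columns {missing}")
    bad = df.index[df["freq_khz"].isna() | df["time_s"].isna()]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ContourParseError(f"{path}: malformed row at line {bad[0] + 2}")
    contours: list[FrequencyContour] = []
    for sid, g in df.groupby("syllable_id", sort=False):
        g = g.sort_values("sample_index")
        times = g["time_s"].to_numpy(dtype=float)
        if len(times) < 2:
            raise ContourParseError(
                f"{path}: syllable {sid!r} has fewer than 2 samples"
            )
        dt = np.diff(times)
        if np.any(dt <= 0) or (dt.max() - dt.min()) / dt.max() > 1e-4:
            raise ContourParseError(
                f"{path}: syllable {sid!r} is not uniformly sampled"
            )
        contours.append(
            FrequencyContour(
                syllable_id=str(sid),
                individual_id=str(g["individual_id"].iloc[0]),
                group=str(g["group"].iloc[0]),
                start_time=float(times[0]),
                hop=float(dt.mean()),
                frequencies=g["freq_khz"].to_numpy(dtype=float),
                clipped=bool(g["clipped"].iloc[0]),
            )
        )
    return contours


def _read_json(path: Path) -> list[FrequencyContour]:
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as e:
            raise ContourParseError(f"{path}: invalid JSON at line {e.lineno}") from e
    records = payload["contours"] if isinstance(payload, Mapping) else payload
    contours = []
    for rec in records:
        contours.append(
            FrequencyContour(
                syllable_id=str(rec["syllable_id"]),
                individual_id=str(rec["individual_id"]),
                group=str(rec["group"]),
                start_time=float(rec.get("start_time", 0.0)),
                hop=float(rec["hop"]),
                frequencies=np.asarray(rec["freq_khz"], dtype=float),
                clipped=bool(rec.get("clipped", False)),
            )
        )
    return contours


def write_contours(
    collection: ContourCollection, path: str | Path, format: str | None = None
) -> Path:
    """Write a collection to CSV or JSON (inverse of :func:`read_contours`)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        rows = []
        for c in collection:
            times = c.start_time + c.times
            for k in range(c.n_samples):
                rows.append(
                    (
                        c.syllable_id,
                        c.individual_id,
                        c.group,
                        k,
                        times[k],
                        c.frequencies[k],
                        c.clipped,
                    )
                )
        pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
    elif fmt == "json":
        records = [
            {
                "syllable_id": c.syllable_id,
                "individual_id": c.individual_id,
                "group": c.group,
                "start_time": c.start_time,
                "hop": c.hop,
                "clipped": c.clipped,
                "freq_khz": c.frequencies.tolist(),
            }
            for c in collection
        ]
        with open(path, "w") as fh:
            json.dump({"contours": records}, fh, indent=1)
    else:
        raise ValueError(f"unknown contour format {fmt!r}")
    return path
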