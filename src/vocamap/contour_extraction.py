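"""Multitaper F-test contour extraction from WAV recordings.

A simplified audio front-end: overlapping waveform segments are Fourier
transformed under discrete prolate spheroidal (DPSS, Slepian) tapers and
Thomson's harmonic F-test is applied at every time-frequency bin to find
sinusoidal components significantly above the noise floor (default
p < 0.01, F with (2, 2K-2) degrees of freedom for K tapers, applied per bin
without multiplicity correction).  Per time step, the frequency of the
highest-F significant bin inside the analysis band becomes the contour
sample; runs separated by silent gaps become separate syllables, and
syllables shorter than a minimum duration are dropped.

This is a single-dominant-contour tracer: no multi-harmonic merging and no
manual-correction stage.  Recordings whose samples reach the amplitude limit
("clipped") are flagged so downstream analysis can exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from scipy.io import wavfile
from scipy.signal.windows import dpss

from .contour_core import ContourCollection, FrequencyContour

__all__ = [
    "ExtractionParams",
    "TFPoints",
    "detect_tf_points",
    "trace_contours",
    "extract_contours",
    "flag_clipping",
    "read_wav",
    "write_wav",
]


@dataclass(frozen=True)
class ExtractionParams:
    """Detection and tracing parameters (defaults suit 250 kHz recordings)."""

    window_length: float = 0.5e-3  # s
    overlap_fraction: float = 0.5
    time_bandwidth: float = 3.0  # DPSS NW
    n_tapers: int = 5
    f_test_p: float = 0.01
    min_freq: float = 35.0  # kHz
    max_freq: float = 115.0  # kHz
    max_gap: float = 10e-3  # s; longer silent gaps split syllables
    min_duration: float = 5e-3  # s
    clip_threshold: float = 0.999  # fraction of full scale
    nfft: int = 512

    def __post_init__(self) -> None:
        if self.n_tapers > 2 * self.time_bandwidth - 1:
            raise ValueError("n_tapers must be <= 2*time_bandwidth - 1")
        if not 0 < self.f_test_p < 1:
            raise ValueError("f_test_p must be in (0, 1)")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")


@dataclass
class TFPoints:
    """Significant time-frequency points from the harmonic F-test."""

    times: np.ndarray  # s, frame centers
    freqs: np.ndarray  # kHz
    f_stat: np.ndarray
    hop: float  # s, frame hop
    n_frames: int

    def __len__(self) -> int:
        return self.times.size


def _frame(x: np.ndarray, m: int, hop: int) -> np.ndarray:
    n_frames = 1 + max(0, (x.size - m) // hop)
    idx = np.arange(m)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def detect_tf_points(
    waveform: np.ndarray, sample_rate: float, params: ExtractionParams | None = None
) -> TFPoints:
    """Harmonic F-test over the multitaper spectrogram.

    Returns the time-frequency points within the analysis band whose F
    statistic exceeds the ``f_test_p`` significance level (df = (2, 2K-2)).
    Silent (all-zero) frames produce no points.
    """
    p = params or ExtractionParams()
    x = np.asarray(waveform, dtype=float)
    if x.size == 0:
        raise ValueError("empty waveform")
    nyq_khz = sample_rate / 2e3
    if p.max_freq > nyq_khz:
        raise ValueError(
            f"band edge {p.max_freq} kHz exceeds Nyquist {nyq_khz:g} kHz"
        )
    m = int(round(p.window_length * sample_rate))
    if m < 8:
        raise ValueError("window_length too short for this sample rate")
    hop = max(int(round(m * (1.0 - p.overlap_fraction))), 1)
    if x.size < m:
        x = np.pad(x, (0, m - x.size))
    frames = _frame(x, m, hop)  # (n_frames, m)
    n_frames = frames.shape[0]

    tapers = dpss(m, NW=p.time_bandwidth, Kmax=p.n_tapers)  # (K, m)
    k = tapers.shape[0]
    nfft = max(p.nfft, m)
    # eigencoefficients J_k(f): (K, n_frames, nfft//2+1)
    j = np.fft.rfft(tapers[:, None, :] * frames[None, :, :], n=nfft, axis=-1)
    u0 = tapers.sum(axis=1)  # DC of each taper; odd tapers ~ 0
    u0sq = float((u0**2).sum())
    mu = np.tensordot(u0, j, axes=(0, 0)) / u0sq  # (n_frames, nbins)
    resid = j - u0[:, None, None] * mu[None, :, :]
    sse = (np.abs(resid) ** 2).sum(axis=0)
    num = (k - 1) * (np.abs(mu) ** 2) * u0sq
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = np.where(sse > 0, num / np.where(sse > 0, sse, 1.0), 0.0)

    f_crit = stats.f.isf(p.f_test_p, 2, 2 * k - 2)
    freqs_khz = np.fft.rfftfreq(nfft, d=1.0 / sample_rate) / 1e3
    in_band = (freqs_khz >= p.min_freq) & (freqs_khz <= p.max_freq)
    sig = (f_stat > f_crit) & in_band[None, :]

    frame_idx, bin_idx = np.nonzero(sig)
    frame_hop_s = hop / sample_rate
    times = (frame_idx * hop + m / 2) / sample_rate
    return TFPoints(
        times=times,
        freqs=freqs_khz[bin_idx],
        f_stat=f_stat[frame_idx, bin_idx],
        hop=frame_hop_s,
        n_frames=n_frames,
    )


def trace_contours(
    points: TFPoints,
    params: ExtractionParams | None = None,
    individual_id: str = "unknown",
    group: str = "unknown",
    syllable_prefix: str = "syl",
) -> ContourCollection:
    """Link significant points into per-syllable frequency contours.

    Per time step the maximal-F significant frequency is kept; runs of
    voiced frames separated by silent gaps longer than ``max_gap`` become
    separate syllables and syllables shorter than ``min_duration`` are
    dropped.  The contour hop equals the analysis frame hop.
    """
    p = params or ExtractionParams()
    if len(points) == 0:
        return ContourCollection([])
    frame_of = np.round(points.times / points.hop).astype(int)
    # per frame, keep the point with the largest F statistic
    best_f: dict[int, float] = {}
    best_freq: dict[int, float] = {}
    for fr, fq, fs in zip(frame_of, points.freqs, points.f_stat):
        if fs > best_f.get(fr, -np.inf):
            best_f[fr] = fs
            best_freq[fr] = fq

    voiced = np.array(sorted(best_freq), dtype=int)
    max_gap_frames = max(int(round(p.max_gap / points.hop)), 1)
    min_len = int(np.ceil(p.min_duration / points.hop)) + 1
    contours: list[FrequencyContour] = []
    run_start = 0
    breaks = np.nonzero(np.diff(voiced) > max_gap_frames)[0]
    for stop in list(breaks) + [voiced.size - 1]:
        run = voiced[run_start : stop + 1]
        run_start = stop + 1
        if run.size < max(min_len, 2):
            continue
        # fill short unvoiced gaps inside the run by interpolation
        full = np.arange(run[0], run[-1] + 1)
        freqs = np.interp(full, run, [best_freq[f] for f in run])
        contours.append(
            FrequencyContour(
                syllable_id=f"{syllable_prefix}_{len(contours):04d}",
                individual_id=individual_id,
                group=group,
                start_time=float(run[0] * points.hop),
                hop=points.hop,
                frequencies=freqs,
            )
        )
    return ContourCollection(contours)


def extract_contours(
    waveform: np.ndarray,
    sample_rate: float,
    params: ExtractionParams | None = None,
    **trace_kwargs,
) -> ContourCollection:
    """Detect + trace in one call, flagging syllables from clipped audio."""
    p = params or ExtractionParams()
    points = detect_tf_points(waveform, sample_rate, p)
    coll = trace_contours(points, p, **trace_kwargs)
    if len(coll) and flag_clipping(waveform, p.clip_threshold):
        x = np.abs(np.asarray(waveform, dtype=float))
        out = []
        for c in coll:
            a = int(c.start_time * sample_rate)
            b = int((c.start_time + c.duration) * sample_rate) + 1
            clipped = bool(x[a:b].max() >= p.clip_threshold)
            out.append(
                FrequencyContour(
                    c.syllable_id, c.individual_id, c.group,
                    c.start_time, c.hop, c.frequencies, clipped=clipped,
                )
            )
        coll = ContourCollection(out)
    return coll


def flag_clipping(waveform: np.ndarray, clip_threshold: float = 0.999) -> bool:
    """True iff any sample magnitude reaches ``clip_threshold`` x full scale.

    Integer PCM waveforms are referred to their dtype's full scale; float
    waveforms to full scale 1.0.
    """
    x = np.asarray(waveform)
    if np.issubdtype(x.dtype, np.integer):
        full_scale = float(np.iinfo(x.dtype).max)
        x = x.astype(float)
    else:
        full_scale = 1.0
        x = x.astype(float)
    if x.size == 0:
        return False
    return bool(np.abs(x).max() >= clip_threshold * full_scale)


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a mono PCM/float WAV; returns (float waveform in [-1, 1], rate)."""
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    else:
        data = data.astype(float)
    return data, float(rate)


def write_wav(path: str | Path, waveform: np.ndarray, sample_rate: float) -> Path:
    """Write a float waveform as 16-bit PCM."""
    x = np.clip(np.asarray(waveform, dtype=float), -1.0, 1.0)
    wavfile.write(path, int(sample_rate), (x * 32767).astype(np.int16))
    return Path(path)
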