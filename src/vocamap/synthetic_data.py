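"""Synthetic mouse-pup USV repertoires with genotype structure.

Pup isolation calls fall into a small set of recurring contour shapes: flat
tones, upward/downward frequency sweeps, chevrons (rise-then-fall arcs), and
"step" (jump/punctuated) syllables containing an abrupt discontinuity in
frequency between adjacent time points.  This module generates collections
of such contours with

* per-group step prevalence (defaults 0.69 vs 0.48 — the step-call
  proportions observed in wild-type vs heterozygous pups),
* per-individual random frequency offsets (litter/animal variation), and
* per-sample frequency jitter,

so that every downstream stage (distances, embedding, density significance,
step classification) can be exercised and calibrated without recordings.

Construction guarantees
-----------------------
Non-step contours never contain an adjacent-sample frequency change at or
above the default 10 kHz step-detection threshold (sweep slopes are <= ~2
kHz/ms and jitter is clipped to +/-3 kHz), while step contours contain
exactly one discontinuity drawn from [12, 40] kHz — unambiguously above the
threshold.  All contours stay inside a configurable frequency band (default
35-115 kHz) with durations in the pup-call range (tens of ms).

An analytic FM synthesizer (:func:`synthesize_audio`) turns any contour into
a waveform, providing round-trip fixtures for the extraction front-end; it
makes no attempt at vocal-tract realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .contour_core import ContourCollection, FrequencyContour

__all__ = [
    "SyllableTemplate",
    "RepertoireConfig",
    "DEFAULT_TEMPLATES",
    "generate_repertoire",
    "synthesize_audio",
]

#: per-sample jitter is clipped to this many kHz so non-step families can
#: never cross the 10 kHz step-detection threshold by chance
_JITTER_CLIP_KHZ = 3.0


@dataclass(frozen=True)
class SyllableTemplate:
    """Parametric family of contour shapes.

    ``freq_extent`` is the sweep depth in kHz (signed for sweeps, peak height
    for chevrons, 0 for flat).  ``duration_range`` is in milliseconds.  For
    the ``step`` family the discontinuity is drawn from ``step_jump_range``
    and is the only adjacent-sample jump in the contour.
    """

    family: str  # flat | upsweep | downsweep | chevron | step
    base_freq: float  # kHz
    freq_extent: float = 0.0  # kHz
    duration_range: tuple[float, float] = (30.0, 100.0)  # ms
    step_jump_range: tuple[float, float] = (12.0, 40.0)  # kHz, step family only


DEFAULT_TEMPLATES: tuple[SyllableTemplate, ...] = (
    SyllableTemplate("flat", base_freq=70.0, freq_extent=0.0, duration_range=(20, 60)),
    SyllableTemplate("upsweep", base_freq=55.0, freq_extent=25.0, duration_range=(30, 100)),
    SyllableTemplate("downsweep", base_freq=90.0, freq_extent=-25.0, duration_range=(30, 100)),
    SyllableTemplate("chevron", base_freq=60.0, freq_extent=18.0, duration_range=(40, 90)),
)

_STEP_TEMPLATE = SyllableTemplate("step", base_freq=0.0, duration_range=(40, 120))


@dataclass(frozen=True)
class RepertoireConfig:
    """Study-design parameters for a synthetic repertoire.

    Defaults emulate a two-genotype pup isolation-call study: step-call
    probabilities 0.69 (WT) vs 0.48 (HT), several hundred calls per
    individual, individual base-frequency offsets of a few kHz, and 1 ms
    contour sampling.
    """

    n_individuals_per_group: int = 5
    calls_per_individual: int | tuple[int, int] = 900
    step_probability: Mapping[str, float] = field(
        default_factory=lambda: {"WT": 0.69, "HT": 0.48}
    )
    individual_effect_sd: float = 3.0  # kHz
    freq_jitter_sd: float = 0.5  # kHz
    hop: float = 1e-3  # s
    seed: int = 0
    band: tuple[float, float] = (35.0, 115.0)  # kHz
    templates: tuple[SyllableTemplate, ...] = DEFAULT_TEMPLATES

    def __post_init__(self) -> None:
        for g, p in self.step_probability.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"step_probability[{g!r}] = {p} not in [0, 1]")
        if self.individual_effect_sd < 0 or self.freq_jitter_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_individuals_per_group < 1:
            raise ValueError("need at least one individual per group")
        lo = (
            self.calls_per_individual
            if isinstance(self.calls_per_individual, int)
            else self.calls_per_individual[0]
        )
        if lo < 1:
            raise ValueError("need at least one call per individual")
        if not (self.hop > 0):
            raise ValueError("hop must be > 0")


def _clipped_normal(rng: np.random.Generator, sd: float, n: int) -> np.ndarray:
    return np.clip(rng.normal(0.0, sd, size=n), -_JITTER_CLIP_KHZ, _JITTER_CLIP_KHZ)


def _nonstep_contour(
    rng: np.random.Generator,
    tmpl: SyllableTemplate,
    ind_shift: float,
    cfg: RepertoireConfig,
) -> np.ndarray:
    dur_ms = rng.uniform(*tmpl.duration_range)
    n = max(int(round(dur_ms * 1e-3 / cfg.hop)) + 1, 2)
    t = np.linspace(0.0, 1.0, n)
    if tmpl.family == "flat":
        traj = np.full(n, tmpl.base_freq)
    elif tmpl.family in ("upsweep", "downsweep"):
        traj = tmpl.base_freq + tmpl.freq_extent * t
    elif tmpl.family == "chevron":
        traj = tmpl.base_freq + tmpl.freq_extent * (1.0 - (2.0 * t - 1.0) ** 2)
    else:
        raise ValueError(f"unknown non-step family {tmpl.family!r}")
    traj = traj + ind_shift + _clipped_normal(rng, cfg.freq_jitter_sd, n)
    lo, hi = cfg.band
    return np.clip(traj, lo + 1.0, hi - 1.0)


def _step_contour(
    rng: np.random.Generator, ind_shift: float, cfg: RepertoireConfig
) -> np.ndarray:
    """Two flat sub-segments with exactly one >= 12 kHz discontinuity."""
    tmpl = _STEP_TEMPLATE
    dur_ms = rng.uniform(*tmpl.duration_range)
    n = max(int(round(dur_ms * 1e-3 / cfg.hop)) + 1, 4)
    jump = float(rng.uniform(*tmpl.step_jump_range))
    up = bool(rng.integers(2))
    # keep both plateaus >= 7 kHz inside the band so jitter never clips
    lo, hi = cfg.band[0] + 7.0, cfg.band[1] - 7.0
    f1 = float(np.clip(rng.uniform(lo, hi) + np.clip(ind_shift, -6, 6), lo, hi))
    headroom = (hi - f1) if up else (f1 - lo)
    if jump > headroom:
        # flip toward the roomier side; worst case that side has
        # (hi - lo) / 2 = 33 kHz of room, still >= the 12 kHz minimum
        up = (hi - f1) >= (f1 - lo)
        jump = min(jump, (hi - f1) if up else (f1 - lo))
    split = int(round(n * rng.uniform(0.3, 0.7)))
    split = min(max(split, 2), n - 2)
    seg1 = f1 + _clipped_normal(rng, cfg.freq_jitter_sd, split)
    f2 = seg1[-1] + (jump if up else -jump)
    jitter2 = _clipped_normal(rng, cfg.freq_jitter_sd, n - split)
    jitter2[0] = 0.0  # boundary discontinuity is exactly `jump`
    seg2 = f2 + jitter2
    return np.concatenate([seg1, seg2])


def _individual_rng(seed: int, g_idx: int, i_idx: int) -> np.random.Generator:
    # spawn-key addressing: adding individuals/groups never perturbs others
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(g_idx, i_idx))
    return np.random.Generator(np.random.PCG64(ss))


def generate_repertoire(config: RepertoireConfig | None = None) -> ContourCollection:
    """Generate a genotype- and individual-structured contour collection.

    Deterministic given ``config.seed``; each individual draws from its own
    seed stream.  Each call is a step syllable with its group's
    ``step_probability``, otherwise a uniformly chosen non-step family.
    """
    cfg = config if config is not None else RepertoireConfig()
    contours: list[FrequencyContour] = []
    for g_idx, (group, p_step) in enumerate(cfg.step_probability.items()):
        for i_idx in range(cfg.n_individuals_per_group):
            rng = _individual_rng(cfg.seed, g_idx, i_idx)
            ind_id = f"{group}_i{i_idx:02d}"
            ind_shift = float(
                np.clip(rng.normal(0.0, cfg.individual_effect_sd), -6.0, 6.0)
            )
            if isinstance(cfg.calls_per_individual, int):
                n_calls = cfg.calls_per_individual
            else:
                lo, hi = cfg.calls_per_individual
                n_calls = int(rng.integers(lo, hi + 1))
            for k in range(n_calls):
                if rng.random() < p_step:
                    freqs = _step_contour(rng, ind_shift, cfg)
                    family = "step"
                else:
                    tmpl = cfg.templates[int(rng.integers(len(cfg.templates)))]
                    freqs = _nonstep_contour(rng, tmpl, ind_shift, cfg)
                    family = tmpl.family
                contours.append(
                    FrequencyContour(
                        syllable_id=f"{ind_id}_s{k:04d}_{family}",
                        individual_id=ind_id,
                        group=group,
                        start_time=0.0,
                        hop=cfg.hop,
                        frequencies=freqs,
                    )
                )
    if not contours:
        raise ValueError("configuration generated no calls")
    return ContourCollection(contours)


def template_family(c: FrequencyContour) -> str:
    """Generating family recorded in a synthetic syllable's id."""
    return c.syllable_id.rsplit("_", 1)[-1]


def synthesize_audio(
    c: FrequencyContour,
    sample_rate: float = 250_000.0,
    amplitude: float = 0.8,
    pad: float = 5e-3,
) -> np.ndarray:
    """Render a contour as a frequency-modulated tone.

    The instantaneous frequency follows the contour (linearly interpolated to
    the audio rate); ``pad`` seconds of silence are prepended and appended.
    Raises if the contour's maximum frequency violates Nyquist.
    """
    f_max_hz = float(c.frequencies.max()) * 1e3
    if sample_rate < 2.0 * f_max_hz:
        raise ValueError(
            f"sample rate {sample_rate:g} Hz < Nyquist for {f_max_hz:g} Hz contour"
        )
    n = int(round(c.duration * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    inst_f_hz = np.interp(t, c.times, c.frequencies) * 1e3
    phase = 2.0 * np.pi * np.cumsum(inst_f_hz) / sample_rate
    tone = amplitude * np.sin(phase)
    zeros = np.zeros(int(round(pad * sample_rate)))
    return np.concatenate([zeros, tone, zeros])
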