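"""Trill waveform synthesis and acoustic feature extraction.

A trill is a multi-syllable, frequency-modulated ultrasonic call of up to 30
syllables.  Its tempo-spectral structure is summarised by 29 parameters: the
whole-call duration and syllable count, plus nine fundamental-frequency (F0)
landmarks for each of three *key syllables* — the first, the middle and the
end syllable of the call.  This module provides

* a deterministic synthesizer for frequency-modulated trills (the test bed
  for the extractor),
* energy-based syllable segmentation ("smallest vocal unit of continuous
  sound energy"),
* short-time spectral-peak F0 tracking, and
* the 29-parameter feature extractor.

F0 landmarks per key syllable: duration, start/end/min/max/mean F0, F0 range,
and the relative (0–1) time positions of the F0 minimum and maximum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile as _wavfile

logger = logging.getLogger("vocalkin.trill_signal")

#: Key-syllable suffixes: F = first, M = middle, E = end syllable.
KEY_SYLLABLES = ("F", "M", "E")

#: The nine per-syllable F0 landmark parameters.
SYLLABLE_PARAMS = (
    "duration",
    "startF0",
    "endF0",
    "minF0",
    "maxF0",
    "meanF0",
    "rangeF0",
    "timeminF0",
    "timemaxF0",
)

#: Canonical order of the 29 acoustic parameters of one trill.
FEATURE_COLUMNS: tuple[str, ...] = ("trill_duration_s", "n_syllables") + tuple(
    f"{p}_{k}" for k in KEY_SYLLABLES for p in SYLLABLE_PARAMS
)

assert len(FEATURE_COLUMNS) == 29

MAX_SYLLABLES = 30

# segmentation / tracking defaults (seconds, dB relative to waveform peak)
DEFAULT_ENERGY_THRESHOLD_DB = -40.0
DEFAULT_MIN_GAP_S = 0.005
DEFAULT_MIN_SYLLABLE_S = 0.005
DEFAULT_FRAME = 256
DEFAULT_HOP = 64


@dataclass(frozen=True)
class Waveform:
    """Mono audio buffer."""

    samples: np.ndarray
    sample_rate: float

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass(frozen=True)
class SyllableSegment:
    """One syllable: a span of continuous supra-threshold sound energy."""

    start_s: float
    end_s: float
    f0_track: np.ndarray = field(default=None, repr=False)  # (n, 2): time_s, f0_hz

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


class ExtractionError(ValueError):
    """Raised when a call cannot be measured (e.g. no syllables found)."""


# ---------------------------------------------------------------------------
# synthesis
# ---------------------------------------------------------------------------

def synthesize_trill(
    contours: Sequence[Sequence[tuple[float, float]]],
    gaps_s: float = 0.010,
    amplitude: float = 0.8,
    sample_rate: float = 96_000.0,
    durations_s: float | Sequence[float] = 0.05,
) -> Waveform:
    """Synthesize a trill as FM tones separated by silent gaps.

    Each contour is a sequence of ``(relative_time, f0_hz)`` breakpoints with
    relative time in [0, 1]; the instantaneous frequency is the piecewise
    linear interpolation of the breakpoints over the syllable duration.  The
    tone phase is the integral of the instantaneous frequency, so contours
    are rendered without phase discontinuities.

    Parameters
    ----------
    contours
        One breakpoint list per syllable (at least one syllable).
    gaps_s
        Silence between consecutive syllables, seconds.
    amplitude
        Peak amplitude of the sine carrier.
    sample_rate
        Samples per second; every F0 must stay below Nyquist.
    durations_s
        Scalar duration for all syllables or one duration per syllable.
    """
    if len(contours) == 0:
        raise ValueError("need at least one syllable contour")
    if np.isscalar(durations_s):
        durations = [float(durations_s)] * len(contours)
    else:
        durations = [float(d) for d in durations_s]
        if len(durations) != len(contours):
            raise ValueError("one duration per contour required")
    nyquist = sample_rate / 2.0
    pieces: list[np.ndarray] = []
    gap = np.zeros(int(round(gaps_s * sample_rate)))
    for i, (contour, dur) in enumerate(zip(contours, durations)):
        pts = np.asarray(contour, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
            raise ValueError("contour must be a list of (time, f0) breakpoints")
        if np.any(pts[:, 1] >= nyquist):
            raise ValueError(
                f"contour {i}: F0 {pts[:, 1].max():.0f} Hz >= Nyquist {nyquist:.0f} Hz"
            )
        n = max(int(round(dur * sample_rate)), 2)
        t_rel = np.linspace(0.0, 1.0, n)
        f_inst = np.interp(t_rel, pts[:, 0], pts[:, 1])
        phase = 2.0 * np.pi * np.cumsum(f_inst) / sample_rate
        pieces.append(amplitude * np.sin(phase))
        if i < len(contours) - 1:
            pieces.append(gap)
    return Waveform(samples=np.concatenate(pieces), sample_rate=sample_rate)


def linear_contour(f0_start: float, f0_end: float) -> list[tuple[float, float]]:
    """Breakpoints of a linear F0 sweep."""
    return [(0.0, f0_start), (1.0, f0_end)]


def vee_contour(f0_edge: float, f0_mid: float, at: float = 0.5) -> list[tuple[float, float]]:
    """Breakpoints of a V-shaped (or inverted-V) contour with apex at ``at``."""
    return [(0.0, f0_edge), (float(at), f0_mid), (1.0, f0_edge)]


# ---------------------------------------------------------------------------
# segmentation and F0 tracking
# ---------------------------------------------------------------------------

def _frame_energy_db(x: np.ndarray, frame: int, hop: int) -> tuple[np.ndarray, np.ndarray]:
    """Short-time RMS energy in dB relative to the loudest frame."""
    n_frames = max(1 + (len(x) - frame) // hop, 1)
    idx = np.arange(frame)[None, :] + hop * np.arange(n_frames)[:, None]
    idx = np.minimum(idx, len(x) - 1)
    frames = x[idx]
    rms = np.sqrt(np.mean(frames**2, axis=1))
    peak = rms.max()
    if peak <= 0:
        db = np.full(n_frames, -np.inf)
    else:
        with np.errstate(divide="ignore"):
            db = 20.0 * np.log10(rms / peak)
    centers = (hop * np.arange(n_frames) + frame / 2.0)
    return centers, db


def _track_f0(
    x: np.ndarray,
    sample_rate: float,
    start_s: float,
    end_s: float,
    frame: int = DEFAULT_FRAME,
    hop: int = DEFAULT_HOP,
) -> np.ndarray:
    """F0 track of one segment by windowed spectral peak picking.

    The dominant spectral peak per frame is refined by parabolic
    interpolation of the log-magnitude spectrum, giving sub-bin resolution
    for the synthetic FM tones this extractor targets.
    """
    i0, i1 = int(round(start_s * sample_rate)), int(round(end_s * sample_rate))
    seg = x[i0:i1]
    if len(seg) < frame:  # pad very short syllables to one analysis frame
        seg = np.pad(seg, (0, frame - len(seg)))
    n_frames = 1 + (len(seg) - frame) // hop
    win = np.hanning(frame)
    times = np.empty(n_frames)
    f0s = np.empty(n_frames)
    for k in range(n_frames):
        chunk = seg[k * hop : k * hop + frame] * win
        spec = np.abs(np.fft.rfft(chunk))
        p = int(np.argmax(spec))
        # parabolic refinement on log magnitude
        if 0 < p < len(spec) - 1 and spec[p] > 0:
            a, b, c = np.log(spec[p - 1] + 1e-300), np.log(spec[p] + 1e-300), np.log(
                spec[p + 1] + 1e-300
            )
            denom = a - 2 * b + c
            delta = 0.5 * (a - c) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        f0s[k] = (p + delta) * sample_rate / frame
        times[k] = start_s + (k * hop + frame / 2.0) / sample_rate
    return np.column_stack([times, f0s])


def segment_syllables(
    waveform: Waveform,
    energy_threshold_db: float = DEFAULT_ENERGY_THRESHOLD_DB,
    min_gap_s: float = DEFAULT_MIN_GAP_S,
    min_syllable_s: float = DEFAULT_MIN_SYLLABLE_S,
    frame: int = DEFAULT_FRAME,
    hop: int = DEFAULT_HOP,
) -> list[SyllableSegment]:
    """Segment a waveform into syllables by short-time energy.

    Frames whose RMS energy exceeds ``energy_threshold_db`` (relative to the
    loudest frame) are voiced; runs of voiced frames separated by gaps
    shorter than ``min_gap_s`` are merged, and runs shorter than
    ``min_syllable_s`` are discarded.  Returns an empty list for silence.
    """
    x = np.asarray(waveform.samples, dtype=float)
    if len(x) == 0:
        raise ValueError("empty waveform")
    sr = waveform.sample_rate
    centers, db = _frame_energy_db(x, frame, hop)
    voiced = db > energy_threshold_db
    if not voiced.any():
        return []
    # voiced runs as (start_frame, end_frame) inclusive
    edges = np.diff(voiced.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0])
    if voiced[0]:
        starts.insert(0, 0)
    if voiced[-1]:
        ends.append(len(voiced) - 1)
    runs = [[s, e] for s, e in zip(starts, ends)]
    # merge runs separated by short gaps
    merged: list[list[int]] = [runs[0]]
    for s, e in runs[1:]:
        gap_s = (centers[s] - centers[merged[-1][1]]) / sr
        if gap_s < min_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    segments = []
    half = frame / 2.0
    for s, e in merged:
        t0 = max((centers[s] - half) / sr, 0.0)
        t1 = min((centers[e] + half) / sr, len(x) / sr)
        if t1 - t0 < min_syllable_s:
            continue
        track = _track_f0(x, sr, t0, t1, frame=frame, hop=hop)
        segments.append(SyllableSegment(start_s=t0, end_s=t1, f0_track=track))
    return segments


# ---------------------------------------------------------------------------
# key-syllable selection and parameter extraction
# ---------------------------------------------------------------------------

def select_key_syllables(n_syllables: int) -> tuple[int, int, int]:
    """1-based indices of the first, middle and end syllables.

    The middle syllable is half of the total count, rounded up for odd
    counts (e.g. 19 syllables -> 9.5 -> syllable 10).
    """
    n = int(n_syllables)
    if n < 1:
        raise ValueError("a trill has at least one syllable")
    return 1, math.ceil(n / 2), n


def extract_syllable_params(segment: SyllableSegment) -> dict[str, float]:
    """The nine F0 landmark parameters of one key syllable.

    Relative time positions of the F0 extrema are normalised by the syllable
    duration to [0, 1]; ties take the first occurrence.  An untrackable
    segment (fewer than two F0 samples) yields NaNs.
    """
    track = segment.f0_track
    if track is None or len(track) < 2:
        logger.warning("untrackable segment at %.3fs: missing values", segment.start_s)
        return {p: float("nan") for p in SYLLABLE_PARAMS}
    f0 = track[:, 1]
    t = track[:, 0]
    dur = segment.duration_s
    i_min = int(np.argmin(f0))
    i_max = int(np.argmax(f0))
    rel = lambda i: float(np.clip((t[i] - segment.start_s) / dur, 0.0, 1.0))
    return {
        "duration": float(dur),
        "startF0": float(f0[0]),
        "endF0": float(f0[-1]),
        "minF0": float(f0[i_min]),
        "maxF0": float(f0[i_max]),
        "meanF0": float(f0.mean()),
        "rangeF0": float(f0[i_max] - f0[i_min]),
        "timeminF0": rel(i_min),
        "timemaxF0": rel(i_max),
    }


def extract_trill_features(
    waveform: Waveform,
    energy_threshold_db: float = DEFAULT_ENERGY_THRESHOLD_DB,
    min_gap_s: float = DEFAULT_MIN_GAP_S,
    min_syllable_s: float = DEFAULT_MIN_SYLLABLE_S,
) -> dict[str, float]:
    """Measure the 29 acoustic parameters of one trill.

    Whole-call measures are the trill duration (onset of the first to offset
    of the last syllable) and syllable count; the remaining 27 parameters are
    the nine landmarks of the first, middle and end syllables.  A call
    without detectable syllables is rejected.
    """
    segments = segment_syllables(
        waveform, energy_threshold_db, min_gap_s, min_syllable_s
    )
    if not segments:
        raise ExtractionError("call rejected: no supra-threshold syllables")
    n = len(segments)
    first, middle, end = select_key_syllables(n)
    features: dict[str, float] = {
        "trill_duration_s": segments[-1].end_s - segments[0].start_s,
        "n_syllables": float(n),
    }
    for key, idx in zip(KEY_SYLLABLES, (first, middle, end)):
        params = extract_syllable_params(segments[idx - 1])
        for p, v in params.items():
            features[f"{p}_{key}"] = v
    return features


# ---------------------------------------------------------------------------
# WAV and CSV I/O
# ---------------------------------------------------------------------------

def read_wav(path) -> Waveform:
    """Read a mono RIFF WAV file (PCM16/PCM32 or float)."""
    sr, data = _wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        raise ValueError("only mono WAV files are supported")
    if data.dtype.kind == "i":
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    return Waveform(samples=data.astype(float), sample_rate=float(sr))


def write_wav(path, waveform: Waveform) -> None:
    _wavfile.write(path, int(waveform.sample_rate), waveform.samples.astype(np.float32))


def features_to_frame(rows: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Assemble per-call feature dicts (keyed by call id) into the canonical table."""
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "call_id"
    return df.reindex(columns=list(FEATURE_COLUMNS))
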