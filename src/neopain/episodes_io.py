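"""Multimodal episode data model, on-disk bundles, and signal preprocessing.

An *episode* is one synchronized multimodal clip from a NICU bedside:

* mono audio at 16 kHz (cry vocalizations), samples in [-1, 1];
* physiological time series at 100 Hz after preprocessing
  (heart rate [bpm], SpO2 [%], respiratory rate [breaths/min],
  optional mean arterial pressure [mmHg]);
* four facial action channels at 30 fps in [0, 1] (brow lowering, eye
  squeeze, nasolabial furrow, mouth opening intensity) standing in for a
  raw-video facial pipeline;
* context metadata (gestational age, postnatal age, weight, ventilation
  flag, optional labels).

On disk an episode is a directory: ``meta.json`` plus any of ``audio.wav``,
``physio.csv``, ``facial.csv`` and an optional ``physio_baseline.csv``
holding up to two minutes of physiology preceding the clip (the baseline
window that the physiological concept detectors compare against).

Time is in seconds, windows are half-open [t, t+10), and all series are
0-based on a shared clip timeline.
"""

from __future__ import annotations

import io
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pywt
from scipy.io import wavfile
from scipy.signal import get_window

from .errors import (EmptyEpisodeError, FormatError, InsufficientDataError,
                     ValidationError)

logger = logging.getLogger("neopain")

AUDIO_RATE = 16_000
PHYSIO_RATE = 100
FACIAL_FPS = 30
CLIP_SECONDS = 10.0
CLIP_HOP_SECONDS = 5.0
BASELINE_SECONDS = 120.0

# mel-spectrogram contract: 2048-point FFT, hop 1024 (50% overlap),
# 128 bands, no center padding, log floor 1e-10
N_FFT = 2048
HOP = 1024
N_MELS = 128
LOG_FLOOR = 1e-10

GA_RANGE = (24.0, 44.0)
POSTNATAL_RANGE = (0.0, 35.0)

PHYSIO_COLUMNS = ("hr", "spo2", "rr")  # 'map' is optional


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ContextMeta:
    """Context metadata for one infant episode."""

    infant_id: str
    site_id: str
    ga_weeks: float
    postnatal_days: float
    weight_g: float
    ventilated: bool = False
    pain_label: int | None = None
    concept_labels: list[int] | None = None

    def __post_init__(self) -> None:
        if not (GA_RANGE[0] <= self.ga_weeks <= GA_RANGE[1]):
            raise ValidationError("ga_weeks",
                                  f"{self.ga_weeks} outside [{GA_RANGE[0]}, {GA_RANGE[1]}]")
        if not (POSTNATAL_RANGE[0] <= self.postnatal_days <= POSTNATAL_RANGE[1]):
            raise ValidationError("postnatal_days",
                                  f"{self.postnatal_days} outside {POSTNATAL_RANGE}")
        if self.weight_g <= 0:
            raise ValidationError("weight_g", "must be positive")
        if self.pain_label is not None and self.pain_label not in (0, 1, 2, 3):
            raise ValidationError("pain_label", f"{self.pain_label} not in {{0,1,2,3}}")
        if self.concept_labels is not None and len(self.concept_labels) != 12:
            raise ValidationError("concept_labels", "needs exactly 12 entries")

    def to_dict(self) -> dict:
        return {
            "infant_id": self.infant_id,
            "site_id": self.site_id,
            "ga_weeks": self.ga_weeks,
            "postnatal_days": self.postnatal_days,
            "weight_g": self.weight_g,
            "ventilated": self.ventilated,
            "pain_label": self.pain_label,
            "concept_labels": self.concept_labels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ContextMeta":
        return cls(**{k: d.get(k) for k in (
            "infant_id", "site_id", "ga_weeks", "postnatal_days", "weight_g",
            "ventilated", "pain_label", "concept_labels")})


@dataclass
class Episode:
    """One synchronized multimodal clip with metadata and modality mask.

    ``modality_mask`` is ordered (video/facial, audio, physio).
    """

    meta: ContextMeta
    duration_s: float
    audio: np.ndarray | None = None
    physio: pd.DataFrame | None = None
    facial: np.ndarray | None = None
    physio_baseline: pd.DataFrame | None = None
    modality_mask: tuple[bool, bool, bool] = field(init=False)

    def __post_init__(self) -> None:
        self.modality_mask = (self.facial is not None,
                              self.audio is not None,
                              self.physio is not None)
        if not any(self.modality_mask):
            raise EmptyEpisodeError("episode has no modality present")
        # present streams must span the same [0, duration) window (+-50 ms)
        tol = 0.05
        if self.audio is not None and abs(
                len(self.audio) / AUDIO_RATE - self.duration_s) > tol:
            raise ValidationError("audio", "does not span the episode window")
        if self.facial is not None and abs(
                len(self.facial) / FACIAL_FPS - self.duration_s) > tol:
            raise ValidationError("facial", "does not span the episode window")
        if self.physio is not None and len(self.physio) and abs(
                len(self.physio) / PHYSIO_RATE - self.duration_s) > tol:
            raise ValidationError("physio", "does not span the episode window")


# ---------------------------------------------------------------------------
# bundle I/O
# ---------------------------------------------------------------------------

def write_bundle(episode: Episode, path: str | Path) -> Path:
    """Write an episode to a bundle directory; returns the path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = episode.meta.to_dict()
    meta["duration_s"] = episode.duration_s
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    if episode.audio is not None:
        wavfile.write(path / "audio.wav", AUDIO_RATE,
                      episode.audio.astype(np.float32))
    if episode.physio is not None:
        episode.physio.to_csv(path / "physio.csv", index=False)
    if episode.physio_baseline is not None:
        episode.physio_baseline.to_csv(path / "physio_baseline.csv", index=False)
    if episode.facial is not None:
        df = pd.DataFrame(episode.facial, columns=["c1", "c2", "c3", "c4"])
        df.insert(0, "time", np.arange(len(df)) / FACIAL_FPS)
        df.to_csv(path / "facial.csv", index=False)
    return path


def read_bundle(path: str | Path) -> Episode:
    """Read a bundle directory back into an :class:`Episode`.

    Absent signal files clear the matching modality-mask bit; a bundle with
    no signal file at all raises :class:`EmptyEpisodeError`.
    """
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FormatError(f"missing meta.json in {path}")
    try:
        raw = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"meta.json is not valid JSON: {exc}") from exc
    duration = float(raw.pop("duration_s", CLIP_SECONDS))
    meta = ContextMeta.from_dict(raw)

    audio = physio = facial = baseline = None
    if (path / "audio.wav").exists():
        rate, data = wavfile.read(path / "audio.wav")
        if rate != AUDIO_RATE:
            raise FormatError(f"audio.wav at {rate} Hz, expected {AUDIO_RATE}")
        if data.dtype == np.int16:
            data = data.astype(np.float64) / 32768.0
        audio = np.asarray(data, dtype=np.float64)
    if (path / "physio.csv").exists():
        physio = pd.read_csv(path / "physio.csv")
    if (path / "physio_baseline.csv").exists():
        baseline = pd.read_csv(path / "physio_baseline.csv")
    if (path / "facial.csv").exists():
        df = pd.read_csv(path / "facial.csv")
        facial = df[["c1", "c2", "c3", "c4"]].to_numpy(dtype=np.float64)
    if audio is None and physio is None and facial is None:
        raise EmptyEpisodeError(f"no signal file present in {path}")
    return Episode(meta=meta, duration_s=duration, audio=audio,
                   physio=physio, facial=facial, physio_baseline=baseline)


# ---------------------------------------------------------------------------
# physiological preprocessing
# ---------------------------------------------------------------------------

def _denoise_channel(x: np.ndarray) -> np.ndarray:
    """Wavelet denoising: Symlet-4, level-5 decomposition, soft universal
    threshold estimated from the finest detail band (MAD / 0.6745)."""
    n = len(x)
    if n < 8:
        return x.copy()
    level = min(5, pywt.dwt_max_level(n, pywt.Wavelet("sym4").dec_len))
    if level < 1:
        return x.copy()
    coeffs = pywt.wavedec(x, "sym4", level=level, mode="symmetric")
    sigma = np.median(np.abs(coeffs[-1])) / 0.6745 if len(coeffs[-1]) else 0.0
    thr = sigma * math.sqrt(2.0 * math.log(max(n, 2)))
    coeffs = [coeffs[0]] + [pywt.threshold(c, thr, mode="soft") for c in coeffs[1:]]
    return pywt.waverec(coeffs, "sym4", mode="symmetric")[:n]


def preprocess_physio(raw_series: pd.DataFrame,
                      raw_rate: float | None = None,
                      max_gap_s: float = 2.0) -> pd.DataFrame:
    """Denoise and resample a raw physiological table to a regular 100 Hz grid.

    Parameters
    ----------
    raw_series
        Columns ``time`` (seconds, strictly increasing) plus any of
        ``hr``, ``spo2``, ``rr``, ``map``.
    raw_rate
        Nominal input rate; only used to sanity-check gap detection. May be
        ``None`` (inferred from the median time step).
    max_gap_s
        Gaps shorter than this are linearly interpolated; gaps at least this
        long are marked missing (NaN) rather than silently filled.

    Returns
    -------
    DataFrame with ``time`` on the exact ``k/100`` grid and the input
    channels; missing segments are NaN.
    """
    if len(raw_series) < 2:
        raise InsufficientDataError("preprocess_physio needs at least 2 samples")
    t = raw_series["time"].to_numpy(dtype=np.float64)
    if np.any(np.diff(t) <= 0):
        raise ValidationError("time", "timestamps must be strictly increasing")
    dt = np.diff(t)
    nominal = 1.0 / raw_rate if raw_rate else float(np.median(dt))

    # output grid: k/100 s exactly, covering [t0, t_end]
    k0 = int(math.ceil(round(t[0] * PHYSIO_RATE, 9)))
    k1 = int(math.floor(round(t[-1] * PHYSIO_RATE, 9)))
    grid = np.arange(k0, k1 + 1, dtype=np.float64) / PHYSIO_RATE

    # long gaps in the raw record
    gap_starts = t[:-1][dt >= max_gap_s]
    gap_ends = t[1:][dt >= max_gap_s]

    out = {"time": grid}
    channels = [c for c in raw_series.columns if c != "time"]
    for col in channels:
        x = raw_series[col].to_numpy(dtype=np.float64)
        valid = ~np.isnan(x)
        if valid.sum() < 2:
            out[col] = np.full_like(grid, np.nan)
            continue
        xd = x.copy()
        # denoise contiguous valid stretches
        xd[valid] = _segmentwise_denoise(t[valid], xd[valid], nominal, max_gap_s)
        y = np.interp(grid, t[valid], xd[valid])
        # blank out grid points inside long raw gaps (never silently filled)
        for gs, ge in zip(gap_starts, gap_ends):
            y[(grid > gs) & (grid < ge)] = np.nan
        # NaN runs in the raw channel longer than max_gap_s are also gaps
        for gs, ge in _nan_gaps(t, x, max_gap_s):
            y[(grid > gs) & (grid < ge)] = np.nan
        out[col] = y
    return pd.DataFrame(out)


def _segmentwise_denoise(t: np.ndarray, x: np.ndarray, nominal_dt: float,
                         max_gap_s: float) -> np.ndarray:
    breaks = np.where(np.diff(t) >= max_gap_s)[0] + 1
    pieces = []
    for seg in np.split(np.arange(len(x)), breaks):
        pieces.append(_denoise_channel(x[seg]))
    return np.concatenate(pieces)


def _nan_gaps(t: np.ndarray, x: np.ndarray, max_gap_s: float):
    isnan = np.isnan(x)
    gaps = []
    i = 0
    n = len(x)
    while i < n:
        if isnan[i]:
            j = i
            while j < n and isnan[j]:
                j += 1
            lo = t[i - 1] if i > 0 else t[0]
            hi = t[j] if j < n else t[-1]
            if hi - lo >= max_gap_s:
                gaps.append((lo, hi))
            i = j
        else:
            i += 1
    return gaps


# ---------------------------------------------------------------------------
# audio preprocessing
# ---------------------------------------------------------------------------

def _mel_filterbank(n_mels: int = N_MELS, n_fft: int = N_FFT,
                    rate: int = AUDIO_RATE) -> np.ndarray:
    """Triangular mel filterbank (HTK mel scale), shape (n_mels, n_fft//2+1)."""
    def to_mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)

    def from_mel(m):
        return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)

    fmin, fmax = 0.0, rate / 2.0
    mel_pts = np.linspace(to_mel(fmin), to_mel(fmax), n_mels + 2)
    hz_pts = from_mel(mel_pts)
    bins = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    fb = np.zeros((n_mels, len(bins)))
    for m in range(n_mels):
        lo, ctr, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (bins - lo) / max(ctr - lo, 1e-12)
        down = (hi - bins) / max(hi - ctr, 1e-12)
        fb[m] = np.maximum(0.0, np.minimum(up, down))
    return fb


def mel_band_centers(n_mels: int = N_MELS, rate: int = AUDIO_RATE) -> np.ndarray:
    """Center frequencies (Hz) of the mel bands."""
    mel = 2595.0 * np.log10(1.0 + np.array([0.0, rate / 2.0]) / 700.0)
    pts = np.linspace(mel[0], mel[1], n_mels + 2)
    return 700.0 * (10.0 ** (pts[1:-1] / 2595.0) - 1.0)


def frame_signal(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    """Frame a 1-D signal into (n_frames, frame_len) without padding."""
    if len(x) < frame_len:
        raise InsufficientDataError(
            f"signal of {len(x)} samples shorter than frame {frame_len}")
    n_frames = 1 + (len(x) - frame_len) // hop
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def mel_spectrogram(waveform: np.ndarray) -> np.ndarray:
    """Log-power mel spectrogram, shape (128, 1 + floor((n - 2048)/1024)).

    2048-point FFT, hop 1024 (50% overlap), Hann window, no center padding,
    log floor 1e-10.
    """
    waveform = np.asarray(waveform, dtype=np.float64)
    if len(waveform) < N_FFT:
        raise InsufficientDataError(
            f"waveform of {len(waveform)} samples < FFT size {N_FFT}")
    frames = frame_signal(waveform, N_FFT, HOP)
    window = get_window("hann", N_FFT, fftbins=True)
    spec = np.abs(np.fft.rfft(frames * window, axis=1)) ** 2
    mel = _mel_filterbank() @ spec.T
    return np.log(np.maximum(mel, LOG_FLOOR))


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_clips(episode: Episode) -> list[Episode]:
    """Cut an episode into 10-second clips with 50% overlap.

    Clips start at 0, 5, 10, ... s on the shared timeline; the trailing
    sub-10-s residue is dropped. Episodes shorter than 10 s yield zero clips
    and a logged warning. Each clip inherits metadata and modality mask, and
    receives as ``physio_baseline`` the (up to) two minutes of physiology
    preceding its start, assembled from the parent's baseline and stream.
    """
    if episode.duration_s < CLIP_SECONDS:
        logger.warning("episode of %.1f s shorter than %.0f s clip; no clips",
                       episode.duration_s, CLIP_SECONDS)
        return []
    n_clips = 1 + int(math.floor(
        round((episode.duration_s - CLIP_SECONDS) / CLIP_HOP_SECONDS, 9)))
    clips = []
    for k in range(n_clips):
        start = k * CLIP_HOP_SECONDS
        end = start + CLIP_SECONDS
        audio = physio = facial = baseline = None
        if episode.audio is not None:
            audio = episode.audio[int(start * AUDIO_RATE):int(end * AUDIO_RATE)].copy()
        if episode.facial is not None:
            facial = episode.facial[int(start * FACIAL_FPS):int(end * FACIAL_FPS)].copy()
        if episode.physio is not None:
            t = episode.physio["time"].to_numpy()
            in_clip = (t >= start - 1e-9) & (t < end - 1e-9)
            physio = episode.physio.loc[in_clip].copy()
            physio["time"] = physio["time"] - start
            physio.reset_index(drop=True, inplace=True)
            baseline = _clip_baseline(episode, start)
        clips.append(Episode(meta=replace(episode.meta),
                             duration_s=CLIP_SECONDS, audio=audio,
                             physio=physio, facial=facial,
                             physio_baseline=baseline))
    return clips


def _clip_baseline(episode: Episode, start: float) -> pd.DataFrame | None:
    parts = []
    if episode.physio_baseline is not None:
        parts.append(episode.physio_baseline)
    t = episode.physio["time"].to_numpy()
    before = episode.physio.loc[t < start - 1e-9]
    if len(before):
        parts.append(before)
    if not parts:
        return None
    base = pd.concat(parts, ignore_index=True)
    # keep the trailing 2-minute window
    keep = len(base) - int(BASELINE_SECONDS * PHYSIO_RATE)
    if keep > 0:
        base = base.iloc[keep:].reset_index(drop=True)
    return base.copy()
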