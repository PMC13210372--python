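"""The 12-concept clinical vocabulary and its detectors.

Pain evidence is represented as 12 interpretable concepts grounded in the
NIPS / PIPP-R / COMFORT-B observational scales:

* facial (C1-C4): brow lowering, eye squeeze, nasolabial furrow, mouth
  opening — detected from the 4 facial action channels;
* vocal (C5-C8): cry intensity, fundamental-frequency elevation, harmonic
  distortion, silence periods — detected from the 16 kHz waveform;
* physiological (C9-C12): HR acceleration, O2 desaturation, respiratory
  irregularity, blood-pressure elevation — detected from the 100 Hz series
  against a 2-minute baseline window.

Each concept has a binary firing rule in its native units (see
``data/thresholds.yaml``) and a graded activation in [0, 1]: the logistic of
the normalized margin to threshold, with scale 10% of the threshold. For
every single-threshold concept this makes ``fired`` equivalent to
``activation > 0.5`` (strict), so downstream layers can reason on one scale.
Facial thresholds are stratified by gestational age (GA); all comparisons
are strict inequalities.

Alongside the rule-based detectors, :func:`concept_heads_forward` exposes
the learned concept bottleneck: per-modality linear heads mapping each
128-dim encoder embedding to 12 sigmoid activations (a 3x12 concept
matrix), with the canonical 12-vector taken from each concept's source
modality row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .episodes_io import AUDIO_RATE, PHYSIO_RATE, Episode, frame_signal
from .errors import InsufficientDataError, ShapeError, ValidationError

logger = logging.getLogger("neopain")

CONCEPT_IDS = tuple(f"C{i}" for i in range(1, 13))
FACIAL = CONCEPT_IDS[0:4]
VOCAL = CONCEPT_IDS[4:8]
PHYSIO = CONCEPT_IDS[8:12]
#: source modality index per concept (0 = video/facial, 1 = audio, 2 = physio)
CONCEPT_MODALITY = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2])

GA_STRATA = ("<28", "28-32", "32-37", ">=37")

VOICE_FLOOR = 0.05          # frame-RMS floor defining voiced activity
RMS_FRAME_S = 0.050         # C5 analysis frame
F0_FRAME_S = 0.025          # pitch/HNR analysis frame
F0_MIN_HZ, F0_MAX_HZ = 150.0, 1000.0
HNR_CLIP = 20.0


def ga_stratum(ga_weeks: float) -> str:
    """Map gestational age to its stratum; boundaries are half-open."""
    if not (24.0 <= ga_weeks <= 44.0):
        raise ValidationError("ga_weeks", f"{ga_weeks} outside [24, 44]")
    if ga_weeks < 28.0:
        return "<28"
    if ga_weeks < 32.0:
        return "28-32"
    if ga_weeks < 37.0:
        return "32-37"
    return ">=37"


# ---------------------------------------------------------------------------
# threshold table
# ---------------------------------------------------------------------------

@dataclass
class ThresholdTable:
    """Per-concept clinical thresholds with GA stratification for C1-C4."""

    raw: dict

    @classmethod
    def default(cls) -> "ThresholdTable":
        text = resources.files("neopain.data").joinpath("thresholds.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def from_yaml(cls, path) -> "ThresholdTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_dict(cls, raw: dict) -> "ThresholdTable":
        table = cls(raw=raw)
        table.validate()
        return table

    def validate(self) -> None:
        concepts = self.raw["concepts"]
        for cid in CONCEPT_IDS:
            if cid not in concepts:
                raise ValidationError(cid, "missing from threshold table")
        for cid in FACIAL:
            spec = concepts[cid]
            default = spec["default"]
            vals = [spec["by_stratum"][s] for s in GA_STRATA]
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise ValidationError(
                    cid, "facial thresholds must be non-decreasing in GA stratum")
            if any(abs(v - default) > 0.15 + 1e-12 for v in vals):
                raise ValidationError(cid, "stratum value further than 0.15 from default")

    def concept(self, cid: str) -> dict:
        return self.raw["concepts"][cid]

    @property
    def flat_defaults(self) -> dict:
        return self.raw.get("flat_defaults", {"brow": 0.7, "cry": 0.6, "hr": 0.5})


def resolve_thresholds(table: ThresholdTable, ga_weeks: float) -> dict:
    """Resolve the GA-dependent thresholds for one infant.

    Returns a mapping concept id -> parameter dict; facial concepts get the
    stratum value under key ``threshold``, C6 gets the preterm/term F0 cut
    (term means GA >= 37 w), the rest carry their flat parameters.
    """
    stratum = ga_stratum(ga_weeks)
    out: dict[str, dict] = {}
    for cid in CONCEPT_IDS:
        spec = dict(table.concept(cid))
        if cid in FACIAL:
            spec["threshold"] = spec["by_stratum"][stratum]
        if cid == "C6":
            spec["threshold"] = (spec["f0_term_hz"] if stratum == ">=37"
                                 else spec["f0_preterm_hz"])
        out[cid] = spec
    out["_stratum"] = {"stratum": stratum, "ga_weeks": ga_weeks}
    return out


def _logistic_margin(value: float, threshold: float, scale: float | None = None) -> float:
    """Graded activation: sigmoid of the normalized margin to threshold."""
    if scale is None:
        scale = 0.1 * abs(threshold)
    scale = max(scale, 1e-9)
    return float(1.0 / (1.0 + np.exp(-np.clip((value - threshold) / scale, -60, 60))))


# ---------------------------------------------------------------------------
# concept vector
# ---------------------------------------------------------------------------

@dataclass
class ConceptVector:
    """12 graded activations with availability and binary firing flags."""

    activations: np.ndarray
    available: np.ndarray
    fired: np.ndarray
    provenance: list[str] = field(default_factory=lambda: ["rule-based"] * 12)

    def __post_init__(self) -> None:
        self.activations = np.asarray(self.activations, dtype=np.float64)
        self.available = np.asarray(self.available, dtype=bool)
        self.fired = np.asarray(self.fired, dtype=bool)
        if self.activations.shape != (12,):
            raise ShapeError(f"activations shape {self.activations.shape} != (12,)")
        if np.any(self.activations < 0) or np.any(self.activations > 1):
            raise ValidationError("activations", "must lie in [0, 1]")
        # an unavailable concept is never reported as fired
        self.fired = self.fired & self.available

    def copy(self) -> "ConceptVector":
        return ConceptVector(self.activations.copy(), self.available.copy(),
                             self.fired.copy(), list(self.provenance))


# ---------------------------------------------------------------------------
# vocal concepts (C5-C8)
# ---------------------------------------------------------------------------

def _voiced_runs(voiced: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, stop) frame index pairs."""
    runs = []
    i = 0
    n = len(voiced)
    while i < n:
        if voiced[i]:
            j = i
            while j < n and voiced[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _frame_f0_and_harmonicity(frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame F0 (Hz) and normalized autocorrelation peak via FFT autocorr."""
    n = frames.shape[1]
    x = frames - frames.mean(axis=1, keepdims=True)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft, axis=1)
    ac = np.fft.irfft(np.abs(spec) ** 2, axis=1)[:, :n]
    ac0 = np.maximum(ac[:, 0], 1e-12)
    lag_lo = int(np.floor(AUDIO_RATE / F0_MAX_HZ))
    lag_hi = int(np.ceil(AUDIO_RATE / F0_MIN_HZ))
    lag_hi = min(lag_hi, n - 2)
    seg = ac[:, lag_lo:lag_hi + 1]
    peak = np.argmax(seg, axis=1) + lag_lo
    # parabolic refinement of the autocorrelation peak
    idx = np.arange(len(frames))
    y0, y1, y2 = ac[idx, peak - 1], ac[idx, peak], ac[idx, peak + 1]
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / np.where(
        np.abs(denom) > 1e-12, denom, 1.0), 0.0)
    lag = peak + np.clip(shift, -0.5, 0.5)
    f0 = AUDIO_RATE / lag
    r = np.clip(y1 / ac0, 0.0, 0.999)
    return f0, r


def detect_vocal_concepts(waveform: np.ndarray | None, ga_weeks: float,
                          thresholds: dict) -> dict:
    """Detect cry intensity, F0 elevation, harmonic distortion and silence
    periods (C5-C8) from a 16 kHz mono waveform.

    Returns a dict keyed by concept id with ``value``, ``activation``,
    ``fired`` and ``available`` entries.
    """
    out = {cid: {"value": np.nan, "activation": 0.0, "fired": False,
                 "available": waveform is not None} for cid in VOCAL}
    if waveform is None:
        return out
    if len(waveform) < AUDIO_RATE:
        raise InsufficientDataError("vocal detection needs at least 1 s of audio")

    frame_len = int(RMS_FRAME_S * AUDIO_RATE)
    frames = frame_signal(np.asarray(waveform, dtype=np.float64),
                          frame_len, frame_len)
    rms = np.sqrt((frames ** 2).mean(axis=1))
    voiced = rms > VOICE_FLOOR
    runs = _voiced_runs(voiced)
    run_ms = [(b - a) * RMS_FRAME_S * 1000.0 for a, b in runs]

    th5 = thresholds["C5"]
    eligible = [(a, b) for (a, b), ms in zip(runs, run_ms) if ms > th5["sustain_ms"]]
    c5_value = max((float(rms[a:b].mean()) for a, b in eligible), default=0.0)
    out["C5"].update(value=c5_value,
                     activation=_logistic_margin(c5_value, th5["rms"]),
                     fired=c5_value > th5["rms"])

    # pitch / harmonicity analysis on 25-ms frames inside voiced regions
    f_len = int(F0_FRAME_S * AUDIO_RATE)
    pframes = frame_signal(np.asarray(waveform, dtype=np.float64), f_len, f_len)
    prms = np.sqrt((pframes ** 2).mean(axis=1))
    pvoiced = prms > VOICE_FLOOR
    th6, th7 = thresholds["C6"], thresholds["C7"]
    if pvoiced.any():
        f0s, rs = _frame_f0_and_harmonicity(pframes[pvoiced])
        f0 = float(np.median(f0s))
        r = float(np.median(rs))
        hnr = min(r / max(1.0 - r, 1e-9), HNR_CLIP)
        irregularity = _spectral_irregularity(pframes, pvoiced)
        out["C6"].update(value=f0,
                         activation=_logistic_margin(f0, th6["threshold"]),
                         fired=f0 > th6["threshold"])
        act7 = min(_logistic_margin(th7["hnr_max"] - hnr, 0.0, 0.1 * th7["hnr_max"]),
                   _logistic_margin(irregularity, th7["irregularity_min"]))
        out["C7"].update(value=hnr, activation=act7,
                         fired=(hnr < th7["hnr_max"])
                         and (irregularity > th7["irregularity_min"]))
    # C8: pause gaps between vocalization runs ("during cry episodes")
    th8 = thresholds["C8"]
    if len(runs) >= 2:
        gaps_ms = [(runs[k + 1][0] - runs[k][1]) * RMS_FRAME_S * 1000.0
                   for k in range(len(runs) - 1)]
        gap = float(max(gaps_ms))
        out["C8"].update(value=gap,
                         activation=_logistic_margin(gap, th8["pause_ms"]),
                         fired=gap > th8["pause_ms"])
    return out


def _spectral_irregularity(pframes: np.ndarray, pvoiced: np.ndarray) -> float:
    """Mean normalized frame-to-frame spectral (power) flux over voiced frames."""
    pairs = np.where(pvoiced[1:] & pvoiced[:-1])[0]
    if len(pairs) == 0:
        return 0.0
    spec = np.abs(np.fft.rfft(pframes, axis=1)) ** 2
    a, b = spec[pairs], spec[pairs + 1]
    num = np.abs(b - a).sum(axis=1)
    den = a.sum(axis=1) + b.sum(axis=1) + 1e-12
    return float((num / den).mean())


# ---------------------------------------------------------------------------
# physiological concepts (C9-C12)
# ---------------------------------------------------------------------------

def detect_physio_concepts(physio: pd.DataFrame | None, thresholds: dict,
                           baseline: pd.DataFrame | None = None) -> dict:
    """Detect HR acceleration, desaturation, respiratory irregularity and
    BP elevation (C9-C12) on a 100 Hz clip against its 2-min baseline.

    If no baseline window is supplied, the first half of the clip serves as
    a degraded baseline (logged). C12 is unavailable without a MAP column.
    SpO2 drops are in percentage points.
    """
    out = {cid: {"value": np.nan, "activation": 0.0, "fired": False,
                 "available": physio is not None} for cid in PHYSIO}
    if physio is None:
        return out
    if baseline is None or not len(baseline):
        half = max(1, len(physio) // 2)
        baseline = physio.iloc[:half]
        logger.warning("no physio baseline window; using first half of clip")
    history_s = (len(baseline) + len(physio)) / PHYSIO_RATE
    if history_s < 30.0:
        logger.warning("only %.1f s of physio history; degraded baseline", history_s)

    th9 = thresholds["C9"]
    base_hr = float(np.nanmean(baseline["hr"]))
    clip_hr = float(np.nanmean(physio["hr"]))
    pct = (clip_hr - base_hr) / max(base_hr, 1e-9) * 100.0
    act9 = max(_logistic_margin(pct, th9["pct_increase"]),
               _logistic_margin(clip_hr, th9["abs_bpm"], 5.0))
    out["C9"].update(value=pct, activation=act9,
                     fired=(pct > th9["pct_increase"]) or (clip_hr > th9["abs_bpm"]))

    th10 = thresholds["C10"]
    window = int(th10["window_s"] * PHYSIO_RATE)
    tail = baseline.iloc[-window:] if len(baseline) else baseline
    spo2 = pd.concat([tail["spo2"], physio["spo2"]], ignore_index=True)
    # desaturation is a sustained event: evaluate on a 0.5-s smoothed trace
    # so sample-level sensor noise does not inflate the drop statistic
    smooth = spo2.rolling(int(0.5 * PHYSIO_RATE), min_periods=1, center=True).mean()
    run_max = smooth.rolling(window, min_periods=1).max()
    drop = float((run_max - smooth).max())
    spo2_min = float(np.nanmin(smooth.iloc[len(tail):]))
    act10 = max(_logistic_margin(drop, th10["drop_points"]),
                _logistic_margin(th10["abs_pct"] - spo2_min, 0.0, 1.0))
    out["C10"].update(value=drop, activation=act10,
                      fired=(drop > th10["drop_points"]) or (spo2_min < th10["abs_pct"]))

    th11 = thresholds["C11"]
    need = int(th11["window_s"] * PHYSIO_RATE)
    rr = pd.concat([baseline["rr"], physio["rr"]], ignore_index=True).to_numpy()
    rr = rr[-need:]
    rr = rr[~np.isnan(rr)]
    if len(rr) >= 2 and np.nanmean(rr) > 0:
        cv = float(np.std(rr) / np.mean(rr))
        out["C11"].update(value=cv, activation=_logistic_margin(cv, th11["cv"]),
                          fired=cv > th11["cv"])

    th12 = thresholds["C12"]
    has_map = ("map" in physio.columns and not physio["map"].isna().all()
               and "map" in baseline.columns and not baseline["map"].isna().all())
    if has_map:
        delta = float(np.nanmean(physio["map"]) - np.nanmean(baseline["map"]))
        out["C12"].update(value=delta,
                          activation=_logistic_margin(delta, th12["delta_mmhg"], 1.0),
                          fired=delta > th12["delta_mmhg"])
    else:
        out["C12"]["available"] = False
    return out


# ---------------------------------------------------------------------------
# facial concepts (C1-C4)
# ---------------------------------------------------------------------------

def detect_facial_concepts(facial: np.ndarray | None, ga_weeks: float,
                           thresholds: dict) -> dict:
    """Facial action concepts: activation is the 90th-percentile channel
    value over the clip; firing compares it to the GA-resolved threshold."""
    out = {cid: {"value": np.nan, "activation": 0.0, "fired": False,
                 "available": facial is not None} for cid in FACIAL}
    if facial is None:
        return out
    facial = np.asarray(facial, dtype=np.float64)
    if facial.ndim != 2 or facial.shape[1] != 4:
        raise ShapeError(f"facial channels shape {facial.shape}, expected (n, 4)")
    for k, cid in enumerate(FACIAL):
        tau = thresholds[cid]["threshold"]
        act = float(np.clip(np.percentile(facial[:, k], 90.0), 0.0, 1.0))
        out[cid].update(value=act, activation=act, fired=act > tau)
    return out


# ---------------------------------------------------------------------------
# whole-episode detection
# ---------------------------------------------------------------------------

def detect_concepts(episode: Episode,
                    table: ThresholdTable | None = None) -> ConceptVector:
    """Run all rule-based detectors on a 10-s clip, honoring the modality
    mask, and assemble the canonical :class:`ConceptVector`."""
    table = table or ThresholdTable.default()
    resolved = resolve_thresholds(table, episode.meta.ga_weeks)
    video_ok, audio_ok, physio_ok = episode.modality_mask
    res = {}
    res.update(detect_facial_concepts(episode.facial if video_ok else None,
                                      episode.meta.ga_weeks, resolved))
    res.update(detect_vocal_concepts(episode.audio if audio_ok else None,
                                     episode.meta.ga_weeks, resolved))
    res.update(detect_physio_concepts(episode.physio if physio_ok else None,
                                      resolved, episode.physio_baseline))
    acts = np.array([res[cid]["activation"] for cid in CONCEPT_IDS])
    avail = np.array([res[cid]["available"] for cid in CONCEPT_IDS])
    fired = np.array([res[cid]["fired"] for cid in CONCEPT_IDS])
    return ConceptVector(acts, avail, fired)


# ---------------------------------------------------------------------------
# learned concept heads (concept bottleneck)
# ---------------------------------------------------------------------------

def concept_heads_forward(h_v, h_a, h_p, head_params,
                          modality_mask: tuple[bool, bool, bool] = (True, True, True)):
    """Project the three 128-dim embeddings to the 3x12 concept matrix
    (sigmoid of per-modality linear heads) and select the canonical
    12-vector from each concept's source modality row.

    Returns ``(concept_matrix, canonical, available)`` where
    ``concept_matrix`` is an autodiff Tensor of shape (3, 12), ``canonical``
    a (12,) Tensor, and ``available`` the per-concept availability implied
    by the modality mask.
    """
    from ._autodiff import Tensor, stack

    embs = []
    for name, h in (("h_v", h_v), ("h_a", h_a), ("h_p", h_p)):
        arr = h if isinstance(h, Tensor) else Tensor(np.asarray(h, dtype=np.float64))
        if arr.shape != (128,):
            raise ShapeError(f"{name} has shape {arr.shape}, expected (128,)")
        embs.append(arr)
    rows = [head(emb).sigmoid() for head, emb in zip(head_params.heads, embs)]
    matrix = stack(rows, axis=0)            # (3, 12)
    sel = CONCEPT_MODALITY                   # source row per concept
    canonical = stack([rows[sel[k]][k] for k in range(12)], axis=0)
    available = np.array([modality_mask[sel[k]] for k in range(12)])
    return matrix, canonical, available


class ConceptHeads:
    """Three per-modality linear heads (128 -> 12) of the learned
    concept bottleneck."""

    def __init__(self, rng: np.random.Generator | None = None):
        from ._autodiff import Linear
        rng = rng or np.random.default_rng(0)
        self.heads = [Linear(128, 12, rng) for _ in range(3)]

    def parameters(self):
        return [p for head in self.heads for p in head.parameters()]
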