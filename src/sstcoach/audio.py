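"""Speech and language narrative features.

Seven features are fed back to the user: F0 variation, amplitude, voice
quality, pause ratio, words per minute, long-word count, and filler count.
The prosodic definitions are this package's operational choices (fixed in
:class:`~sstcoach.config.ProsodyConfig`):

* **F0** per frame by short-time autocorrelation (75-500 Hz search, parabolic
  peak interpolation), restricted to voiced frames (normalized autocorrelation
  peak above threshold and RMS above the silence floor).
* **f0_variation** — sample standard deviation of frame F0 in semitones.
* **amplitude** — mean per-frame RMS in dB re full scale, over speech frames.
* **voice_quality** — mean absolute relative frame-to-frame F0 perturbation
  (a jitter-like measure; 0 for a perfectly steady tone).
* **pause_ratio** — total duration of silent runs at least ``min_pause_s``
  long, divided by clip duration.

On an all-silent clip F0 variation, amplitude and voice quality are undefined
and reported as ``None`` (explicitly missing, never silently zero).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy.io import wavfile

from .config import (
    DEFAULT_FILLER_LEXICON,
    LONG_WORD_THRESHOLD,
    ProsodyConfig,
    logger,
)

__all__ = [
    "AudioClip",
    "Transcript",
    "ProsodyFeatures",
    "extract_prosody",
    "words_per_minute",
    "long_word_count",
    "filler_count",
    "read_wav",
    "write_wav",
]


@dataclass(frozen=True)
class AudioClip:
    """Mono audio in [-1, 1] floats."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float).ravel()
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        object.__setattr__(self, "samples", s)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass(frozen=True)
class Transcript:
    """Pre-tokenized transcript with the spoken duration in seconds."""

    tokens: tuple[str, ...]
    duration: float
    lang: str = "ja"

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        object.__setattr__(self, "tokens", tuple(self.tokens))

    @classmethod
    def from_json(cls, path) -> "Transcript":
        with open(path) as fh:
            d = json.load(fh)
        return cls(tokens=d["tokens"], duration=d["duration_s"], lang=d.get("lang", "ja"))


@dataclass(frozen=True)
class ProsodyFeatures:
    """Prosodic feature bundle; ``None`` marks an undefined (all-silent) value."""

    f0_variation: Optional[float]
    amplitude: Optional[float]
    voice_quality: Optional[float]
    pause_ratio: float
    n_voiced_frames: int = 0


# ---------------------------------------------------------------------------
# WAV I/O (PCM 16-bit or float); stereo is down-mixed with a warning
# ---------------------------------------------------------------------------


def read_wav(path) -> AudioClip:
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        logger.warning("stereo WAV %s down-mixed to mono", path)
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return AudioClip(samples=data, sample_rate=int(rate))


def write_wav(clip: AudioClip, path) -> None:
    pcm = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(path, clip.sample_rate, (pcm * 32767).astype(np.int16))


# ---------------------------------------------------------------------------
# Prosody
# ---------------------------------------------------------------------------


def _frame_signal(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    """(n_frames, frame_len) view of consecutive windows."""
    n = 1 + max(0, (len(x) - frame_len)) // hop
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n)[:, None]
    return x[idx]


def _frame_f0(frame: np.ndarray, sr: int, cfg: ProsodyConfig) -> Optional[float]:
    """Autocorrelation F0 of one frame; None if unvoiced.

    Uses the Hann-windowed autocorrelation divided by the window's own
    autocorrelation, which removes the taper bias of the raw estimator, then
    parabolic interpolation for sub-sample lag accuracy.  Among candidate
    peaks within 10% of the strongest, the smallest lag wins, suppressing
    subharmonic (octave-down) errors.
    """
    frame = frame - frame.mean()
    if not frame.any():
        return None
    n = len(frame)
    lag_min = max(2, int(np.floor(sr / cfg.f0_max)))
    lag_max = min(n - 2, int(np.ceil(sr / cfg.f0_min)))
    if lag_max <= lag_min:
        return None
    w = np.hanning(n)
    xw = frame * w
    acf = np.correlate(xw, xw, mode="full")[n - 1 :][: lag_max + 2]
    wacf = np.correlate(w, w, mode="full")[n - 1 :][: lag_max + 2]
    norm = acf / wacf
    if norm[0] <= 0:
        return None
    seg = norm[lag_min : lag_max + 1]
    vmax = float(seg.max())
    if vmax / norm[0] < cfg.voicing_threshold:
        return None
    # smallest-lag local maximum within 10% of the global peak
    is_peak = (seg[1:-1] >= seg[:-2]) & (seg[1:-1] >= seg[2:]) & (
        seg[1:-1] >= 0.9 * vmax
    )
    candidates = np.flatnonzero(is_peak) + 1
    k = (int(candidates[0]) if candidates.size else int(np.argmax(seg))) + lag_min
    y0, y1, y2 = norm[k - 1], norm[k], norm[k + 1]
    denom = y0 - 2 * y1 + y2
    delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    lag = k + float(np.clip(delta, -0.5, 0.5))
    return sr / lag


def extract_prosody(clip: AudioClip, cfg: ProsodyConfig | None = None) -> ProsodyFeatures:
    """Compute (f0_variation, amplitude, voice_quality, pause_ratio) for a clip.

    See the module docstring for the operational definitions.  Deterministic
    for a fixed config.
    """
    cfg = cfg or ProsodyConfig()
    if len(clip.samples) == 0:
        raise ValueError("empty audio clip")
    sr = clip.sample_rate
    frame_len = max(2, int(round(cfg.frame_s * sr)))
    hop = max(1, int(round(cfg.hop_s * sr)))
    frames = _frame_signal(clip.samples, frame_len, hop)

    rms = np.sqrt(np.mean(frames**2, axis=1))
    with np.errstate(divide="ignore"):
        rms_db = 20.0 * np.log10(rms)
    speech = rms_db >= cfg.silence_db

    # pause ratio from silent runs >= min_pause_s; a run of k frames spans
    # (k - 1) * hop + frame_len samples (first frame start to last frame end)
    silent = ~speech
    pause_time = 0.0
    i = 0
    n = len(silent)
    while i < n:
        if silent[i]:
            j = i
            while j + 1 < n and silent[j + 1]:
                j += 1
            run_s = ((j - i) * hop + frame_len) / sr
            if run_s >= cfg.min_pause_s:
                pause_time += run_s
            i = j + 1
        else:
            i += 1
    pause_ratio = min(1.0, pause_time / clip.duration)

    if not speech.any():
        logger.warning("all-silent clip: prosodic values undefined")
        return ProsodyFeatures(None, None, None, pause_ratio, 0)

    amplitude = float(np.mean(rms_db[speech]))

    f0s: list[Optional[float]] = [
        _frame_f0(frames[i], sr, cfg) if speech[i] else None for i in range(len(frames))
    ]
    voiced = np.array([f for f in f0s if f is not None])
    if voiced.size >= 2:
        semitones = 12.0 * np.log2(voiced / 100.0)
        f0_variation = float(np.std(semitones, ddof=1))
    elif voiced.size == 1:
        f0_variation = 0.0
    else:
        f0_variation = None

    # jitter proxy: mean |dF0| / F0 over consecutive voiced frame pairs
    perturb = [
        abs(b - a) / a
        for a, b in zip(f0s, f0s[1:])
        if a is not None and b is not None
    ]
    voice_quality = float(np.mean(perturb)) if perturb else (0.0 if voiced.size else None)

    return ProsodyFeatures(
        f0_variation=f0_variation,
        amplitude=amplitude,
        voice_quality=voice_quality,
        pause_ratio=pause_ratio,
        n_voiced_frames=int(voiced.size),
    )


# ---------------------------------------------------------------------------
# Linguistic features
# ---------------------------------------------------------------------------


def words_per_minute(tr: Transcript) -> float:
    """Tokens per minute: 60 * len(tokens) / duration."""
    if tr.duration <= 0:
        raise ValueError("duration must be > 0")
    return 60.0 * len(tr.tokens) / tr.duration


def long_word_count(tr: Transcript, threshold: int = LONG_WORD_THRESHOLD) -> int:
    """Number of tokens strictly longer than ``threshold`` characters."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return sum(1 for tok in tr.tokens if len(tok) > threshold)


def filler_count(
    tr: Transcript,
    lexicon: Iterable[str] = DEFAULT_FILLER_LEXICON,
    normalize: bool = True,
) -> int:
    """Number of tokens exactly matching a filler-lexicon entry.

    With ``normalize`` both tokens and lexicon entries are case-folded and
    stripped before comparison; every occurrence counts.
    """
    lex = {w.casefold().strip() if normalize else w for w in lexicon}
    if not lex:
        raise ValueError("lexicon must be non-empty")
    toks = (t.casefold().strip() if normalize else t for t in tr.tokens)
    return sum(1 for t in toks if t in lex)
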