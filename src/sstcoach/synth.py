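"""Seeded synthetic fixtures with known ground truth.

Every pipeline stage can be exercised without recorded data: landmark tracks
with contiguous smile episodes and head-pose wander, harmonic-tone speech
surrogates with scheduled silences, model cohorts drawn from declared feature
distributions, and ratings generated from a known linear model.  All
generators are pure functions of (spec, seed); truth values are computed
analytically from the specification, never measured back from the output.

The happy/neutral landmark templates are constructed schematic faces (raised
lip corners and brows, wider mouth, slightly narrowed eyes) — synthetic
geometry, not derived from any face database.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import FULL_FEATURES, N_LANDMARKS
from .feedback import ModelCohort
from .audio import AudioClip
from .visual import FaceFeatureVector, LandmarkFrame, LandmarkTrack, extract_face_features

__all__ = [
    "TrackSpec",
    "AudioSpec",
    "build_face_templates",
    "gen_smile_training_set",
    "gen_landmark_track",
    "gen_audio",
    "gen_cohort",
    "gen_ratings",
    "DEFAULT_COHORT_PARAMS",
    "DEFAULT_SCORE_WEIGHTS",
]


# ---------------------------------------------------------------------------
# Face templates (66-point schematic face, image coordinates: y grows down)
# ---------------------------------------------------------------------------


def _arc(cx, cy, rx, ry, a0, a1, n):
    th = np.linspace(a0, a1, n)
    return np.column_stack([cx + rx * np.cos(th), cy + ry * np.sin(th)])


def build_face_templates() -> tuple[np.ndarray, np.ndarray]:
    """Construct (neutral, happy) 66-point templates on a ~200x200 px canvas.

    The happy face raises and widens the lip corners, opens the mouth, lifts
    the eyebrows, and narrows the eyes slightly, so all six geometric face
    features separate the two expressions.
    """
    pts = np.zeros((N_LANDMARKS, 2))
    # jaw 0-16: lower face arc
    pts[0:17] = _arc(100, 90, 62, 85, np.pi * 0.02, np.pi * 0.98, 17)[::-1]
    # eyebrows 17-21 (right), 22-26 (left)
    pts[17:22] = np.column_stack([np.linspace(52, 88, 5), [64, 61, 60, 61, 63]])
    pts[22:27] = np.column_stack([np.linspace(112, 148, 5), [63, 61, 60, 61, 64]])
    # nose 27-35: bridge + nostril row
    pts[27:31] = np.column_stack([np.full(4, 100.0), np.linspace(80, 110, 4)])
    pts[31:36] = np.column_stack([np.linspace(88, 112, 5), [116, 118, 119, 118, 116]])
    # right eye 36-41: corners 36/39, upper lid 37,38, lower lid 40,41
    pts[36] = (60, 80)
    pts[37] = (66, 77)
    pts[38] = (74, 77)
    pts[39] = (80, 80)
    pts[40] = (74, 83)
    pts[41] = (66, 83)
    # left eye 42-47
    pts[42] = (120, 80)
    pts[43] = (126, 77)
    pts[44] = (134, 77)
    pts[45] = (140, 80)
    pts[46] = (134, 83)
    pts[47] = (126, 83)
    # outer mouth 48-59: corners 48/54, upper 49-53, lower 55-59
    pts[48] = (80, 140)
    pts[49:54] = np.column_stack([np.linspace(86, 114, 5), [136, 134, 133, 134, 136]])
    pts[54] = (120, 140)
    pts[55:60] = np.column_stack([np.linspace(114, 86, 5), [145, 147, 148, 147, 145]])
    # inner mouth 60-65: upper 60-62, lower 63-65
    pts[60:63] = np.column_stack([[92, 100, 108], [138.5, 138, 138.5]])
    pts[63:66] = np.column_stack([[108, 100, 92], [141.5, 142, 141.5]])
    neutral = pts

    happy = neutral.copy()
    happy[48] += (-6, -8)          # lip corners out and up
    happy[54] += (6, -8)
    happy[49:54, 1] -= 3           # upper lip up
    happy[55:60, 1] += 4           # lower lip down (mouth opens)
    happy[60:63, 1] -= 2.5         # inner lips part
    happy[63:66, 1] += 2.5
    happy[17:27, 1] -= 3           # brows raised
    happy[[37, 38, 43, 44], 1] += 1.2   # eyes narrow slightly
    happy[[40, 41, 46, 47], 1] -= 1.2
    return neutral, happy


# ---------------------------------------------------------------------------
# Smile-classifier training fixtures
# ---------------------------------------------------------------------------


def gen_smile_training_set(
    n_happy: int = 31,
    n_neutral: int = 30,
    separation_sd: float = 3.0,
    seed: int = 0,
    templates: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[list[FaceFeatureVector], list[FaceFeatureVector]]:
    """Draw happy/neutral feature clusters with a known class separation.

    Cluster centers are the face features of the two templates; per-feature
    within-class noise sd is set to |center difference| / separation_sd, so
    the classes are ``separation_sd`` standard deviations apart on every
    feature.  The default sample counts mirror a small expression-exemplar
    set (31 happy, 30 neutral).
    """
    rng = np.random.default_rng(seed)
    neutral_t, happy_t = templates or build_face_templates()
    fn = extract_face_features(LandmarkFrame(neutral_t, 0.0, 0.0, 0.0)).to_array()
    fh = extract_face_features(LandmarkFrame(happy_t, 0.0, 0.0, 0.0)).to_array()
    delta = np.abs(fh - fn)
    noise_sd = np.where(delta > 0, delta / separation_sd, 1e-3)
    happy = [
        FaceFeatureVector.from_array(fh + rng.normal(0, noise_sd))
        for _ in range(n_happy)
    ]
    neutral = [
        FaceFeatureVector.from_array(fn + rng.normal(0, noise_sd))
        for _ in range(n_neutral)
    ]
    return happy, neutral


# ---------------------------------------------------------------------------
# Landmark tracks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrackSpec:
    """Specification of a synthetic landmark track.

    Defaults emulate the one-minute role-play video at 30 fps.  ``smile_level``
    is the neutral→happy interpolation applied during smile episodes;
    ``landmark_jitter_px`` adds per-frame Gaussian tracker noise.
    """

    duration_s: float = 60.0
    fps: float = 30.0
    smile_fraction: float = 0.3
    smile_level: float = 1.0
    episode_frames: int = 30
    landmark_jitter_px: float = 0.4
    yaw_offset_deg: float = 0.0
    pitch_offset_deg: float = 0.0
    yaw_walk_sd: float = 0.2
    pitch_walk_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.smile_fraction <= 1.0:
            raise ValueError("smile_fraction must be in [0, 1]")
        if self.duration_s <= 0 or self.fps <= 0:
            raise ValueError("duration and fps must be > 0")


def _episode_mask(n: int, k: int, episode: int, rng) -> np.ndarray:
    """Boolean mask with k True frames in contiguous blocks of <= episode."""
    if k > n:
        raise ValueError("smile_fraction unreachable: more smile frames than frames")
    mask = np.zeros(n, dtype=bool)
    if k == 0:
        return mask
    blocks = [episode] * (k // episode)
    if k % episode:
        blocks.append(k % episode)
    free = n - k
    # distribute the free frames as random gaps before each block and at the end:
    # block j starts at cut_j + (total length of earlier blocks)
    cuts = np.sort(rng.integers(0, free + 1, size=len(blocks)))
    offset = 0
    for cut, blk in zip(cuts, blocks):
        start = int(cut) + offset
        mask[start : start + blk] = True
        offset += blk
    return mask


def gen_landmark_track(
    spec: TrackSpec,
    templates: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[LandmarkTrack, np.ndarray]:
    """Generate a landmark track plus its ground-truth per-frame smile mask.

    Smile episodes are contiguous blocks totalling ``round(smile_fraction *
    n_frames)`` frames; yaw and pitch follow seeded Gaussian random walks
    around their offsets.  Deterministic per (spec, templates).
    """
    rng = np.random.default_rng(spec.seed)
    neutral_t, happy_t = templates or build_face_templates()
    if neutral_t.shape != (N_LANDMARKS, 2) or happy_t.shape != (N_LANDMARKS, 2):
        raise ValueError(f"templates must be ({N_LANDMARKS}, 2) point arrays")
    n = int(round(spec.duration_s * spec.fps))
    k = int(round(spec.smile_fraction * n))
    mask = _episode_mask(n, k, spec.episode_frames, rng)

    yaw = spec.yaw_offset_deg + np.cumsum(rng.normal(0, spec.yaw_walk_sd, n))
    pitch = spec.pitch_offset_deg + np.cumsum(rng.normal(0, spec.pitch_walk_sd, n))
    if spec.yaw_walk_sd == 0:
        yaw = np.full(n, spec.yaw_offset_deg)
    if spec.pitch_walk_sd == 0:
        pitch = np.full(n, spec.pitch_offset_deg)

    delta = happy_t - neutral_t
    frames = []
    for i in range(n):
        alpha = spec.smile_level if mask[i] else 0.0
        pts = neutral_t + alpha * delta
        if spec.landmark_jitter_px > 0:
            pts = pts + rng.normal(0, spec.landmark_jitter_px, size=pts.shape)
        frames.append(
            LandmarkFrame(
                points=pts,
                t=i / spec.fps,
                yaw=float(yaw[i]),
                pitch=float(pitch[i]),
            )
        )
    return LandmarkTrack(frames=tuple(frames), fps=spec.fps), mask


# ---------------------------------------------------------------------------
# Audio
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AudioSpec:
    """Specification of a harmonic-tone speech surrogate.

    ``pauses`` is a schedule of (onset_s, length_s) digital-silence intervals;
    they must lie within the clip and not overlap.  ``f0_jitter_sd_hz`` is the
    sd of the per-10-ms F0 perturbation around ``base_f0_hz``.
    """

    duration_s: float = 10.0
    sample_rate: int = 16000
    base_f0_hz: float = 150.0
    f0_jitter_sd_hz: float = 0.0
    amplitude_db: float = -20.0
    pauses: tuple[tuple[float, float], ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample_rate must be > 0")
        spans = sorted(self.pauses)
        end = 0.0
        for onset, length in spans:
            if onset < end or length <= 0 or onset + length > self.duration_s:
                raise ValueError("pause schedule invalid: overlap or out of range")
            end = onset + length


_HARMONICS = ((1, 1.0), (2, 0.5), (3, 0.25))


def gen_audio(spec: AudioSpec) -> tuple[AudioClip, dict]:
    """Generate the surrogate clip and its analytic truth values.

    Returns ``(clip, truth)`` with ``truth = {"pause_ratio", "f0_hz",
    "amplitude_db"}`` computed from the schedule, not measured.  Different
    seeds change the waveform (starting phase, jitter draws) but never the
    truth.
    """
    rng = np.random.default_rng(spec.seed)
    sr = spec.sample_rate
    n = int(round(spec.duration_s * sr))
    step = max(1, sr // 100)  # 10 ms F0 update
    n_steps = int(np.ceil(n / step))
    f0_steps = spec.base_f0_hz + rng.normal(0, spec.f0_jitter_sd_hz, n_steps)
    f0 = np.repeat(f0_steps, step)[:n]
    phase = 2 * np.pi * np.cumsum(f0) / sr + rng.uniform(0, 2 * np.pi)

    wave = np.zeros(n)
    for h, a in _HARMONICS:
        wave += a * np.sin(h * phase)
    # scale so the speech RMS hits amplitude_db re full scale
    rms_now = np.sqrt(sum(a * a for _, a in _HARMONICS) / 2.0)
    wave *= 10.0 ** (spec.amplitude_db / 20.0) / rms_now

    for onset, length in spec.pauses:
        i0, i1 = int(round(onset * sr)), int(round((onset + length) * sr))
        wave[i0:i1] = 0.0

    truth = {
        "pause_ratio": sum(l for _, l in spec.pauses) / spec.duration_s,
        "f0_hz": spec.base_f0_hz,
        "amplitude_db": spec.amplitude_db,
    }
    return AudioClip(samples=wave, sample_rate=sr), truth


# ---------------------------------------------------------------------------
# Cohorts and ratings
# ---------------------------------------------------------------------------

#: Per-feature (mean, sd) of the synthetic model-speaker population —
#: plausible magnitudes for one-minute narrative role-plays.
DEFAULT_COHORT_PARAMS: Mapping[str, tuple[float, float]] = {
    "smiling_ratio": (0.40, 0.10),
    "yaw_abs_mean": (5.0, 2.0),
    "pitch_mean": (3.0, 2.0),
    "f0_variation": (2.0, 0.5),
    "amplitude": (-25.0, 3.0),
    "voice_quality": (0.010, 0.003),
    "pause_ratio": (0.20, 0.05),
    "words_per_minute": (120.0, 20.0),
    "long_word_count": (8.0, 3.0),
    "filler_count": (5.0, 2.0),
}

#: Generating weights for synthetic overall-skill ratings (0-100 scale).
DEFAULT_SCORE_WEIGHTS: Mapping[str, float] = {
    "words_per_minute": 0.15,
    "amplitude": 0.8,
    "long_word_count": 0.9,
    "smiling_ratio": 35.0,
}
DEFAULT_SCORE_INTERCEPT = 60.0


def gen_cohort(
    n_models: int = 10,
    feature_params: Mapping[str, tuple[float, float]] = DEFAULT_COHORT_PARAMS,
    seed: int = 0,
) -> ModelCohort:
    """Draw a model cohort from per-feature normal distributions."""
    if n_models < 2:
        raise ValueError("need at least 2 model speakers")
    for f, (_, sd) in feature_params.items():
        if sd <= 0:
            raise ValueError(f"non-positive sd for feature {f!r}")
    rng = np.random.default_rng(seed)
    cols = {
        f: rng.normal(mu, sd, n_models) for f, (mu, sd) in feature_params.items()
    }
    return ModelCohort(pd.DataFrame(cols))


def gen_ratings(
    cohort: ModelCohort,
    weights: Mapping[str, float] = DEFAULT_SCORE_WEIGHTS,
    intercept: float = DEFAULT_SCORE_INTERCEPT,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Ratings = declared linear combination of features + Gaussian noise.

    Returns ``(ratings, truth)`` where truth carries the generating weights,
    intercept and noise sd.
    """
    rng = np.random.default_rng(seed)
    y = np.full(len(cohort.table), float(intercept))
    for f, w in weights.items():
        y = y + w * cohort.table[f].to_numpy(float)
    y = y + rng.normal(0, noise_sd, len(y))
    truth = {"weights": dict(weights), "intercept": float(intercept), "noise_sd": noise_sd}
    return y, truth
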