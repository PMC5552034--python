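"""Shared configuration: landmark index map, prosody parameters, feature presets.

Every constant here is a documented default that callers may override; the
geometry and signal-processing thresholds are this package's operational
choices, kept in one place so they are auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

logger = logging.getLogger("sstcoach")
if not logger.handlers:  # library default: warnings and above to stderr
    logging.basicConfig(level=logging.WARNING)

# ---------------------------------------------------------------------------
# 66-point landmark annotation
#
# Point groups follow the common constrained-local-model layout:
#   0-16  jaw (17)        17-26 eyebrows (10: right 17-21, left 22-26)
#   27-35 nose (9)        36-47 eyes (12: right 36-41, left 42-47)
#   48-65 mouth (18: outer 48-59, inner 60-65)
# Within each eye: corners (36,39)/(42,45), upper lid (37,38)/(43,44),
# lower lid (40,41)/(46,47). Outer mouth: corners 48/54, upper 49-53,
# lower 55-59. Inner mouth: upper 60-62, lower 63-65.
# ---------------------------------------------------------------------------

N_LANDMARKS = 66

#: Face-feature names, in canonical order, as consumed by the smile classifier.
FACE_FEATURE_NAMES = (
    "outer_eyebrow_height",
    "inner_eyebrow_height",
    "outer_lip_height",
    "inner_lip_height",
    "eye_opening",
    "lip_corner_distance",
)

#: Default landmark index map.  Each *height* feature is the mean vertical
#: distance between its "upper" and "lower" point sets; lip_corner_distance is
#: the Euclidean distance between the two mouth corners; everything is
#: normalized by the inter-ocular distance (distance between the centroids of
#: the two full eye contours).
DEFAULT_INDEX_MAP: dict = {
    "right_eye": [36, 37, 38, 39, 40, 41],
    "left_eye": [42, 43, 44, 45, 46, 47],
    "outer_eyebrow_height": {"upper": [17, 26], "lower": [36, 45]},
    "inner_eyebrow_height": {"upper": [21, 22], "lower": [39, 42]},
    "outer_lip_height": {"upper": [50, 51, 52], "lower": [55, 56, 57]},
    "inner_lip_height": {"upper": [60, 61, 62], "lower": [63, 64, 65]},
    "eye_opening": {"upper": [37, 38, 43, 44], "lower": [40, 41, 46, 47]},
    "lip_corners": [48, 54],
}


def load_index_map(path: str) -> dict:
    """Load an index-map override from the ``visual:`` section of a YAML file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg.get("visual", {}).get("index_map", cfg)


# ---------------------------------------------------------------------------
# Prosody
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProsodyConfig:
    """Short-time analysis parameters for the prosodic feature extractor.

    Attributes
    ----------
    frame_s, hop_s:
        Analysis window length and hop, seconds.
    f0_min, f0_max:
        Autocorrelation F0 search range, Hz.
    voicing_threshold:
        Minimum normalized autocorrelation peak for a frame to count as voiced.
    silence_db:
        Frames whose RMS falls below this level (dB re full scale) are silent.
    min_pause_s:
        Silent runs at least this long count toward the pause ratio.
    """

    frame_s: float = 0.04
    hop_s: float = 0.01
    f0_min: float = 75.0
    f0_max: float = 500.0
    voicing_threshold: float = 0.5
    silence_db: float = -35.0
    min_pause_s: float = 0.3

    def as_dict(self) -> dict:
        return asdict(self)


#: Default Japanese filler lexicon; fully user-replaceable.
DEFAULT_FILLER_LEXICON = frozenset(
    {"eto", "etto", "anou", "ano", "maa", "nanka", "sono", "uun", "un", "e"}
)

#: Tokens longer than this many characters count as "long words".
LONG_WORD_THRESHOLD = 6

# ---------------------------------------------------------------------------
# Feature presets (canonical order = tie-break order for comment selection)
# ---------------------------------------------------------------------------

#: Full feature set: three visual + seven audio/linguistic features.
FULL_FEATURES = (
    "smiling_ratio",
    "yaw_abs_mean",
    "pitch_mean",
    "f0_variation",
    "amplitude",
    "voice_quality",
    "pause_ratio",
    "words_per_minute",
    "long_word_count",
    "filler_count",
)

#: Reduced five-feature set used with ASD participants.
ASD5_FEATURES = (
    "pitch_mean",
    "words_per_minute",
    "amplitude",
    "long_word_count",
    "smiling_ratio",
)

#: Features entering the 0-100 overall-score regression.
SCORE_FEATURES = (
    "words_per_minute",
    "amplitude",
    "long_word_count",
    "smiling_ratio",
)

# ---------------------------------------------------------------------------
# Comment templates: (feature, direction) -> text.  Direction is "high" when
# the user's z-score is >= 0 and "low" otherwise; "positive" entries praise
# the feature closest to the models.
# ---------------------------------------------------------------------------

COMMENT_TEMPLATES_EN: Mapping[str, Mapping[str, str]] = {
    "smiling_ratio": {
        "positive": "Your smiling was very close to the model speakers. Keep it up!",
        "high": "You smiled a lot; try to match the models' natural amount of smiling.",
        "low": "Try smiling a little more while you tell your story.",
    },
    "yaw_abs_mean": {
        "positive": "You kept facing forward just like the model speakers.",
        "high": "Try to look toward the listener instead of turning your head away.",
        "low": "You held your head steady; aim for the models' relaxed posture.",
    },
    "pitch_mean": {
        "positive": "Your head position matched the model speakers well.",
        "high": "Try to lift your head a little instead of looking down.",
        "low": "Try not to tilt your head up too much while speaking.",
    },
    "f0_variation": {
        "positive": "Your intonation was close to the model speakers.",
        "high": "Your voice pitch varied a lot; aim for the models' steadier melody.",
        "low": "Try varying your voice pitch a little more to sound lively.",
    },
    "amplitude": {
        "positive": "Your loudness matched the model speakers well.",
        "high": "Try speaking a little more softly.",
        "low": "Try speaking a little louder and clearer.",
    },
    "voice_quality": {
        "positive": "Your voice was as steady as the model speakers'.",
        "high": "Your voice wavered a little; take a breath and speak calmly.",
        "low": "Your voice was very steady; keep that up.",
    },
    "pause_ratio": {
        "positive": "Your pausing matched the model speakers well.",
        "high": "Try to keep the story flowing with fewer long pauses.",
        "low": "Short pauses between ideas can help the listener follow you.",
    },
    "words_per_minute": {
        "positive": "Your speaking rate was right in line with the models.",
        "high": "Try slowing down a little so the listener can follow.",
        "low": "Try speaking a little faster to keep the story moving.",
    },
    "long_word_count": {
        "positive": "Your choice of words matched the model speakers well.",
        "high": "Try using slightly simpler words.",
        "low": "Using a few richer words can make the story more vivid.",
    },
    "filler_count": {
        "positive": "You used very few fillers, just like the models.",
        "high": "Try to pause silently instead of using fillers like 'um'.",
        "low": "You barely used fillers; well done.",
    },
}

COMMENT_TEMPLATES_JA: Mapping[str, Mapping[str, str]] = {
    feat: {
        "positive": f"{feat}: モデルの話者にとても近いです。その調子です!",
        "high": f"{feat}: モデルの話者より高めです。少し抑えてみましょう。",
        "low": f"{feat}: モデルの話者より低めです。少し増やしてみましょう。",
    }
    for feat in FULL_FEATURES
}
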