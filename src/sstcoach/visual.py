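"""Visual narrative features from 66-point facial-landmark tracks.

Three per-session features are produced from a landmark track with per-frame
head pose:

* **smiling ratio** — the fraction of frames a linear smile/neutral classifier
  labels as smiling.  The classifier operates on six geometric face features
  (eyebrow heights, lip heights, eye opening, lip-corner distance), each
  normalized by the inter-ocular distance so that the representation is
  invariant to translation and uniform scale.
* **mean absolute yaw** — average of |yaw| over frames, the shift from frontal.
* **mean pitch** — signed average of pitch (positive = facing down), since both
  looking up and looking down are informative.

Frames with missing (NaN) landmarks are excluded from every average, with a
logged count.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .config import (
    DEFAULT_INDEX_MAP,
    FACE_FEATURE_NAMES,
    N_LANDMARKS,
    logger,
)

__all__ = [
    "LandmarkFrame",
    "LandmarkTrack",
    "FaceFeatureVector",
    "SmileModel",
    "HeadPoseSummary",
    "DegenerateTrainingError",
    "extract_face_features",
    "train_smile_model",
    "classify_frame",
    "smiling_ratio",
    "head_pose_summary",
    "read_landmark_csv",
    "write_landmark_csv",
]


class DegenerateTrainingError(ValueError):
    """Raised when the smile training data cannot define a classifier."""


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LandmarkFrame:
    """One tracked video frame: 66 (x, y) points plus head pose in degrees.

    ``pitch`` is positive when the head faces down, negative when it faces up;
    ``yaw`` is positive when the head turns to the subject's left.
    """

    points: np.ndarray  # (66, 2) float
    t: float
    yaw: float
    pitch: float
    roll: float = 0.0

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise ValueError(f"expected ({N_LANDMARKS}, 2) points, got {pts.shape}")
        if self.t < 0:
            raise ValueError("frame time must be >= 0")
        object.__setattr__(self, "points", pts)

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.points).any())


@dataclass(frozen=True)
class LandmarkTrack:
    """An ordered, strictly time-increasing sequence of landmark frames."""

    frames: tuple[LandmarkFrame, ...]
    fps: float

    def __post_init__(self):
        if not self.frames:
            raise ValueError("track must contain at least one frame")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        ts = np.array([f.t for f in self.frames])
        if not np.all(np.diff(ts) > 0) and len(ts) > 1:
            raise ValueError("frame times must be strictly increasing")
        object.__setattr__(self, "frames", tuple(self.frames))

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def yaw(self) -> np.ndarray:
        return np.array([f.yaw for f in self.frames])

    @property
    def pitch(self) -> np.ndarray:
        return np.array([f.pitch for f in self.frames])


@dataclass(frozen=True)
class FaceFeatureVector:
    """Six dimensionless geometric face features (inter-ocular normalized)."""

    outer_eyebrow_height: float
    inner_eyebrow_height: float
    outer_lip_height: float
    inner_lip_height: float
    eye_opening: float
    lip_corner_distance: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FACE_FEATURE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "FaceFeatureVector":
        return cls(**dict(zip(FACE_FEATURE_NAMES, map(float, arr))))


@dataclass(frozen=True)
class HeadPoseSummary:
    """Per-track head-pose aggregates, degrees."""

    yaw_abs_mean: float
    pitch_mean: float


@dataclass
class SmileModel:
    """Linear max-margin smile/neutral classifier over standardized features.

    The decision value is ``w . (x - mean) / sd + b``; a frame is *smiling*
    iff the decision value is strictly positive (an exact zero is classified
    neutral: smiling requires positive evidence).
    """

    weights: np.ndarray
    bias: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    index_map_hash: str = ""

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.feature_means = np.asarray(self.feature_means, dtype=float)
        self.feature_sds = np.asarray(self.feature_sds, dtype=float)
        if self.weights.shape != (len(FACE_FEATURE_NAMES),):
            raise ValueError("weight count must equal the number of face features")
        if np.any(self.feature_sds <= 0):
            raise ValueError("feature sds must all be > 0")

    def decision_value(self, features: FaceFeatureVector) -> float:
        x = features.to_array()
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite face feature")
        z = (x - self.feature_means) / self.feature_sds
        return float(self.weights @ z + self.bias)

    def to_json(self, path: str) -> None:
        payload = {
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "index_map_hash": self.index_map_hash,
            "feature_names": list(FACE_FEATURE_NAMES),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "SmileModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            weights=d["weights"],
            bias=d["bias"],
            feature_means=d["feature_means"],
            feature_sds=d["feature_sds"],
            index_map_hash=d.get("index_map_hash", ""),
        )


def index_map_hash(index_map: dict) -> str:
    return hashlib.sha256(
        json.dumps(index_map, sort_keys=True).encode()
    ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def _check_indices(idx: Iterable[int]) -> np.ndarray:
    a = np.asarray(list(idx), dtype=int)
    if a.size == 0 or a.min() < 0 or a.max() >= N_LANDMARKS:
        raise IndexError(f"landmark index out of range [0, {N_LANDMARKS}): {a}")
    return a


def extract_face_features(
    frame: LandmarkFrame, index_map: dict | None = None
) -> FaceFeatureVector:
    """Compute the six geometric face features for one frame.

    Each height feature is the mean absolute vertical distance between the
    upper and lower point sets named in ``index_map``; lip_corner_distance is
    the Euclidean distance between the two mouth-corner points.  All values
    are divided by the inter-ocular distance (distance between the centroids
    of the two eye contours), making the vector translation- and
    scale-invariant.

    Raises
    ------
    ValueError
        If the inter-ocular distance is zero (degenerate face) or any needed
        coordinate is non-finite.
    IndexError
        If the index map references a landmark outside [0, 66).
    """
    imap = index_map if index_map is not None else DEFAULT_INDEX_MAP
    pts = frame.points

    right_eye = pts[_check_indices(imap["right_eye"])]
    left_eye = pts[_check_indices(imap["left_eye"])]
    inter_ocular = float(np.linalg.norm(right_eye.mean(axis=0) - left_eye.mean(axis=0)))
    if not np.isfinite(inter_ocular):
        raise ValueError("non-finite landmark coordinates in eye regions")
    if inter_ocular == 0:
        raise ValueError("degenerate face: inter-ocular distance is zero")

    values = {}
    for name in FACE_FEATURE_NAMES[:-1]:
        spec = imap[name]
        upper = pts[_check_indices(spec["upper"]), 1]
        lower = pts[_check_indices(spec["lower"]), 1]
        values[name] = abs(float(lower.mean() - upper.mean())) / inter_ocular

    c1, c2 = pts[_check_indices(imap["lip_corners"])]
    values["lip_corner_distance"] = float(np.linalg.norm(c2 - c1)) / inter_ocular

    if not all(np.isfinite(v) for v in values.values()):
        raise ValueError("non-finite face feature value")
    return FaceFeatureVector(**values)


# ---------------------------------------------------------------------------
# Smile classifier
# ---------------------------------------------------------------------------


def train_smile_model(
    happy: Sequence[FaceFeatureVector],
    neutral: Sequence[FaceFeatureVector],
    regularization: float = 1.0,
    index_map: dict | None = None,
    on_constant_feature: str = "error",
) -> SmileModel:
    """Fit a linear-kernel SVM separating happy from neutral face geometry.

    Features are standardized to training mean 0 / sd 1 before fitting.
    Deterministic given the inputs and ``regularization``.

    Parameters
    ----------
    on_constant_feature:
        ``"error"`` raises if a feature is constant across all training
        samples; ``"drop"`` zeroes its weight with a warning.
    """
    if not happy or not neutral:
        raise DegenerateTrainingError("both classes must be non-empty")
    Xh = np.array([f.to_array() for f in happy])
    Xn = np.array([f.to_array() for f in neutral])
    X = np.vstack([Xh, Xn])
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite training features")
    y = np.concatenate([np.ones(len(Xh)), np.zeros(len(Xn))])

    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    constant = np.ptp(X, axis=0) == 0  # exact: sd of a constant column can round to ~1e-16
    if constant.any():
        names = [n for n, c in zip(FACE_FEATURE_NAMES, constant) if c]
        if on_constant_feature == "error":
            raise DegenerateTrainingError(f"constant training feature(s): {names}")
        logger.warning("dropping constant training feature(s): %s", names)
        sds = np.where(constant, 1.0, sds)

    # identical class distributions admit no separating direction
    if len(Xh) == len(Xn) and np.array_equal(
        Xh[np.lexsort(Xh.T)], Xn[np.lexsort(Xn.T)]
    ):
        raise DegenerateTrainingError("happy and neutral classes are identical")

    Z = (X - means) / sds
    if constant.any():
        Z[:, constant] = 0.0
    svc = SVC(kernel="linear", C=regularization)
    svc.fit(Z, y)
    weights = svc.coef_.ravel().copy()
    if constant.any():
        weights[constant] = 0.0
    return SmileModel(
        weights=weights,
        bias=float(svc.intercept_[0]),
        feature_means=means,
        feature_sds=sds,
        index_map_hash=index_map_hash(index_map or DEFAULT_INDEX_MAP),
    )


def classify_frame(model: SmileModel, features: FaceFeatureVector) -> str:
    """Label a feature vector ``"smiling"`` or ``"neutral"``.

    Smiling requires a strictly positive decision value; a value of exactly
    zero is labelled neutral.
    """
    return "smiling" if model.decision_value(features) > 0 else "neutral"


def smiling_ratio(
    track: LandmarkTrack, model: SmileModel, index_map: dict | None = None
) -> float:
    """Fraction of (valid) frames classified as smiling; no temporal smoothing.

    Frames with missing landmarks are excluded from both numerator and
    denominator; the excluded count is logged.
    """
    n_smile = 0
    n_valid = 0
    n_missing = 0
    for frame in track.frames:
        if frame.has_missing:
            n_missing += 1
            continue
        feats = extract_face_features(frame, index_map)
        n_smile += classify_frame(model, feats) == "smiling"
        n_valid += 1
    if n_missing:
        logger.info("smiling_ratio: excluded %d frames with missing landmarks", n_missing)
    if n_valid == 0:
        raise ValueError("no valid frames in track")
    return n_smile / n_valid


def head_pose_summary(track: LandmarkTrack) -> HeadPoseSummary:
    """Mean |yaw| and signed mean pitch over frames, NaN poses excluded."""
    yaw = track.yaw
    pitch = track.pitch
    yaw = yaw[np.isfinite(yaw)]
    pitch = pitch[np.isfinite(pitch)]
    if yaw.size == 0 or pitch.size == 0:
        raise ValueError("no finite pose values in track")
    return HeadPoseSummary(
        yaw_abs_mean=float(np.mean(np.abs(yaw))),
        pitch_mean=float(np.mean(pitch)),
    )


# ---------------------------------------------------------------------------
# Landmark CSV I/O: header frame,t,x0..x65,y0..y65,yaw,pitch,roll
# ---------------------------------------------------------------------------

_XCOLS = [f"x{i}" for i in range(N_LANDMARKS)]
_YCOLS = [f"y{i}" for i in range(N_LANDMARKS)]


def read_landmark_csv(path, fps: float | None = None, angle_unit: str = "deg") -> LandmarkTrack:
    """Read a landmark track from CSV.

    ``angle_unit`` must be ``"deg"`` or ``"rad"``; radians are converted to
    degrees at read time.  If ``fps`` is omitted it is inferred from the
    median frame-time step.
    """
    if angle_unit not in ("deg", "rad"):
        raise ValueError("angle_unit must be 'deg' or 'rad'")
    df = pd.read_csv(path)
    scale = 1.0 if angle_unit == "deg" else 180.0 / np.pi
    frames = []
    xs = df[_XCOLS].to_numpy(float)
    ys = df[_YCOLS].to_numpy(float)
    for i, row in enumerate(df.itertuples(index=False)):
        pts = np.column_stack([xs[i], ys[i]])
        frames.append(
            LandmarkFrame(
                points=pts,
                t=float(row.t),
                yaw=float(row.yaw) * scale,
                pitch=float(row.pitch) * scale,
                roll=float(row.roll) * scale,
            )
        )
    if fps is None:
        ts = df["t"].to_numpy(float)
        fps = 1.0 / float(np.median(np.diff(ts))) if len(ts) > 1 else 30.0
    return LandmarkTrack(frames=tuple(frames), fps=fps)


def write_landmark_csv(track: LandmarkTrack, path) -> None:
    rows = []
    for i, f in enumerate(track.frames):
        row = {"frame": i, "t": f.t}
        row.update({c: f.points[j, 0] for j, c in enumerate(_XCOLS)})
        row.update({c: f.points[j, 1] for j, c in enumerate(_YCOLS)})
        row.update({"yaw": f.yaw, "pitch": f.pitch, "roll": f.roll})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
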