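"""Reading videos and score tables, clip standardization, and feature caching.

Trials arrive as video clips that are standardized to the network's input
geometry — 300 x 300 pixel frames at 30 frames/s, cut into 125-frame clips —
and as delimited score tables holding the expert's per-element ratings on the
0 / 0.5 / 1 scale.  Encoded per-frame features are cached to HDF5, one dataset
per trial, keyed ``<animal>/<day>/<trial>``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .grammar import SCORED_ELEMENTS

__all__ = [
    "FrameStack",
    "ClipSpec",
    "ScoreTable",
    "load_clip",
    "segment_trial",
    "read_score_table",
    "write_score_table",
    "cache_features",
    "read_feature_cache",
    "ScoreTableError",
    "CacheIntegrityError",
]

#: Required columns of a score table CSV.
REQUIRED_COLUMNS = ("animal_id", "day", "trial_id", "group")
ELEMENT_COLUMNS = tuple(SCORED_ELEMENTS)
VALID_ELEMENT_SCORES = (0.0, 0.5, 1.0)


class ScoreTableError(ValueError):
    """Schema or validation failure in a score table, with cell locations."""


class CacheIntegrityError(RuntimeError):
    """The feature cache file is unreadable or internally inconsistent."""


@dataclass
class FrameStack:
    """A decoded trial video: T x H x W x 3 8-bit frames plus provenance."""

    frames: np.ndarray
    source_path: str = ""
    fps: float = 30.0
    trial_id: str = ""

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must be T x H x W x 3")
        if self.frames.shape[0] < 1 or min(self.frames.shape[1:3]) < 1:
            raise ValueError("empty frame stack")
        if self.frames.dtype != np.uint8:
            if self.frames.min() < 0 or self.frames.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            self.frames = self.frames.astype(np.uint8)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class ClipSpec:
    """Standardization target for incoming video.

    ``out_size`` and ``out_fps`` default to the network geometry (300 x 300 at
    30 frames/s); ``clip_len`` to 125 frames.  ``crop_center`` is the (row,
    col) pixel around which the crop window is taken — the pellet location is
    not auto-detected, so it is explicit user input; ``None`` means the frame
    center.
    """

    out_size: tuple[int, int] = (300, 300)
    out_fps: float = 30.0
    clip_len: int = 125
    crop_center: tuple[int, int] | None = None

    def __post_init__(self):
        if self.clip_len < 1:
            raise ValueError("clip_len must be >= 1")
        if self.out_fps <= 0:
            raise ValueError("out_fps must be > 0")


def _decimate_indices(n_frames: int, src_fps: float, out_fps: float) -> np.ndarray:
    """Nearest-frame decimation indices (no interpolation)."""
    if out_fps > src_fps:
        raise ValueError(f"out_fps {out_fps} exceeds source fps {src_fps}")
    step = src_fps / out_fps
    n_out = int(np.floor(n_frames / step + 1e-9))
    idx = np.floor(np.arange(n_out) * step).astype(int)
    return np.clip(idx, 0, n_frames - 1)


def _crop_resize(frames: np.ndarray, out_size: tuple[int, int],
                 crop_center: tuple[int, int] | None) -> np.ndarray:
    t, h, w, _ = frames.shape
    oh, ow = out_size
    cy, cx = crop_center if crop_center is not None else (h // 2, w // 2)
    # Take the out_size window around the center, clipped to frame bounds.
    y0 = int(np.clip(cy - oh // 2, 0, max(h - oh, 0)))
    x0 = int(np.clip(cx - ow // 2, 0, max(w - ow, 0)))
    win = frames[:, y0:y0 + min(oh, h), x0:x0 + min(ow, w), :]
    if win.shape[1] == oh and win.shape[2] == ow:
        return win
    # Source smaller than the target window: rescale photographically.
    from PIL import Image
    out = np.empty((t, oh, ow, 3), dtype=np.uint8)
    for i in range(t):
        out[i] = np.asarray(
            Image.fromarray(win[i]).resize((ow, oh), Image.BILINEAR))
    return out


def load_clip(path: str, spec: ClipSpec, source_fps: float | None = None,
              trial_id: str | None = None) -> FrameStack:
    """Decode a video file and standardize it to the network geometry.

    Frames are cropped to the ``out_size`` window around ``crop_center``,
    resized only when the source is smaller than the window, and temporally
    resampled to ``out_fps`` by nearest-frame decimation.  The operation is
    deterministic: repeated calls on the same file are bit-identical.

    ``source_fps`` overrides container metadata (required for containers that
    do not carry a frame rate, e.g. TIFF stacks).
    """
    import imageio.v3 as iio

    if not os.path.exists(path):
        raise IOError(f"video file not found: {path}")
    try:
        frames = np.asarray(iio.imread(path, index=None))
    except Exception as exc:
        raise IOError(f"could not decode video file {path}: {exc}") from exc
    if frames.ndim == 3 and frames.shape[-1] in (3, 4):
        frames = frames[None]  # single frame
    if frames.ndim == 3:  # T x H x W grayscale
        frames = np.repeat(frames[..., None], 3, axis=-1)
    if frames.ndim != 4 or frames.shape[0] == 0:
        raise ValueError(f"no decodable frames in {path}")
    frames = frames[..., :3]

    fps = source_fps
    if fps is None:
        try:
            meta = iio.immeta(path)
            fps = float(meta.get("fps", 0)) or None
            if fps is None and "duration" in meta and meta["duration"]:
                fps = 1000.0 / float(meta["duration"])  # GIF per-frame ms
        except Exception:
            fps = None
    if fps is None:
        fps = spec.out_fps  # assume already at target rate

    idx = _decimate_indices(frames.shape[0], fps, spec.out_fps)
    frames = frames[idx]
    frames = _crop_resize(frames, spec.out_size, spec.crop_center)
    return FrameStack(frames=frames, source_path=path, fps=spec.out_fps,
                      trial_id=trial_id or os.path.splitext(os.path.basename(path))[0])


def segment_trial(stack: FrameStack, clip_len: int = 125,
                  pad_policy: str = "repeat_last") -> list[FrameStack]:
    """Cut a trial into consecutive non-overlapping ``clip_len`` windows.

    Windows are half-open ``[start, start + clip_len)`` over 0-indexed frames.
    A trailing shorter remainder is padded by repeating its last frame
    (``repeat_last``; repeated frames do not disturb downstream temporal
    max-pooling) or dropped (``reject``).
    """
    if clip_len <= 0:
        raise ValueError("clip_len must be positive")
    if pad_policy not in ("repeat_last", "reject"):
        raise ValueError(f"unknown pad_policy {pad_policy!r}")
    frames = stack.frames
    n = frames.shape[0]
    clips: list[FrameStack] = []
    for k, start in enumerate(range(0, n, clip_len)):
        chunk = frames[start:start + clip_len]
        if chunk.shape[0] < clip_len:
            if pad_policy == "reject":
                break
            pad = np.repeat(chunk[-1:], clip_len - chunk.shape[0], axis=0)
            chunk = np.concatenate([chunk, pad], axis=0)
        clips.append(FrameStack(frames=chunk, source_path=stack.source_path,
                                fps=stack.fps,
                                trial_id=f"{stack.trial_id}_c{k}"))
    return clips


@dataclass
class ScoreTable:
    """Expert score table keyed by (animal_id, day, trial_id).

    Wraps a DataFrame with columns ``animal_id, day, trial_id, group`` plus
    optional per-element scores (``lift`` ... ``supination_ii`` on the
    0/0.5/1 scale), ``cumulative`` (their sum, in [0, 7]), ``lesion_volume``
    (mm^3, 0 for controls) and ``rater_id``.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        self.validate()

    @property
    def has_elements(self) -> bool:
        return all(c in self.df.columns for c in ELEMENT_COLUMNS)

    def validate(self) -> None:
        df = self.df
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ScoreTableError(f"missing required column(s): {missing}")
        if len(df) == 0:
            raise ScoreTableError("score table has no rows")
        problems: list[str] = []
        present = [c for c in ELEMENT_COLUMNS if c in df.columns]
        for col in present:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = ~vals.isin(VALID_ELEMENT_SCORES)
            for row in df.index[bad]:
                problems.append(
                    f"row {row}, column {col!r}: value {df.at[row, col]!r} "
                    "not in {0, 0.5, 1}")
        if "cumulative" in df.columns and len(present) == len(ELEMENT_COLUMNS):
            esum = df[list(ELEMENT_COLUMNS)].astype(float).sum(axis=1)
            off = (df["cumulative"].astype(float) - esum).abs() > 1e-9
            for row in df.index[off]:
                problems.append(
                    f"row {row}: cumulative {df.at[row, 'cumulative']} != "
                    f"element sum {esum[row]}")
        if "lesion_volume" in df.columns:
            ctrl = df["group"].astype(int) == 0
            bad = ctrl & (df["lesion_volume"].astype(float) != 0)
            for row in df.index[bad]:
                problems.append(
                    f"row {row}: control animal with nonzero lesion_volume "
                    f"{df.at[row, 'lesion_volume']}")
        if problems:
            raise ScoreTableError("score table validation failed:\n  "
                                  + "\n  ".join(problems))

    def cumulative_scores(self) -> pd.Series:
        if "cumulative" in self.df.columns:
            return self.df["cumulative"].astype(float)
        if not self.has_elements:
            raise ScoreTableError("neither cumulative nor element scores present")
        return self.df[list(ELEMENT_COLUMNS)].astype(float).sum(axis=1)

    def per_animal_means(self, column: str = "cumulative") -> pd.Series:
        s = (self.cumulative_scores() if column == "cumulative"
             else self.df[column].astype(float))
        return s.groupby(self.df["animal_id"]).mean()


def read_score_table(path: str) -> ScoreTable:
    """Read and validate a score table CSV.

    Raises :class:`ScoreTableError` naming missing columns or the offending
    rows/cells for values off the three-point scale.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ScoreTableError(f"empty score table file: {path}") from exc
    for col in ELEMENT_COLUMNS + ("cumulative", "lesion_volume"):
        if col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                rows = list(df.index[bad])
                raise ScoreTableError(
                    f"non-numeric value(s) in column {col!r} at row(s) {rows}")
            df[col] = coerced
    return ScoreTable(df=df)


def write_score_table(table: ScoreTable, path: str) -> None:
    table.df.to_csv(path, index=False)


def cache_features(clips, path: str, extra_attrs: dict | None = None) -> None:
    """Write feature clips to an HDF5 cache, one dataset per trial.

    Datasets are named ``<animal>/<day>/<trial>`` with group / day / encoder
    tag stored as attributes.  All clips must share a feature dimension and an
    encoder tag (caches never mix backends).
    """
    clips = list(clips)
    if not clips:
        raise ValueError("no clips to cache")
    dims = {c.n_features for c in clips}
    if len(dims) != 1:
        raise ValueError(f"clips disagree on feature dimension: {sorted(dims)}")
    tags = {c.encoder_tag for c in clips}
    if len(tags) != 1:
        raise ValueError(f"clips from different encoder backends: {sorted(tags)}")
    with h5py.File(path, "w") as f:
        f.attrs["encoder_tag"] = clips[0].encoder_tag
        if extra_attrs:
            for k, v in extra_attrs.items():
                f.attrs[k] = v
        for clip in clips:
            ds = f.create_dataset(
                f"{clip.animal_id}/{clip.day}/{clip.trial_id}",
                data=clip.features.astype(np.float32))
            ds.attrs["animal_id"] = clip.animal_id
            ds.attrs["day"] = int(clip.day)
            ds.attrs["group"] = int(clip.group)
            ds.attrs["trial_id"] = clip.trial_id
            ds.attrs["encoder_tag"] = clip.encoder_tag


def read_feature_cache(path: str) -> list:
    """Read back every trial of an HDF5 feature cache (inverse of
    :func:`cache_features`); round-trips are bit-identical."""
    from .encoder import FeatureClip

    clips: list[FeatureClip] = []
    try:
        with h5py.File(path, "r") as f:
            def visit(_name, obj):
                if isinstance(obj, h5py.Dataset):
                    clips.append(FeatureClip(
                        features=obj[()],
                        trial_id=str(obj.attrs["trial_id"]),
                        animal_id=str(obj.attrs["animal_id"]),
                        day=int(obj.attrs["day"]),
                        group=int(obj.attrs["group"]),
                        encoder_tag=str(obj.attrs["encoder_tag"])))
            f.visititems(visit)
    except OSError as exc:
        raise CacheIntegrityError(f"unreadable feature cache {path}: {exc}") from exc
    if not clips:
        raise CacheIntegrityError(f"feature cache {path} contains no trials")
    clips.sort(key=lambda c: (c.animal_id, c.day, c.trial_id))
    return clips
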