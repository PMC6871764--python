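"""Frame-to-feature encoders.

Each video frame is mapped to a 2,048-dimensional non-negative feature vector
before any temporal modelling.  Two backends implement that contract:

* ``PretrainedEncoder`` — a deep convolutional image encoder (Inception-V3
  style) run inference-only from an external weight artifact.  It is never
  trained or fine-tuned here.
* ``StubEncoder`` — a deterministic stand-in for tests and synthetic runs: the
  frame is converted to grayscale, average-pool downsampled to 32 x 32, passed
  through a fixed seeded random projection, and rectified.  Because the map is
  linear-then-ReLU it has a closed-form Jacobian, which makes frame saliency
  exactly checkable.

Both backends tag their output so cached features from different encoders can
never be mixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_media import FrameStack

__all__ = [
    "FeatureClip",
    "StubEncoder",
    "PretrainedEncoder",
    "encode_clip",
    "encoder_fidelity_check",
    "EncoderConfigError",
]

N_FEATURES = 2048
_STUB_POOL = 32  # stub downsample size (32 x 32 grayscale)


class EncoderConfigError(RuntimeError):
    """A backend is mis-wired (wrong dimension, missing weights, ...)."""


@dataclass
class FeatureClip:
    """Per-trial encoder features: one row of ``n_features`` per frame.

    Attributes
    ----------
    features : (T, F) float32 array of non-negative activations.
    trial_id, animal_id : identifiers; ``day`` the recording day; ``group``
        0 for control, 1 for stroke.
    encoder_tag : identifies the backend (and its preprocessing) that
        produced the features.
    """

    features: np.ndarray
    trial_id: str
    animal_id: str = ""
    day: int = 0
    group: int = 0
    encoder_tag: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float32)
        if self.features.ndim != 2:
            raise ValueError("features must be a T x F array")
        if not np.all(np.isfinite(self.features)):
            raise ValueError(f"non-finite features in trial {self.trial_id!r}")
        if not self.encoder_tag:
            raise ValueError("encoder_tag must be nonempty")

    @property
    def n_frames(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


def _to_gray(frames: np.ndarray) -> np.ndarray:
    """T x H x W x 3 uint8 -> T x H x W float32 luma in [0, 1]."""
    f = frames.astype(np.float32) / 255.0
    return 0.299 * f[..., 0] + 0.587 * f[..., 1] + 0.114 * f[..., 2]


def _avg_pool(img: np.ndarray, out: int) -> np.ndarray:
    """Average-pool a (T, H, W) stack to (T, out, out) with edge-aligned bins."""
    t, h, w = img.shape
    ry = np.minimum((np.arange(h) * out) // h, out - 1)
    rx = np.minimum((np.arange(w) * out) // w, out - 1)
    pooled = np.zeros((t, out, out), dtype=np.float32)
    counts = np.zeros((out, out), dtype=np.float32)
    np.add.at(counts, (ry[:, None].repeat(w, 1), rx[None, :].repeat(h, 0)), 1.0)
    for ti in range(t):
        acc = np.zeros((out, out), dtype=np.float32)
        np.add.at(acc, (ry[:, None].repeat(w, 1), rx[None, :].repeat(h, 0)), img[ti])
        pooled[ti] = acc / counts
    return pooled


class StubEncoder:
    """Deterministic linear-ReLU encoder for tests and synthetic pipelines.

    ``features = relu(P @ vec(avg_pool32(gray(frame))))`` with ``P`` drawn once
    from a fixed, documented seed, so output is bit-reproducible across
    machines and the Jacobian is simply ``P`` masked by the ReLU.
    """

    #: Seed of the fixed projection matrix; part of the encoder contract.
    PROJECTION_SEED = 20191121

    def __init__(self, n_features: int = N_FEATURES):
        rng = np.random.default_rng(self.PROJECTION_SEED)
        d = _STUB_POOL * _STUB_POOL
        self.projection = (rng.standard_normal((d, n_features)) / np.sqrt(d)).astype(np.float32)
        self.n_features = n_features
        self.tag = f"stub-v1-seed{self.PROJECTION_SEED}-f{n_features}"

    def encode_frames(self, frames: np.ndarray) -> np.ndarray:
        """Encode a (T, H, W, 3) uint8 stack to (T, F) features."""
        gray = _to_gray(np.asarray(frames))
        pooled = _avg_pool(gray, _STUB_POOL)
        flat = pooled.reshape(pooled.shape[0], -1)
        return np.maximum(flat @ self.projection, 0.0)

    def pre_activation(self, frames: np.ndarray) -> np.ndarray:
        """Pre-ReLU projection; homogeneous of degree 1 in pixel intensity."""
        gray = _to_gray(np.asarray(frames))
        pooled = _avg_pool(gray, _STUB_POOL)
        return pooled.reshape(pooled.shape[0], -1) @ self.projection

    def pixel_gradient(self, frames: np.ndarray, feature_grad: np.ndarray) -> np.ndarray:
        """Closed-form d(features)/d(pixels) pullback at the 32 x 32 scale.

        ``feature_grad`` is (T, F); returns (T, 32, 32) gradients w.r.t. the
        pooled grayscale image (the resize back to full frame geometry is the
        caller's concern).
        """
        pre = self.pre_activation(frames)
        masked = feature_grad * (pre > 0)
        g = masked @ self.projection.T
        return g.reshape(-1, _STUB_POOL, _STUB_POOL)


class PretrainedEncoder:
    """Inference-only wrapper around an external pretrained image encoder.

    The heavy convolutional backbone is consumed as an artifact: it needs a
    deep-learning runtime and a weight file, neither of which this package
    ships.  Constructing it without them raises an actionable error so
    pipelines fail fast rather than mid-run.
    """

    def __init__(self, weights_path: str | None = None):
        try:
            import tensorflow  # noqa: F401  pragma: no cover
        except ImportError as exc:
            raise EncoderConfigError(
                "the pretrained encoder backend needs a deep-learning runtime "
                "(tensorflow) and an Inception-V3 weight artifact; install the "
                "runtime and pass weights_path, or use backend='stub'"
            ) from exc
        if not weights_path:  # pragma: no cover
            raise EncoderConfigError(
                "pretrained backend requires weights_path pointing at the "
                "Inception-V3 weight artifact")
        self.weights_path = weights_path  # pragma: no cover
        self.tag = f"inception_v3@{weights_path}"  # pragma: no cover


def encode_clip(stack: FrameStack, backend: str | StubEncoder = "stub",
                **backend_kwargs) -> FeatureClip:
    """Encode a frame stack into a :class:`FeatureClip`.

    ``backend`` may be ``"stub"``, ``"pretrained"`` or an encoder instance.
    """
    if backend == "stub":
        enc = StubEncoder(**backend_kwargs)
    elif backend == "pretrained":
        enc = PretrainedEncoder(**backend_kwargs)  # raises without runtime
    elif hasattr(backend, "encode_frames"):
        enc = backend
    else:
        raise ValueError(f"unknown encoder backend {backend!r}")
    feats = enc.encode_frames(stack.frames)
    return FeatureClip(features=feats, trial_id=stack.trial_id,
                       encoder_tag=enc.tag)


def encoder_fidelity_check(backend: StubEncoder, n_probe: int = 4,
                           expected_features: int = N_FEATURES) -> dict:
    """Probe a backend and fail fast if it is mis-wired.

    Checks output dimensionality, non-negativity, and that responses vary
    across random probe images (a constant encoder is useless downstream).
    """
    rng = np.random.default_rng(0)
    probes = rng.integers(0, 256, size=(n_probe, 75, 75, 3), dtype=np.uint8)
    feats = backend.encode_frames(probes)
    if feats.shape[1] != expected_features:
        raise EncoderConfigError(
            f"backend {backend.tag!r} emits {feats.shape[1]} features, "
            f"expected {expected_features}")
    report = {
        "tag": backend.tag,
        "n_features": int(feats.shape[1]),
        "non_negative": bool(np.all(feats >= 0)),
        "response_variance": float(feats.var()),
    }
    if not report["non_negative"]:
        raise EncoderConfigError(f"backend {backend.tag!r} emits negative features")
    if report["response_variance"] == 0.0:
        raise EncoderConfigError(f"backend {backend.tag!r} is constant on probes")
    return report
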