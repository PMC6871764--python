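"""Knowledge extraction: which encoder features drive the scorer's output.

The workhorse is epsilon layer-wise relevance propagation (eps-LRP): the
output score is propagated backwards through the trained scorer, layer by
layer, each input receiving the share of relevance proportional to its
stabilized contribution ``a_i w_ij / (z_j + eps * sign(z_j))`` to the next
layer's pre-activation.  Through the recurrent scorer the rule is applied in
its modified-gradient form (every activation derivative replaced by the
stabilized ratio act(z)/(z + eps sign z)); multiplicative LSTM gates pass
relevance through both factors.  Gradient x input and plain saliency are
assumption-free cross-checks — on linear networks gradient x input coincides
with eps-LRP in the eps -> 0 limit.

Per-feature relevance is aggregated across frames and clips into a global
importance vector (mean absolute relevance), from which the most informative
features are selected for the discovery analytics.  Importance vectors from
scorers trained on different tasks are compared by correlating their
log-transformed values (importances span orders of magnitude).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .encoder import FeatureClip, StubEncoder
from .scorer import TrainedScorer

__all__ = [
    "RelevanceClip", "FeatureImportance",
    "elrp_relevance", "aggregate_importance", "compare_importance",
    "frame_saliency",
]


@dataclass
class RelevanceClip:
    """Signed per-frame, per-feature relevance for one clip's score."""

    relevance: np.ndarray          # T x F, signed
    output_value: float            # the scalar score being explained
    epsilon: float
    rule: str
    trial_id: str = ""
    output_index: int = 0

    def __post_init__(self):
        self.relevance = np.asarray(self.relevance)
        if not np.all(np.isfinite(self.relevance)):
            raise ValueError("non-finite relevance values")


@dataclass
class FeatureImportance:
    """Mean |relevance| per encoder feature, across frames and clips."""

    importance: np.ndarray
    n_clips: int
    model_tag: str = ""
    rule: str = "elrp"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.importance = np.asarray(self.importance, dtype=np.float64)
        if self.importance.ndim != 1:
            raise ValueError("importance must be a flat F-vector")
        if (self.importance < 0).any():
            raise ValueError("importance must be non-negative")


def elrp_relevance(model: TrainedScorer, clip: FeatureClip | np.ndarray,
                   epsilon: float = 1e-4, rule: str = "elrp",
                   output_index: int = 0) -> RelevanceClip:
    """Relevance of each input feature at each frame for one head output.

    ``rule`` selects the attribution method: ``"elrp"`` (the epsilon rule),
    ``"grad_x_input"`` (gradient times input) or ``"saliency"`` (absolute
    gradient).  The model must be trained; for eps-LRP ``epsilon`` must be
    positive.
    """
    if not model.is_trained:
        raise RuntimeError("attribution requires a trained scorer")
    feats = clip.features if isinstance(clip, FeatureClip) else np.asarray(clip)
    trial_id = clip.trial_id if isinstance(clip, FeatureClip) else ""

    if rule == "elrp":
        if epsilon <= 0:
            raise ValueError("epsilon must be > 0 for the elrp rule")
        rel, out = model.net.elrp(feats, output_index=output_index, epsilon=epsilon)
    elif rule in ("grad_x_input", "saliency"):
        grad = model.net.input_gradient(feats, output_index=output_index)
        rel = (grad * model.net.center_input(feats)
               if rule == "grad_x_input" else np.abs(grad))
        out = float(model.net.predict(feats)[0, output_index])
    else:
        raise ValueError(f"unknown attribution rule {rule!r}")
    return RelevanceClip(relevance=rel, output_value=float(out),
                         epsilon=epsilon, rule=rule, trial_id=trial_id,
                         output_index=output_index)


def aggregate_importance(relevances: list[RelevanceClip],
                         model_tag: str = "") -> FeatureImportance:
    """Global feature importance: mean |relevance| over frames and clips.

    Deterministic; duplicating the clip list leaves the result unchanged.
    """
    if not relevances:
        raise ValueError("no relevance clips to aggregate")
    shapes = {r.relevance.shape for r in relevances}
    if len({s[1] for s in shapes}) != 1:
        raise ValueError(f"inconsistent feature dimensions: {shapes}")
    per_clip = np.stack([np.abs(r.relevance).mean(axis=0) for r in relevances])
    rule = relevances[0].rule
    return FeatureImportance(importance=per_clip.mean(axis=0),
                             n_clips=len(relevances), model_tag=model_tag,
                             rule=rule,
                             meta={"epsilon": relevances[0].epsilon})


def compare_importance(a: FeatureImportance, b: FeatureImportance,
                       floor: float = 1e-12,
                       n_permutations: int = 0,
                       seed: int = 0) -> dict:
    """Correlate two importance vectors on the log scale.

    Importance values span orders of magnitude, so both vectors are floored
    at ``floor`` and log-transformed before computing a Pearson correlation.
    With ``n_permutations`` > 0 a permutation p-value for r > 0 is estimated
    by shuffling one vector.
    """
    ia, ib = a.importance, b.importance
    if ia.shape != ib.shape:
        raise ValueError(f"length mismatch: {ia.shape} vs {ib.shape}")
    la = np.log(np.maximum(ia, floor))
    lb = np.log(np.maximum(ib, floor))
    r, p = stats.pearsonr(la, lb)
    report = {"r": float(r), "p": float(p), "floor": floor, "n_features": ia.size}
    if n_permutations:
        rng = np.random.default_rng(seed)
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            null[i] = stats.pearsonr(la, rng.permutation(lb))[0]
        report["p_permutation"] = float((1 + np.sum(null >= r)) / (1 + n_permutations))
    return report


def frame_saliency(encoder: StubEncoder, model: TrainedScorer,
                   frames: np.ndarray, frame_index: int,
                   output_index: int = 0,
                   out_size: tuple[int, int] | None = None) -> np.ndarray:
    """Saliency map over pixels of one frame of a clip.

    The composed path encoder -> scorer is differentiated: the scorer's
    feature gradient at ``frame_index`` is pulled back through the encoder's
    Jacobian.  For the stub encoder this pullback is the closed form
    ``|P^T (grad * relu_mask)|`` at the encoder's internal 32 x 32 geometry,
    bilinearly resized to ``out_size`` (the frame size by default).
    Non-negative; a constant-output model yields all zeros.
    """
    if not hasattr(encoder, "pixel_gradient"):
        raise NotImplementedError(
            "saliency needs a differentiable encoder backend exposing "
            "pixel_gradient (the stub does; pixel-level propagation through "
            "an external pretrained backbone is out of scope)")
    feats = encoder.encode_frames(frames)
    grad = model.net.input_gradient(feats, output_index=output_index)  # T x F
    g32 = encoder.pixel_gradient(frames, grad)[frame_index]            # 32 x 32
    sal = np.abs(g32)
    h, w = out_size if out_size is not None else frames.shape[1:3]
    if (h, w) != sal.shape:
        from PIL import Image
        img = Image.fromarray(sal.astype(np.float32), mode="F")
        sal = np.asarray(img.resize((w, h), Image.BILINEAR))
    return sal
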