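"""The recurrent deficit scorer: build, train, cross-validate, predict.

One architecture serves four tasks through interchangeable dense heads on the
same LSTM -> temporal-max-pool -> dropout trunk:

* ``cumulative`` — one ReLU output regressing the expert's summed deficit
  score (0-7) for a whole 125-frame trial;
* ``elements`` — seven sigmoid outputs, one per scored movement element;
* ``categorical`` — two sigmoid "votes" (stroke, control) trained on group
  labels only; their combination ``Nsc = (n0 + (1 - n1)) / 2`` yields a
  continuous severity score from purely categorical supervision;
* ``lesion`` — one sigmoid output regressing normalized lesion volume;
* ``element_class`` — a softmax classifier over movement-element categories,
  trained on short (7-frame) labeled windows and used to segment continuous
  video into movement elements.

Regression heads train with Adam + mean squared error (batch 8, learning rate
1e-6 over 1,000 epochs in the full-scale parity preset; CPU-sized runs use a
few dozen epochs at a raised rate).  Generalization is always reported under
leave-one-animal-out (or leave-one-day-out) cross-validation: every trial is
predicted by a model whose training set excluded that animal (or day).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import grammar
from .encoder import FeatureClip
from .nn import LSTMScorerNet, Adam, mse_loss, cross_entropy_loss

__all__ = [
    "ScorerArchitecture", "TrainHyper", "TrainedScorer", "PredictionTable",
    "build_scorer", "train_scorer", "predict_score", "compute_nsc",
    "crossvalidate", "segment_movements", "evaluate_segmentation",
    "make_segment_dataset", "targets_for_head", "DivergenceError", "DataError",
]

#: head kind -> (n_outputs or None for configurable, activation)
_HEADS = {
    "cumulative": (1, "relu"),
    "elements": (7, "sigmoid"),
    "categorical": (2, "sigmoid"),
    "lesion": (1, "sigmoid"),
    "element_class": (None, "softmax"),
}


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


class DataError(ValueError):
    """Targets and clips are misaligned or incompatible with the head."""


@dataclass
class ScorerArchitecture:
    """Scorer hyper-structure.

    ``lstm_units`` defaults to 2,048 for parity with the full-scale model;
    CPU-sized runs use 32-64 (the architecture is robust to such changes).
    ``temporal_pool`` is global max over all timesteps by default.
    """

    n_features: int = 2048
    lstm_units: int = 2048
    temporal_pool: str = "global_max"
    dropout_rate: float = 0.1
    head: str = "cumulative"
    n_classes: int = len(grammar.ALL_CATEGORIES)

    def __post_init__(self):
        if self.head not in _HEADS:
            raise ValueError(f"unknown head {self.head!r}; one of {sorted(_HEADS)}")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.lstm_units < 1:
            raise ValueError("lstm_units must be >= 1")
        if self.temporal_pool != "global_max":
            raise ValueError("only global_max temporal pooling is implemented")

    @property
    def n_outputs(self) -> int:
        n, _ = _HEADS[self.head]
        return self.n_classes if n is None else n

    @property
    def head_activation(self) -> str:
        return _HEADS[self.head][1]


@dataclass
class TrainHyper:
    """Optimization hyperparameters (Adam + MSE; batch 8, lr 1e-6, 1,000
    epochs in the parity preset)."""

    learning_rate: float = 1e-6
    batch_size: int = 8
    epochs: int = 1000
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")

    @classmethod
    def cpu_preset(cls, epochs: int = 40, seed: int = 0,
                   weight_decay: float = 0.1) -> "TrainHyper":
        """Scaled-down budget for CPU-sized runs on synthetic cohorts.

        Raised learning rate, moderate batch, and decoupled weight decay:
        the decay shrinks weights on feature dimensions that never carry
        coherent gradient, which keeps relevance attribution sharp."""
        return cls(learning_rate=1e-3, batch_size=32, epochs=epochs,
                   weight_decay=weight_decay, seed=seed)


@dataclass
class TrainedScorer:
    """A scorer network plus its architecture and training manifest."""

    architecture: ScorerArchitecture
    net: LSTMScorerNet
    manifest: dict = field(default_factory=dict)

    @property
    def head(self) -> str:
        return self.architecture.head

    @property
    def is_trained(self) -> bool:
        return bool(self.manifest.get("epochs_run", 0))

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.net.params.values()))


def build_scorer(arch: ScorerArchitecture, seed: int = 0) -> TrainedScorer:
    """Instantiate an untrained scorer for ``arch``.

    Layer order: per-timestep LSTM outputs -> temporal max-pool -> flatten ->
    dropout -> dense head.  Weight init is Glorot uniform from ``seed``.
    """
    net = LSTMScorerNet(
        n_features=arch.n_features, lstm_units=arch.lstm_units,
        n_outputs=arch.n_outputs, head_activation=arch.head_activation,
        dropout_rate=arch.dropout_rate, seed=seed)
    manifest = {"architecture": asdict(arch), "init_seed": seed,
                "n_parameters": int(sum(p.size for p in net.params.values()))}
    return TrainedScorer(architecture=arch, net=net, manifest=manifest)


def _stack_features(clips: list[FeatureClip]) -> np.ndarray:
    lens = {c.features.shape for c in clips}
    if len(lens) != 1:
        raise DataError(f"clips disagree on shape: {sorted(lens)}")
    return np.stack([c.features for c in clips])


def _check_targets(arch: ScorerArchitecture, targets: np.ndarray, n: int) -> np.ndarray:
    t = np.asarray(targets, dtype=np.float32)
    if t.ndim == 1:
        t = t[:, None]
    if t.shape[0] != n:
        raise DataError(f"{t.shape[0]} targets for {n} clips")
    if t.shape[1] != arch.n_outputs:
        raise DataError(
            f"head {arch.head!r} expects {arch.n_outputs} target column(s), got {t.shape[1]}")
    if arch.head == "cumulative" and (t.min() < 0 or t.max() > 7):
        raise DataError("cumulative targets must lie in [0, 7]")
    if arch.head in ("elements",) and not np.isin(t, [0.0, 0.5, 1.0]).all():
        raise DataError("element targets must be on the {0, 0.5, 1} scale")
    if arch.head in ("categorical", "lesion", "element_class") and (
            t.min() < 0 or t.max() > 1):
        raise DataError(f"{arch.head} targets must lie in [0, 1]")
    return t


def train_scorer(model: TrainedScorer, clips: list[FeatureClip],
                 targets: np.ndarray, hyper: TrainHyper,
                 x: np.ndarray | None = None) -> TrainedScorer:
    """Train ``model`` in place on aligned (clips, targets).

    Mini-batch Adam with the head's loss (MSE for regression heads,
    cross-entropy for the softmax classifier); steps per epoch =
    n_training_clips / batch_size, with a seeded shuffle each epoch.  The
    manifest records seed, epochs run and the per-epoch loss curve, enough to
    re-run training bit-comparably on the same platform.

    ``x`` optionally supplies the pre-stacked (N, T, F) feature array to
    avoid re-stacking in repeated calls.
    """
    if x is None:
        x = _stack_features(clips)
    t = _check_targets(model.architecture, targets, x.shape[0])
    net = model.net
    # Center inputs on the training-set feature mean (encoder activations
    # have a large positive offset that would saturate the LSTM gates).
    net.input_center = x.mean(axis=(0, 1), dtype=np.float64).astype(np.float32)
    softmax = model.architecture.head_activation == "softmax"
    if model.architecture.head_activation == "relu":
        # Warm-start the head bias at the mean target so the rectified
        # output unit starts alive and on the target scale; a dead output
        # unit would receive no gradient at all.
        probe = x[: min(64, x.shape[0])]
        _, cache0 = net.forward(probe, keep_cache=True)
        pre_wo_bias = cache0.head_pre - net.params["bd"]
        net.params["bd"][:] = np.maximum(
            t.mean(axis=0) - pre_wo_bias.mean(axis=0), 0.1)

    opt = Adam(net.params, lr=hyper.learning_rate,
               weight_decay=hyper.weight_decay)
    rng = np.random.default_rng(hyper.seed)
    n = x.shape[0]
    losses: list[float] = []
    for epoch in range(hyper.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        nb = 0
        for start in range(0, n, hyper.batch_size):
            idx = order[start:start + hyper.batch_size]
            xb, tb = x[idx], t[idx]
            y, cache = net.forward(xb, train=True, rng=rng, keep_cache=True)
            if softmax:
                loss, dy_pre = cross_entropy_loss(y, tb)
            else:
                loss, dy = mse_loss(y, tb)
                dy_pre = net.head_pre_grad(cache, dy)
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch + 1}")
            grads, _ = net.backward(cache, dy_pre)
            opt.step(net.params, grads)
            epoch_loss += loss
            nb += 1
        losses.append(epoch_loss / max(nb, 1))

    model.manifest.update({
        "hyper": asdict(hyper),
        "epochs_run": hyper.epochs,
        "loss_curve": losses,
        "n_training_clips": int(n),
        "train_trial_ids": [c.trial_id for c in clips],
        "data_fingerprint": float(np.float64(x).sum()),
    })
    return model


def predict_score(model: TrainedScorer, clip: FeatureClip | np.ndarray) -> np.ndarray:
    """Predict head outputs for one clip (dropout inactive)."""
    feats = clip.features if isinstance(clip, FeatureClip) else np.asarray(clip)
    if feats.shape[-1] != model.architecture.n_features:
        raise DataError(
            f"clip has {feats.shape[-1]} features, model expects "
            f"{model.architecture.n_features}")
    return model.net.predict(feats)[0]


def predict_batch(model: TrainedScorer, clips: list[FeatureClip],
                  batch: int = 64) -> np.ndarray:
    x = _stack_features(clips)
    outs = [model.net.predict(x[i:i + batch]) for i in range(0, len(x), batch)]
    return np.concatenate(outs, axis=0)


def compute_nsc(votes) -> float:
    """Continuous deficit score from the two categorical votes.

    ``Nsc = (n0 + (1 - n1)) / 2`` where n0 is the stroke vote and n1 the
    control vote; increasing in n0, decreasing in n1, bounded in [0, 1].
    """
    n0, n1 = float(votes[0]), float(votes[1])
    if not (0.0 <= n0 <= 1.0 and 0.0 <= n1 <= 1.0):
        raise ValueError(f"votes must lie in [0, 1], got ({n0}, {n1})")
    return (n0 + (1.0 - n1)) / 2.0


@dataclass
class PredictionTable:
    """Held-out predictions, one row per trial, with fold identity."""

    df: pd.DataFrame = field(repr=False)

    def per_animal_means(self, column: str = "pred") -> pd.Series:
        return self.df.groupby("animal_id")[column].mean()

    def per_day_means(self, column: str = "pred") -> pd.Series:
        return self.df.groupby("day")[column].mean()


def crossvalidate(clips: list[FeatureClip], targets: np.ndarray,
                  arch: ScorerArchitecture, hyper: TrainHyper,
                  scheme: str = "leave_one_animal_out",
                  max_train_clips_per_unit: int | None = None) -> PredictionTable:
    """Cross-validated held-out predictions.

    ``scheme`` is ``leave_one_animal_out`` (fold per animal) or
    ``leave_one_day_out`` (fold per recording day).  One model is trained per
    fold; every trial is predicted exactly once, by the model whose training
    set excluded that trial's held-out unit.  ``max_train_clips_per_unit``
    optionally subsamples the training side (deterministically, by trial
    order) to bound CPU cost on large cohorts.
    """
    if scheme == "leave_one_animal_out":
        unit = np.array([c.animal_id for c in clips])
    elif scheme == "leave_one_day_out":
        unit = np.array([c.day for c in clips])
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    units = sorted(set(unit.tolist()))
    if len(units) < 2:
        raise ValueError(f"{scheme} needs >= 2 units, found {len(units)}")

    targets = np.asarray(targets, dtype=np.float32)
    if targets.ndim == 1:
        targets = targets[:, None]
    if len(targets) != len(clips):
        raise DataError(f"{len(targets)} targets for {len(clips)} clips")

    x_all = _stack_features(clips)
    rows = []
    for fold, held in enumerate(units):
        test_mask = unit == held
        train_idx = np.flatnonzero(~test_mask)
        if train_idx.size == 0:
            raise ValueError(f"fold {held!r} has an empty training set")
        if max_train_clips_per_unit is not None:
            keep = []
            for u in units:
                if u == held:
                    continue
                ui = np.flatnonzero(unit == u)
                if ui.size > max_train_clips_per_unit:
                    # evenly spaced picks cover all days/sessions of the unit
                    pick = np.linspace(0, ui.size - 1,
                                       max_train_clips_per_unit).round().astype(int)
                    ui = ui[np.unique(pick)]
                keep.append(ui)
            train_idx = np.sort(np.concatenate(keep))
        model = build_scorer(arch, seed=hyper.seed + fold)
        train_scorer(model, [clips[i] for i in train_idx], targets[train_idx],
                     hyper, x=x_all[train_idx])
        model.manifest["fold"] = {"scheme": scheme, "held_out": str(held),
                                  "n_train": int(train_idx.size)}
        test_idx = np.flatnonzero(test_mask)
        preds = model.net.predict(x_all[test_idx])
        for j, i in enumerate(test_idx):
            c = clips[i]
            row = {"trial_id": c.trial_id, "animal_id": c.animal_id,
                   "day": c.day, "group": c.group, "fold": str(held)}
            if preds.shape[1] == 1:
                row["pred"] = float(preds[j, 0])
            else:
                for k in range(preds.shape[1]):
                    row[f"pred_{k}"] = float(preds[j, k])
                if arch.head == "categorical":
                    row["nsc"] = compute_nsc(preds[j])
            if targets.shape[1] == 1:
                row["target"] = float(targets[i, 0])
            rows.append(row)
    df = pd.DataFrame(rows)
    assert len(df) == len(clips) and df["trial_id"].is_unique
    return PredictionTable(df=df)


# -- movement-element segmentation ------------------------------------------

def make_segment_dataset(clips: list[FeatureClip], timelines: dict[str, list[str]],
                         window: int = 7) -> tuple[list[FeatureClip], np.ndarray, list[str]]:
    """Cut clips into labeled ``window``-frame segments for classifier training.

    Each segment's label is the modal frame category within the window (ties
    toward the earlier grammar position).  Returns (segment clips, one-hot
    targets, class names).
    """
    classes = list(grammar.ALL_CATEGORIES)
    cls_idx = {c: i for i, c in enumerate(classes)}
    segs: list[FeatureClip] = []
    labels: list[int] = []
    for clip in clips:
        tl = timelines[clip.trial_id]
        n_win = clip.n_frames // window
        for w in range(n_win):
            frame_labels = tl[w * window:(w + 1) * window]
            vals, counts = np.unique(frame_labels, return_counts=True)
            top = counts.max()
            cands = [v for v, c in zip(vals, counts) if c == top]
            lab = min(cands, key=lambda v: (grammar.ORDINAL_POSITION[v],
                                            grammar.CATEGORY_INDEX[v]))
            segs.append(FeatureClip(
                features=clip.features[w * window:(w + 1) * window],
                trial_id=f"{clip.trial_id}_w{w}", animal_id=clip.animal_id,
                day=clip.day, group=clip.group, encoder_tag=clip.encoder_tag))
            labels.append(cls_idx[lab])
    onehot = np.eye(len(classes), dtype=np.float32)[labels]
    return segs, onehot, classes


def segment_movements(model: TrainedScorer, clip: FeatureClip,
                      window: int = 7) -> tuple[np.ndarray, list[str]]:
    """Classify consecutive non-overlapping ``window``-frame segments.

    Returns (probabilities of shape (n_windows, n_classes) summing to 1 per
    row, predicted category per window).  Trailing frames that do not fill a
    window are dropped; argmax ties break toward the earlier grammar
    position.
    """
    if model.architecture.head != "element_class":
        raise ValueError("segment_movements needs an element_class head")
    if clip.n_frames < window:
        raise ValueError(
            f"clip has {clip.n_frames} frames, shorter than window {window}")
    classes = model.manifest.get("classes", list(grammar.ALL_CATEGORIES))
    n_win = clip.n_frames // window
    x = clip.features[:n_win * window].reshape(n_win, window, -1)
    probs = model.net.predict(x)
    order = np.array([(grammar.ORDINAL_POSITION[c], grammar.CATEGORY_INDEX[c])
                      for c in classes])
    timeline = []
    for row in probs:
        best = np.flatnonzero(row == row.max())
        pick = best[np.lexsort((order[best, 1], order[best, 0]))[0]]
        timeline.append(classes[pick])
    return probs, timeline


def evaluate_segmentation(pred_timeline: list[str], true_timeline: list[str],
                          tolerance: int = 1) -> dict[str, float]:
    """Accuracy / macro precision / macro recall of a predicted timeline.

    A window counts as a success when the predicted category sits within
    ``tolerance`` ordinal movement-element positions of the true one (the
    +/-1-category convention).  Precision and recall are macro-averaged over
    the true/predicted classes present.  All values are percentages.
    """
    if len(pred_timeline) != len(true_timeline):
        raise ValueError("timelines differ in length")
    pred_pos = np.array(grammar.positions_of(pred_timeline))
    true_pos = np.array(grammar.positions_of(true_timeline))
    success = np.abs(pred_pos - true_pos) <= tolerance
    pred = np.array(pred_timeline)
    true = np.array(true_timeline)

    recalls = [success[true == c].mean() for c in np.unique(true)]
    precisions = [success[pred == c].mean() for c in np.unique(pred)]
    return {
        "accuracy": float(success.mean() * 100.0),
        "precision": float(np.mean(precisions) * 100.0),
        "recall": float(np.mean(recalls) * 100.0),
    }


def targets_for_head(head: str, score_df: pd.DataFrame,
                     clips: list[FeatureClip]) -> np.ndarray:
    """Align a score table to ``clips`` and extract the head's targets.

    ``cumulative`` -> (N, 1) summed scores; ``elements`` -> (N, 7);
    ``categorical`` -> one-hot (stroke, control) from the group label;
    ``lesion`` -> (N, 1) min-max normalized lesion volume.
    """
    df = score_df.set_index("trial_id")
    missing = [c.trial_id for c in clips if c.trial_id not in df.index]
    if missing:
        raise DataError(f"score table lacks trials: {missing[:5]}...")
    sub = df.loc[[c.trial_id for c in clips]]
    if head == "cumulative":
        return sub["cumulative"].to_numpy(dtype=np.float32)[:, None]
    if head == "elements":
        return sub[list(grammar.SCORED_ELEMENTS)].to_numpy(dtype=np.float32)
    if head == "categorical":
        g = sub["group"].to_numpy(dtype=np.float32)
        return np.stack([g, 1.0 - g], axis=1)
    if head == "lesion":
        v = sub["lesion_volume"].to_numpy(dtype=np.float32)
        rng = v.max() - v.min()
        if rng == 0:
            raise DataError("lesion volumes are constant; cannot normalize")
        return ((v - v.min()) / rng)[:, None]
    raise ValueError(f"no automatic targets for head {head!r}")
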