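"""Synthetic reaching cohort with planted ground truth.

The study's animal videos are not deposited, so every downstream stage is
exercised on a generated cohort that emulates the structure of the real
experiment: animals recorded over five days (one pre-lesion, four during
recovery), twenty reaching trials per day, each trial a 125-frame clip of
2,048 encoder features per frame.

What is planted, and what each downstream stage should recover:

* **Severity trajectories** — each stroke animal carries a latent severity
  ``sigma`` in [0, 1]: zero before lesion, maximal on day 1, decaying
  geometrically over recovery days.  Controls stay at zero.
* **A movement-element grammar** — every trial is a contiguous sequence of
  reach elements in canonical order (lift ... supination II, then eating).
  With probability increasing in sigma the mid-reach elements are replaced by
  the compensatory "reach with mouth"; the normal terminal "eat with both
  hands" is emitted only when sigma is low, otherwise generic one-handed
  eating.  These condition-specific categories are what the clustering stage
  should rediscover.
* **An informative feature subset F\\*** — category identity and the
  severity-dependent impairment shift live only on ``informative_set_size``
  of the feature dimensions.  Off-F* dimensions carry a shared baseline,
  day-specific nuisance offsets (emulating day-to-day recording drift) and
  AR(1) noise, and are statistically independent of sigma and category.
  Feature attribution should therefore recover F*.
* **Expert scores** — each of the seven elements is scored by thresholding
  sigma plus rater noise onto the 0 / 0.5 / 1 scale; the cumulative score is
  their sum.
* **Lesion volumes** — a monotone function of peak severity plus noise;
  exactly zero for controls.

Within-trial feature noise and timeline jitter are amplified with sigma, so
post-lesion trajectories are less reproducible than pre-lesion ones — the
planted analogue of increased movement variability after stroke.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import grammar
from .encoder import FeatureClip
from .io_media import ScoreTable

__all__ = ["CohortConfig", "SyntheticCohort", "CohortModel",
           "generate_cohort", "generate_trial", "render_frames"]


@dataclass
class CohortConfig:
    """Generator parameters; the defaults define the standard study conditions.

    Sizes mirror the real experiment (half-stroke cohort, days -1/1/6/11/15,
    20 trials per session, 2,048 features of which 200 are informative).
    ``severity_day1`` is the mean day-1 severity of stroke animals (each
    animal's own level is jittered around it); ``recovery_rate`` the per-day
    geometric decay of severity during recovery.  ``rater_noise_sd`` is the
    scoring noise on the 0-1 severity scale before thresholding onto
    {0, 0.5, 1}.
    """

    n_animals: int = 8
    fraction_stroke: float = 0.5
    days: tuple[int, ...] = (-1, 1, 6, 11, 15)
    trials_per_day: int = 20
    clip_len: int = 125
    n_features: int = 2048
    informative_set_size: int = 200
    severity_day1: float = 0.8
    recovery_rate: float = 0.1
    noise_sd: float = 0.3
    ar1_rho: float = 0.6
    nuisance_day_sd: float = 0.2
    contaminate_informative: bool = False
    rater_noise_sd: float = 0.08
    mouth_prob_max: float = 0.8
    eat_hands_threshold: float = 0.25
    severity_noise_gain: float = 1.0
    lesion_scale: float = 50.0
    lesion_noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.informative_set_size <= self.n_features):
            raise ValueError("need 0 < informative_set_size <= n_features")
        if not (0.0 <= self.fraction_stroke <= 1.0):
            raise ValueError("fraction_stroke must be in [0, 1]")
        if not (0.0 <= self.ar1_rho < 1.0):
            raise ValueError("ar1_rho must be in [0, 1)")
        if self.trials_per_day * len(self.days) == 0:
            raise ValueError("empty cohort: trials_per_day x days must be > 0")


# Mean frame budget per element of a normal reach; the remainder of the
# 125-frame clip is the terminal eating phase.
_ELEMENT_MEAN_FRAMES = {
    "lift": 8, "aim": 8, "advance": 10, "pronation": 8,
    "grasp": 10, "supination_i": 8, "supination_ii": 8,
}
# Mid-reach phase replaced by compensatory mouth-reaching.
_MOUTH_REPLACES = ("advance", "pronation", "grasp", "supination_i", "supination_ii")


class CohortModel:
    """Frozen random structure of one cohort: prototypes, F*, day offsets."""

    def __init__(self, config: CohortConfig, seed_seq: np.random.SeedSequence):
        rng = np.random.default_rng(seed_seq)
        cfg = config
        self.config = cfg
        self.informative = np.sort(rng.choice(
            cfg.n_features, size=cfg.informative_set_size, replace=False))
        mask = np.zeros(cfg.n_features, dtype=bool)
        mask[self.informative] = True
        self.informative_mask = mask
        # Shared positive baseline on every dimension.  Kept well above zero
        # so the final rectification almost never clips off-F* dimensions:
        # clipping would otherwise couple their means to the severity-scaled
        # noise variance, breaking the planted independence from sigma.
        self.baseline = (2.5 + np.abs(rng.normal(0.0, 0.5, cfg.n_features))).astype(np.float32)
        # Category prototypes and impairment shifts, supported on F* only.
        ncat = len(grammar.ALL_CATEGORIES)
        self.cat_proto = rng.normal(0.0, 1.0, (ncat, cfg.informative_set_size)).astype(np.float32)
        self.impair_shift = rng.normal(0.0, 0.8, (ncat, cfg.informative_set_size)).astype(np.float32)
        # Day-specific recording nuisance (off-F* unless contamination is on).
        self.day_offsets = {}
        for d in cfg.days:
            off = rng.normal(0.0, cfg.nuisance_day_sd, cfg.n_features).astype(np.float32)
            if not cfg.contaminate_informative:
                off[self.informative] = 0.0
            self.day_offsets[int(d)] = off


def _timeline(model: CohortModel, sigma: float, rng: np.random.Generator) -> list[str]:
    cfg = model.config
    jitter_sd = 0.15 * (1.0 + cfg.severity_noise_gain * sigma)
    durs = {}
    for e, mean in _ELEMENT_MEAN_FRAMES.items():
        durs[e] = max(1, int(round(mean * rng.lognormal(0.0, jitter_sd))))
    labels: list[str] = []
    for e in grammar.SCORED_ELEMENTS:
        labels.extend([e] * durs[e])
    # Compensatory substitution: mouth-reaching replaces the mid-reach phase.
    if rng.random() < cfg.mouth_prob_max * sigma:
        labels = [grammar.REACH_WITH_MOUTH if lab in _MOUTH_REPLACES else lab
                  for lab in labels]
    terminal = (grammar.EAT_WITH_HANDS if sigma < cfg.eat_hands_threshold
                else grammar.EAT)
    if len(labels) >= cfg.clip_len:
        labels = labels[:cfg.clip_len - 1] + [terminal]
    else:
        labels.extend([terminal] * (cfg.clip_len - len(labels)))
    return labels


def generate_trial(model: CohortModel, sigma: float,
                   rng: np.random.Generator | int,
                   trial_id: str = "trial", animal_id: str = "a0",
                   day: int = 0, group: int = 0) -> tuple[FeatureClip, list[str]]:
    """Generate one trial: a feature clip plus its per-frame element timeline.

    Features are ``baseline + prototype(category) + sigma * impairment shift
    + day nuisance + AR(1) noise``, rectified at zero; category structure and
    the severity shift live on F* only, so off-F* dimensions deviate from
    baseline only by noise, independently of ``sigma``.
    """
    if not (0.0 <= sigma <= 1.0):
        raise ValueError("sigma must be in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cfg = model.config
    labels = _timeline(model, sigma, rng)
    cat_idx = np.array([grammar.CATEGORY_INDEX[lab] for lab in labels])

    feats = np.tile(model.baseline, (cfg.clip_len, 1)).astype(np.float32)
    feats[:, model.informative] += (model.cat_proto[cat_idx]
                                    + np.float32(sigma) * model.impair_shift[cat_idx])
    feats += model.day_offsets.get(int(day), 0.0)

    # Stationary AR(1) noise per dimension, variance amplified with severity.
    sd = cfg.noise_sd * (1.0 + cfg.severity_noise_gain * sigma)
    innov_sd = sd * np.sqrt(1.0 - cfg.ar1_rho ** 2)
    eps = rng.normal(0.0, innov_sd, (cfg.clip_len, cfg.n_features))
    noise = lfilter([1.0], [1.0, -cfg.ar1_rho], eps, axis=0)
    feats += noise.astype(np.float32)

    np.maximum(feats, 0.0, out=feats)
    clip = FeatureClip(features=feats, trial_id=trial_id, animal_id=animal_id,
                       day=int(day), group=int(group),
                       encoder_tag="synthetic-cohort-v1")
    return clip, labels


def _severity(cfg: CohortConfig, day1_level: float, day: int) -> float:
    if day <= 0 or day1_level == 0.0:
        return 0.0
    return float(np.clip(day1_level * (1.0 - cfg.recovery_rate) ** (day - 1), 0.0, 1.0))


def _score_elements(sigma: float, rng: np.random.Generator,
                    noise_sd: float) -> np.ndarray:
    """Three-point expert scoring: 0 if sigma+noise < 1/3, 0.5 if < 2/3, else 1."""
    eta = rng.normal(0.0, noise_sd, len(grammar.SCORED_ELEMENTS))
    v = sigma + eta
    return np.where(v < 1.0 / 3.0, 0.0, np.where(v < 2.0 / 3.0, 0.5, 1.0))


@dataclass
class SyntheticCohort:
    """A generated cohort plus its planted truth.

    ``truth`` keys: ``informative_features`` (sorted index array),
    ``severity`` (``{animal_id: {day: sigma}}``), ``timelines``
    (``{trial_id: [category per frame]}``), ``lesion`` (``{animal_id: mm^3}``)
    and ``config`` (the generating parameters).
    """

    clips: list[FeatureClip]
    scores: ScoreTable
    truth: dict = field(repr=False)

    @property
    def config(self) -> CohortConfig:
        return CohortConfig(**self.truth["config"])

    def save(self, cache_path: str, table_path: str, truth_path: str) -> None:
        """Serialize to the HDF5 feature cache + CSV table + truth JSON."""
        from .io_media import cache_features, write_score_table
        cache_features(self.clips, cache_path)
        write_score_table(self.scores, table_path)
        truth = dict(self.truth)
        truth["informative_features"] = [int(i) for i in truth["informative_features"]]
        with open(truth_path, "w") as fh:
            json.dump(truth, fh)


def generate_cohort(config: CohortConfig | None = None, **overrides) -> SyntheticCohort:
    """Generate a full synthetic cohort under ``config``.

    All randomness flows from ``config.seed`` through named substreams
    (cohort structure, per-trial noise, rater noise), so the same config
    yields a bit-identical cohort.
    """
    if config is None:
        config = CohortConfig(**overrides)
    elif overrides:
        config = CohortConfig(**{**asdict(config), **overrides})
    cfg = config

    root = np.random.SeedSequence(cfg.seed)
    ss_model, ss_animals, ss_trials, ss_rater = root.spawn(4)
    model = CohortModel(cfg, ss_model)
    arng = np.random.default_rng(ss_animals)
    rater_rng = np.random.default_rng(ss_rater)
    trial_rngs = iter(ss_trials.spawn(cfg.n_animals * len(cfg.days) * cfg.trials_per_day))

    n_stroke = int(round(cfg.fraction_stroke * cfg.n_animals))
    groups = [1] * n_stroke + [0] * (cfg.n_animals - n_stroke)
    day1_levels = [
        float(np.clip(cfg.severity_day1 * arng.uniform(0.8, 1.2), 0.0, 1.0))
        if g == 1 else 0.0
        for g in groups
    ]
    lesions = {}
    clips: list[FeatureClip] = []
    rows = []
    severity_truth: dict[str, dict[str, float]] = {}
    timelines: dict[str, list[str]] = {}

    for a in range(cfg.n_animals):
        animal_id = f"animal{a:02d}"
        group = groups[a]
        peak = max(_severity(cfg, day1_levels[a], d) for d in cfg.days)
        if group == 1:
            lesions[animal_id] = float(max(
                0.0, cfg.lesion_scale * peak + arng.normal(0.0, cfg.lesion_noise_sd)))
        else:
            lesions[animal_id] = 0.0
        severity_truth[animal_id] = {}
        for d in cfg.days:
            sigma = _severity(cfg, day1_levels[a], d)
            severity_truth[animal_id][str(d)] = sigma
            for k in range(cfg.trials_per_day):
                trial_id = f"{animal_id}_d{d}_t{k:03d}"
                trng = np.random.default_rng(next(trial_rngs))
                clip, labels = generate_trial(
                    model, sigma, trng, trial_id=trial_id, animal_id=animal_id,
                    day=d, group=group)
                clips.append(clip)
                timelines[trial_id] = labels
                el = _score_elements(sigma, rater_rng, cfg.rater_noise_sd)
                rows.append({
                    "animal_id": animal_id, "day": d, "trial_id": trial_id,
                    "group": group, "rater_id": "synthetic_expert",
                    **dict(zip(grammar.SCORED_ELEMENTS, el)),
                    "cumulative": float(el.sum()),
                    "lesion_volume": lesions[animal_id],
                })

    scores = ScoreTable(df=pd.DataFrame(rows))
    truth = {
        "informative_features": model.informative,
        "severity": severity_truth,
        "timelines": timelines,
        "lesion": lesions,
        "config": asdict(cfg),
    }
    return SyntheticCohort(clips=clips, scores=scores, truth=truth)


# -- optional geometric rendering -------------------------------------------

_CAT_ANGLE = {c: np.pi * (0.15 + 0.07 * i)
              for i, c in enumerate(grammar.ALL_CATEGORIES)}


def render_frames(timeline: list[str], sigma: float = 0.0, seed: int = 0,
                  size: int = 300) -> np.ndarray:
    """Render a timeline as simple geometric scenes (T x size x size x 3).

    A limb segment rotates with the current movement element; severity tilts
    the angle.  Not photorealistic — just enough structure that an image
    encoder sees element- and impairment-dependent pixels, enabling true
    end-to-end runs.  Deterministic given (timeline, sigma, seed).
    """
    t = len(timeline)
    frames = np.full((t, size, size, 3), 30, dtype=np.uint8)
    shoulder = (size * 3 // 4, size // 2)
    length = size // 3
    # pellet marker, fixed across frames
    py, px = size // 3, size // 2
    frames[:, py - 4:py + 4, px - 4:px + 4, :] = 200
    for i, lab in enumerate(timeline):
        ang = _CAT_ANGLE[lab] + 0.35 * sigma
        n = 2 * length
        rr = (shoulder[0] - np.sin(np.linspace(0, ang, n)) * np.linspace(0, length, n)).astype(int)
        cc = (shoulder[1] + np.cos(np.linspace(0, ang, n)) * np.linspace(0, length, n)).astype(int)
        ok = (rr >= 1) & (rr < size - 1) & (cc >= 1) & (cc < size - 1)
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                frames[i, rr[ok] + dy, cc[ok] + dx, :] = 255
    return frames
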