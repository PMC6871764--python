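"""Statistical comparisons of network, expert, and anatomical severity.

Per-animal mean scores from the network and the expert are min-max normalized
to [0, 1] alongside lesion volumes so all three live on one scale; which
score sits closer to the anatomical ground truth is tested by a Wilcoxon
signed-rank test on the paired per-animal distances (z-score normalization
gives the same conclusions and is available as a variant).  Inter-rater
agreement is summarized by the mean absolute per-animal score difference
(± SEM over animals) and compared between raters by paired t-tests.  Lesion
volume is also predicted from the seven per-element scores by least-squares
regression under leave-one-animal-out cross-validation, which weights each
movement element instead of using their plain sum.  For the parallel-beam
walking task the composite motor-disability score is the mean of three
min-max-normalized measures (paw-placement deviation, traversal time,
placing attempts per step).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementReport", "BeamScore",
    "minmax_normalize", "zscore_normalize", "lesion_agreement",
    "rater_discrepancy", "regress_lesion_from_elements", "beam_composite",
    "mean_trials_per_animal",
]


def minmax_normalize(values) -> np.ndarray:
    """Map values to [0, 1] by ``(x - min) / (max - min)``.

    Raises on constant input (degenerate range); rank order is preserved, so
    min-max and z-score normalizations agree on all orderings.
    """
    x = np.asarray(values, dtype=np.float64)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("cannot min-max normalize a constant series")
    return (x - lo) / (hi - lo)


def zscore_normalize(values) -> np.ndarray:
    x = np.asarray(values, dtype=np.float64)
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot z-score a constant series")
    return (x - x.mean()) / sd


@dataclass
class AgreementReport:
    """Normalized per-animal scores and their agreement with lesion volume."""

    animals: list
    net_norm: np.ndarray
    expert_norm: np.ndarray
    lesion_norm: np.ndarray
    net_distance: np.ndarray       # |net - lesion| per animal
    expert_distance: np.ndarray
    wilcoxon_stat: float
    wilcoxon_p: float
    r_net_lesion: float
    p_net_lesion: float
    r_expert_lesion: float
    p_expert_lesion: float
    normalization: str = "minmax"


def _wilcoxon(d_a: np.ndarray, d_b: np.ndarray) -> tuple[float, float]:
    diff = d_a - d_b
    if np.allclose(diff, 0):
        return 0.0, 1.0
    n = np.count_nonzero(diff)
    method = "exact" if n <= 25 else "approx"
    try:
        res = stats.wilcoxon(d_a, d_b, method=method, correction=(method == "approx"))
    except ValueError:
        res = stats.wilcoxon(d_a, d_b, method="approx", correction=True)
    return float(res.statistic), float(res.pvalue)


def lesion_agreement(net_scores, expert_scores, lesions,
                     animals=None, normalization: str = "minmax") -> AgreementReport:
    """Which score tracks lesion volume better, network or expert?

    All three per-animal series are normalized (min-max by default, z-score
    as the variant), the per-animal distances |score - lesion| computed for
    both scores, and the paired distances compared by a Wilcoxon signed-rank
    test (exact distribution for n <= 25, normal approximation with
    continuity correction above).  Pearson correlations of each score with
    lesion volume are reported alongside.
    """
    net = np.asarray(net_scores, dtype=float)
    exp_ = np.asarray(expert_scores, dtype=float)
    les = np.asarray(lesions, dtype=float)
    if not (len(net) == len(exp_) == len(les)):
        raise ValueError("net, expert and lesion series must be aligned per animal")
    if len(net) < 6:
        raise ValueError("need >= 6 animals for the signed-rank comparison")
    norm = minmax_normalize if normalization == "minmax" else zscore_normalize
    nn, ee, ll = norm(net), norm(exp_), norm(les)
    d_net = np.abs(nn - ll)
    d_exp = np.abs(ee - ll)
    w, p = _wilcoxon(d_net, d_exp)
    r_n, p_n = stats.pearsonr(net, les)
    r_e, p_e = stats.pearsonr(exp_, les)
    return AgreementReport(
        animals=list(animals) if animals is not None else list(range(len(net))),
        net_norm=nn, expert_norm=ee, lesion_norm=ll,
        net_distance=d_net, expert_distance=d_exp,
        wilcoxon_stat=w, wilcoxon_p=p,
        r_net_lesion=float(r_n), p_net_lesion=float(p_n),
        r_expert_lesion=float(r_e), p_expert_lesion=float(p_e),
        normalization=normalization)


def rater_discrepancy(reference, other, comparator_other=None) -> dict:
    """Mean |difference| between per-animal mean scores of two raters.

    Returns the mean absolute per-animal difference with its SEM over
    animals.  With ``comparator_other`` given (a second rater or the network)
    a paired t-test compares the two discrepancy series |reference - other|
    vs |reference - comparator| on the same animals.
    """
    ref = np.asarray(reference, dtype=float)
    oth = np.asarray(other, dtype=float)
    if len(ref) != len(oth):
        raise ValueError("rater series must be aligned per animal")
    if len(ref) < 3:
        raise ValueError("need >= 3 animals")
    d = np.abs(ref - oth)
    out = {
        "mean_abs_diff": float(d.mean()),
        "sem": float(d.std(ddof=1) / np.sqrt(len(d))) if len(d) > 1 else 0.0,
        "n": len(d),
    }
    if comparator_other is not None:
        cmp_ = np.asarray(comparator_other, dtype=float)
        if len(cmp_) != len(ref):
            raise ValueError("comparator series must be aligned per animal")
        d2 = np.abs(ref - cmp_)
        if np.allclose(d, d2):
            out.update(t=0.0, p=1.0, comparator_mean_abs_diff=float(d2.mean()))
        else:
            t, p = stats.ttest_rel(d, d2)
            out.update(t=float(t), p=float(p),
                       comparator_mean_abs_diff=float(d2.mean()))
    return out


def regress_lesion_from_elements(element_scores: np.ndarray, lesions,
                                 animals=None) -> dict:
    """Predict lesion volume from the 7 element scores, cross-validated.

    Ordinary least squares with intercept, leave-one-animal-out: each
    animal's lesion volume is predicted by a model fitted on the others;
    held-out predictions are assembled and correlated (Pearson) with the true
    volumes.  A rank-deficient design falls back to the pseudo-inverse with
    a warning.
    """
    x = np.asarray(element_scores, dtype=float)
    y = np.asarray(lesions, dtype=float)
    if x.ndim != 2:
        raise ValueError("element_scores must be (n_animals, n_elements)")
    n, k = x.shape
    if n < k + 2:
        raise ValueError(f"need >= {k + 2} animals for {k} predictors + holdout")
    design = np.c_[np.ones(n), x]
    if np.linalg.matrix_rank(design) < design.shape[1]:
        import warnings
        warnings.warn("collinear element scores; using pseudo-inverse")
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        coef, *_ = np.linalg.lstsq(design[mask], y[mask], rcond=None)
        preds[i] = design[i] @ coef
    r, p = stats.pearsonr(preds, y)
    return {"predictions": preds, "r": float(r), "p": float(p),
            "animals": list(animals) if animals is not None else list(range(n))}


@dataclass
class BeamScore:
    """Composite parallel-beam-task disability score per animal."""

    placement_deviation: np.ndarray   # min-max normalized
    walk_time: np.ndarray
    attempts_per_step: np.ndarray
    composite: np.ndarray             # mean of the three, in [0, 1]
    animals: list = field(default_factory=list)


def beam_composite(deviation, time, attempts, animals=None) -> BeamScore:
    """Parallel-beam composite: mean of three min-max-normalized measures."""
    dev = np.asarray(deviation, dtype=float)
    tim = np.asarray(time, dtype=float)
    att = np.asarray(attempts, dtype=float)
    if not (len(dev) == len(tim) == len(att)) or len(dev) == 0:
        raise ValueError("all three beam measures must be present per animal")
    if np.isnan(dev).any() or np.isnan(tim).any() or np.isnan(att).any():
        raise ValueError("missing values in beam measures")
    nd, nt, na = minmax_normalize(dev), minmax_normalize(tim), minmax_normalize(att)
    comp = (nd + nt + na) / 3.0
    return BeamScore(placement_deviation=nd, walk_time=nt, attempts_per_step=na,
                     composite=comp,
                     animals=list(animals) if animals is not None else list(range(len(dev))))


def mean_trials_per_animal(n_trials_total: int, n_animals: int) -> float:
    """Mean recorded trials per animal from cohort totals (e.g. 692 trials
    over 16 animals -> 43.25)."""
    if n_animals <= 0:
        raise ValueError("n_animals must be positive")
    return n_trials_total / n_animals
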