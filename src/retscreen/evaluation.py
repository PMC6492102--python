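"""ROC analysis, threshold choice, cross-validation and screening-policy arithmetic.

Conventions follow screening-programme reporting: sensitivity is the
percentage of patients who truly developed STDR within 1 year that the
classifier flags; specificity the percentage of non-progressors correctly
left unflagged; PCC (probability of correct classification) their
prevalence-weighted average.  The operating threshold is the point on the
empirical ROC curve nearest the top-left corner.  Screening reduction
assumes low-risk patients move from annual to biennial intervals, halving
their episode count.

The repeated-split protocol refits both group models on 70% of each
prognostic group, selects the threshold on the training ROC only, and
evaluates on the held-out 30%; repeats are averaged with percentile
intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import PredictionInstance
from .discriminant import GroupModelPair, score_cohort
from .glmm import MCMCConfig, ModelSpec, fit_mcmc

logger = logging.getLogger("retscreen")


@dataclass
class RocResult:
    thresholds: np.ndarray       # candidate thresholds, decreasing
    sensitivity: np.ndarray      # proportions, aligned with thresholds
    specificity: np.ndarray
    auc: float
    chosen_threshold: float | None = None
    operating_point: tuple[float, float] | None = None   # (sens, spec)


@dataclass
class PolicyMetrics:
    """Classification and policy numbers, percentages in [0, 100]."""

    sensitivity: float
    specificity: float
    pcc: float
    n_pos: int
    n_neg: int
    ppv: float | None = None
    reduction: float | None = None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class CVResult:
    per_repeat: pd.DataFrame
    summary: dict[str, tuple[float, float, float]]   # metric -> (mean, lo, hi)
    n_repeats: int
    seed: int


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc_and_auc(scores: Sequence[float], labels: Sequence[bool]) -> RocResult:
    """Empirical ROC over all distinct score thresholds, AUC by trapezoid.

    Classification is strict (``score > threshold``), so each distinct score
    is a candidate threshold plus one value just below the minimum (predict
    everyone positive).  The trapezoidal AUC equals the Mann-Whitney
    concordance with half credit for ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    ok = ~np.isnan(scores)
    scores, labels = scores[ok], labels[ok]
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")

    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    starts = np.concatenate([[0], np.flatnonzero(np.diff(s_sorted)) + 1])
    uniq = s_sorted[starts]                              # decreasing
    pos_cum = np.cumsum(l_sorted)
    ends = np.concatenate([starts[1:], [s_sorted.size]]) - 1
    # threshold = u predicts positive for scores strictly greater than u
    tp = np.concatenate([[0.0], pos_cum[ends]])
    fp = np.concatenate([[0.0], (ends + 1.0) - pos_cum[ends]])
    below = max(0.0, float(np.nextafter(uniq[-1], -np.inf)))
    thresholds = np.concatenate([uniq, [below]])
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    fpr = fp / n_neg
    auc = float(np.trapezoid(sens, fpr))
    return RocResult(thresholds=thresholds, sensitivity=sens, specificity=spec, auc=auc)


def select_threshold(roc: RocResult) -> float:
    """Threshold nearest the top-left corner; ties go to the lower threshold
    (higher sensitivity)."""
    d = np.sqrt((1.0 - roc.sensitivity) ** 2 + (1.0 - roc.specificity) ** 2)
    best = d.min()
    tied = np.flatnonzero(d <= best + 1e-12)
    pick = tied[np.argmin(roc.thresholds[tied])]
    roc.chosen_threshold = float(roc.thresholds[pick])
    roc.operating_point = (float(roc.sensitivity[pick]), float(roc.specificity[pick]))
    return roc.chosen_threshold


# ---------------------------------------------------------------------------
# classification metrics and policy arithmetic
# ---------------------------------------------------------------------------

def confusion_metrics(predicted: Sequence[bool], truth: Sequence[bool]) -> PolicyMetrics:
    """Sensitivity, specificity and PCC (percentages) from hard labels."""
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    tp = int(np.sum(predicted & truth))
    fn = int(np.sum(~predicted & truth))
    tn = int(np.sum(~predicted & ~truth))
    fp = int(np.sum(predicted & ~truth))
    n_pos, n_neg = tp + fn, tn + fp
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    sens = 100.0 * tp / n_pos
    spec = 100.0 * tn / n_neg
    pcc = 100.0 * (tp + tn) / (n_pos + n_neg)
    ppv_pct = 100.0 * tp / (tp + fp) if tp + fp else None
    return PolicyMetrics(sensitivity=sens, specificity=spec, pcc=pcc,
                         n_pos=n_pos, n_neg=n_neg, ppv=ppv_pct)


def pcc_from_rates(sens_pct: float, spec_pct: float, n_pos: int, n_neg: int) -> float:
    """PCC as the group-size-weighted average of sensitivity and specificity."""
    if not (0 <= sens_pct <= 100 and 0 <= spec_pct <= 100):
        raise ValueError("rates must be percentages in [0, 100]")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("group sizes must be positive")
    return (sens_pct * n_pos + spec_pct * n_neg) / (n_pos + n_neg)


def ppv(sens: float, spec: float, prevalence: float) -> float:
    """Positive predictive value from sensitivity, specificity and prevalence
    (all proportions)."""
    for v in (sens, spec, prevalence):
        if not 0.0 < v <= 1.0:
            raise ValueError("inputs must be proportions in (0, 1]")
    denom = sens * prevalence + (1.0 - spec) * (1.0 - prevalence)
    if denom == 0.0:
        raise ValueError("no predicted positives: PPV undefined")
    return sens * prevalence / denom


def screening_reduction(low_risk_fraction: float) -> float:
    """Fractional reduction in screening episodes when the low-risk fraction
    moves from annual to biennial screening (half their episodes saved)."""
    if not 0.0 <= low_risk_fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    return low_risk_fraction / 2.0


# ---------------------------------------------------------------------------
# repeated stratified splits
# ---------------------------------------------------------------------------

def _stratified_split(labels: np.ndarray, train_frac: float, rng: np.random.Generator):
    train = np.zeros(labels.size, dtype=bool)
    for cls in (False, True):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_train = int(round(train_frac * idx.size))
        train[idx[:n_train]] = True
    return train


def cross_validate(instances: Sequence[PredictionInstance], spec: ModelSpec,
                   mcmc: MCMCConfig | None = None, n_repeats: int = 100,
                   train_frac: float = 0.7, posterior_draws: int = 50,
                   n_nodes: int = 20, method: str = "average",
                   seed: int = 0) -> CVResult:
    """Repeated stratified 70/30 evaluation of the full discriminant pipeline.

    Each repeat: split both prognostic groups ``train_frac``/rest, fit the two
    group models on the training patients, select the operating threshold on
    the *training* ROC, then report AUC/sensitivity/specificity/PCC on the
    held-out patients.  Metrics are averaged over repeats with 2.5/97.5
    percentile intervals.  Fully deterministic given ``seed``.
    """
    labels = np.array([inst.label for inst in instances], dtype=bool)
    if labels.sum() < 10 or (~labels).sum() < 10:
        raise ValueError("each prognostic group needs at least 10 patients to stratify")
    rows = []
    for r in range(n_repeats):
        rng = np.random.default_rng([seed, r])
        train = _stratified_split(labels, train_frac, rng)
        tr = [inst for inst, t in zip(instances, train) if t]
        te = [inst for inst, t in zip(instances, train) if not t]
        tr_labels = labels[train]
        fit_seed = int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % (2 ** 31))
        fit_s = fit_mcmc([i for i in tr if i.label], spec, mcmc, seed=fit_seed)
        fit_n = fit_mcmc([i for i in tr if not i.label], spec, mcmc, seed=fit_seed + 1)
        pair = GroupModelPair(fit_stdr=fit_s, fit_nonstdr=fit_n,
                              prevalence_stdr=float(tr_labels.mean()))
        tr_scores = score_cohort(tr, pair, posterior_draws, n_nodes, method)
        tr_roc = roc_and_auc([s.probability_stdr for s in tr_scores], tr_labels)
        thr = select_threshold(tr_roc)
        te_scores = score_cohort(te, pair, posterior_draws, n_nodes, method)
        te_prob = np.array([s.probability_stdr for s in te_scores])
        te_labels = labels[~train]
        te_roc = roc_and_auc(te_prob, te_labels)
        m = confusion_metrics(te_prob > thr, te_labels)
        rows.append((r, thr, te_roc.auc, m.sensitivity, m.specificity, m.pcc))
        logger.info("repeat %d/%d: AUC %.3f sens %.1f spec %.1f", r + 1, n_repeats,
                    te_roc.auc, m.sensitivity, m.specificity)
    per_repeat = pd.DataFrame(rows, columns=["repeat", "threshold", "auc",
                                             "sensitivity", "specificity", "pcc"])
    summary = {}
    for col in ("auc", "sensitivity", "specificity", "pcc", "threshold"):
        vals = per_repeat[col].to_numpy()
        lo, hi = np.percentile(vals, [2.5, 97.5])
        summary[col] = (float(vals.mean()), float(lo), float(hi))
    return CVResult(per_repeat=per_repeat, summary=summary,
                    n_repeats=n_repeats, seed=seed)


def subgroup_evaluate(scores: Sequence[float], labels: Sequence[bool],
                      subgroups: Sequence[str], threshold: float
                      ) -> dict[str, dict[str, float]]:
    """Per-subgroup AUC (subgroup ROC) and sens/spec/PCC at the global threshold.

    Subgroups with a single outcome class are skipped with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    subgroups = np.asarray(subgroups)
    out: dict[str, dict[str, float]] = {}
    for g in pd.unique(subgroups):
        m = subgroups == g
        if labels[m].all() or not labels[m].any():
            warnings.warn(f"subgroup '{g}' has a single outcome class; skipped",
                          stacklevel=2)
            continue
        roc = roc_and_auc(scores[m], labels[m])
        cm = confusion_metrics(scores[m] > threshold, labels[m])
        out[str(g)] = {"auc": roc.auc, "sensitivity": cm.sensitivity,
                       "specificity": cm.specificity, "pcc": cm.pcc,
                       "n": int(m.sum())}
    return out


def roc_points_frame(roc: RocResult) -> pd.DataFrame:
    return pd.DataFrame({"threshold": roc.thresholds, "sensitivity": roc.sensitivity,
                         "specificity": roc.specificity})


def plot_roc(roc: RocResult, path) -> None:
    """ROC curve with the chosen operating point, written to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(1.0 - roc.specificity, roc.sensitivity, drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls=":", c="grey")
    if roc.operating_point is not None:
        ax.plot(1.0 - roc.operating_point[1], roc.operating_point[0], "o", c="green")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {roc.auc:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
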