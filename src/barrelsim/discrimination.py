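"""Single-trial linear classifiers for deflection velocity and direction.

Velocity: the net cortical RS spike count of a trial is compared against
cutoffs placed at the midpoints between the trial-mean net counts of
adjacent velocity classes; a trial is correct when its count falls in its
own class's interval.  Direction (for a 0-degree deflection): the trial's
0-degree-domain response quotient — per-cell domain response divided by
per-cell cortical response — is compared against the midpoint between the
trial-averaged quotients of the 0-degree domain and of the pooled
45/315-degree domains; a trial is correct when its quotient strictly
exceeds the cutoff.

By default classifiers are fitted on one half of the trials and scored on
the other half; ``split="none"`` fits and scores on the same set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .dynamics import TrialResult
from .metrics import net_counts, population_counts
from .network import Wiring


@dataclass
class VelocityClassifier:
    """Nearest-mean classifier on net cortical counts, one class per sigma.

    ``sigmas`` are ordered from high to low velocity (ascending sigma);
    ``cutoffs`` are the midpoints between adjacent class means, descending
    when the means are monotone.  A count equal to a cutoff is assigned to
    the lower-velocity side.
    """

    sigmas: List[float]
    class_means: np.ndarray
    cutoffs: np.ndarray
    monotone: bool = True

    def classify(self, net_count: float) -> float:
        idx = int(np.sum(net_count <= self.cutoffs))
        return self.sigmas[idx]


@dataclass
class DirectionClassifier:
    """Threshold on the 0-degree domain response quotient.

    ``cutoff`` is the midpoint between the trial-averaged quotient of the
    target (0 degree) domain and that of the pooled competitor domains
    (45/315 degrees); training trials with undefined quotients (silent
    cortex) are excluded from the means.
    """

    target_domain: int
    competitor_domains: Tuple[int, int]
    cutoff: float
    target_mean: float = float("nan")
    competitor_mean: float = float("nan")
    separable: bool = True


class UnfittableError(ValueError):
    """Training responses carry no signal to place a cutoff on."""


def fit_velocity_classifier(
    training: Mapping[float, Sequence[float]]
) -> VelocityClassifier:
    """Fit per-velocity mean net counts and midpoint cutoffs.

    ``training`` maps sigma to the net cortical counts of its trials.
    Non-monotone class means produce a usable classifier with
    ``monotone=False``.
    """
    sigmas = sorted(training)
    if any(len(training[s]) < 1 for s in sigmas):
        raise ValueError("every velocity class needs at least one training trial")
    means = np.array([float(np.mean(training[s])) for s in sigmas])
    cutoffs = (means[:-1] + means[1:]) / 2.0
    monotone = bool(np.all(np.diff(means) < 0))
    return VelocityClassifier(
        sigmas=list(sigmas), class_means=means, cutoffs=cutoffs, monotone=monotone
    )


def classify_velocity(net_count: float, clf: VelocityClassifier) -> float:
    """Predicted sigma class for one trial's net cortical count."""
    return clf.classify(net_count)


def direction_quotient(
    trial: TrialResult, wiring: Wiring, domains: Sequence[int] = (0,)
) -> float:
    """Per-cell domain response over per-cell cortical response.

    Normalizing both responses per cell removes the 20-vs-160 population
    size imbalance: a trial with all spikes inside one 20-cell domain
    scores 8.  NaN when the cortex is silent.
    """
    net, per_domain = population_counts(trial, wiring)
    if net == 0:
        return float("nan")
    n_cells = sum(len(wiring.rs_cells_in_domain(d)) for d in domains)
    count = sum(per_domain[d % 360] for d in domains)
    return (count / n_cells) / (net / trial.n_rs)


def fit_direction_classifier(
    training: Sequence[TrialResult],
    wiring: Wiring,
    target_domain: int = 0,
    competitor_domains: Tuple[int, int] = (45, 315),
) -> DirectionClassifier:
    """Place the cutoff between target and pooled-competitor mean quotients."""
    tq = np.array([direction_quotient(t, wiring, (target_domain,)) for t in training])
    cq = np.array(
        [direction_quotient(t, wiring, competitor_domains) for t in training]
    )
    tq, cq = tq[~np.isnan(tq)], cq[~np.isnan(cq)]
    if len(tq) == 0 or len(cq) == 0:
        raise UnfittableError("all training trials have silent cortex")
    t_mean, c_mean = float(np.mean(tq)), float(np.mean(cq))
    if t_mean == 0 and c_mean == 0:
        raise UnfittableError("no domain response to separate")
    return DirectionClassifier(
        target_domain=target_domain,
        competitor_domains=competitor_domains,
        cutoff=(t_mean + c_mean) / 2.0,
        target_mean=t_mean,
        competitor_mean=c_mean,
        separable=t_mean > c_mean,
    )


def classify_direction(
    trial: TrialResult, clf: DirectionClassifier, wiring: Wiring
) -> Optional[bool]:
    """True (correct) iff the target-domain quotient strictly exceeds the cutoff.

    Returns None for an undefined quotient (silent cortex): such a trial
    carries no direction signal.  How undefined trials enter accuracy is
    decided by the scoring policy of :func:`direction_accuracy`.
    """
    q = direction_quotient(trial, wiring, (clf.target_domain,))
    if np.isnan(q):
        return None
    return bool(q > clf.cutoff)


def _split(trials: Sequence, split: str):
    if split == "half":
        mid = len(trials) // 2
        return trials[:mid], trials[mid:]
    if split == "none":
        return trials, trials
    raise ValueError(f"unknown split {split!r}")


def velocity_accuracy(
    trials_by_sigma: Mapping[float, Sequence[TrialResult]],
    wiring: Wiring,
    split: str = "half",
) -> Dict:
    """Fit the velocity classifier and score held-out trials per class.

    Returns per-sigma fractions correct, the trial-weighted aggregate, and
    the fitted classifier.
    """
    train = {}
    test = {}
    for s, trials in trials_by_sigma.items():
        tr, te = _split(list(trials), split)
        train[s] = net_counts(tr, wiring)
        test[s] = net_counts(te, wiring)
    clf = fit_velocity_classifier(train)
    per_class, n_correct, n_total = {}, 0, 0
    for s, counts in test.items():
        correct = sum(clf.classify(c) == s for c in counts)
        per_class[s] = correct / len(counts)
        n_correct += correct
        n_total += len(counts)
    return {
        "per_class": per_class,
        "aggregate": n_correct / n_total,
        "classifier": clf,
    }


def direction_accuracy(
    trials_by_sigma: Mapping[float, Sequence[TrialResult]],
    wiring: Wiring,
    split: str = "half",
    undefined: str = "drop",
) -> Dict:
    """Per-velocity and aggregate single-trial direction classification.

    All trials are 0-degree deflections; a separate cutoff is fitted per
    velocity (mean responses differ across velocities).  ``undefined``
    sets the scoring of silent-cortex trials, whose quotient carries no
    direction signal: ``"drop"`` (default) excludes them from the
    accuracy denominator, ``"incorrect"`` counts them as misclassified.
    """
    if undefined not in ("drop", "incorrect"):
        raise ValueError(f"unknown undefined policy {undefined!r}")
    per_class, n_correct, n_total, clfs = {}, 0, 0, {}
    for s, trials in trials_by_sigma.items():
        tr, te = _split(list(trials), split)
        clf = fit_direction_classifier(tr, wiring)
        clfs[s] = clf
        outcomes = [classify_direction(t, clf, wiring) for t in te]
        if undefined == "drop":
            outcomes = [o for o in outcomes if o is not None]
        correct = sum(bool(o) for o in outcomes)
        per_class[s] = correct / len(outcomes) if outcomes else float("nan")
        n_correct += correct
        n_total += len(outcomes)
    return {
        "per_class": per_class,
        "aggregate": n_correct / n_total,
        "classifiers": clfs,
    }


def accuracy_report(per_class: Mapping, n_per_class: Mapping) -> Dict:
    """Assemble per-class fractions into a JSON-ready report with aggregate."""
    total = sum(n_per_class.values())
    aggregate = sum(per_class[k] * n_per_class[k] for k in per_class) / total
    return {
        "per_class": {str(k): float(per_class[k]) for k in per_class},
        "n_per_class": {str(k): int(n_per_class[k]) for k in n_per_class},
        "aggregate": float(aggregate),
        "n_trials": int(total),
    }
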