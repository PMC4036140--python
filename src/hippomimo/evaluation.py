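"""Goodness-of-fit and performance assessment.

The encoding model is validated with a Kolmogorov-Smirnov test based on
the time-rescaling theorem: if the per-bin firing probabilities are
correct, the integrated conditional intensity between successive spikes
is a unit-rate exponential sample, so ``1 - exp(-ISI_rescaled)`` must be
uniform on [0, 1]. Decoder performance is summarized as fraction
correct with a Wilson binomial interval, and trial-level K-fold split
plans (optionally stratified by label) are provided for cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "KSResult",
    "SplitPlan",
    "ks_time_rescaling",
    "classification_accuracy",
    "make_trial_splits",
    "chance_band",
]

#: asymptotic KS critical distances, c / sqrt(n)
KS_CRITICAL = {0.95: 1.36, 0.99: 1.63}


@dataclass
class KSResult:
    """Uniformity check of time-rescaled interspike intervals."""

    rescaled_quantiles: np.ndarray
    ks_statistic: float
    band_95: float
    inside_band: bool
    n_intervals: int


def ks_time_rescaling(spikes, p, jitter_seed: int | None = 0) -> KSResult:
    """Time-rescaling KS test of a per-bin probability trace.

    Per-bin intensity mass is taken as ``-ln(1 - p)`` rather than ``p``
    itself — the discrete-time correction that matters at 2 ms bins with
    non-negligible spike probability. The mass is accumulated between
    successive spikes, transformed through ``1 - exp(-ISI)``, and the
    empirical quantiles are compared against the uniform distribution
    with the asymptotic 95% distance ``1.36 / sqrt(n)``.

    By default the within-bin arrival time of each spike is drawn from
    the conditional exponential distribution (seeded; the randomized
    discrete-time rescaling). Without it the rescaled intervals live on
    a lattice and the test rejects a *correct* model almost surely once
    the spike count is large relative to the bin probability;
    ``jitter_seed=None`` disables the randomization for callers who
    want the raw deterministic transform.
    """
    spikes = np.asarray(spikes)
    p = np.asarray(p, float)
    if spikes.shape != p.shape:
        raise ValueError("spike series and probability trace must align")
    if not np.isin(spikes, (0, 1)).all():
        raise ValueError("spike series must be binary")
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("probabilities must lie strictly inside (0, 1)")
    times = np.flatnonzero(spikes)
    if len(times) < 2:
        raise ValueError("need at least 2 spikes to form interspike intervals")
    mass = -np.log1p(-p)
    cum = np.concatenate([[0.0], np.cumsum(mass)])
    # integrated intensity between successive spikes (bin of each spike included)
    Lambda = cum[times[1:] + 1] - cum[times[:-1] + 1]
    if jitter_seed is not None:
        rng = np.random.default_rng(jitter_seed)
        q_spike = mass[times[1:]]
        u = rng.random(len(q_spike))
        # replace the spike bin's full mass by the within-bin arrival time
        # conditional on a spike in that bin
        Lambda = Lambda - q_spike - np.log1p(-u * (1.0 - np.exp(-q_spike)))
    q = np.sort(1.0 - np.exp(-Lambda))
    n = len(q)
    grid_hi = np.arange(1, n + 1) / n
    grid_lo = np.arange(0, n) / n
    ks = float(np.max(np.maximum(np.abs(q - grid_hi), np.abs(q - grid_lo))))
    band = KS_CRITICAL[0.95] / np.sqrt(n)
    return KSResult(
        rescaled_quantiles=q,
        ks_statistic=ks,
        band_95=float(band),
        inside_band=bool(ks <= band),
        n_intervals=n,
    )


def classification_accuracy(labels, predictions, alpha: float = 0.05):
    """Fraction correct with a Wilson binomial confidence interval."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("label and prediction vectors must have equal length")
    if labels.size == 0:
        raise ValueError("empty label vector")
    correct = int(np.sum(labels == predictions))
    acc = correct / labels.size
    lo, hi = proportion_confint(correct, labels.size, alpha=alpha, method="wilson")
    return acc, (float(lo), float(hi))


def chance_band(n_trials: int, p: float = 0.5, alpha: float = 0.05):
    """Binomial (1-alpha) acceptance band for accuracy under chance."""
    from scipy.stats import binom

    lo = binom.ppf(alpha / 2, n_trials, p) / n_trials
    hi = binom.isf(alpha / 2, n_trials, p) / n_trials
    return float(lo), float(hi)


@dataclass
class SplitPlan:
    """Fold assignment per trial for K-fold cross-validation."""

    trial_ids: np.ndarray
    fold_assignment: np.ndarray
    n_folds: int
    stratified: bool
    seed: int

    def folds(self):
        for f in range(self.n_folds):
            yield self.trial_ids[self.fold_assignment != f], self.trial_ids[
                self.fold_assignment == f
            ]


def make_trial_splits(trials, labels, n_folds: int, stratified: bool = True,
                      seed: int = 0) -> SplitPlan:
    """Deterministic K-fold partition of trials, optionally label-stratified.

    When stratified, each class's trials are shuffled (seeded) and dealt
    round-robin across folds, keeping per-fold class proportions within
    one trial of the global proportions.
    """
    trials = np.asarray(trials)
    labels = np.asarray(labels)
    if trials.shape != labels.shape:
        raise ValueError("trials and labels must have equal length")
    n = len(trials)
    if n_folds < 2 and n_folds != n:
        if n_folds < 1:
            raise ValueError("n_folds must be >= 1")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    if stratified:
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            if len(idx) < n_folds:
                raise ValueError(
                    f"class {cls}: {len(idx)} trials < {n_folds} folds; "
                    "stratification infeasible"
                )
            idx = rng.permutation(idx)
            assignment[idx] = np.arange(len(idx)) % n_folds
    else:
        assignment[:] = rng.permutation(np.arange(n) % n_folds)
    return SplitPlan(
        trial_ids=trials,
        fold_assignment=assignment,
        n_folds=n_folds,
        stratified=stratified,
        seed=seed,
    )
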