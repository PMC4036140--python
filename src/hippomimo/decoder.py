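"""B-spline L1-logistic decoding of memory category from spike patterns.

A single-trial spatio-temporal pattern (N neurons x M+1 time bins around
the sample lever press) is projected per neuron onto a B-spline basis,
giving a length-N*J feature vector z. Logistic regression on z predicts
the probability that the trial was a *left* sample (label 1; right = 0).
Because N*J can approach the number of trials, the weights are estimated
with an L1 (lasso) penalty by coordinate descent, which zeroes the
features of uninformative neuron/time-range combinations. The fitted
weights can be folded back through the basis into a time-domain
classification feature matrix F, and decoding via <F, pattern> is
algebraically identical to decoding via <w, z>.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bspline import BSplineBasis, bspline_basis
from .evaluation import make_trial_splits
from .spike_data import PerieventPattern

__all__ = [
    "FeatureVector",
    "DecoderModel",
    "FeatureMatrix",
    "project_features",
    "features_matrix",
    "fit_decoder",
    "lambda_max_logistic",
    "default_lambda_grid_logistic",
    "cross_validate_decoder",
    "select_J",
    "reconstruct_feature_matrix",
    "decode",
    "save_decoder",
    "load_decoder",
]


@dataclass
class FeatureVector:
    """Length N*J projection of one pattern (neuron-major, basis-minor)."""

    z: np.ndarray
    neuron_ids: list
    basis: BSplineBasis
    label: int | None = None
    trial_id: object = None


@dataclass
class DecoderModel:
    """Fitted L1-logistic classifier in the B-spline feature space.

    ``w`` is N x J (neuron x basis); label convention is left = 1,
    right = 0, and an exact boundary probability of 0.5 maps to label 0.
    """

    w0: float
    w: np.ndarray
    lam: float
    basis: BSplineBasis
    neuron_ids: list = field(default_factory=list)
    diagnostics: dict | None = None

    @property
    def n_neurons(self) -> int:
        return self.w.shape[0]


@dataclass
class FeatureMatrix:
    """Time-domain classification weights F (N x (M+1))."""

    F: np.ndarray
    w0: float
    neuron_ids: list = field(default_factory=list)


def project_features(pattern: PerieventPattern | np.ndarray, basis: BSplineBasis,
                     neuron_ids=None) -> FeatureVector:
    """Inner products z^(n)(j) = sum_tau B_j(tau) x_n(tau).

    The pattern's M+1 time columns must match the basis grid (a 2000-bin
    perievent window maps to the grid 0..1999, i.e. M = 1999).
    """
    if isinstance(pattern, PerieventPattern):
        x = pattern.pattern
        nids = pattern.neuron_ids
        label, trial = pattern.label, pattern.trial_id
    else:
        x = np.asarray(pattern)
        nids = list(neuron_ids) if neuron_ids is not None else list(range(x.shape[0]))
        label = trial = None
    if x.shape[1] != basis.M + 1:
        raise ValueError(
            f"pattern has {x.shape[1]} time bins; basis grid has {basis.M + 1}"
        )
    z = (x @ basis.values.T).ravel()  # (N, J) -> neuron-major flat
    return FeatureVector(z=z, neuron_ids=list(nids), basis=basis, label=label,
                         trial_id=trial)


def features_matrix(patterns: list[PerieventPattern], basis: BSplineBasis):
    """Stack per-trial feature vectors into (Z [n_trials x N*J], labels)."""
    feats = [project_features(p, basis) for p in patterns]
    Z = np.array([f.z for f in feats])
    labels = np.array([p.label for p in patterns], dtype=int)
    return Z, labels, feats[0].neuron_ids


# ---------------------------------------------------------------------------
# estimation


def _logistic_nll(w0, wv, Z, y):
    eta = w0 + Z @ wv
    # stable log(1 + exp(eta)) - y*eta
    return float(np.sum(np.logaddexp(0.0, eta) - y * eta))


def _objective(w0, wv, Z, y, lam):
    return _logistic_nll(w0, wv, Z, y) + lam * np.abs(wv).sum()


def _soft(x, t):
    return np.sign(x) * max(abs(x) - t, 0.0)


def _cd_logistic(Z, y, lam, tol=1e-7, max_iter=500, w_init=None, warn_nonconv=True):
    """Coordinate-descent L1 logistic regression (bias unpenalized).

    Outer IRLS quadratic approximation, inner cyclic coordinate descent
    with soft-thresholding, step-halving for a monotone objective.
    """
    n, P = Z.shape
    if w_init is None:
        w0, wv = 0.0, np.zeros(P)
    else:
        w0, wv = float(w_init[0]), np.asarray(w_init[1], float).copy()
    col_sq = (Z**2).sum(axis=0)
    S = _objective(w0, wv, Z, y, lam)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = w0 + Z @ wv
        p = 1.0 / (1.0 + np.exp(-eta))
        W = np.clip(p * (1 - p), 1e-5, None)
        z_work = eta + (y - p) / W
        w0_new, wv_new = w0, wv.copy()
        r = z_work - w0_new - Z @ wv_new  # working residual
        WZ = Z * W[:, None]
        wz2 = np.einsum("ij,ij->j", WZ, Z)  # sum_i W_i Z_ij^2
        Wsum = W.sum()
        inner_tol = 1e-6

        def _sweep(coords):
            max_delta = 0.0
            nonlocal w0_new
            new = np.dot(W, r + w0_new) / Wsum  # bias, unpenalized
            r[:] += w0_new - new
            max_delta = max(max_delta, abs(new - w0_new))
            w0_new = new
            for j in coords:
                if wz2[j] <= 0:
                    continue
                wj = wv_new[j]
                num = np.dot(WZ[:, j], r) + wz2[j] * wj
                new = _soft(num, lam) / wz2[j]
                if new != wj:
                    r[:] += Z[:, j] * (wj - new)
                    max_delta = max(max_delta, abs(new - wj))
                    wv_new[j] = new
            return max_delta

        # glmnet-style: full sweep, then iterate on the active set until
        # stable, then one confirming full sweep
        all_coords = range(P)
        for _ in range(3):
            _sweep(all_coords)
            active = np.flatnonzero(wv_new)
            for _ in range(30):
                if _sweep(active) < inner_tol:
                    break
            if _sweep(all_coords) < inner_tol:
                break
        S_new = _objective(w0_new, wv_new, Z, y, lam)
        for _ in range(30):
            if S_new <= S + 1e-12 * (1 + abs(S)):
                break
            w0_new = 0.5 * (w0 + w0_new)
            wv_new = 0.5 * (wv + wv_new)
            S_new = _objective(w0_new, wv_new, Z, y, lam)
        if S_new > S:
            break
        drop = S - S_new
        w0, wv, S = w0_new, wv_new, S_new
        if drop <= tol * (1 + abs(S)):
            converged = True
            break
    if not converged and warn_nonconv:
        warnings.warn(f"L1 logistic fit: not converged after {it} iterations")
    return w0, wv, {"objective": S, "n_iter": it, "converged": converged}


def fit_decoder(
    features,
    labels,
    lam: float,
    basis: BSplineBasis | None = None,
    neuron_ids=None,
    tol: float = 1e-7,
    max_iter: int = 500,
    w_init=None,
) -> DecoderModel:
    """Fit the L1-penalized logistic decoder at a fixed lambda.

    ``features`` may be a list of :class:`FeatureVector` or a stacked
    (n_trials x N*J) array (then ``basis`` is required). Both classes
    must be present in ``labels``.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    Z, basis, neuron_ids = _as_feature_array(features, basis, neuron_ids)
    y = np.asarray(labels, int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit a decoder")
    if Z.shape[0] != y.shape[0]:
        raise ValueError("feature and label counts differ")
    w0, wv, diag = _cd_logistic(Z, y.astype(float), lam, tol, max_iter, w_init)
    J = basis.J
    N = Z.shape[1] // J
    model = DecoderModel(
        w0=float(w0), w=wv.reshape(N, J), lam=float(lam), basis=basis,
        neuron_ids=list(neuron_ids) if neuron_ids is not None else list(range(N)),
        diagnostics=diag,
    )
    return model


def _as_feature_array(features, basis, neuron_ids):
    if isinstance(features, np.ndarray):
        if basis is None:
            raise ValueError("basis is required with a plain feature array")
        return features, basis, neuron_ids
    feats = list(features)
    Z = np.array([f.z for f in feats])
    return Z, feats[0].basis, feats[0].neuron_ids


def lambda_max_logistic(Z: np.ndarray, y: np.ndarray) -> float:
    """Smallest lambda zeroing every weight (KKT at the intercept-only fit)."""
    y = np.asarray(y, float)
    pbar = y.mean()
    return float(np.abs(Z.T @ (y - pbar)).max())


def default_lambda_grid_logistic(Z, y, n_lambda: int = 30, decades: float = 4.0):
    lmax = lambda_max_logistic(Z, y)
    return np.geomspace(lmax, lmax * 10.0 ** (-decades), n_lambda)


@dataclass
class DecoderCVCurve:
    lambda_grid: np.ndarray
    mean_accuracy: np.ndarray
    fold_accuracy: np.ndarray
    chosen: float


def cross_validate_decoder(
    features,
    labels,
    lambda_grid=None,
    n_folds: int = 4,
    seed: int = 0,
    basis: BSplineBasis | None = None,
    tol: float = 1e-7,
    max_iter: int = 500,
) -> tuple[float, DecoderCVCurve]:
    """Choose lambda by stratified K-fold held-out accuracy.

    Ties go to the larger (sparser) lambda. Requires at least
    ``n_folds`` trials of each class.
    """
    Z, basis, _ = _as_feature_array(features, basis, None)
    y = np.asarray(labels, int)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid_logistic(Z, y)
    grid = np.sort(np.asarray(lambda_grid, float))[::-1]
    plan = make_trial_splits(np.arange(len(y)), y, n_folds, stratified=True, seed=seed)
    fold_acc = np.empty((n_folds, len(grid)))
    for f in range(n_folds):
        tr = plan.fold_assignment != f
        te = ~tr
        w_init = None
        for i, lam in enumerate(grid):
            w0, wv, _ = _cd_logistic(Z[tr], y[tr].astype(float), lam, tol, max_iter,
                                     w_init, warn_nonconv=False)
            w_init = (w0, wv)
            eta = w0 + Z[te] @ wv
            pred = (eta > 0).astype(int)
            fold_acc[f, i] = np.mean(pred == y[te])
    mean_acc = fold_acc.mean(axis=0)
    best = int(np.argmax(mean_acc))  # grid descending: ties -> larger lambda
    chosen = float(grid[best])
    return chosen, DecoderCVCurve(grid, mean_acc, fold_acc, chosen)


def select_J(
    patterns: list[PerieventPattern],
    labels,
    J_candidates,
    degree: int = 3,
    n_folds: int = 4,
    seed: int = 0,
    lambda_grid=None,
) -> tuple[int, dict]:
    """Pick the number of basis functions by out-of-sample accuracy.

    For each candidate J (must satisfy m = J - d - 1 >= 0), build the
    basis, cross-validate lambda, and keep the J with the best CV
    accuracy; ties go to the smaller J. The candidate range 5..100
    brackets the temporal resolutions relevant for these spike trains.
    """
    J_candidates = sorted(set(int(j) for j in J_candidates))
    if not J_candidates:
        raise ValueError("empty J candidate list")
    bad = [j for j in J_candidates if j - degree - 1 < 0]
    if bad:
        raise ValueError(f"J candidates {bad} invalid for degree {degree}")
    M = patterns[0].n_bins - 1
    y = np.asarray(labels, int)
    table = {}
    for J in J_candidates:
        basis = bspline_basis(J - degree - 1, degree, M)
        Z, _, _ = features_matrix(patterns, basis)
        lam, curve = cross_validate_decoder(
            Z, y, lambda_grid=lambda_grid, n_folds=n_folds, seed=seed, basis=basis
        )
        table[J] = {"lambda": lam, "cv_accuracy": float(curve.mean_accuracy.max())}
    best = max(table, key=lambda j: (table[j]["cv_accuracy"], -j))  # ties -> smaller J
    return best, table


def reconstruct_feature_matrix(model: DecoderModel) -> FeatureMatrix:
    """Fold the weights through the basis: F^(n)(tau) = sum_j B_j(tau) w^(n)(j).

    Neurons whose weights are all zero give exactly-zero rows, making
    the sparse structure of the decoder visible in the time domain.
    """
    return FeatureMatrix(
        F=model.w @ model.basis.values, w0=model.w0, neuron_ids=model.neuron_ids
    )


def decode(pattern_or_features, model: DecoderModel):
    """Posterior P(left) and hard label for one pattern.

    The hard label is 1 iff the linear predictor is > 0 (P > 0.5); an
    exact boundary P = 0.5 maps to label 0.
    """
    x = pattern_or_features
    if isinstance(x, FeatureVector):
        z = x.z
    elif isinstance(x, PerieventPattern):
        z = project_features(x, model.basis).z
    else:
        z = np.asarray(x).ravel()
        if z.size == model.n_neurons * (model.basis.M + 1):
            z = project_features(
                np.asarray(x).reshape(model.n_neurons, -1), model.basis
            ).z
    if z.size != model.w.size:
        raise ValueError("feature dimension does not match the decoder")
    eta = model.w0 + float(model.w.ravel() @ z)
    prob = 1.0 / (1.0 + np.exp(-eta))
    return prob, int(eta > 0)


def decode_batch(patterns, model: DecoderModel):
    """Vector of probabilities and labels for a list of patterns."""
    probs, labels = zip(*(decode(p, model) for p in patterns))
    return np.array(probs), np.array(labels, dtype=int)


# ---------------------------------------------------------------------------
# serialization


def save_decoder(model: DecoderModel, path) -> None:
    doc = {
        "label_convention": {"left": 1, "right": 0},
        "basis": model.basis.to_dict(),
        "w0": model.w0,
        "w": model.w.tolist(),
        "lambda": model.lam,
        "neuron_ids": [str(n) for n in model.neuron_ids],
    }
    Path(path).write_text(json.dumps(doc))


def load_decoder(path) -> DecoderModel:
    doc = json.loads(Path(path).read_text())
    basis = BSplineBasis.from_dict(doc["basis"])
    return DecoderModel(
        w0=float(doc["w0"]),
        w=np.array(doc["w"], float),
        lam=float(doc["lambda"]),
        basis=basis,
        neuron_ids=doc["neuron_ids"],
    )
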