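"""Sparse generalized Laguerre-Volterra spike-transformation model.

Each output neuron is modeled as a probit point-process (MISO) unit: a
second-order Volterra expansion of the input spike trains produces a
synaptic potential ``u``, the neuron's own past spikes produce a
feedback after-potential ``a`` through a first-order kernel ``h``, and a
spike occurs in a bin when ``u + a + noise`` crosses a threshold. With
standard-normal noise the per-bin spike probability is
``p(t) = Phi(u(t) + a(t))`` (sigma = 1 and theta = 0 are fixed for
identifiability; the intercept absorbs the threshold). A MIMO model is a
concatenation of independently fitted MISO units sharing the input
ensemble.

Kernels are expanded on discrete Laguerre bases, and the expansion
coefficients are estimated by group-LASSO penalized likelihood: one
group per input's first-order block and one per input's second-order
block, so an uninformative input is removed as a whole. The intercept
and the feedback coefficients are not penalized. Optimization is an
outer iteratively-reweighted least-squares (Fisher scoring) loop with an
inner block coordinate descent using group soft-threshold updates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import ndtr

from .laguerre import LaguerreBasis, laguerre_basis
from .spike_data import ConcatenatedSession

__all__ = [
    "Group",
    "GLVMDesign",
    "GLVMCoefficients",
    "VolterraKernels",
    "IntensityTrace",
    "MISOFit",
    "MIMOModel",
    "MIMOConfig",
    "build_design",
    "glvm_neg_log_likelihood",
    "fit_miso_glvm",
    "default_lambda_grid",
    "adaptive_group_weights",
    "cross_validate_lambda",
    "reconstruct_kernels",
    "project_kernels",
    "predict_intensity",
    "simulate_output",
    "fit_mimo",
    "save_mimo_model",
    "load_mimo_model",
]

_PCLIP = 1e-12
_PHI_FLOOR = 1e-100


# ---------------------------------------------------------------------------
# design matrix


@dataclass
class Group:
    kind: str  # intercept | first_order | second_order | feedback
    input_index: int | None
    sl: slice
    penalized: bool


def _make_groups(n_inputs: int, J: int, L: int) -> list[Group]:
    groups = [Group("intercept", None, slice(0, 1), False)]
    col = 1
    n_pair = J * (J + 1) // 2
    for n in range(n_inputs):
        groups.append(Group("first_order", n, slice(col, col + J), True))
        col += J
        groups.append(Group("second_order", n, slice(col, col + n_pair), True))
        col += n_pair
    groups.append(Group("feedback", None, slice(col, col + L), False))
    return groups


def _pair_order(J: int) -> list[tuple[int, int]]:
    """Lower-triangular (j1, j2 <= j1) ordering of second-order pairs."""
    return [(j1, j2) for j1 in range(J) for j2 in range(j1 + 1)]


@dataclass
class GLVMDesign:
    """Feature matrix for one output neuron's MISO fit.

    Column 0 is the intercept; then for each input, J first-order
    Laguerre convolution features followed by J(J+1)/2 second-order
    products (lower-triangular order); the last L columns are feedback
    features from the observed output at lags >= 1 (teacher forcing).
    """

    X: np.ndarray = field(repr=False)
    groups: list[Group]
    n_inputs: int
    ff_basis: LaguerreBasis
    fb_basis: LaguerreBasis
    segment_bounds: list
    output_id: object = None

    @property
    def n_bins(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]


def _segment_slices(bounds, T):
    b = list(bounds) + [T]
    return [slice(a, c) for a, c in zip(b, b[1:])]


def _input_features(inputs: np.ndarray, ff_basis: LaguerreBasis, seg_slices) -> np.ndarray:
    """Per-input, per-basis causal convolutions v[n, j, t], reset per segment."""
    N, T = inputs.shape
    J = ff_basis.n_basis
    B = ff_basis.values  # (J, M+1)
    v = np.empty((N, J, T))
    x = np.asarray(inputs, float)
    for sl in seg_slices:
        seg = x[:, sl]
        full = fftconvolve(seg[:, None, :], B[None, :, :], axes=2)
        v[:, :, sl] = full[:, :, : seg.shape[1]]
    return v


def _feedback_features(y: np.ndarray, fb_basis: LaguerreBasis, seg_slices) -> np.ndarray:
    """Feedback features v[j, t] from output lags 1..M_h, reset per segment."""
    T = y.shape[0]
    L = fb_basis.n_basis
    kern = np.concatenate([np.zeros((L, 1)), fb_basis.values[:, 1:]], axis=1)
    v = np.empty((L, T))
    yf = np.asarray(y, float)
    for sl in seg_slices:
        seg = yf[sl]
        full = fftconvolve(seg[None, :], kern, axes=1)
        v[:, sl] = full[:, : seg.shape[0]]
    return v


def build_design(
    session: ConcatenatedSession,
    ff_basis: LaguerreBasis,
    fb_basis: LaguerreBasis,
    output_index: int,
) -> GLVMDesign:
    """Assemble the teacher-forced design matrix for one output neuron.

    Convolution history resets at every trial-segment boundary (the
    perievent windows are not contiguous in real time). Feedback
    features come from the *observed* output spike train at lags 1..M_h.
    """
    T = session.n_bins
    seg_slices = session.segment_slices
    shortest = session.min_segment_length()
    if max(ff_basis.memory_bins, fb_basis.memory_bins) > shortest:
        raise ValueError(
            f"basis memory ({ff_basis.memory_bins}/{fb_basis.memory_bins} bins) "
            f"exceeds the shortest trial segment ({shortest} bins)"
        )
    N = session.inputs.shape[0]
    J, L = ff_basis.n_basis, fb_basis.n_basis
    groups = _make_groups(N, J, L)
    P = groups[-1].sl.stop
    X = np.empty((T, P))
    X[:, 0] = 1.0
    v1 = _input_features(session.inputs, ff_basis, seg_slices)
    pairs = _pair_order(J)
    for g in groups[1:-1]:
        n = g.input_index
        if g.kind == "first_order":
            X[:, g.sl] = v1[n].T
        else:
            for k, (j1, j2) in enumerate(pairs):
                X[:, g.sl.start + k] = v1[n, j1] * v1[n, j2]
    y = session.outputs[output_index]
    X[:, groups[-1].sl] = _feedback_features(y, fb_basis, seg_slices).T
    out_id = session.output_ids[output_index] if session.output_ids else output_index
    return GLVMDesign(
        X=X,
        groups=groups,
        n_inputs=N,
        ff_basis=ff_basis,
        fb_basis=fb_basis,
        segment_bounds=list(session.segment_bounds),
        output_id=out_id,
    )


# ---------------------------------------------------------------------------
# coefficients and kernels


@dataclass
class GLVMCoefficients:
    """Laguerre-domain model coefficients for one MISO unit.

    ``c1`` is N x J (first-order), ``c2s`` is N x J(J+1)/2 in
    lower-triangular pair order, ``ch`` the feedback coefficients.
    ``sigma`` and ``theta`` are fixed at 1 and 0: only (c0 - theta)/sigma
    is identified, so the intercept absorbs the threshold.
    """

    c0: float
    c1: np.ndarray
    c2s: np.ndarray
    ch: np.ndarray
    sigma: float = 1.0
    theta: float = 0.0
    diagnostics: dict | None = None

    @property
    def n_inputs(self) -> int:
        return self.c1.shape[0]

    @property
    def J(self) -> int:
        return self.c1.shape[1]

    @property
    def L(self) -> int:
        return self.ch.shape[0]

    def to_vector(self) -> np.ndarray:
        parts = [np.atleast_1d(self.c0)]
        for n in range(self.n_inputs):
            parts.append(self.c1[n])
            parts.append(self.c2s[n])
        parts.append(self.ch)
        return np.concatenate(parts)

    @classmethod
    def from_vector(cls, vec: np.ndarray, n_inputs: int, J: int, L: int) -> "GLVMCoefficients":
        vec = np.asarray(vec, float)
        n_pair = J * (J + 1) // 2
        c1 = np.empty((n_inputs, J))
        c2s = np.empty((n_inputs, n_pair))
        col = 1
        for n in range(n_inputs):
            c1[n] = vec[col : col + J]
            col += J
            c2s[n] = vec[col : col + n_pair]
            col += n_pair
        return cls(c0=float(vec[0]), c1=c1, c2s=c2s, ch=vec[col : col + L].copy())

    def zero_groups(self, tol: float = 0.0) -> list[tuple[str, int]]:
        """Penalized groups whose norm is <= tol (exactly zero by default)."""
        out = []
        for n in range(self.n_inputs):
            if np.linalg.norm(self.c1[n]) <= tol:
                out.append(("first_order", n))
            if np.linalg.norm(self.c2s[n]) <= tol:
                out.append(("second_order", n))
        return out


@dataclass
class VolterraKernels:
    """Time(lag)-domain kernels reconstructed from Laguerre coefficients.

    ``k1`` is N x (M_k+1); ``k2s`` is N x (M_k+1) x (M_k+1), symmetric in
    its two lags; ``h`` has length M_h covering feedback lags 1..M_h.
    """

    k0: float
    k1: np.ndarray
    k2s: np.ndarray
    h: np.ndarray


@dataclass
class IntensityTrace:
    """Per-bin synaptic potential, after-potential and firing probability."""

    u: np.ndarray
    a: np.ndarray
    p: np.ndarray


def reconstruct_kernels(
    coeffs: GLVMCoefficients, ff_basis: LaguerreBasis, fb_basis: LaguerreBasis
) -> VolterraKernels:
    """Map Laguerre coefficients to lag-domain Volterra kernels.

    k1^(n)(tau) = sum_j c1(n,j) b_j(tau). The second-order kernel is
    symmetrized from the lower-triangular expansion: an off-diagonal
    coefficient is split evenly between (tau1, tau2) and (tau2, tau1).
    h(tau) = sum_j ch(j) b_j(tau) for tau = 1..M_h.
    """
    B = ff_basis.values
    N, J = coeffs.c1.shape
    Mk1 = B.shape[1]
    k1 = coeffs.c1 @ B
    k2s = np.zeros((N, Mk1, Mk1))
    for k, (j1, j2) in enumerate(_pair_order(J)):
        outer = np.outer(B[j1], B[j2])
        for n in range(N):
            c = coeffs.c2s[n, k]
            if j1 == j2:
                k2s[n] += c * outer
            else:
                k2s[n] += 0.5 * c * (outer + outer.T)
    h = coeffs.ch @ fb_basis.values[:, 1:]
    return VolterraKernels(k0=coeffs.c0, k1=k1, k2s=k2s, h=h)


def project_kernels(
    kernels: VolterraKernels, ff_basis: LaguerreBasis, fb_basis: LaguerreBasis
) -> GLVMCoefficients:
    """Least-squares projection of lag-domain kernels back onto the bases."""
    B = ff_basis.values  # (J, M+1)
    J = ff_basis.n_basis
    c1 = np.atleast_2d(ff_basis.project(kernels.k1))
    Bp = np.linalg.pinv(B)  # (M+1, J)
    pairs = _pair_order(J)
    N = kernels.k1.shape[0]
    c2s = np.empty((N, len(pairs)))
    for n in range(N):
        C = Bp.T @ kernels.k2s[n] @ Bp  # symmetric J x J coefficient matrix
        for k, (j1, j2) in enumerate(pairs):
            c2s[n, k] = C[j1, j1] if j1 == j2 else C[j1, j2] + C[j2, j1]
    Bfb = fb_basis.values[:, 1:]
    ch, *_ = np.linalg.lstsq(Bfb.T, np.asarray(kernels.h, float), rcond=None)
    return GLVMCoefficients(float(kernels.k0), c1, c2s, ch)


# ---------------------------------------------------------------------------
# likelihood and estimation


def _check_binary(y) -> np.ndarray:
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("output series must be binary 0/1")
    return y.astype(float)


def _probit_parts(eta: np.ndarray, y: np.ndarray):
    p = np.clip(ndtr(eta), _PCLIP, 1 - _PCLIP)
    phi = np.exp(-0.5 * eta**2) / np.sqrt(2 * np.pi)
    nll = -np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))
    dnll_deta = -(y - p) * phi / (p * (1 - p))
    return p, phi, nll, dnll_deta


def glvm_neg_log_likelihood(coeffs_or_vec, design: GLVMDesign, y, return_grad: bool = True):
    """Bernoulli-probit negative log-likelihood and its exact gradient.

    Per-bin probability Phi(x_t . c) with probabilities clipped away from
    {0, 1} by 1e-12. The gradient is with respect to the flat coefficient
    vector in design-column order.
    """
    y = _check_binary(y)
    if y.shape[0] != design.n_bins:
        raise ValueError("design and output series have different lengths")
    if isinstance(coeffs_or_vec, GLVMCoefficients):
        c = coeffs_or_vec.to_vector()
    else:
        c = np.asarray(coeffs_or_vec, float)
    eta = design.X @ c
    _, _, nll, dnll_deta = _probit_parts(eta, y)
    if not return_grad:
        return nll
    return nll, design.X.T @ dnll_deta


def _group_weights(groups, weights):
    """Per-group penalty multipliers; 1 everywhere unless given.

    A weight of +inf clamps that group to exactly zero (used by the
    adaptive second stage for groups the first stage zeroed)."""
    if weights is None:
        return {gi: 1.0 for gi, g in enumerate(groups) if g.penalized}
    return {gi: float(weights[gi]) for gi, g in enumerate(groups) if g.penalized}


def _penalty_value(c, lam, groups, wts):
    pen = 0.0
    for gi, g in enumerate(groups):
        if not g.penalized:
            continue
        nrm = np.linalg.norm(c[g.sl])
        if np.isinf(wts[gi]):
            if nrm > 0:
                return np.inf
            continue
        pen += wts[gi] * nrm
    return lam * pen


def _penalized_objective(c, X, y, lam, groups, wts=None):
    eta = X @ c
    _, _, nll, _ = _probit_parts(eta, y)
    if wts is None:
        wts = _group_weights(groups, None)
    return nll + _penalty_value(c, lam, groups, wts)


def _bcd_quadratic(G, b, c, lam, groups, gammas, wts, n_sweeps=100, tol=1e-9):
    """Block coordinate descent on 0.5 c'Gc - b'c + lam * sum w_g ||c_g||.

    Penalized blocks take a majorized prox (group soft-threshold) step;
    unpenalized blocks are minimized exactly. Monotone on the quadratic.
    """
    Gc = G @ c

    def _qobj():
        return 0.5 * c @ Gc - b @ c + _penalty_value(c, lam, groups, wts)

    obj = _qobj()
    for _ in range(n_sweeps):
        for gi, g in enumerate(groups):
            sl = g.sl
            old = c[sl].copy()
            if g.penalized:
                if np.isinf(wts[gi]):
                    new = np.zeros_like(old)
                else:
                    gamma = gammas[gi]
                    v = old - (Gc[sl] - b[sl]) / gamma
                    nv = np.linalg.norm(v)
                    thr = lam * wts[gi] / gamma
                    shrink = max(0.0, 1.0 - thr / nv) if nv > 0 else 0.0
                    new = shrink * v
            else:
                r = b[sl] - Gc[sl] + G[sl, sl] @ old
                new = np.linalg.solve(
                    G[sl, sl] + 1e-10 * np.eye(sl.stop - sl.start), r
                )
            delta = new - old
            if np.any(delta):
                c[sl] = new
                Gc += G[:, sl] @ delta
        new_obj = _qobj()
        if obj - new_obj <= tol * (1 + abs(new_obj)):
            obj = new_obj
            break
        obj = new_obj
    return c


def _fit_vector(
    X, y, groups, lam, tol=1e-6, max_iter=200, coef_init=None, warn_nonconv=True,
    weights=None,
):
    """IRLS + group-BCD minimizer of NLL(c) + lam * sum_g w_g ||c_g||_2."""
    P = X.shape[1]
    c = np.zeros(P) if coef_init is None else np.asarray(coef_init, float).copy()
    wts = _group_weights(groups, weights)
    S = _penalized_objective(c, X, y, lam, groups, wts)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = X @ c
        p, phi, _, dnll_deta = _probit_parts(eta, y)
        w = np.clip(phi**2 / (p * (1 - p)), 1e-10, None)
        g_vec = X.T @ dnll_deta
        A = X * np.sqrt(w)[:, None]
        G = A.T @ A
        b = G @ c - g_vec
        gammas = {
            gi: float(np.linalg.eigvalsh(G[g.sl, g.sl])[-1]) + 1e-12
            for gi, g in enumerate(groups)
            if g.penalized
        }
        c_new = _bcd_quadratic(G, b, c.copy(), lam, groups, gammas, wts,
                               tol=0.01 * tol)
        S_new = _penalized_objective(c_new, X, y, lam, groups, wts)
        # the quadratic is only a local model; halve the step until the
        # true penalized objective decreases
        for _ in range(30):
            if S_new <= S + 1e-10 * (1 + abs(S)):
                break
            c_new = 0.5 * (c + c_new)
            S_new = _penalized_objective(c_new, X, y, lam, groups, wts)
        if S_new > S:
            break  # no further progress possible
        drop = S - S_new
        c, S = c_new, S_new
        if drop <= tol * (1 + abs(S)):
            converged = True
            break
    if not converged and warn_nonconv:
        warnings.warn(f"group-LASSO probit fit: not converged after {n_iter} "
                      f"iterations (objective {S:.6g})")
    return c, {"objective": float(S), "n_iter": n_iter, "converged": converged,
               "lambda": float(lam)}


def fit_miso_glvm(
    design: GLVMDesign,
    y,
    lam: float,
    tol: float = 1e-6,
    max_iter: int = 200,
    coef_init: np.ndarray | None = None,
    group_weights=None,
) -> GLVMCoefficients:
    """Fit one MISO unit by group-LASSO penalized probit likelihood.

    Minimizes NLL(c) + lam * (sum_n ||c1^(n)|| + sum_n ||c2s^(n)||);
    the intercept and feedback coefficients are unpenalized.
    ``group_weights`` (indexed like ``design.groups``) scales the
    penalty per group — the adaptive second stage uses weights inversely
    proportional to a pilot fit's group norms, with +inf clamping groups
    the pilot zeroed.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    y = _check_binary(y)
    c, diag = _fit_vector(design.X, y, design.groups, lam, tol, max_iter, coef_init,
                          weights=group_weights)
    coeffs = GLVMCoefficients.from_vector(
        c, design.n_inputs, design.ff_basis.n_basis, design.fb_basis.n_basis
    )
    coeffs.diagnostics = diag
    return coeffs


def adaptive_group_weights(design: GLVMDesign, pilot: "GLVMCoefficients") -> np.ndarray:
    """Per-group penalty weights from a pilot fit: w_g = <norm>/||c_g||.

    Groups the pilot zeroed get +inf (stay zero in the second stage);
    the finite weights are scaled to mean 1 so the adaptive lambda grid
    lives on a comparable scale.
    """
    c = pilot.to_vector()
    weights = np.ones(len(design.groups))
    norms = {}
    for gi, g in enumerate(design.groups):
        if g.penalized:
            norms[gi] = np.linalg.norm(c[g.sl])
    finite = [n for n in norms.values() if n > 0]
    scale = np.mean(finite) if finite else 1.0
    for gi, nrm in norms.items():
        weights[gi] = np.inf if nrm == 0 else scale / nrm
    return weights


def _null_fit(X, y, groups, tol=1e-8, max_iter=100):
    """Unpenalized fit of the intercept + feedback columns only."""
    cols = np.concatenate(
        [np.arange(g.sl.start, g.sl.stop) for g in groups if not g.penalized]
    )
    sub_groups = []
    start = 0
    for g in groups:
        if not g.penalized:
            n = g.sl.stop - g.sl.start
            sub_groups.append(Group(g.kind, g.input_index, slice(start, start + n), False))
            start += n
    c_sub, _ = _fit_vector(X[:, cols], y, sub_groups, 0.0, tol, max_iter,
                           warn_nonconv=False)
    c = np.zeros(X.shape[1])
    c[cols] = c_sub
    return c


def lambda_max(design: GLVMDesign, y, group_weights=None) -> float:
    """Smallest lambda at which every penalized group is zero.

    Computed from the group-wise gradient norms of the NLL at the null
    model (intercept + feedback fitted without penalty): the group-LASSO
    KKT conditions zero a group exactly when its gradient norm is
    <= lam * w_g.
    """
    y = _check_binary(y)
    c = _null_fit(design.X, y, design.groups)
    _, grad = glvm_neg_log_likelihood(c, design, y)
    wts = _group_weights(design.groups, group_weights)
    vals = [np.linalg.norm(grad[g.sl]) / wts[gi]
            for gi, g in enumerate(design.groups)
            if g.penalized and np.isfinite(wts[gi])]
    return max(vals)


def default_lambda_grid(
    design: GLVMDesign, y, n_lambda: int = 30, decades: float = 4.0,
    group_weights=None,
) -> np.ndarray:
    """Descending log-spaced grid from lambda_max down by ``decades``."""
    lmax = lambda_max(design, y, group_weights)
    return np.geomspace(lmax, lmax * 10.0 ** (-decades), n_lambda)


@dataclass
class CVCurve:
    lambda_grid: np.ndarray
    mean_nll: np.ndarray  # per-bin held-out NLL, averaged over folds
    fold_nll: np.ndarray  # n_folds x n_lambda
    chosen: float


def _fit_path(X, y, groups, grid, tol, max_iter, weights=None):
    """Warm-started coefficient path along a descending lambda grid."""
    coefs = []
    c = None
    for lam in grid:
        c, _ = _fit_vector(X, y, groups, lam, tol, max_iter, coef_init=c,
                           warn_nonconv=False, weights=weights)
        coefs.append(c.copy())
    return coefs


def cross_validate_lambda(
    design: GLVMDesign,
    y,
    lambda_grid=None,
    n_folds: int = 2,
    tol: float = 1e-6,
    max_iter: int = 200,
    rule: str = "min",
    group_weights=None,
) -> tuple[float, CVCurve]:
    """Choose lambda by K-fold cross-validation over contiguous trial blocks.

    Folds are contiguous blocks of trial segments (the default two-fold
    split is first half vs second half of the session). With
    ``rule="min"`` (default) the selected lambda minimizes the mean
    held-out per-bin NLL; ties go to the larger (sparser) lambda. With
    ``rule="1se"`` the largest lambda whose mean NLL is within one
    standard error of that minimum is chosen — the standard choice when
    the goal is support recovery rather than raw prediction, because the
    CV curve is typically flat near its minimum while sparsity is not.
    """
    y = _check_binary(y)
    segs = _segment_slices(design.segment_bounds, design.n_bins)
    if len(segs) < n_folds:
        raise ValueError(f"{len(segs)} trial segments < {n_folds} folds")
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(design, y, group_weights=group_weights)
    grid = np.sort(np.asarray(lambda_grid, float))[::-1]
    fold_of_seg = np.minimum(
        (np.arange(len(segs)) * n_folds) // len(segs), n_folds - 1
    )
    fold_nll = np.empty((n_folds, len(grid)))
    for f in range(n_folds):
        train_rows = np.concatenate(
            [np.arange(s.start, s.stop) for s, fo in zip(segs, fold_of_seg) if fo != f]
        )
        test_rows = np.concatenate(
            [np.arange(s.start, s.stop) for s, fo in zip(segs, fold_of_seg) if fo == f]
        )
        path = _fit_path(design.X[train_rows], y[train_rows], design.groups,
                         grid, tol, max_iter, weights=group_weights)
        Xte, yte = design.X[test_rows], y[test_rows]
        for i, c in enumerate(path):
            _, _, nll, _ = _probit_parts(Xte @ c, yte)
            fold_nll[f, i] = nll / len(test_rows)
    mean_nll = fold_nll.mean(axis=0)
    best = int(np.argmin(mean_nll))  # grid descending: first argmin = larger lam
    if rule == "1se":
        se = fold_nll.std(axis=0, ddof=1) / np.sqrt(n_folds)
        cutoff = mean_nll[best] + se[best]
        best = int(np.flatnonzero(mean_nll <= cutoff)[0])
    elif rule != "min":
        raise ValueError("rule must be 'min' or '1se'")
    chosen = float(grid[best])
    return chosen, CVCurve(grid, mean_nll, fold_nll, chosen)


# ---------------------------------------------------------------------------
# prediction and simulation


def predict_intensity(
    coeffs: GLVMCoefficients,
    session: ConcatenatedSession,
    ff_basis: LaguerreBasis,
    fb_basis: LaguerreBasis,
    observed_output: np.ndarray | None = None,
) -> IntensityTrace:
    """Per-bin potentials and firing probability for one MISO unit.

    Teacher-forced mode (``observed_output`` given): the after-potential
    comes from the observed output history. Input-only mode: a(t) = 0.
    """
    seg_slices = session.segment_slices
    v1 = _input_features(session.inputs, ff_basis, seg_slices)
    u = np.full(session.n_bins, coeffs.c0, float)
    for n in range(coeffs.n_inputs):
        u += coeffs.c1[n] @ v1[n]
        for k, (j1, j2) in enumerate(_pair_order(coeffs.J)):
            u += coeffs.c2s[n, k] * v1[n, j1] * v1[n, j2]
    if observed_output is None:
        a = np.zeros_like(u)
    else:
        yo = _check_binary(observed_output)
        a = coeffs.ch @ _feedback_features(yo, fb_basis, seg_slices)
    p = ndtr(u + a - coeffs.theta)
    return IntensityTrace(u=u, a=a, p=p)


def simulate_output(
    coeffs: GLVMCoefficients,
    session: ConcatenatedSession,
    ff_basis: LaguerreBasis,
    fb_basis: LaguerreBasis,
    n_realizations: int = 1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Free-run stochastic spike generation with feedback.

    Bin by bin: u(t) from the inputs, a(t) from the realization's own
    simulated spike history through the reconstructed feedback kernel h,
    then y(t) ~ Bernoulli(Phi(u + a)). Each realization carries its own
    feedback state; history resets at trial-segment bounds.

    Returns (realizations [K x T] int8, mean firing probability [T]).
    """
    rng = np.random.default_rng(seed)
    u = predict_intensity(coeffs, session, ff_basis, fb_basis).u
    h = (coeffs.ch @ fb_basis.values[:, 1:]).astype(float)  # lags 1..M_h
    Mh = h.shape[0]
    K = int(n_realizations)
    T = session.n_bins
    Y = np.zeros((K, T), dtype=np.int8)
    mean_p = np.zeros(T)
    for sl in session.segment_slices:
        Ts = sl.stop - sl.start
        # A[:, t] accumulates the after-potential; a spike at local bin t
        # adds h to bins t+1 .. t+Mh
        A = np.zeros((K, Ts + Mh))
        useg = u[sl]
        draws = rng.random((K, Ts))
        for t in range(Ts):
            p = ndtr(useg[t] + A[:, t] - coeffs.theta)
            spk = draws[:, t] < p
            mean_p[sl.start + t] = p.mean()
            if spk.any():
                Y[spk, sl.start + t] = 1
                hi = min(Ts + Mh, t + 1 + Mh)
                for k in np.flatnonzero(spk):
                    A[k, t + 1 : hi] += h[: hi - t - 1]
    return Y, mean_p


# ---------------------------------------------------------------------------
# MIMO assembly


@dataclass
class MIMOConfig:
    """Settings for the MIMO fit (shared across all MISO units)."""

    J: int = 3
    L: int = 3
    alpha_ff: float = 0.98
    alpha_fb: float = 0.98
    memory_ff_bins: int = 1000
    memory_fb_bins: int = 1000
    n_lambda: int = 30
    lambda_decades: float = 4.0
    lambda_grid: np.ndarray | None = None
    n_folds: int = 2
    tol: float = 1e-6
    max_iter: int = 200
    #: adaptive (two-stage) group LASSO: a pilot CV fit sets per-group
    #: penalty weights proportional to 1/||c_g||, then lambda is
    #: re-cross-validated and the model refitted with those weights.
    #: Strong groups are barely shrunk (debiased kernels), weak and
    #: zeroed groups stay regularized, so the kernel estimates avoid
    #: both lasso shrinkage bias and unpenalized-refit variance.
    adaptive: bool = True

    def make_bases(self) -> tuple[LaguerreBasis, LaguerreBasis]:
        return (
            laguerre_basis(self.alpha_ff, self.J, self.memory_ff_bins),
            laguerre_basis(self.alpha_fb, self.L, self.memory_fb_bins),
        )


@dataclass
class MISOFit:
    output_id: object
    coeffs: GLVMCoefficients
    lam: float
    cv: CVCurve | None = None


@dataclass
class MIMOModel:
    """A concatenation of independently fitted MISO units."""

    fits: list[MISOFit]
    ff_basis: LaguerreBasis
    fb_basis: LaguerreBasis
    input_ids: list
    bin_width_s: float = 0.002

    @property
    def n_outputs(self) -> int:
        return len(self.fits)

    def output_ids(self) -> list:
        return [f.output_id for f in self.fits]

    def kernels(self) -> list[VolterraKernels]:
        return [reconstruct_kernels(f.coeffs, self.ff_basis, self.fb_basis) for f in self.fits]

    def predict(self, session: ConcatenatedSession, teacher_forced: bool = True):
        """Intensity traces per output (teacher-forced or input-only)."""
        traces = []
        for i, f in enumerate(self.fits):
            obs = session.outputs[i] if teacher_forced else None
            traces.append(
                predict_intensity(f.coeffs, session, self.ff_basis, self.fb_basis, obs)
            )
        return traces

    def simulate(self, session: ConcatenatedSession, n_realizations: int = 1, seed: int = 0):
        """Free-run simulation for every output.

        Returns (list of per-output realization arrays [K x T],
        array of mean probability traces [n_outputs x T]).
        """
        Ys, Ps = [], []
        for i, f in enumerate(self.fits):
            Y, P = simulate_output(
                f.coeffs, session, self.ff_basis, self.fb_basis,
                n_realizations, seed=seed + 7919 * i,
            )
            Ys.append(Y)
            Ps.append(P)
        return Ys, np.array(Ps)


def fit_mimo(
    session: ConcatenatedSession,
    config: MIMOConfig | None = None,
    verbose: bool = False,
) -> MIMOModel:
    """Fit an independent MISO unit (with its own CV lambda) per output.

    A single coefficient set serves all trials regardless of the memory
    label — left and right trials are pooled, which is what lets the
    fitted model predict outputs without knowing the behavioral event.
    """
    if config is None:
        config = MIMOConfig()
    if session.outputs.shape[0] < 1:
        raise ValueError("session has no output neurons")
    ff, fb = config.make_bases()
    fits = []
    for i in range(session.outputs.shape[0]):
        design = build_design(session, ff, fb, i)
        y = session.outputs[i].astype(float)
        grid = config.lambda_grid
        lam, cv = cross_validate_lambda(
            design, y, lambda_grid=grid, n_folds=config.n_folds,
            tol=config.tol, max_iter=config.max_iter,
        )
        coeffs = fit_miso_glvm(design, y, lam, tol=config.tol,
                               max_iter=config.max_iter)
        if config.adaptive:
            weights = adaptive_group_weights(design, coeffs)
            lam, cv = cross_validate_lambda(
                design, y, lambda_grid=None, n_folds=config.n_folds,
                tol=config.tol, max_iter=config.max_iter, group_weights=weights,
            )
            coeffs = fit_miso_glvm(design, y, lam, tol=config.tol,
                                   max_iter=config.max_iter,
                                   group_weights=weights,
                                   coef_init=coeffs.to_vector())
        fits.append(MISOFit(output_id=design.output_id, coeffs=coeffs, lam=lam, cv=cv))
        if verbose:
            print(f"  output {design.output_id}: lambda={lam:.4g}, "
                  f"zero groups={len(coeffs.zero_groups())}")
    return MIMOModel(
        fits=fits,
        ff_basis=ff,
        fb_basis=fb,
        input_ids=list(session.input_ids),
        bin_width_s=session.bin_width_s,
    )


# ---------------------------------------------------------------------------
# serialization


def save_mimo_model(model: MIMOModel, path) -> None:
    """JSON serialization: basis parameters, coefficients, lambdas."""
    doc = {
        "bin_width_s": model.bin_width_s,
        "input_ids": [str(i) for i in model.input_ids],
        "ff_basis": model.ff_basis.to_dict(),
        "fb_basis": model.fb_basis.to_dict(),
        "fits": [
            {
                "output_id": str(f.output_id),
                "lambda": f.lam,
                "c0": f.coeffs.c0,
                "c1": f.coeffs.c1.tolist(),
                "c2s": f.coeffs.c2s.tolist(),
                "ch": f.coeffs.ch.tolist(),
                "diagnostics": f.coeffs.diagnostics,
            }
            for f in model.fits
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_mimo_model(path) -> MIMOModel:
    doc = json.loads(Path(path).read_text())
    ff = LaguerreBasis.from_dict(doc["ff_basis"])
    fb = LaguerreBasis.from_dict(doc["fb_basis"])
    fits = []
    for fd in doc["fits"]:
        coeffs = GLVMCoefficients(
            c0=float(fd["c0"]),
            c1=np.array(fd["c1"], float),
            c2s=np.array(fd["c2s"], float),
            ch=np.array(fd["ch"], float),
            diagnostics=fd.get("diagnostics"),
        )
        fits.append(MISOFit(output_id=fd["output_id"], coeffs=coeffs, lam=float(fd["lambda"])))
    return MIMOModel(
        fits=fits,
        ff_basis=ff,
        fb_basis=fb,
        input_ids=doc["input_ids"],
        bin_width_s=float(doc["bin_width_s"]),
    )
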