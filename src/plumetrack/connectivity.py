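"""Eigen-structure and stimulus-integration-timescale analysis of recurrent
weights and recurrence Jacobians.

For the vanilla RNN update ``h_t = tanh(W_h h_{t-1} + W_x x_t + b)`` the
recurrence Jacobian at an expansion point (h, x) is
``J_rec = diag(1 - tanh^2(W_h h + W_x x + b)) W_h`` (and analogously
``J_inp`` with ``W_x``); at (0, 0) with zero bias, ``J_rec = W_h``.

A stable eigenvalue ``|lambda| <= 1`` corresponds to a stimulus integration
timescale ``tau = |1 / ln |lambda||`` (steps): the number of steps over
which input along that eigenmode decays by 1/e.  Eigenvalues within a small
margin of the unit circle have unbounded tau and are flagged marginal;
eigenvalues outside it are unstable modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EigenReport",
    "TimescaleReport",
    "eigenspectrum",
    "recurrence_jacobian",
    "input_jacobian",
    "integration_timescales",
    "trajectory_timescale_profile",
    "STABILITY_MARGIN",
]

#: eigenvalues with |lambda| within this margin of 1 are flagged marginal.
STABILITY_MARGIN = 1e-6

REAL_TOL = 1e-9


@dataclass
class EigenReport:
    eigenvalues: np.ndarray            # complex, descending by modulus
    eigenvectors: np.ndarray
    unstable: np.ndarray               # |lambda| > 1
    n_real_gt_one: int                 # strictly real eigenvalues > 1


@dataclass
class TimescaleReport:
    timescales: np.ndarray             # steps, sorted descending
    n_unstable: int
    n_marginal: int
    mean_curve: np.ndarray | None = None   # per-rank mean over steps
    ci_halfwidth: np.ndarray | None = None  # 99% confidence half-width
    n_steps: int = 0


def eigenspectrum(matrix) -> EigenReport:
    """Full eigendecomposition with unit-circle classification."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    vals, vecs = np.linalg.eig(m)
    order = np.argsort(-np.abs(vals))
    vals, vecs = vals[order], vecs[:, order]
    mod = np.abs(vals)
    real_gt_one = (np.abs(vals.imag) < REAL_TOL) & (vals.real > 1.0)
    return EigenReport(vals, vecs, mod > 1.0, int(real_gt_one.sum()))


def _jacobian(h, x, W_h, W_x, b, wrt):
    h = np.zeros(W_h.shape[0]) if h is None else np.asarray(h, dtype=float)
    x = np.zeros(W_x.shape[1]) if x is None else np.asarray(x, dtype=float)
    z = W_h @ h + W_x @ x + b
    gain = 1.0 - np.tanh(z) ** 2
    return gain[:, None] * wrt


def recurrence_jacobian(h, x, W_h, W_x, b) -> np.ndarray:
    """J_rec = diag(1 - tanh^2(z)) W_h at expansion point (h, x); pass
    ``x=None`` for the zero-input expansion."""
    return _jacobian(h, x, W_h, W_x, b, W_h)


def input_jacobian(h, x, W_h, W_x, b) -> np.ndarray:
    """J_inp = diag(1 - tanh^2(z)) W_x at expansion point (h, x)."""
    return _jacobian(h, x, W_h, W_x, b, W_x)


def integration_timescales(eigenvalues, margin: float = STABILITY_MARGIN
                           ) -> TimescaleReport:
    """tau = |1 / ln|lambda|| for each stable eigenvalue, sorted descending.

    Unstable eigenvalues (|lambda| > 1) are excluded and counted; moduli
    within ``margin`` of 1 are excluded as marginal (tau unbounded);
    lambda = 0 yields tau = 0 (instantaneous forgetting) by the limiting
    convention.
    """
    mod = np.abs(np.asarray(eigenvalues))
    unstable = mod > 1.0
    marginal = (~unstable) & (mod > 1.0 - margin)
    stable = ~(unstable | marginal)
    m = mod[stable]
    tau = np.zeros(m.size)
    nz = m > 0
    tau[nz] = np.abs(1.0 / np.log(m[nz]))
    tau = np.sort(tau)[::-1]
    return TimescaleReport(tau, int(unstable.sum()), int(marginal.sum()))


def trajectory_timescale_profile(W_h, W_x, b, hidden_trace,
                                 margin: float = STABILITY_MARGIN,
                                 confidence: float = 0.99) -> TimescaleReport:
    """Per-step recurrence-Jacobian timescales along a trajectory.

    At each step the recurrence Jacobian is evaluated at ``(h_t, 0)`` (zero
    input), its eigenvalues converted to timescales, and the sorted
    timescale vectors averaged across steps; a normal-approximation
    confidence band accompanies the mean curve.  Intended use: pool one
    successful and one unsuccessful episode from each of three wind regimes.
    """
    from scipy.stats import norm

    H = np.asarray(hidden_trace, dtype=float)
    if H.ndim != 2 or H.shape[0] == 0:
        raise ValueError("hidden trace must be a non-empty (T, n) array")
    n = W_h.shape[0]
    per_step = []
    n_unstable = n_marginal = 0
    for h in H:
        J = recurrence_jacobian(h, None, W_h, W_x, b)
        vals = np.linalg.eigvals(J)
        rep = integration_timescales(vals, margin)
        n_unstable += rep.n_unstable
        n_marginal += rep.n_marginal
        # pad excluded modes with nan so ranks stay aligned
        tau = np.full(n, np.nan)
        tau[:rep.timescales.size] = rep.timescales
        per_step.append(tau)
    M = np.vstack(per_step)
    mean_curve = np.nanmean(M, axis=0)
    counts = np.sum(np.isfinite(M), axis=0)
    sd = np.nanstd(M, axis=0, ddof=1)
    z = norm.ppf(0.5 + confidence / 2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        half = z * sd / np.sqrt(np.maximum(counts, 1))
    pooled = np.sort(M[np.isfinite(M)])[::-1]
    return TimescaleReport(pooled, n_unstable, n_marginal,
                           mean_curve=mean_curve, ci_halfwidth=half,
                           n_steps=H.shape[0])
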