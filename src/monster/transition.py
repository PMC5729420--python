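"""Estimation of the TF x TF network transition matrix.

Given an initial-state network A and a final-state network B (both
genes x TFs), the transition model is B = A T + E: each TF's final-state
targeting column is a linear combination of the initial-state columns.
Estimation regresses the *change* in targeting, b_i - a_i, on the columns
of A (no intercept — the map is homogeneous), giving the coefficients
T_diff; the identity-referenced matrix is T_full = T_diff + I. When A has
full column rank the two parameterizations are algebraically equivalent:
regressing b_i directly on A gives T_full, because the projection of a_i
onto col(A) has coefficient vector e_i. Two nearly identical states
therefore produce T_full close to the identity, and deviation from the
identity encodes regulatory rewiring.

Solvers are SVD/QR based (never an explicit inverse). Optional ridge
(lambda * ||tau||_2^2) and lasso (lambda * ||tau||_1) penalties are
available; the unpenalized least-squares fit is the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

log = logging.getLogger(__name__)

METHODS = ("ols", "ridge", "lasso")


@dataclass(frozen=True)
class TransitionResult:
    """The estimated transition matrix in both parameterizations.

    ``T_full`` maps the initial network onto the final one (B ~ A T_full);
    ``T_diff = T_full - I`` holds the difference-regression coefficients.
    ``residuals`` is E = B - A T_full (genes x TFs).
    """

    tf_ids: tuple[str, ...]
    T_full: np.ndarray
    T_diff: np.ndarray
    residuals: np.ndarray
    method: str
    penalty: float


def _lasso_column(A: np.ndarray, y: np.ndarray, lam: float,
                  tol: float = 1e-12, max_iter: int = 10_000) -> np.ndarray:
    """Coordinate descent for ||y - A tau||_2^2 + lam * ||tau||_1.

    Intercept-free; columns are used as-is (no re-standardization).
    """
    m = A.shape[1]
    col_ss = np.einsum("ij,ij->j", A, A)
    tau = np.zeros(m)
    resid = y.copy()
    thresh = lam / 2.0
    for _ in range(max_iter):
        max_delta = 0.0
        for k in range(m):
            if col_ss[k] == 0.0:
                continue
            rho = A[:, k] @ resid + col_ss[k] * tau[k]
            new = np.sign(rho) * max(abs(rho) - thresh, 0.0) / col_ss[k]
            delta = new - tau[k]
            if delta != 0.0:
                resid -= delta * A[:, k]
                tau[k] = new
                max_delta = max(max_delta, abs(delta))
        if max_delta < tol:
            break
    return tau


def estimate_transition(A: np.ndarray, B: np.ndarray, method: str = "ols",
                        penalty: float = 0.0,
                        tf_ids: Sequence[str] | None = None) -> TransitionResult:
    """Estimate the TF x TF transition matrix mapping network A onto B.

    Parameters
    ----------
    A, B
        Initial- and final-state edge-weight matrices, genes x TFs, same
        shape.
    method
        ``"ols"`` (default, unpenalized), ``"ridge"`` or ``"lasso"``.
    penalty
        Nonnegative penalty weight; must be 0 for OLS.
    tf_ids
        Optional TF labels; defaults to TF1..TFm positional names.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"A {A.shape} and B {B.shape} must have the same shape")
    if A.ndim != 2:
        raise ValueError("A and B must be 2-D (genes x TFs)")
    if not (np.isfinite(A).all() and np.isfinite(B).all()):
        raise ValueError("transition inputs contain NaN/inf")
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    if penalty < 0:
        raise ValueError("penalty must be nonnegative")
    if method == "ols" and penalty != 0:
        raise ValueError("penalty must be 0 for method='ols'")
    if method != "ols" and penalty == 0:
        log.warning("method=%s with penalty=0 is equivalent to OLS", method)
    p, m = A.shape
    if p < m:
        log.warning("fewer genes (%d) than TFs (%d): transition regression is "
                    "under-determined", p, m)
    if tf_ids is None:
        tf_ids = tuple(f"TF{i + 1}" for i in range(m))
    else:
        tf_ids = tuple(tf_ids)
        if len(tf_ids) != m:
            raise ValueError("tf_ids length does not match the TF dimension")

    Y = B - A
    if method == "ols":
        T_diff, _, rank, _ = np.linalg.lstsq(A, Y, rcond=None)
        if rank < m:
            log.warning(
                "A'A is singular (rank %d < %d TFs): reporting the "
                "minimum-norm least-squares transition matrix", rank, m,
            )
    elif method == "ridge":
        # ||y - A t||^2 + penalty * ||t||^2 via the augmented system
        aug_A = np.vstack([A, np.sqrt(penalty) * np.eye(m)])
        aug_Y = np.vstack([Y, np.zeros((m, m))])
        T_diff = np.linalg.lstsq(aug_A, aug_Y, rcond=None)[0]
    else:
        T_diff = np.column_stack([_lasso_column(A, Y[:, i], penalty)
                                  for i in range(m)])

    T_full = T_diff + np.eye(m)
    residuals = Y - A @ T_diff
    return TransitionResult(tf_ids=tf_ids, T_full=T_full, T_diff=T_diff,
                            residuals=residuals, method=method, penalty=float(penalty))


def equivalence_check(A: np.ndarray, B: np.ndarray, tol: float = 1e-8) -> bool:
    """Audit that the two regression targets agree on full-rank designs.

    Regressing b_i directly on A and regressing the difference b_i - a_i on
    A (then adding I) must produce the same transition matrix whenever A
    has full column rank. For rank-deficient A the identity is not
    guaranteed, so the check is skipped with a warning (vacuously True).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    m = A.shape[1]
    if np.linalg.matrix_rank(A) < m:
        log.warning("equivalence check skipped: A is rank-deficient")
        return True
    direct = np.linalg.lstsq(A, B, rcond=None)[0]
    via_diff = np.linalg.lstsq(A, B - A, rcond=None)[0] + np.eye(m)
    return bool(np.max(np.abs(direct - via_diff)) < tol)
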