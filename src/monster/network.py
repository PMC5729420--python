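"""Phenotype-specific bipartite TF->gene network inference.

A network is built from two complementary evidence sources and a motif
prior M (genes x TFs, binary):

* **direct evidence** ``d[j, i]`` — the squared partial correlation between
  TF i's encoding-gene expression and gene j's expression, conditional on
  the expression of all *other* motif-predicted regulators of gene j. It
  captures TF-target co-expression beyond what the remaining regulators
  explain.
* **indirect evidence** ``theta[j, i]`` — the fitted probability, from one
  logistic regression per TF (response: column i of M over the genes;
  predictors: each gene's expression profile across the phenotype's
  samples), that gene j is a motif target of TF i. It captures whether a
  gene's expression pattern looks like that of the TF's known targets.

Both lie in [0, 1] but measure different things (an R^2 versus a
probability), so they are combined non-parametrically: within each TF
column the genes are ranked on each evidence source (ascending, average
ties, normalized by the number of genes) and the edge weight is
``(1 - alpha) * rank(direct) + alpha * rank(indirect)`` with ``alpha = 0.5``
by default. Everything here is deterministic — there is no randomness in
network inference.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy.special import expit
from scipy.stats import rankdata

from .io import ExpressionDataset, MotifPrior

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.5
#: ridge penalty on non-intercept logistic coefficients (predictors are
#: standardized internally), guarding against perfect separation
LOGISTIC_PENALTY = 1e-6


@dataclass(frozen=True)
class EvidenceTable:
    """Direct (squared partial correlation) and indirect (fitted
    probability) evidence matrices, both genes x TFs in [0, 1], plus the
    per-TF logistic coefficient vectors kept for diagnostics."""

    direct: np.ndarray
    indirect: np.ndarray
    fit_coefficients: list | None = None


@dataclass(frozen=True)
class BipartiteNetwork:
    """A weighted bipartite TF->gene adjacency matrix (genes x TFs) with the
    evidence that produced it. Column weights lie in (0, 1] after rank
    normalization."""

    tf_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    weights: np.ndarray
    evidence: EvidenceTable
    alpha: float | None


def _orthonormal_basis(design: np.ndarray) -> np.ndarray:
    """Orthonormal basis of a design's column space (SVD, rank-tolerant).

    Projection onto this basis gives the least-squares fit; for
    rank-deficient or under-determined designs the residual is the unique
    minimum-norm least-squares residual.
    """
    q = sla.orth(design)
    return q


def _row_correlations(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Pearson correlation between rows of two already-centered matrices.

    Rows with (numerically) zero variance yield correlation 0 rather than
    NaN, so downstream ranking stays well-defined.
    """
    ln = np.linalg.norm(left, axis=1)
    rn = np.linalg.norm(right, axis=1)
    scale = max(float(ln.max(initial=0.0)), float(rn.max(initial=0.0)), 1.0)
    tol = 1e-12 * scale
    ls = np.where(ln > tol, ln, np.inf)
    rs = np.where(rn > tol, rn, np.inf)
    return (left @ right.T) / np.outer(ls, rs)


def direct_evidence(values: np.ndarray, prior: MotifPrior) -> np.ndarray:
    """Squared partial correlations of each TF with each gene.

    ``values`` rows must align with ``prior.gene_ids`` (harmonized order)
    and every TF id must name a gene row. Entry (j, i) conditions on the
    expression of the motif-predicted regulators of gene j other than TF i;
    an empty conditioning set reduces to the squared Pearson correlation.

    Residualization uses an orthonormal basis of [intercept, conditioning
    block], which yields the minimum-norm least-squares residual even when
    the block is collinear or wider than n - 2 (a warning counts the genes
    affected). Zero-variance residuals produce entry 0.
    """
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    if n < 3:
        raise ValueError("direct evidence requires at least 3 samples")
    gene_pos = {g: j for j, g in enumerate(prior.gene_ids)}
    try:
        tf_rows = np.array([gene_pos[t] for t in prior.tf_ids])
    except KeyError as exc:
        raise ValueError(f"TF {exc.args[0]!r} has no expression row") from exc
    tf_expr = values[tf_rows]  # m x n
    M = prior.M.astype(bool)

    groups: dict[tuple[int, ...], list[int]] = defaultdict(list)
    for j in range(p):
        groups[tuple(np.nonzero(M[j])[0])].append(j)

    out = np.zeros((p, len(prior.tf_ids)))
    ones = np.ones((n, 1))
    n_underdetermined = 0

    def residualize(rows: np.ndarray, basis: np.ndarray) -> np.ndarray:
        return rows - (rows @ basis) @ basis.T

    for cond_set, gene_rows in groups.items():
        gene_rows = np.asarray(gene_rows)
        block = values[tf_rows[list(cond_set)]].T if cond_set else np.empty((n, 0))
        if n < len(cond_set) + 2:
            n_underdetermined += len(gene_rows)
        basis = _orthonormal_basis(np.hstack([ones, block]))
        r_tf = residualize(tf_expr, basis)
        r_genes = residualize(values[gene_rows], basis)
        out[gene_rows, :] = _row_correlations(r_genes, r_tf) ** 2
        # regulators of these genes condition on the *other* regulators only
        for i in cond_set:
            reduced = [k for k in cond_set if k != i]
            block2 = values[tf_rows[reduced]].T if reduced else np.empty((n, 0))
            basis2 = _orthonormal_basis(np.hstack([ones, block2]))
            r_i = residualize(tf_expr[i][None, :], basis2)
            r_g = residualize(values[gene_rows], basis2)
            out[gene_rows, i] = _row_correlations(r_g, r_i)[:, 0] ** 2

    if n_underdetermined:
        log.warning(
            "minimum-norm residualization used for %d gene(s): conditioning "
            "set wider than n - 2", n_underdetermined,
        )
    return np.clip(out, 0.0, 1.0)


def _penalized_logistic(design: np.ndarray, response: np.ndarray,
                        penalty: float, tol: float = 1e-10,
                        max_iter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Newton (IRLS) fit of ridge-penalized logistic regression.

    Minimizes ``-loglik(beta) + penalty/2 * ||beta[1:]||^2`` for a design
    whose first column is the intercept. Returns (coefficients, fitted
    probabilities). Step-halving keeps the penalized objective monotone.
    """
    n_obs, n_par = design.shape
    pen = np.full(n_par, penalty)
    pen[0] = 0.0
    beta = np.zeros(n_par)

    def objective(b: np.ndarray) -> float:
        eta = design @ b
        # -loglik = sum(log(1 + e^eta) - y*eta), computed overflow-safely
        return float(np.sum(np.logaddexp(0.0, eta) - response * eta)
                     + 0.5 * np.sum(pen * b * b))

    obj = objective(beta)
    for _ in range(max_iter):
        eta = design @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = design.T @ (mu - response) + pen * beta
        hess = design.T @ (design * w[:, None]) + np.diag(pen)
        # tiny Levenberg fallback keeps the solve well-posed when w -> 0
        try:
            step = np.linalg.solve(hess + 1e-12 * np.eye(n_par), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        size = 1.0
        for _ in range(40):
            cand = beta - size * step
            cand_obj = objective(cand)
            if cand_obj <= obj + 1e-14:
                break
            size *= 0.5
        if not np.all(np.isfinite(cand)):
            break
        delta = np.max(np.abs(cand - beta))
        beta, obj = cand, cand_obj
        if delta < tol:
            break
    return beta, expit(design @ beta)


def indirect_evidence(values: np.ndarray, prior: MotifPrior,
                      penalty: float = LOGISTIC_PENALTY) -> np.ndarray:
    """Fitted motif-membership probabilities, one logistic fit per TF.

    Observations are genes; predictors are the samples of the current
    phenotype (design p x N plus intercept, predictors standardized
    internally). A TF whose motif column is all-0 or all-1 gets a constant
    column equal to the response mean, with a warning.
    """
    theta, _ = indirect_evidence_with_coefficients(values, prior, penalty)
    return theta


def indirect_evidence_with_coefficients(
    values: np.ndarray, prior: MotifPrior, penalty: float = LOGISTIC_PENALTY
) -> tuple[np.ndarray, list]:
    """Like :func:`indirect_evidence` but also returns the coefficient
    vectors (intercept first; ``None`` for degenerate motif columns)."""
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    safe_sd = np.where(sd > 0, sd, 1.0)
    standardized = (values - mean) / safe_sd
    standardized[:, sd == 0] = 0.0
    design = np.hstack([np.ones((p, 1)), standardized])

    theta = np.zeros((p, prior.n_tfs))
    coefs: list = []
    for i in range(prior.n_tfs):
        y = prior.M[:, i].astype(float)
        if y.min() == y.max():
            log.warning("motif column for TF %s is constant; indirect evidence "
                        "set to the response mean", prior.tf_ids[i])
            theta[:, i] = y.mean()
            coefs.append(None)
            continue
        beta, fitted = _penalized_logistic(design, y, penalty)
        theta[:, i] = fitted
        coefs.append(beta)
    return np.clip(theta, 0.0, 1.0), coefs


def rank_normalize(matrix: np.ndarray) -> np.ndarray:
    """Per-column ascending ranks (average ties) scaled by the row count,
    mapping each column into (0, 1]."""
    matrix = np.asarray(matrix, dtype=float)
    p = matrix.shape[0]
    return rankdata(matrix, axis=0, method="average") / p


def combine_evidence(direct: np.ndarray, indirect: np.ndarray,
                     alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Rank-based weighted combination of the two evidence matrices.

    ``alpha`` weights the indirect evidence; 0.5 gives the two sources
    equal say. Only within-column ranks matter, so the result is invariant
    to any strictly monotone per-column transform of either input.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    direct = np.asarray(direct, dtype=float)
    indirect = np.asarray(indirect, dtype=float)
    if direct.shape != indirect.shape:
        raise ValueError("evidence matrices must share a shape")
    return (1.0 - alpha) * rank_normalize(direct) + alpha * rank_normalize(indirect)


def infer_network(expr: ExpressionDataset, prior: MotifPrior, group: str,
                  alpha: float = DEFAULT_ALPHA) -> BipartiteNetwork:
    """Infer the bipartite regulatory network for one phenotype group.

    ``expr`` and ``prior`` must be harmonized (same gene universe/order).
    """
    if tuple(expr.gene_ids) != tuple(prior.gene_ids):
        raise ValueError("expression and prior are not harmonized (gene order differs)")
    values = expr.subset_values(group)
    direct = direct_evidence(values, prior)
    indirect, coefs = indirect_evidence_with_coefficients(values, prior)
    weights = combine_evidence(direct, indirect, alpha)
    return BipartiteNetwork(
        tf_ids=prior.tf_ids,
        gene_ids=prior.gene_ids,
        weights=weights,
        evidence=EvidenceTable(direct=direct, indirect=indirect, fit_coefficients=coefs),
        alpha=alpha,
    )
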