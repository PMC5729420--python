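"""Differential TF involvement (dTFI) and its permutation-based calibration.

For each TF j, dTFI is the fraction of the transition-matrix column's sum
of squares that lies off the diagonal:

    dTFI_j = sum_{i != j} tau_{i,j}^2 / sum_i tau_{i,j}^2

A TF that keeps its targets between states has a transition column close
to the unit vector e_j, hence dTFI near 0; a TF whose targeting is fully
replaced by another TF's has dTFI near 1.

Significance is calibrated by shuffling the sample-to-phenotype labels
(preserving the two group sizes), re-running the *entire* pipeline —
both network inferences, the transition fit and dTFI — for each shuffle,
and summarizing the per-TF null by its mean and standard deviation. The
observed dTFI is converted to a one-sided upper-tail z-score p-value, and
FDR across TFs uses Benjamini-Hochberg. The default number of shuffles
is 400.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .io import GROUP_FINAL, GROUP_INITIAL, ExpressionDataset, MotifPrior
from .network import DEFAULT_ALPHA, infer_network
from .transition import estimate_transition

log = logging.getLogger(__name__)

DEFAULT_N_PERMUTATIONS = 400


@dataclass(frozen=True)
class DtfiTable:
    """Per-TF dTFI with its permutation-null summary and significance."""

    tf_ids: tuple[str, ...]
    dtfi: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    z: np.ndarray
    p_value: np.ndarray
    fdr: np.ndarray
    n_permutations: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "tf": list(self.tf_ids),
            "dtfi": self.dtfi,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": self.z,
            "p_value": self.p_value,
            "fdr": self.fdr,
        })


def dtfi(T_full: np.ndarray) -> np.ndarray:
    """Off-diagonal fraction of each transition-matrix column's sum of squares.

    Columns with zero sum of squares return 0 with a warning. Always in
    [0, 1].
    """
    T = np.asarray(T_full, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError(f"transition matrix must be square, got shape {T.shape}")
    sq = T ** 2
    total = sq.sum(axis=0)
    off = total - np.diag(sq)
    zero = total == 0
    if zero.any():
        log.warning("%d transition column(s) have zero sum of squares; dTFI set to 0",
                    int(zero.sum()))
    out = np.zeros(T.shape[1])
    np.divide(off, total, out=out, where=~zero)
    return np.clip(out, 0.0, 1.0)


def observed_dtfi(expr: ExpressionDataset, prior: MotifPrior,
                  alpha: float = DEFAULT_ALPHA, method: str = "ols",
                  penalty: float = 0.0) -> np.ndarray:
    """Run both network inferences, the transition fit and dTFI once."""
    net_a = infer_network(expr, prior, GROUP_INITIAL, alpha)
    net_b = infer_network(expr, prior, GROUP_FINAL, alpha)
    result = estimate_transition(net_a.weights, net_b.weights, method=method,
                                 penalty=penalty, tf_ids=prior.tf_ids)
    return dtfi(result.T_full)


def _permuted_groups(expr: ExpressionDataset, rng: np.random.Generator) -> dict[str, str]:
    samples = list(expr.sample_ids)
    n_initial = len(expr.samples_in(GROUP_INITIAL))
    order = rng.permutation(len(samples))
    groups = {}
    for pos, idx in enumerate(order):
        groups[samples[idx]] = GROUP_INITIAL if pos < n_initial else GROUP_FINAL
    return groups


def permutation_null(expr: ExpressionDataset, prior: MotifPrior,
                     alpha: float = DEFAULT_ALPHA, method: str = "ols",
                     penalty: float = 0.0,
                     n_perm: int = DEFAULT_N_PERMUTATIONS,
                     seed: int = 0, n_jobs: int = 1) -> np.ndarray:
    """Null dTFI matrix (n_perm x m) from sample-label shuffles.

    Each shuffle reassigns samples to the two phenotypes (group sizes
    preserved) and reruns the whole pipeline. Shuffle k draws from an
    independent child stream of ``seed``, so the output is identical
    whether permutations run serially or on ``n_jobs`` workers.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be at least 2 (null SD is undefined otherwise)")
    children = np.random.SeedSequence(seed).spawn(n_perm)

    def one(child: np.random.SeedSequence) -> np.ndarray:
        rng = np.random.default_rng(child)
        permuted = expr.with_groups(_permuted_groups(expr, rng))
        return observed_dtfi(permuted, prior, alpha=alpha, method=method,
                             penalty=penalty)

    if n_jobs == 1:
        rows = [one(c) for c in children]
    else:
        rows = Parallel(n_jobs=n_jobs)(delayed(one)(c) for c in children)
    return np.vstack(rows)


def significance(observed: np.ndarray, null: np.ndarray,
                 tf_ids=None, seed: int | None = None) -> DtfiTable:
    """Summarize observed dTFI against its permutation null.

    z_j = (observed_j - null_mean_j) / null_sd_j with the n-1 SD
    denominator; one-sided upper-tail normal p-values; Benjamini-Hochberg
    FDR across TFs. TFs with zero null SD get p = 1 with a warning.
    """
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    if null.ndim != 2 or null.shape[1] != observed.shape[0]:
        raise ValueError("null matrix must be n_perm x m, matching the observed vector")
    m = observed.shape[0]
    if tf_ids is None:
        tf_ids = tuple(f"TF{i + 1}" for i in range(m))
    else:
        tf_ids = tuple(tf_ids)
        if len(tf_ids) != m:
            raise ValueError("tf_ids length does not match the observed vector")

    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=1)
    degenerate = null_sd == 0
    if degenerate.any():
        log.warning("%d TF(s) have zero null SD; their p-values are set to 1",
                    int(degenerate.sum()))
    z = np.zeros(m)
    np.divide(observed - null_mean, null_sd, out=z, where=~degenerate)
    p = norm.sf(z)
    p[degenerate] = 1.0
    fdr = multipletests(p, method="fdr_bh")[1]
    return DtfiTable(tf_ids=tf_ids, dtfi=observed, null_mean=null_mean,
                     null_sd=null_sd, z=z, p_value=p, fdr=fdr,
                     n_permutations=null.shape[0], seed=seed)
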