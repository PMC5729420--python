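"""Synthetic two-group expression data with known TF-target rewiring.

The generator emulates the co-expression premise the inference method
rests on: genes regulated by a common TF co-vary with that TF. TF
expression rows are i.i.d. standard normal per sample; each target gene is
a linear combination of its regulators' expression plus Gaussian noise:

    g_target = effect_size * sum(regulator TF expression) + N(0, noise_sd)

The initial group is generated from a true weight matrix W_initial whose
nonzero pattern matches the motif prior. The final group is generated from
W_final, in which ``n_drivers`` disjoint TF *pairs* rewire: in ``swap``
mode the two TFs exchange entire target columns, in ``transfer`` mode half
of the first TF's targets move to the second. The motif prior handed to
the pipeline always describes the initial state only — as in real use,
where one static motif map serves both phenotypes and the rewiring signal
must come from expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GROUP_FINAL, GROUP_INITIAL, ExpressionDataset, MotifPrior

REWIRE_MODES = ("swap", "transfer")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a simulated dataset: the prior, both true weight
    matrices, and which TFs rewire between groups."""

    prior: MotifPrior
    W_initial: np.ndarray
    W_final: np.ndarray
    driver_tfs: frozenset[str]
    driver_pairs: tuple[tuple[str, str], ...]
    noise_sd: float
    effect_size: float
    n_per_group: tuple[int, int]
    seed: int


@dataclass(frozen=True)
class RecoveryReport:
    """Where the true driver TFs land in the descending dTFI ordering."""

    applicable: bool
    driver_ranks: dict[str, int]
    top_k: int
    success: bool | None


def generate(p: int = 200, m: int = 10, targets_per_gene: int = 2,
             n_per_group: tuple[int, int] = (30, 30), effect_size: float = 1.0,
             noise_sd: float = 0.5, n_drivers: int = 1,
             rewire_mode: str = "swap", seed: int = 0,
             ) -> tuple[ExpressionDataset, MotifPrior, SyntheticTruth]:
    """Simulate a two-group dataset with known regulatory rewiring.

    ``p`` counts all genes including the ``m`` TF-encoding genes; every
    non-TF gene gets ``targets_per_gene`` regulators drawn uniformly.
    Fully reproducible from ``seed``.
    """
    if p <= m:
        raise ValueError("p must exceed m (TF genes are part of the gene universe)")
    if n_drivers > 0 and m < 2 * n_drivers:
        raise ValueError("need m >= 2 * n_drivers disjoint TFs to rewire")
    if n_drivers < 0:
        raise ValueError("n_drivers must be nonnegative")
    if not 1 <= targets_per_gene <= m:
        raise ValueError("targets_per_gene must lie in [1, m]")
    if rewire_mode not in REWIRE_MODES:
        raise ValueError(f"rewire_mode must be one of {REWIRE_MODES}")
    if effect_size <= 0 or noise_sd <= 0:
        raise ValueError("effect_size and noise_sd must be positive")
    n1, n2 = n_per_group
    if min(n1, n2) < 3:
        raise ValueError("each group needs at least 3 samples")

    rng = np.random.default_rng(seed)
    tf_width = max(2, len(str(m)))
    gene_width = max(4, len(str(p)))
    tf_ids = tuple(f"TF{i + 1:0{tf_width}d}" for i in range(m))
    target_ids = tuple(f"G{k + 1:0{gene_width}d}" for k in range(p - m))
    gene_ids = tf_ids + target_ids

    M = np.zeros((p, m), dtype=np.int8)
    for j in range(m, p):
        M[j, rng.choice(m, size=targets_per_gene, replace=False)] = 1
    prior = MotifPrior(tf_ids=tf_ids, gene_ids=gene_ids, M=M)

    W_initial = effect_size * M.astype(float)
    W_final = W_initial.copy()
    driver_pairs: list[tuple[str, str]] = []
    if n_drivers > 0:
        chosen = rng.choice(m, size=2 * n_drivers, replace=False)
        for d in range(n_drivers):
            a, b = int(chosen[2 * d]), int(chosen[2 * d + 1])
            driver_pairs.append((tf_ids[a], tf_ids[b]))
            if rewire_mode == "swap":
                W_final[:, [a, b]] = W_initial[:, [b, a]]
            else:
                targets_a = np.nonzero(W_initial[:, a])[0]
                moved = targets_a[: math.ceil(len(targets_a) / 2)]
                W_final[moved, a] = 0.0
                W_final[moved, b] = effect_size
    drivers = frozenset(tf for pair in driver_pairs for tf in pair)

    n_total = n1 + n2
    tf_expr = rng.standard_normal((m, n_total))
    noise = noise_sd * rng.standard_normal((p - m, n_total))
    values = np.empty((p, n_total))
    values[:m] = tf_expr
    values[m:, :n1] = W_initial[m:] @ tf_expr[:, :n1] + noise[:, :n1]
    values[m:, n1:] = W_final[m:] @ tf_expr[:, n1:] + noise[:, n1:]

    sample_width = max(3, len(str(n_total)))
    sample_ids = tuple(f"S{k + 1:0{sample_width}d}" for k in range(n_total))
    group_of = {s: (GROUP_INITIAL if k < n1 else GROUP_FINAL)
                for k, s in enumerate(sample_ids)}
    expr = ExpressionDataset(gene_ids=gene_ids, sample_ids=sample_ids,
                             values=values, group_of=group_of,
                             label_names=("control", "case"))
    truth = SyntheticTruth(prior=prior, W_initial=W_initial, W_final=W_final,
                           driver_tfs=drivers, driver_pairs=tuple(driver_pairs),
                           noise_sd=noise_sd, effect_size=effect_size,
                           n_per_group=(n1, n2), seed=seed)
    return expr, prior, truth


def score_recovery(dtfi_table, truth: SyntheticTruth) -> RecoveryReport:
    """Rank the true driver TFs in the descending dTFI ordering.

    Success means every driver falls within the top ``2 * n_drivers``
    positions (each rewired pair contributes two drivers). With no drivers
    the report is marked not applicable.
    """
    if not truth.driver_tfs:
        return RecoveryReport(applicable=False, driver_ranks={}, top_k=0, success=None)
    order = np.argsort(-np.asarray(dtfi_table.dtfi), kind="stable")
    rank_of = {dtfi_table.tf_ids[idx]: pos + 1 for pos, idx in enumerate(order)}
    driver_ranks = {tf: rank_of[tf] for tf in sorted(truth.driver_tfs)}
    top_k = len(truth.driver_tfs)
    success = all(r <= top_k for r in driver_ranks.values())
    return RecoveryReport(applicable=True, driver_ranks=driver_ranks,
                          top_k=top_k, success=success)


def write_dataset(expr: ExpressionDataset, prior: MotifPrior, out_dir) -> dict[str, Path]:
    """Write the simulated dataset in the pipeline's input TSV dialects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "phenotype": out / "phenotype.tsv",
        "motif_prior": out / "motif_prior.tsv",
    }
    frame = pd.DataFrame(expr.values, index=list(expr.gene_ids),
                         columns=list(expr.sample_ids))
    frame.to_csv(paths["expression"], sep="\t", index_label="gene")
    initial_name, final_name = expr.label_names
    pheno = pd.DataFrame({
        0: list(expr.sample_ids),
        1: [initial_name if expr.group_of[s] == GROUP_INITIAL else final_name
            for s in expr.sample_ids],
    })
    pheno.to_csv(paths["phenotype"], sep="\t", index=False, header=False)
    rows = [(prior.tf_ids[i], prior.gene_ids[j], 1)
            for j, i in zip(*np.nonzero(prior.M))]
    pd.DataFrame(rows).to_csv(paths["motif_prior"], sep="\t", index=False, header=False)
    return paths
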