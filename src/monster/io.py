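"""Readers, writers and container types for expression, phenotype and motif-prior data.

All external files are plain tab-separated text:

* expression — genes x samples matrix, first column gene ids, header row of
  sample ids;
* phenotype — two columns (sample_id, group_label), no header, exactly two
  distinct labels;
* motif prior — edge list of two columns (tf_id, gene_id) or three columns
  (tf_id, gene_id, value); any nonzero value marks a motif.

Floats are written with the shortest representation that round-trips
exactly, so ``read(write(x))`` reproduces every numeric value bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

GROUP_INITIAL = "initial"
GROUP_FINAL = "final"


@dataclass(frozen=True)
class ExpressionDataset:
    """A labeled genes x samples expression matrix with a two-group design.

    ``group_of`` maps every sample id to ``"initial"`` or ``"final"``;
    ``label_names`` remembers the original phenotype labels in
    (initial, final) order. Expression is assumed to be on a roughly
    log/continuous scale but any real matrix is accepted.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    group_of: Mapping[str, str]
    label_names: tuple[str, str] = (GROUP_INITIAL, GROUP_FINAL)

    def __post_init__(self) -> None:
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"expression matrix shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.isfinite(values).all():
            raise ValueError("expression matrix contains missing/non-finite entries")
        missing = [s for s in self.sample_ids if s not in self.group_of]
        if missing:
            raise ValueError(f"samples without group assignment: {missing[:5]}")
        bad = {g for g in self.group_of.values()} - {GROUP_INITIAL, GROUP_FINAL}
        if bad:
            raise ValueError(f"unknown group codes {sorted(bad)}; exactly two groups required")
        for grp in (GROUP_INITIAL, GROUP_FINAL):
            if len(self.samples_in(grp)) < 3:
                raise ValueError(f"group '{grp}' has fewer than 3 samples")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_of[s] == group]

    def subset_values(self, group: str) -> np.ndarray:
        """Expression submatrix (genes x group samples) for one phenotype."""
        cols = [i for i, s in enumerate(self.sample_ids) if self.group_of[s] == group]
        return self.values[:, cols]

    def with_groups(self, group_of: Mapping[str, str]) -> "ExpressionDataset":
        """Same data under a different sample-to-group assignment."""
        return replace(self, group_of=dict(group_of))


@dataclass(frozen=True)
class MotifPrior:
    """Binary p x m matrix M marking motif-predicted TF->gene regulation.

    Rows are genes, columns are transcription factors. ``M[j, i] == 1``
    means TF i has a sequence binding motif near gene j; the prior is input
    evidence, never inferred.
    """

    tf_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    M: np.ndarray

    def __post_init__(self) -> None:
        _check_unique(self.tf_ids, "TF id")
        _check_unique(self.gene_ids, "gene id")
        M = np.asarray(self.M)
        if M.shape != (len(self.gene_ids), len(self.tf_ids)):
            raise ValueError(
                f"motif matrix shape {M.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.tf_ids)} TFs"
            )
        if not np.isin(M, (0, 1)).all():
            raise ValueError("motif prior entries must be 0 or 1")
        object.__setattr__(self, "M", M.astype(np.int8))

    @property
    def n_tfs(self) -> int:
        return len(self.tf_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what}: {x!r}")
        seen.add(x)


def read_expression(
    path,
    phenotype_path,
    initial_label: str | None = None,
    final_label: str | None = None,
) -> ExpressionDataset:
    """Read an expression TSV plus a two-column phenotype TSV.

    The first phenotype label to appear in the file is taken as the initial
    state unless ``initial_label``/``final_label`` override it. Genes with
    any missing value are dropped with a logged count; imputation is out of
    scope.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, header=0)
    genes = [str(g) for g in frame.index]
    samples = [str(s) for s in frame.columns]
    dup_genes = pd.Index(genes)[pd.Index(genes).duplicated()]
    if len(dup_genes):
        raise ValueError(f"duplicate gene id: {dup_genes[0]!r}")
    dup_samples = pd.Index(samples)[pd.Index(samples).duplicated()]
    if len(dup_samples):
        raise ValueError(f"duplicate sample id: {dup_samples[0]!r}")

    pheno = pd.read_csv(phenotype_path, sep="\t", header=None, dtype=str)
    if pheno.shape[1] != 2:
        raise ValueError("phenotype file must have exactly two columns (sample_id, group_label)")
    pheno_samples = list(pheno[0])
    labels = list(pheno[1])
    _check_unique(pheno_samples, "phenotype sample id")

    distinct = list(dict.fromkeys(labels))  # first-appearance order
    if len(distinct) != 2:
        raise ValueError(f"exactly two groups required, found {len(distinct)}: {distinct}")
    if initial_label is None and final_label is None:
        initial, final = distinct
    else:
        initial = initial_label if initial_label is not None else next(l for l in distinct if l != final_label)
        final = final_label if final_label is not None else next(l for l in distinct if l != initial_label)
        if {initial, final} != set(distinct):
            raise ValueError(
                f"requested labels ({initial!r}, {final!r}) do not match file labels {distinct}"
            )

    only_expr = sorted(set(samples) - set(pheno_samples))
    only_pheno = sorted(set(pheno_samples) - set(samples))
    if only_expr or only_pheno:
        raise ValueError(
            "sample mismatch between expression and phenotype files; "
            f"expression-only: {only_expr[:5]}, phenotype-only: {only_pheno[:5]}"
        )

    values = frame.to_numpy(dtype=float)
    keep = np.isfinite(values).all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("dropped %d gene(s) with missing expression values", n_dropped)
        values = values[keep]
        genes = [g for g, k in zip(genes, keep) if k]

    code = {initial: GROUP_INITIAL, final: GROUP_FINAL}
    group_of = {s: code[l] for s, l in zip(pheno_samples, labels)}
    return ExpressionDataset(
        gene_ids=tuple(genes),
        sample_ids=tuple(samples),
        values=values,
        group_of=group_of,
        label_names=(initial, final),
    )


def read_motif_prior(path) -> MotifPrior:
    """Read a 2- or 3-column TSV edge list into a binary motif matrix.

    Duplicate (tf, gene) rows collapse by logical OR; any nonzero third
    column is coerced to 1. Row/column order follows first appearance in
    the file (harmonization later imposes a deterministic order).
    """
    rows = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if rows.shape[1] not in (2, 3):
        raise ValueError("motif prior must have 2 or 3 tab-separated columns")
    if rows.shape[1] == 3:
        vals = pd.to_numeric(rows[2], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            # +1 for 1-based line numbering
            raise ValueError(f"non-numeric motif value on line {bad[0] + 1}")
        present = vals.to_numpy() != 0
    else:
        present = np.ones(len(rows), dtype=bool)

    tfs = list(dict.fromkeys(rows[0]))
    genes = list(dict.fromkeys(rows[1]))
    tf_index = {t: i for i, t in enumerate(tfs)}
    gene_index = {g: j for j, g in enumerate(genes)}
    M = np.zeros((len(genes), len(tfs)), dtype=np.int8)
    for tf, gene, keep in zip(rows[0], rows[1], present):
        if keep:
            M[gene_index[gene], tf_index[tf]] = 1
    return MotifPrior(tf_ids=tuple(tfs), gene_ids=tuple(genes), M=M)


def harmonize(expr: ExpressionDataset, prior: MotifPrior) -> tuple[ExpressionDataset, MotifPrior]:
    """Reconcile the gene/TF universes of expression data and motif prior.

    The harmonized gene universe is every expression gene, ordered
    lexicographically; genes absent from the prior get an all-zero motif
    row. TFs whose encoding gene has no expression row are dropped (the
    method needs TF expression), as are TFs left without any target.
    Idempotent and deterministic.
    """
    genes = tuple(sorted(expr.gene_ids))
    samples = tuple(sorted(expr.sample_ids))
    expr_gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    expr_sample_pos = {s: i for i, s in enumerate(expr.sample_ids)}
    values = expr.values[np.ix_(
        [expr_gene_pos[g] for g in genes],
        [expr_sample_pos[s] for s in samples],
    )]
    expr_h = ExpressionDataset(
        gene_ids=genes,
        sample_ids=samples,
        values=values,
        group_of=dict(expr.group_of),
        label_names=expr.label_names,
    )

    gene_set = set(genes)
    kept_tfs = []
    dropped_no_expr = []
    for tf in prior.tf_ids:
        (kept_tfs if tf in gene_set else dropped_no_expr).append(tf)
    if dropped_no_expr:
        log.warning(
            "dropped %d TF(s) without an expression row: %s",
            len(dropped_no_expr), dropped_no_expr[:5],
        )
    kept_tfs = sorted(kept_tfs)

    prior_gene_pos = {g: j for j, g in enumerate(prior.gene_ids)}
    prior_tf_pos = {t: i for i, t in enumerate(prior.tf_ids)}
    M = np.zeros((len(genes), len(kept_tfs)), dtype=np.int8)
    for j, g in enumerate(genes):
        pj = prior_gene_pos.get(g)
        if pj is None:
            continue
        for i, tf in enumerate(kept_tfs):
            M[j, i] = prior.M[pj, prior_tf_pos[tf]]

    nonzero = M.sum(axis=0) > 0
    if not nonzero.all():
        dropped = [t for t, nz in zip(kept_tfs, nonzero) if not nz]
        log.warning("dropped %d TF(s) with zero motif targets after harmonization: %s",
                    len(dropped), dropped[:5])
        kept_tfs = [t for t, nz in zip(kept_tfs, nonzero) if nz]
        M = M[:, nonzero]
    if not kept_tfs:
        raise ValueError("no TFs survive harmonization (no prior TF has expression and targets)")

    return expr_h, MotifPrior(tf_ids=tuple(kept_tfs), gene_ids=genes, M=M)


# ---------------------------------------------------------------------------
# writers / readers for pipeline artifacts


def write_network(net, path) -> None:
    """Write a bipartite network as (tf, gene, weight, direct, indirect) TSV."""
    p, m = net.weights.shape
    tf_col = np.repeat(net.tf_ids, p)
    gene_col = np.tile(net.gene_ids, m)
    frame = pd.DataFrame({
        "tf": tf_col,
        "gene": gene_col,
        "weight": net.weights.T.ravel(),
        "direct": net.evidence.direct.T.ravel(),
        "indirect": net.evidence.indirect.T.ravel(),
    })
    frame.to_csv(path, sep="\t", index=False)


def read_network(path):
    """Read a network TSV written by :func:`write_network`."""
    from .network import BipartiteNetwork, EvidenceTable

    frame = pd.read_csv(path, sep="\t", dtype={"tf": str, "gene": str})
    tfs = tuple(dict.fromkeys(frame["tf"]))
    genes = tuple(dict.fromkeys(frame["gene"]))
    p, m = len(genes), len(tfs)
    if len(frame) != p * m:
        raise ValueError("network file is not a complete TF x gene grid")
    weights = frame["weight"].to_numpy().reshape(m, p).T
    direct = frame["direct"].to_numpy().reshape(m, p).T
    indirect = frame["indirect"].to_numpy().reshape(m, p).T
    evidence = EvidenceTable(direct=direct, indirect=indirect, fit_coefficients=None)
    return BipartiteNetwork(tf_ids=tfs, gene_ids=genes, weights=weights,
                            evidence=evidence, alpha=None)


def write_transition(result, path, which: str = "full") -> None:
    """Write the m x m transition matrix as a labeled TSV.

    ``which`` selects the identity-referenced matrix (``"full"``) or the
    difference-regression coefficients (``"diff"``).
    """
    mat = result.T_full if which == "full" else result.T_diff
    frame = pd.DataFrame(mat, index=list(result.tf_ids), columns=list(result.tf_ids))
    frame.to_csv(path, sep="\t", index_label="tf")


def read_transition(path) -> pd.DataFrame:
    """Read a labeled transition-matrix TSV into a DataFrame."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_dtfi(table, path) -> None:
    """Write a dTFI table, sorted by descending dTFI."""
    frame = table.to_frame().sort_values("dtfi", ascending=False, kind="stable")
    frame.to_csv(path, sep="\t", index=False)


def read_dtfi(path) -> pd.DataFrame:
    """Read a dTFI TSV into a DataFrame (one row per TF)."""
    return pd.read_csv(path, sep="\t", dtype={"tf": str})


def write_null_distribution(null: np.ndarray, tf_ids: Sequence[str], path) -> None:
    """Write the n_perm x m permutation-null dTFI matrix."""
    pd.DataFrame(null, columns=list(tf_ids)).to_csv(path, sep="\t", index=False)
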