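"""End-to-end orchestration: files in, ranked driver TFs out.

Wires the stages together in the canonical order — read & harmonize,
infer one network per phenotype, fit the transition matrix, compute dTFI,
calibrate it against the sample-label permutation null — and writes every
artifact plus a run manifest (parameters, seed, input checksums, package
version) so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .dtfi import (DEFAULT_N_PERMUTATIONS, observed_dtfi, permutation_null,
                   significance)
from .io import (GROUP_FINAL, GROUP_INITIAL, harmonize, read_expression,
                 read_motif_prior, write_dtfi, write_network,
                 write_null_distribution, write_transition)
from .network import DEFAULT_ALPHA, infer_network
from .transition import METHODS, estimate_transition
from .dtfi import dtfi as compute_dtfi

log = logging.getLogger(__name__)

DEFAULT_SEED = 1618


@dataclass
class PipelineConfig:
    """Run parameters; the defaults reproduce the method's reference
    configuration (alpha = 0.5, unpenalized normal-equations transition fit,
    400 permutations)."""

    alpha: float = DEFAULT_ALPHA
    method: str = "ols"
    penalty: float = 0.0
    n_permutations: int = DEFAULT_N_PERMUTATIONS
    seed: int = DEFAULT_SEED
    initial_label: str | None = None
    final_label: str | None = None
    emit_null: bool = False
    emit_diff: bool = False
    worker_count: int = 1

    def validate(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.penalty < 0:
            raise ValueError("penalty must be nonnegative")
        if self.method == "ols" and self.penalty != 0:
            raise ValueError("penalty must be 0 for method='ols'")
        if self.n_permutations < 2:
            raise ValueError("n_permutations must be at least 2")
        if self.worker_count < 1:
            raise ValueError("worker_count must be at least 1")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(expr_path, phenotype_path, prior_path,
                 config: PipelineConfig | None = None,
                 out_dir=".") -> dict[str, Path]:
    """Run the full pipeline and write its artifact bundle to ``out_dir``.

    Returns a name -> path map of the written artifacts. On any stage
    failure, partial outputs are removed and the error re-raised with the
    failing stage named.
    """
    config = config or PipelineConfig()
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "read-inputs"
    try:
        t0 = time.perf_counter()
        expr = read_expression(expr_path, phenotype_path,
                               initial_label=config.initial_label,
                               final_label=config.final_label)
        prior = read_motif_prior(prior_path)
        expr, prior = harmonize(expr, prior)
        log.info("stage=%s genes=%d tfs=%d samples=%d elapsed=%.2fs", stage,
                 expr.n_genes, prior.n_tfs, expr.n_samples,
                 time.perf_counter() - t0)

        stage = "network-inference"
        t0 = time.perf_counter()
        net_initial = infer_network(expr, prior, GROUP_INITIAL, config.alpha)
        net_final = infer_network(expr, prior, GROUP_FINAL, config.alpha)
        artifacts["network_initial"] = out / "network_initial.tsv"
        artifacts["network_final"] = out / "network_final.tsv"
        write_network(net_initial, artifacts["network_initial"])
        write_network(net_final, artifacts["network_final"])
        log.info("stage=%s elapsed=%.2fs", stage, time.perf_counter() - t0)

        stage = "transition"
        t0 = time.perf_counter()
        result = estimate_transition(net_initial.weights, net_final.weights,
                                     method=config.method, penalty=config.penalty,
                                     tf_ids=prior.tf_ids)
        artifacts["transition"] = out / "transition.tsv"
        write_transition(result, artifacts["transition"], which="full")
        if config.emit_diff:
            artifacts["transition_diff"] = out / "transition_diff.tsv"
            write_transition(result, artifacts["transition_diff"], which="diff")
        log.info("stage=%s elapsed=%.2fs", stage, time.perf_counter() - t0)

        stage = "dtfi"
        t0 = time.perf_counter()
        observed = compute_dtfi(result.T_full)
        null = permutation_null(expr, prior, alpha=config.alpha,
                                method=config.method, penalty=config.penalty,
                                n_perm=config.n_permutations, seed=config.seed,
                                n_jobs=config.worker_count)
        table = significance(observed, null, tf_ids=prior.tf_ids, seed=config.seed)
        artifacts["dtfi"] = out / "dtfi.tsv"
        write_dtfi(table, artifacts["dtfi"])
        if config.emit_null:
            artifacts["null_distribution"] = out / "dtfi_null.tsv"
            write_null_distribution(null, prior.tf_ids, artifacts["null_distribution"])
        log.info("stage=%s n_perm=%d elapsed=%.2fs", stage,
                 config.n_permutations, time.perf_counter() - t0)

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "parameters": {k: v for k, v in asdict(config).items()},
            "inputs": {
                "expression": {"path": str(expr_path), "sha256": _sha256(expr_path)},
                "phenotype": {"path": str(phenotype_path), "sha256": _sha256(phenotype_path)},
                "motif_prior": {"path": str(prior_path), "sha256": _sha256(prior_path)},
            },
            "dimensions": {"genes": expr.n_genes, "tfs": prior.n_tfs,
                           "samples": expr.n_samples},
            "group_labels": {"initial": expr.label_names[0],
                             "final": expr.label_names[1]},
        }
        artifacts["manifest"] = out / "manifest.json"
        artifacts["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return artifacts
    except Exception as exc:
        for path in artifacts.values():
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
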