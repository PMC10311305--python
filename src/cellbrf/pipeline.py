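"""End-to-end pipeline: preprocess -> labels -> balance -> importance -> select."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .balance import BALANCE_MODES, BalancedDataset, balance, plan_balance
from .cluster import ClusterLabeling, predict_labels
from .data import ExpressionMatrix
from .importance import ImportanceVector, fit_forest_importance
from .preprocess import preprocess
from .select import GeneSelection, SelectionConfig, select_features

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "write_artifacts"]


@dataclass
class RunConfig:
    """All tunable parameters of one pipeline run."""

    n_clusters: int | str = "auto"
    seed: int = 0
    min_cells: int = 3
    n_pcs: int = 50
    knn_k: int = 15
    retain_fraction_U: float = 0.8
    smote_k: int = 5
    n_trees: int = 100
    subspace: str | int = "sqrt"
    v: float = 0.8
    v_prime: float = 0.1
    balance_mode: str = "both"

    def __post_init__(self) -> None:
        if self.balance_mode not in BALANCE_MODES:
            raise ValueError(f"balance_mode must be one of {BALANCE_MODES}")
        if not 0 < self.retain_fraction_U <= 1:
            raise ValueError("retain_fraction_U must be in (0, 1]")


@dataclass
class PipelineResult:
    """Everything one run produced."""

    lognorm: ExpressionMatrix
    labeling: ClusterLabeling
    balanced: BalancedDataset
    importance: ImportanceVector
    selection: GeneSelection
    config: RunConfig


def run_pipeline(m: ExpressionMatrix, config: RunConfig | None = None) -> PipelineResult:
    """Run the full feature-selection flow on a raw count matrix."""
    if config is None:
        config = RunConfig()
    ln = preprocess(m, min_cells=config.min_cells) if m.layer == "raw" else m
    lab = predict_labels(
        ln,
        n=config.n_clusters,
        seed=config.seed,
        n_pcs=config.n_pcs,
        knn_k=config.knn_k,
    )
    plan = plan_balance(lab, U=config.retain_fraction_U, smote_k=config.smote_k)
    bal = balance(ln, lab, plan, seed=config.seed, mode=config.balance_mode)
    imp = fit_forest_importance(
        bal, n_trees=config.n_trees, subspace=config.subspace, seed=config.seed
    )
    sel = select_features(
        ln, imp, cfg=SelectionConfig(v=config.v, v_prime=config.v_prime)
    )
    return PipelineResult(
        lognorm=ln,
        labeling=lab,
        balanced=bal,
        importance=imp,
        selection=sel,
        config=config,
    )


def write_artifacts(result: PipelineResult, out_dir: str | Path) -> None:
    """Write selected_genes.txt, importance.tsv, audit.tsv, labels.tsv
    and run_log.json into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    (out / "selected_genes.txt").write_text(
        "".join(f"{g}\n" for g in result.selection.ordered_genes)
    )

    imp_df = pd.DataFrame(
        {"gene_id": result.lognorm.gene_ids, "importance": result.importance.f}
    )
    imp_df.to_csv(out / "importance.tsv", sep="\t", index=False)

    kept = set(result.selection.ordered_genes)
    by_gene = {r.gene: r for r in result.selection.removed}
    audit_rows = []
    for gid in result.selection.ordered_genes:
        audit_rows.append(
            {
                "gene_id": gid,
                "importance": result.selection.importances.get(gid, float("nan")),
                "status": "kept",
                "removed_by": "",
                "correlation": "",
                "threshold": "",
            }
        )
    for rec in result.selection.removed:
        audit_rows.append(
            {
                "gene_id": rec.gene,
                "importance": result.selection.importances.get(rec.gene, float("nan")),
                "status": "removed",
                "removed_by": rec.removed_by,
                "correlation": f"{rec.correlation:.6f}",
                "threshold": f"{rec.threshold:.6f}",
            }
        )
    pd.DataFrame(audit_rows).to_csv(out / "audit.tsv", sep="\t", index=False)

    lab_df = pd.DataFrame(
        {"cell_id": result.lognorm.cell_ids, "cluster": result.labeling.labels}
    )
    lab_df.to_csv(out / "labels.tsv", sep="\t", index=False)

    log = asdict(result.config)
    log.update(
        {
            "n_genes_input": result.lognorm.n_genes,
            "n_cells": result.lognorm.n_cells,
            "n_clusters_used": result.labeling.n,
            "n_selected": result.selection.n_selected,
            "n_removed_redundant": len(result.selection.removed),
            "importance_mu": result.importance.mu,
            "importance_sigma": result.importance.sigma,
        }
    )
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str) + "\n")
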