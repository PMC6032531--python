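"""End-to-end orchestration: discovery and validation workflows.

The discovery workflow chains differential-expression screening, the
median edge filter, the DEG subnetwork with its centralities, the
two-stage candidate-gene selection, PLS model fitting with threshold
selection, and repeated stratified cross-validation. Every stage's gene
count enters an attrition report, and a run manifest records the config
hash, seed, package versions and input digests so a rerun with the same
config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._exceptions import ConfigurationError, PipelineHaltError
from ._version import __version__
from .evaluation import CVReport, compare_auc, evaluate_model, kfold_cv, roc_auc
from .expression import ExpressionMatrix, read_labels
from .network import (
    build_network,
    compute_topology,
    filter_edges_by_median,
    read_edge_table,
    select_candidates,
    select_major_genes,
)
from .pls import PLSSignatureClassifier, fit_pls
from .qpcr import qpcr_to_expression, read_ct_csv, relative_quantify
from .rvm import rvm_ttest, screen_degs

logger = logging.getLogger("tgsig")


@dataclass
class PipelineConfig:
    """Workflow configuration; defaults are the published analysis settings."""

    expression: str = "expression.tsv"
    labels: str = "labels.tsv"
    edges: str = "edges.tsv"
    outdir: str = "results"
    validation_expression: str | None = None
    validation_labels: str | None = None
    ct_table: str | None = None
    log2fc_threshold: float = 0.5
    p_threshold: float = 0.05
    fold_threshold: float = 1.5
    k: int = 5
    repeats: int = 5
    n_components: int = 1
    seed: int = 0
    reference_genes: tuple[str, ...] = ("GAPDH", "RPS18")
    weighted_degree: bool = False
    linear_input: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ConfigurationError("p_threshold must lie in (0, 1)")
        if self.log2fc_threshold <= 0:
            raise ConfigurationError("log2fc_threshold must be > 0")
        if self.fold_threshold <= 1:
            raise ConfigurationError("fold_threshold must be > 1")
        if self.k < 2:
            raise ConfigurationError("k must be >= 2")
        if self.repeats < 1 or self.n_components < 1:
            raise ConfigurationError("repeats and n_components must be >= 1")
        if not isinstance(self.seed, int):
            raise ConfigurationError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "reference_genes" in doc:
            doc["reference_genes"] = tuple(doc["reference_genes"])
        return cls(**doc)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class DiscoveryResult:
    deg_table: pd.DataFrame
    degs: pd.DataFrame
    topology: pd.DataFrame
    major_genes: list[str]
    candidates: list[str]
    model: PLSSignatureClassifier
    cv_report: CVReport
    attrition: dict[str, int] = field(default_factory=dict)


def discover(
    expr: ExpressionMatrix,
    edges: pd.DataFrame,
    *,
    log2fc_threshold: float = 0.5,
    p_threshold: float = 0.05,
    fold_threshold: float = 1.5,
    k: int = 5,
    repeats: int = 5,
    seed: int = 0,
    n_components: int = 1,
    weighted_degree: bool = False,
) -> DiscoveryResult:
    """Run the discovery chain on in-memory inputs.

    Raises :class:`PipelineHaltError` carrying the per-stage attrition
    report when fewer than two candidate genes survive.
    """
    deg_table = rvm_ttest(expr)
    degs = screen_degs(deg_table, log2fc_threshold, p_threshold)
    filtered = filter_edges_by_median(edges)
    net = build_network(list(degs["gene_id"]), filtered)
    attrition = {
        "genes": len(deg_table),
        "degs": len(degs),
        "network_nodes": net.number_of_nodes(),
        "network_edges": net.number_of_edges(),
    }
    logger.info("attrition so far: %s", attrition)
    if net.number_of_nodes() < 2:
        raise PipelineHaltError("DEG subnetwork has fewer than 2 nodes", attrition)
    topology = compute_topology(net, weighted_degree=weighted_degree)
    major = select_major_genes(topology)
    attrition["major_genes"] = len(major)
    candidates = select_candidates(major, deg_table, fold_threshold, p_threshold)
    attrition["candidates"] = len(candidates)
    logger.info("stage counts: %s", attrition)
    if len(candidates) < 2:
        raise PipelineHaltError(
            f"only {len(candidates)} candidate gene(s) survived the filters", attrition
        )
    model = fit_pls(expr, candidates, n_components=n_components)
    cv = kfold_cv(expr, candidates, k=k, repeats=repeats, seed=seed, n_components=n_components)
    return DiscoveryResult(
        deg_table=deg_table,
        degs=degs,
        topology=topology,
        major_genes=major,
        candidates=candidates,
        model=model,
        cv_report=cv,
        attrition=attrition,
    )


def validate(
    model: PLSSignatureClassifier, expr: ExpressionMatrix, restandardize: bool = False
) -> dict:
    """Independent-cohort evaluation plus model-vs-single-gene ROC comparison.

    Each single-gene score is that gene's expression oriented by the
    sign of its model weight, so every per-gene ROC reads in the
    responder direction before comparison with the combined score. With
    ``restandardize=True`` (required when the validation cohort comes
    from a different measurement platform, e.g. qPCR relative
    quantities) the per-gene center/scale are refit on the validation
    cohort while weights and threshold transfer unchanged.
    """
    if restandardize:
        model = model.restandardized(expr)
    report = evaluate_model(model, expr)
    sub = expr.restrict(model.gene_ids_)
    actual = expr.labels.loc[report["scores"]["sample_id"]].to_numpy()
    combined = report["scores"]["score"].to_numpy()
    per_gene = {}
    for i, gene in enumerate(model.gene_ids_):
        gene_score = np.sign(model.weights_[i]) * sub.X[:, i]
        per_gene[gene] = {
            "auc": roc_auc(gene_score, actual).auc,
            **compare_auc(combined, gene_score, actual),
        }
    report["single_gene"] = per_gene
    return report


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_discovery(config: PipelineConfig) -> DiscoveryResult:
    """File-based discovery run: read inputs, execute, write all artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr = ExpressionMatrix.from_tsv(
        config.expression, config.labels, linear_input=config.linear_input
    )
    edges = read_edge_table(config.edges)
    result = discover(
        expr,
        edges,
        log2fc_threshold=config.log2fc_threshold,
        p_threshold=config.p_threshold,
        fold_threshold=config.fold_threshold,
        k=config.k,
        repeats=config.repeats,
        seed=config.seed,
        n_components=config.n_components,
        weighted_degree=config.weighted_degree,
    )
    result.deg_table.to_csv(outdir / "deg_table.tsv", sep="\t", index=False)
    result.degs.to_csv(outdir / "degs.tsv", sep="\t", index=False)
    result.topology.to_csv(outdir / "topology.tsv", sep="\t", index=False)
    (outdir / "major_genes.txt").write_text("\n".join(result.major_genes) + "\n")
    (outdir / "candidates.txt").write_text("\n".join(result.candidates) + "\n")
    result.model.to_json(outdir / "model.json")
    cv_doc = {
        "k": result.cv_report.k,
        "repeats": result.cv_report.repeats,
        "seed": result.cv_report.seed,
        "folds": result.cv_report.folds.to_dict(orient="records"),
        "per_repeat_means": result.cv_report.per_repeat_means.to_dict(orient="index"),
        "means": result.cv_report.means.to_dict(),
        "fold_assignments": result.cv_report.fold_assignments,
    }
    (outdir / "cv_report.json").write_text(json.dumps(cv_doc, indent=2, sort_keys=True))
    manifest = {
        "tool": "tgsig",
        "version": __version__,
        "config": asdict(config),
        "config_sha256": config.digest(),
        "seed": config.seed,
        "inputs": {
            name: _sha256(Path(p))
            for name, p in [
                ("expression", config.expression),
                ("labels", config.labels),
                ("edges", config.edges),
            ]
        },
        "attrition": result.attrition,
        "candidates": result.candidates,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return result


def run_validation(config: PipelineConfig, model: PLSSignatureClassifier) -> dict:
    """File-based validation run; handles direct expression or qPCR input.

    With a Ct table configured, one report is produced per configured
    reference gene (log2 relative quantities per reference); with a
    direct validation expression matrix, a single report.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reports: dict[str, dict] = {}
    if config.ct_table is not None:
        if config.validation_labels is None:
            raise ConfigurationError("validation_labels required with a Ct table")
        ct = read_ct_csv(config.ct_table)
        labels = read_labels(config.validation_labels)
        for ref in config.reference_genes:
            rel = relative_quantify(ct, ref, labels=labels)
            rel = rel[rel["gene"].isin(model.gene_ids_)]
            expr = qpcr_to_expression(rel, labels)
            # Ct-derived quantities live on a different scale than the
            # training platform: refit standardization on this cohort
            reports[ref] = validate(model, expr, restandardize=True)
    else:
        if config.validation_expression is None or config.validation_labels is None:
            raise ConfigurationError(
                "validation needs either a Ct table or a validation expression matrix"
            )
        expr = ExpressionMatrix.from_tsv(
            config.validation_expression,
            config.validation_labels,
            linear_input=config.linear_input,
        )
        reports["expression"] = validate(model, expr)

    doc = {}
    for name, rep in reports.items():
        doc[name] = {
            "accuracy": rep["accuracy"],
            "sensitivity": rep["sensitivity"],
            "specificity": rep["specificity"],
            "auc": rep["auc"],
            "single_gene": rep["single_gene"],
        }
        rep["scores"].to_csv(outdir / f"validation_scores_{name}.tsv", sep="\t", index=False)
    (outdir / "validation_report.json").write_text(json.dumps(doc, indent=2, sort_keys=True))
    return reports
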