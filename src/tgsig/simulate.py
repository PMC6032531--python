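"""Synthetic two-group cohorts with planted signal.

Emulates the statistical structure the downstream analysis assumes:

* gene-wise variances drawn from an inverse-gamma-type prior (the precision
  ``1/sigma^2`` is gamma with shape ``a`` and scale ``b``), matching the
  random-variance-model assumption of the moderated t-test;
* a planted fraction of differentially expressed (DE) genes whose group
  means differ by a log2 effect of random sign, roughly half up and half
  down;
* a STRING-style scored interaction network in which a subset of the DE
  genes are planted as hubs whose edges carry above-median scores;
* qPCR Ct tables with triplicate wells and two group-independent reference
  genes, where each candidate gene's Ct is shifted between groups by
  ``-log2`` of its planted fold change.

Everything is deterministic given the config seed; independent substreams
are derived per stage so the network draw does not perturb the cohort draw.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError
from .expression import NON_RESPONDER, RESPONDER, ExpressionMatrix

_COHORT_STREAM = 0
_NETWORK_STREAM = 1
_QPCR_STREAM = 2


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults mirror the study design the package targets: a 6 + 6
    discovery cohort on ~20k genes is the canonical use, scaled here to
    2,000 genes for quick runs; the variance prior (a=3, b=1) gives a
    realistically heavy-tailed spread of gene variances with prior mean
    variance 0.5 on the log2 scale; planted effects of 1-2 log2 units are
    typical microarray biomarker magnitudes.
    """

    n_genes: int = 2000
    n_responders: int = 6
    n_nonresponders: int = 6
    de_fraction: float = 0.05
    log2_effect: float = 2.0
    prior_shape_a: float = 3.0
    prior_scale_b: float = 1.0
    hub_fraction: float = 0.1
    edge_score_range: tuple[int, int] = (150, 999)
    seed: int = 0
    # secondary knobs
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    background_mean_degree: float = 2.0
    hub_spokes: int = 12
    ct_replicate_sd: float = 0.2
    ct_sample_sd: float = 0.5
    n_ct_replicates: int = 3
    reference_genes: tuple[str, str] = ("GAPDH", "RPS18")

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be a positive integer")
        if self.n_responders < 2 or self.n_nonresponders < 2:
            raise ConfigurationError(
                "n_responders and n_nonresponders must each be >= 2 "
                "(variance is not estimable otherwise)"
            )
        if not 0.0 <= self.de_fraction < 1.0:
            raise ConfigurationError("de_fraction must lie in [0, 1)")
        if self.de_fraction > 0 and self.de_fraction * self.n_genes < 6:
            raise ConfigurationError(
                "de_fraction * n_genes must be >= 6 to exercise candidate selection"
            )
        if self.de_fraction > 0 and self.log2_effect <= 0:
            raise ConfigurationError("log2_effect must be > 0")
        if self.prior_shape_a <= 0 or self.prior_scale_b <= 0:
            raise ConfigurationError("prior_shape_a and prior_scale_b must be > 0")
        if not 0.0 <= self.hub_fraction <= 1.0:
            raise ConfigurationError("hub_fraction must lie in [0, 1]")
        lo, hi = self.edge_score_range
        if not (0 < lo < hi):
            raise ConfigurationError("edge_score_range must be increasing positive integers")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic generator for one pipeline stage."""
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class SimulatedCohort:
    """A generated cohort plus the ground truth planted into it."""

    expression: ExpressionMatrix
    truth: dict[str, float]  # planted DE gene -> true log2 effect
    truth_hubs: set[str] = field(default_factory=set)
    edges: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        genes = set(self.expression.gene_ids)
        if not set(self.truth) <= genes:
            raise ConfigurationError("truth genes must appear in the expression matrix")
        if not self.truth_hubs <= set(self.truth):
            raise ConfigurationError("truth_hubs must be a subset of truth")


def simulate_cohort(config: SimulationConfig, cohort_id: int = 0) -> SimulatedCohort:
    """Draw a two-group log2 expression matrix with planted DE genes.

    Per gene ``g`` a variance is drawn from the inverse-gamma-type prior
    (precision ~ Gamma(a, scale=b)) and a baseline mean from a normal
    distribution. Non-DE genes share one mean across groups; a planted
    DE gene's groups are separated by exactly ``log2_effect`` with a
    random sign (half of the planted genes up in responders, half down).

    ``cohort_id`` selects the sampling-noise stream while the cohort
    *structure* (variances, baselines, which genes are DE and in which
    direction, which are hubs) depends on the seed alone — so a
    discovery cohort (``cohort_id=0``) and an independent validation
    cohort (``cohort_id=1``) share the same planted truth.
    """
    rng = config.rng(_COHORT_STREAM)
    noise_rng = np.random.default_rng([int(config.seed), 100 + int(cohort_id)])
    n_genes = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    resp_ids = [f"R{i:02d}" for i in range(config.n_responders)]
    nonresp_ids = [f"N{i:02d}" for i in range(config.n_nonresponders)]

    sigma2 = 1.0 / rng.gamma(shape=config.prior_shape_a, scale=config.prior_scale_b, size=n_genes)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_genes)

    n_de = int(round(config.de_fraction * n_genes))
    de_idx = np.sort(rng.choice(n_genes, size=n_de, replace=False)) if n_de else np.array([], int)
    signs = np.ones(n_de)
    signs[n_de // 2:] = -1.0
    rng.shuffle(signs)
    delta = np.zeros(n_genes)
    delta[de_idx] = signs * config.log2_effect

    n_hubs = int(round(config.hub_fraction * n_de))
    hub_genes: set[str] = set()
    if n_hubs:
        hub_idx = rng.choice(de_idx, size=n_hubs, replace=False)
        hub_genes = {gene_ids[i] for i in hub_idx}

    sd = np.sqrt(sigma2)[:, None]
    resp = noise_rng.normal(
        (baseline + delta / 2.0)[:, None], sd, size=(n_genes, len(resp_ids))
    )
    nonresp = noise_rng.normal(
        (baseline - delta / 2.0)[:, None], sd, size=(n_genes, len(nonresp_ids))
    )

    data = pd.DataFrame(
        np.hstack([resp, nonresp]), index=gene_ids, columns=resp_ids + nonresp_ids
    )
    labels = pd.Series(
        [RESPONDER] * len(resp_ids) + [NON_RESPONDER] * len(nonresp_ids),
        index=resp_ids + nonresp_ids,
    )
    truth = {gene_ids[i]: float(delta[i]) for i in de_idx}

    return SimulatedCohort(
        expression=ExpressionMatrix(data, labels), truth=truth, truth_hubs=hub_genes
    )


def _decode_pair(index: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Map linear indices into the strict upper triangle of an n x n grid."""
    # row i such that cumulative pair count up to row i exceeds index
    i = (n - 2 - np.floor(np.sqrt(-8 * index + 4 * n * (n - 1) - 7) / 2.0 - 0.5)).astype(int)
    j = (index + i + 1 - i * (2 * n - i - 1) // 2).astype(int)
    return i, j


def simulate_network(cohort: SimulatedCohort, config: SimulationConfig) -> pd.DataFrame:
    """Overlay hub spokes on an Erdos-Renyi background and score the edges.

    Background edges connect uniformly random gene pairs with uniform
    integer combined scores over the full score range. Each planted hub
    receives ``hub_spokes`` extra edges to other planted DE genes (so the
    spokes survive the DEG-subgraph step downstream) with scores drawn
    from the upper half of the range, so they also survive the median
    edge filter. The resulting table is assigned to ``cohort.edges``.
    """
    rng = config.rng(_NETWORK_STREAM)
    genes = cohort.expression.gene_ids
    n = len(genes)
    lo, hi = config.edge_score_range
    upper = (lo + hi + 1) // 2

    n_pairs = n * (n - 1) // 2
    p_edge = min(1.0, config.background_mean_degree / max(n - 1, 1))
    m = rng.binomial(n_pairs, p_edge)
    pair_idx = rng.choice(n_pairs, size=m, replace=False)
    ii, jj = _decode_pair(np.sort(pair_idx), n)
    rows = [
        (genes[i], genes[j], int(score))
        for i, j, score in zip(ii, jj, rng.integers(lo, hi + 1, size=m))
    ]

    de_genes = sorted(cohort.truth)
    for hub in sorted(cohort.truth_hubs):
        targets = [g for g in de_genes if g != hub]
        if not targets:
            targets = [g for g in genes if g != hub]
        k = min(config.hub_spokes, len(targets))
        chosen = rng.choice(len(targets), size=k, replace=False)
        for t, score in zip(chosen, rng.integers(upper, hi + 1, size=k)):
            rows.append((hub, targets[t], int(score)))

    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "combined_score"])
    # canonical endpoint order; on duplicates the hub edge (appended last) wins
    flip = edges["gene_a"] > edges["gene_b"]
    edges.loc[flip, ["gene_a", "gene_b"]] = edges.loc[flip, ["gene_b", "gene_a"]].to_numpy()
    edges = edges.drop_duplicates(subset=["gene_a", "gene_b"], keep="last").reset_index(drop=True)
    cohort.edges = edges
    return edges


def simulate_qpcr(
    candidates: list[str],
    labels: pd.Series,
    config: SimulationConfig,
    truth: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Triplicate Ct values for candidate genes plus two reference genes.

    Reference genes have group-independent Ct means; each candidate's Ct
    is lowered by its planted log2 fold change in responders (one extra
    fold of template halves the threshold cycle). A shared per-sample
    offset emulates loading differences and cancels in the comparative-Ct
    normalization; replicate noise is Gaussian with ``ct_replicate_sd``.
    """
    if not candidates:
        raise ConfigurationError("candidates must be non-empty")
    rng = config.rng(_QPCR_STREAM)
    truth = truth or {}
    labels = pd.Series(labels)
    samples = list(labels.index)
    ref_bases = dict(zip(config.reference_genes, (18.0, 16.0)))
    cand_bases = {g: float(rng.uniform(22.0, 28.0)) for g in candidates}
    sample_offset = dict(zip(samples, rng.normal(0.0, config.ct_sample_sd, size=len(samples))))

    rows = []
    for sample in samples:
        is_resp = labels[sample] == RESPONDER
        for gene, base in {**ref_bases, **cand_bases}.items():
            mean_ct = base + sample_offset[sample]
            if gene in cand_bases and is_resp:
                mean_ct -= truth.get(gene, 0.0)
            noise = rng.normal(0.0, config.ct_replicate_sd, size=config.n_ct_replicates)
            for rep in range(config.n_ct_replicates):
                rows.append((sample, gene, rep + 1, float(mean_ct + noise[rep])))
    return pd.DataFrame(rows, columns=["sample", "gene", "replicate", "ct"])


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write expression/labels/edges TSVs and the truth JSON to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "labels": outdir / "labels.tsv",
        "truth": outdir / "truth.json",
    }
    cohort.expression.to_tsv(paths["expression"], paths["labels"])
    truth_doc = {
        "planted_log2_effects": cohort.truth,
        "truth_hubs": sorted(cohort.truth_hubs),
    }
    paths["truth"].write_text(json.dumps(truth_doc, indent=2, sort_keys=True))
    if cohort.edges is not None:
        paths["edges"] = outdir / "edges.tsv"
        cohort.edges.to_csv(paths["edges"], sep="\t", index=False)
    return paths
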