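"""Over-representation analysis against GMT gene sets.

A local hypergeometric test stands in for web-service enrichment tools:
for each set, the one-sided upper-tail probability of observing at least
the query/set overlap given the background universe. P-values are
corrected both ways the field reports them — Bonferroni across sets and
Benjamini-Hochberg — and a term counts as significant when both corrected
values are below 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._exceptions import DataError, EmptyInputError


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe they are tested against."""

    sets: dict[str, list[str]]
    background: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.sets:
            raise DataError("gene-set collection is empty")
        for name, genes in self.sets.items():
            if not genes:
                raise DataError(f"gene set {name!r} is empty")
        self.background = set(self.background)
        # sets are intersected with the background at test time

    @classmethod
    def from_gmt(cls, path: str | Path, background: set[str] | None = None) -> "GeneSetCollection":
        """Read a GMT file (name <tab> description <tab> genes...).

        Without an explicit background the union of all set members is
        used; in practice pass the genes on the expression platform.
        """
        sets: dict[str, list[str]] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise DataError(f"malformed GMT line: {line[:80]!r}")
            sets[parts[0]] = [g for g in parts[2:] if g]
        bg = set(background) if background is not None else set().union(*map(set, sets.values()))
        return cls(sets=sets, background=bg)


def enrich(query: list[str], collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Query genes outside the background are dropped with a warning. For a
    background of size M, a set of size K (after background
    intersection), a query of size n and overlap k, the raw p-value is
    P[X >= k] for X ~ Hypergeom(M, K, n). Bonferroni multiplies by the
    number of sets tested (capped at 1); BH adjusts across all sets.
    """
    background = collection.background
    query_set = set(query)
    outside = query_set - background
    if outside:
        warnings.warn(
            f"{len(outside)} query genes outside the background were dropped",
            UserWarning,
            stacklevel=2,
        )
    query_set &= background
    if not query_set:
        raise EmptyInputError("query is empty after background intersection")

    M, n = len(background), len(query_set)
    rows = []
    for name, genes in collection.sets.items():
        members = set(genes) & background
        k = len(query_set & members)
        p = float(stats.hypergeom.sf(k - 1, M, len(members), n)) if members else 1.0
        rows.append((name, len(members), k, min(1.0, p)))
    df = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap_count", "p_raw"])
    df["p_bonferroni"] = (df["p_raw"] * len(df)).clip(upper=1.0)
    df["p_bh"] = multipletests(df["p_raw"], method="fdr_bh")[1]
    df["significant"] = (df["p_bonferroni"] < 0.05) & (df["p_bh"] < 0.05)
    return df.sort_values("p_raw", kind="stable").reset_index(drop=True)
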