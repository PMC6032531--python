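"""Comparative-Ct (2^-ddCt) relative quantification of qPCR data.

Per sample and gene, replicate Ct values are averaged first; then
dCt = Ct_gene - Ct_reference, ddCt = dCt - dCt_calibrator, and the
relative quantity is rq = 2^-ddCt. The calibrator defaults to the
non-responder group's mean dCt, so group-level fold changes read off
directly as responder-group rq. Amplification efficiency is fixed at 2
(no efficiency correction).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import DataError, MissingReferenceError
from .expression import NON_RESPONDER, ExpressionMatrix

CT_COLUMNS = ["sample", "gene", "replicate", "ct"]


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    """Read a Ct table CSV with columns sample, gene, replicate, ct."""
    df = pd.read_csv(path)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"Ct table missing columns: {missing}")
    return df[CT_COLUMNS]


def _validate_ct(ct: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise DataError(f"Ct table missing columns: {missing}")
    if not np.isfinite(ct["ct"].to_numpy(dtype=float)).all():
        raise DataError("Ct values must be finite")
    return ct


def relative_quantify(
    ct: pd.DataFrame,
    reference_gene: str,
    labels: pd.Series | None = None,
    calibrator_group: str = NON_RESPONDER,
    calibrator_sample: str | None = None,
    per_replicate: bool = False,
) -> pd.DataFrame:
    """Relative quantities 2^-ddCt against one reference gene.

    Parameters
    ----------
    ct:
        Long-format Ct table (sample, gene, replicate, ct).
    reference_gene:
        Endogenous control; must be measured in every sample.
    labels, calibrator_group:
        When no ``calibrator_sample`` is named, the calibrator dCt is the
        mean dCt of the samples labeled ``calibrator_group`` (requires
        ``labels``).
    calibrator_sample:
        Alternatively, a single named sample whose dCt is the calibrator.
    per_replicate:
        Replicates are averaged into a mean Ct before dCt by default;
        with ``per_replicate=True`` dCt is computed per replicate index
        and averaged afterwards (the alternative aggregation order).

    Returns one row per (sample, target gene) with delta_ct, ddct, rq and
    the replicate SD of dCt.
    """
    ct = _validate_ct(ct)
    if per_replicate:
        wide = ct.pivot_table(index=["sample", "replicate"], columns="gene", values="ct")
        if reference_gene not in wide.columns or wide[reference_gene].isna().any():
            raise MissingReferenceError(
                f"reference gene {reference_gene!r} is not measured in every sample/replicate"
            )
        dct_rep = wide.drop(columns=[reference_gene]).sub(wide[reference_gene], axis=0)
        dct = dct_rep.groupby(level="sample").mean()
        dct_sd = dct_rep.groupby(level="sample").std(ddof=1)
    else:
        mean_ct = ct.groupby(["sample", "gene"])["ct"].mean().unstack("gene")
        sd_ct = ct.groupby(["sample", "gene"])["ct"].std(ddof=1).unstack("gene")
        if reference_gene not in mean_ct.columns or mean_ct[reference_gene].isna().any():
            missing = (
                list(mean_ct.index[mean_ct[reference_gene].isna()])
                if reference_gene in mean_ct.columns
                else list(mean_ct.index)
            )
            raise MissingReferenceError(
                f"reference gene {reference_gene!r} missing for samples: {missing}"
            )
        dct = mean_ct.drop(columns=[reference_gene]).sub(mean_ct[reference_gene], axis=0)
        ref_sd = sd_ct[reference_gene]
        dct_sd = np.sqrt(sd_ct.drop(columns=[reference_gene]) ** 2 + ref_sd.to_numpy()[:, None] ** 2)

    if calibrator_sample is not None:
        if calibrator_sample not in dct.index:
            raise DataError(f"calibrator sample {calibrator_sample!r} not in Ct table")
        calibrator = dct.loc[calibrator_sample]
    else:
        if labels is None:
            raise DataError("group calibrator requires sample labels")
        labels = pd.Series(labels)
        cal_samples = [s for s in dct.index if labels.get(s) == calibrator_group]
        if not cal_samples:
            raise DataError(f"no samples labeled {calibrator_group!r} to use as calibrator")
        calibrator = dct.loc[cal_samples].mean()

    ddct = dct - calibrator
    rq = np.power(2.0, -ddct)
    out = (
        pd.concat(
            {"delta_ct": dct, "ddct": ddct, "rq": rq, "replicate_sd": dct_sd}, axis=1
        )
        .stack(future_stack=True)
        .reset_index()
    )
    out.columns = ["sample", "gene", "delta_ct", "ddct", "rq", "replicate_sd"]
    out["reference_gene"] = reference_gene
    return out.dropna(subset=["delta_ct"]).reset_index(drop=True)


def qpcr_to_expression(rel: pd.DataFrame, labels: pd.Series) -> ExpressionMatrix:
    """Assemble log2 relative quantities into an :class:`ExpressionMatrix`.

    log2(rq) = -ddCt, so the matrix is directly comparable with log2
    microarray expression and suitable for signature scoring.
    """
    refs = rel["reference_gene"].unique()
    if len(refs) != 1:
        raise DataError(
            f"expected a single reference gene, got {list(refs)}; "
            "quantify against each reference separately"
        )
    dup = rel.duplicated(subset=["sample", "gene"])
    if dup.any():
        pairs = rel.loc[dup, ["sample", "gene"]].to_records(index=False).tolist()
        raise DataError(f"duplicate (sample, gene) relative-expression rows: {pairs[:5]}")
    log2rq = -rel.pivot(index="gene", columns="sample", values="ddct")
    log2rq.index.name = None
    log2rq.columns.name = None
    labels = pd.Series(labels).reindex(log2rq.columns)
    return ExpressionMatrix(log2rq, labels)
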