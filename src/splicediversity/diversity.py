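"""Per-gene, per-sample diversity from transcript-level expression.

The central entry point is :func:`calculate_diversity`: transcripts are
grouped into genes via a tx2gene map, single-isoform genes are removed
(diversity is undefined for them), and the chosen metric is evaluated for
every remaining (gene, sample) pair. Supporting steps: relative-abundance
filtering of low transcripts and bootstrap-based uncertainty (MAD of the
diversity across expression bootstrap replicates).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import (
    ENTROPY_METRICS,
    VALID_METRICS,
    BootstrapSet,
    DiversityMatrix,
    ExpressionTable,
    SpliceDiversityError,
    TranscriptGeneMap,
)

logger = logging.getLogger(__name__)

__all__ = [
    "calculate_diversity",
    "filter_low_abundance",
    "bootstrap_diversity_mad",
    "mad",
]


def _metric_columns(sub: np.ndarray, metric: str, normalized: bool) -> np.ndarray:
    """Evaluate one metric on a k-isoform-by-S-sample block, vectorized over
    samples. Columns with zero total yield NaN except for the Laplace entropy."""
    k = sub.shape[0]
    totals = sub.sum(axis=0)
    nonzero = totals > 0

    if metric == "laplace":
        q = (sub + 1.0) / (totals + k)
        with np.errstate(divide="ignore", invalid="ignore"):
            logs = np.where(q > 0, np.log2(np.where(q > 0, q, 1.0)), 0.0)
        h = -(q * logs).sum(axis=0)
        return h / np.log2(k) if normalized else h

    out = np.full(sub.shape[1], np.nan)
    if not nonzero.any():
        return out
    p = sub[:, nonzero] / totals[nonzero]

    if metric == "naive":
        with np.errstate(divide="ignore", invalid="ignore"):
            logs = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
        vals = -(p * logs).sum(axis=0)
        if normalized:
            vals = vals / np.log2(k)
    elif metric == "gini":
        s = np.sort(p, axis=0)
        i = np.arange(1, k + 1)[:, None]
        pair_sum = 2.0 * ((2 * i - k - 1) * s).sum(axis=0)
        vals = pair_sum / (2.0 * k) * k / (k - 1)
    elif metric == "simpson":
        vals = 1.0 - (p**2).sum(axis=0)
    elif metric == "invsimpson":
        vals = 1.0 / (p**2).sum(axis=0)
    else:
        raise SpliceDiversityError(
            f"unknown metric {metric!r}; valid metrics: {VALID_METRICS}"
        )
    out[nonzero] = vals
    return out


def _gene_blocks(expr: ExpressionTable, txmap: TranscriptGeneMap):
    """Yield (gene_id, row-index array) for mapped transcripts, warning about
    unmapped ones. Gene order follows first appearance in the table."""
    genes = txmap.pairs.reindex(expr.transcript_ids)
    unmapped = genes.isna()
    if unmapped.any():
        logger.warning(
            "%d transcripts absent from tx2gene map were excluded (e.g. %s)",
            int(unmapped.sum()),
            ", ".join(map(str, expr.transcript_ids[unmapped][:3])),
        )
    mapped = genes[~unmapped]
    positions = pd.Series(
        np.nonzero(~unmapped.to_numpy())[0], index=mapped.index
    )
    for gene in mapped.unique():
        yield gene, positions[mapped == gene].to_numpy()


def calculate_diversity(
    expr: ExpressionTable,
    txmap: TranscriptGeneMap,
    metric: str = "naive",
    normalized: bool = False,
) -> DiversityMatrix:
    """Compute a gene-by-sample diversity matrix.

    Parameters
    ----------
    expr
        Transcript-by-sample expression (TPM recommended).
    txmap
        Transcript -> gene mapping; transcripts missing from the map are
        excluded with a logged warning.
    metric
        One of ``naive``, ``laplace``, ``gini``, ``simpson``, ``invsimpson``.
    normalized
        Divide entropies by log2(isoform number) so genes with different
        isoform counts share the [0, 1] scale. Ignored (with a warning) for
        the already-bounded Gini/Simpson family.

    Genes with a single isoform are removed entirely; genes whose isoforms
    are all zero in a sample get NaN there (except the Laplace entropy,
    which is defined everywhere).
    """
    if metric not in VALID_METRICS:
        raise SpliceDiversityError(
            f"unknown metric {metric!r}; valid metrics: {VALID_METRICS}"
        )
    if normalized and metric not in ENTROPY_METRICS:
        logger.warning(
            "normalization applies only to entropy metrics; ignoring the flag "
            "for %r (already bounded)",
            metric,
        )
        normalized = False

    mat = expr.values.to_numpy(dtype=float)
    gene_ids: list = []
    rows: list[np.ndarray] = []
    n_single = 0
    for gene, idx in _gene_blocks(expr, txmap):
        if idx.shape[0] < 2:
            n_single += 1
            continue
        gene_ids.append(gene)
        rows.append(_metric_columns(mat[idx], metric, normalized))
    if n_single:
        logger.info("removed %d single-isoform genes", n_single)

    values = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, mat.shape[1])),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=expr.sample_ids,
    )
    return DiversityMatrix(values=values, metric=metric, normalized=normalized)


def filter_low_abundance(
    expr: ExpressionTable,
    txmap: TranscriptGeneMap,
    threshold_pct: float,
) -> ExpressionTable:
    """Drop transcripts that never reach ``threshold_pct`` % of their gene's
    total expression.

    A transcript is kept iff, in every sample where its gene has nonzero
    total expression, transcript / gene-total >= threshold_pct / 100.
    Samples where the gene total is zero are non-disqualifying (0/0 carries
    no evidence against the transcript). Unmapped transcripts are kept
    untouched. threshold 0 is the identity.
    """
    if not 0 <= threshold_pct < 100:
        raise SpliceDiversityError("threshold_pct must be in [0, 100)")
    if threshold_pct == 0:
        return expr
    thr = threshold_pct / 100.0

    mat = expr.values.to_numpy(dtype=float)
    keep = np.ones(mat.shape[0], dtype=bool)
    for _gene, idx in _gene_blocks(expr, txmap):
        sub = mat[idx]
        totals = sub.sum(axis=0)
        expressed = totals > 0
        if not expressed.any():
            continue  # gene silent everywhere: nothing to judge
        rel = sub[:, expressed] / totals[expressed]
        keep[idx] = (rel >= thr).all(axis=1)

    dropped = int((~keep).sum())
    logger.info(
        "filter_low_abundance(%.3g%%): dropped %d of %d transcripts",
        threshold_pct,
        dropped,
        mat.shape[0],
    )
    lengths = expr.lengths[keep] if expr.lengths is not None else None
    return ExpressionTable(
        values=expr.values.loc[keep], unit=expr.unit, lengths=lengths
    )


def mad(values) -> float:
    """Median absolute deviation from the median (unscaled)."""
    arr = np.asarray(values, dtype=float)
    return float(np.median(np.abs(arr - np.median(arr))))


def bootstrap_diversity_mad(
    bs: BootstrapSet,
    txmap: TranscriptGeneMap,
    metric: str = "naive",
    normalized: bool = False,
    point: ExpressionTable | None = None,
) -> pd.DataFrame:
    """Quantify diversity uncertainty from bootstrap expression replicates.

    For each multi-isoform gene, the metric is computed on every replicate
    and summarized by the MAD across replicates; the gene-level summed
    expression is summarized the same way. Replicates where the metric is
    undefined (all-zero gene, non-Laplace metric) are excluded; a gene with
    fewer than 2 defined values gets NaN.

    Returns one row per gene with columns ``gene_id``, ``sample_id``,
    ``diversity_mad``, ``expression_mad`` and ``point_expression`` (gene
    total from the non-bootstrap estimate in ``point``, NaN if absent).
    """
    reps = ExpressionTable(values=bs.replicates.T, unit=bs.unit)
    div = calculate_diversity(reps, txmap, metric=metric, normalized=normalized)

    point_col = None
    if point is not None:
        if bs.sample_id not in point.sample_ids:
            raise SpliceDiversityError(
                f"sample {bs.sample_id!r} absent from the point-estimate table"
            )
        point_col = point.values[bs.sample_id]

    records = []
    rep_mat = bs.replicates.to_numpy(dtype=float)
    genes_of = txmap.pairs.reindex(bs.transcript_ids)
    for gene in div.gene_ids:
        vals = div.values.loc[gene].to_numpy()
        defined = vals[~np.isnan(vals)]
        d_mad = mad(defined) if defined.shape[0] >= 2 else float("nan")
        gene_expr = rep_mat[:, (genes_of == gene).to_numpy()].sum(axis=1)
        point_expr = float("nan")
        if point_col is not None:
            members = txmap.pairs.index[txmap.pairs == gene]
            point_expr = float(point_col.reindex(members).fillna(0.0).sum())
        records.append(
            {
                "gene_id": gene,
                "sample_id": bs.sample_id,
                "diversity_mad": d_mad,
                "expression_mad": mad(gene_expr),
                "point_expression": point_expr,
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "gene_id",
            "sample_id",
            "diversity_mad",
            "expression_mad",
            "point_expression",
        ],
    )
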