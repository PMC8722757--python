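"""Two-group differential diversity analysis.

Given a gene-by-sample diversity matrix and a two-condition sample
assignment, each gene is summarized by the mean or median diversity per
condition, their difference and log2 fold change, and a P-value from
either a two-sided Wilcoxon rank-sum test or a label-shuffling permutation
test; P-values are adjusted with the Benjamini–Hochberg step-up. A gene is
called significant when |difference| exceeds the difference threshold AND
the adjusted P-value is below the significance level (defaults 0.1 and
0.05).

For metrics bounded in [0, 1] (normalized entropies, Gini, Simpson) the
difference of central values is the recommended effect size: the log2
ratio over-emphasizes small changes near zero. For unbounded metrics (raw
entropies, inverse Simpson) the log2 fold change is the better summary.
This guidance is logged as an advisory, never enforced.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    DifferentialConfig,
    DiversityMatrix,
    SampleGroups,
    SpliceDiversityError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "group_central_difference",
    "log2_fold_change",
    "wilcoxon_rank_sum",
    "label_shuffling_test",
    "bh_adjust",
    "calculate_difference",
]

#: Metrics (with their normalization state) whose values live in [0, 1];
#: difference of central values is advised for these, log2 FC otherwise.
BOUNDED_METRICS = {("naive", True), ("laplace", True), ("gini", False), ("simpson", False)}

_EXHAUSTIVE_FALLBACK = 20  # fewer distinct relabelings than this -> enumerate


def _central(values: np.ndarray, central: str) -> float:
    if values.size == 0:
        return float("nan")
    return float(np.mean(values) if central == "mean" else np.median(values))


def group_central_difference(
    values: pd.Series,
    groups: SampleGroups,
    central: str = "mean",
) -> tuple[float, float, float]:
    """Per-condition central diversity and their difference.

    NaN values are dropped per group first; a group left empty makes all
    three outputs NaN. The difference is central_2 - central_1, with group
    1 the reference condition of ``groups``.
    """
    if central not in ("mean", "median"):
        raise SpliceDiversityError("central must be 'mean' or 'median'")
    lab1, lab2 = groups.labels
    v1 = values.reindex(groups.samples_in(lab1)).dropna().to_numpy(dtype=float)
    v2 = values.reindex(groups.samples_in(lab2)).dropna().to_numpy(dtype=float)
    if v1.size == 0 or v2.size == 0:
        return (float("nan"), float("nan"), float("nan"))
    c1, c2 = _central(v1, central), _central(v2, central)
    return (c1, c2, c2 - c1)


def log2_fold_change(central_1: float, central_2: float) -> float:
    """log2(central_2 / central_1); NaN when either value is NaN or <= 0."""
    if (
        central_1 is None
        or central_2 is None
        or math.isnan(central_1)
        or math.isnan(central_2)
        or central_1 <= 0
        or central_2 <= 0
    ):
        return float("nan")
    return math.log2(central_2 / central_1)


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) P-value.

    The exact null distribution is used when there are no ties and the
    pooled sample size is at most 25; otherwise the normal approximation
    with tie and continuity corrections. Two groups with all values
    identical carry no ordering information and return P = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise SpliceDiversityError("both groups must be non-empty")
    if np.isnan(a).any() or np.isnan(b).any():
        raise SpliceDiversityError("NaN values must be removed before testing")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and pooled.size <= 25) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def _shuffle_stat(pooled: np.ndarray, idx1, central: str) -> float:
    mask = np.zeros(pooled.size, dtype=bool)
    mask[list(idx1)] = True
    return abs(_central(pooled[mask], central) - _central(pooled[~mask], central))


def label_shuffling_test(
    values: pd.Series,
    groups: SampleGroups,
    central: str = "mean",
    n_permutations: int = 1000,
    seed: int = 0,
    exhaustive: bool | None = None,
) -> float:
    """Permutation test on |difference of central values|.

    Condition labels are reshuffled over the non-NA samples. Monte-Carlo
    mode uses the add-one estimator p = (1 + #{perm >= obs}) / (1 + B) so
    the P-value is never zero. When the number of distinct relabelings is
    below 20 (or ``exhaustive=True``), all label assignments are
    enumerated instead and p = #{perm >= obs} / #assignments.
    """
    lab1, lab2 = groups.labels
    v1 = values.reindex(groups.samples_in(lab1)).dropna().to_numpy(dtype=float)
    v2 = values.reindex(groups.samples_in(lab2)).dropna().to_numpy(dtype=float)
    if v1.size == 0 or v2.size == 0:
        raise SpliceDiversityError("both groups need non-NA values")
    pooled = np.concatenate([v1, v2])
    n, n1 = pooled.size, v1.size
    observed = abs(_central(v1, central) - _central(v2, central))

    n_distinct = math.comb(n, n1)
    if exhaustive is None:
        exhaustive = n_distinct < _EXHAUSTIVE_FALLBACK
        if exhaustive:
            logger.info(
                "only %d distinct label assignments; enumerating exhaustively",
                n_distinct,
            )
    tol = 1e-12  # permuted stat equal to observed up to roundoff counts as >=
    if exhaustive:
        hits = sum(
            _shuffle_stat(pooled, idx1, central) >= observed - tol
            for idx1 in combinations(range(n), n1)
        )
        return hits / n_distinct

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        stat = abs(_central(perm[:n1], central) - _central(perm[n1:], central))
        if stat >= observed - tol:
            hits += 1
    return (1 + hits) / (1 + n_permutations)


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment.

    NaN entries stay NaN and do not count toward the number of tests.
    Values outside [0, 1] are a hard error.
    """
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    mask = ~np.isnan(arr)
    if ((arr[mask] < 0) | (arr[mask] > 1)).any():
        raise SpliceDiversityError("p-values must lie in [0, 1]")
    if mask.any():
        out[mask] = multipletests(arr[mask], method="fdr_bh")[1]
    return out


def calculate_difference(
    div: DiversityMatrix,
    groups: SampleGroups,
    config: DifferentialConfig | None = None,
) -> pd.DataFrame:
    """Assemble the per-gene differential diversity table.

    Genes with fewer than ``config.min_samples_per_group`` non-NA diversity
    values in either condition are excluded from significance testing
    (their central values are still reported when computable). Returns one
    row per gene with columns gene_id, central_1, central_2, difference,
    log2_fold_change, p_value, adjusted_p, n_1, n_2, significant,
    excluded_reason.
    """
    config = config or DifferentialConfig()
    missing = [s for s in div.sample_ids if s not in groups.assignment.index]
    if missing:
        raise SpliceDiversityError(
            f"samples missing from the groups table: {missing}"
        )
    lab1, lab2 = groups.labels
    s1 = [s for s in groups.samples_in(lab1) if s in div.sample_ids]
    s2 = [s for s in groups.samples_in(lab2) if s in div.sample_ids]

    advised = (
        "difference of central values"
        if (div.metric, div.normalized) in BOUNDED_METRICS
        else "log2 fold change"
    )
    logger.info(
        "metric %s%s: %s is the recommended effect size",
        div.metric,
        " (normalized)" if div.normalized else "",
        advised,
    )

    records = []
    for gene in div.gene_ids:
        row = div.values.loc[gene]
        v1 = row.reindex(s1).dropna().to_numpy(dtype=float)
        v2 = row.reindex(s2).dropna().to_numpy(dtype=float)
        c1 = _central(v1, config.central)
        c2 = _central(v2, config.central)
        diff = c2 - c1 if not (math.isnan(c1) or math.isnan(c2)) else float("nan")
        lfc = log2_fold_change(c1, c2)
        reason = ""
        p = float("nan")
        if min(v1.size, v2.size) < config.min_samples_per_group:
            reason = "insufficient_samples"
        elif config.test == "wilcoxon":
            p = wilcoxon_rank_sum(v1, v2)
        else:
            p = label_shuffling_test(
                row,
                groups,
                central=config.central,
                n_permutations=config.n_permutations,
                seed=config.seed,
            )
        records.append(
            {
                "gene_id": gene,
                "central_1": c1,
                "central_2": c2,
                "difference": diff,
                "log2_fold_change": lfc,
                "p_value": p,
                "n_1": int(v1.size),
                "n_2": int(v2.size),
                "excluded_reason": reason,
            }
        )

    table = pd.DataFrame.from_records(
        records,
        columns=[
            "gene_id",
            "central_1",
            "central_2",
            "difference",
            "log2_fold_change",
            "p_value",
            "n_1",
            "n_2",
            "excluded_reason",
        ],
    )
    table["adjusted_p"] = bh_adjust(table["p_value"].to_numpy())
    table["significant"] = (
        (table["difference"].abs() > config.diff_threshold)
        & (table["adjusted_p"] < config.adj_p_threshold)
    ).fillna(False)
    n_excl = int((table["excluded_reason"] != "").sum())
    logger.info(
        "%d genes tested, %d excluded, %d significant at |diff| > %g and "
        "adjusted P < %g",
        len(table) - n_excl,
        n_excl,
        int(table["significant"].sum()),
        config.diff_threshold,
        config.adj_p_threshold,
    )
    return table[
        [
            "gene_id",
            "central_1",
            "central_2",
            "difference",
            "log2_fold_change",
            "p_value",
            "adjusted_p",
            "n_1",
            "n_2",
            "significant",
            "excluded_reason",
        ]
    ]
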