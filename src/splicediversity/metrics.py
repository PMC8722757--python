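"""Scalar diversity metrics on isoform proportion vectors.

Every metric summarizes how evenly a gene's expression is spread across its
n >= 2 transcript isoforms in one sample. All metrics except the Laplace
entropy are functions of the proportion vector p alone and are therefore
invariant to rescaling the expression vector; the Laplace entropy adds a
pseudocount of +1 to each isoform's raw expression first and so depends on
the absolute scale.

Conventions:

* entropies use base-2 logarithms, so the raw Shannon entropy ranges over
  [0, log2(n)]; 0 * log2(0) is taken as 0
* "normalized" divides an entropy by log2(n), mapping it onto [0, 1]
* a gene whose isoforms are all zero in a sample has no defined proportion
  vector; every metric returns NaN there except the Laplace entropy, whose
  pseudocount makes it defined (and maximal) for all-zero input
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import SpliceDiversityError

__all__ = [
    "ProportionVector",
    "proportions",
    "entropy_naive",
    "entropy_laplace",
    "gini_index",
    "simpson_index",
    "inverse_simpson",
    "metric_function",
]


@dataclass(frozen=True)
class ProportionVector:
    """Isoform proportions for one gene in one sample.

    ``p`` sums to 1, or is all zeros with ``all_zero`` set when the gene is
    entirely unexpressed (metrics other than the Laplace entropy emit NaN).
    """

    p: np.ndarray
    all_zero: bool = False

    @property
    def n(self) -> int:
        return self.p.shape[0]


def _as_expression(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise SpliceDiversityError("expression vector must be one-dimensional")
    if arr.shape[0] < 2:
        raise SpliceDiversityError(
            "diversity is undefined for single-isoform genes (need >= 2 isoforms)"
        )
    if np.isnan(arr).any() or not np.isfinite(arr).all():
        raise SpliceDiversityError("expression vector must be finite with no NA")
    if (arr < 0).any():
        raise SpliceDiversityError("expression vector must be non-negative")
    return arr


def proportions(x) -> ProportionVector:
    """Convert a non-negative expression vector to isoform proportions.

    An all-zero vector yields the flagged all-zero ProportionVector rather
    than an error: downstream metrics turn it into NaN.
    """
    arr = _as_expression(x)
    total = arr.sum()
    if total == 0.0:
        return ProportionVector(np.zeros_like(arr), all_zero=True)
    return ProportionVector(arr / total)


def _coerce(p) -> ProportionVector:
    if isinstance(p, ProportionVector):
        return p
    return proportions(p)


def _shannon_bits(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def entropy_naive(p, normalized: bool = False) -> float:
    """Shannon entropy of the isoform proportions, in bits.

    0 means a single expressed isoform; log2(n) (or 1 when normalized)
    means all isoforms evenly expressed. NaN for an all-zero gene.
    """
    pv = _coerce(p)
    if pv.all_zero:
        return float("nan")
    h = _shannon_bits(pv.p)
    if normalized:
        h /= np.log2(pv.n)
    return h


def entropy_laplace(x, normalized: bool = False) -> float:
    """Shannon entropy after a +1 pseudocount on each isoform's expression.

    q_i = (x_i + 1) / (sum(x) + n). A Bayesian (Laplace-smoothed) entropy
    estimate: defined even when the gene is entirely unexpressed, where it
    attains the maximum (1 when normalized) because the pseudocounts are
    then uniform.
    """
    arr = _as_expression(x)
    q = (arr + 1.0) / (arr.sum() + arr.shape[0])
    h = _shannon_bits(q)
    if normalized:
        h /= np.log2(arr.shape[0])
    return h


def gini_index(p) -> float:
    """Bias-corrected Gini concentration index of isoform proportions.

    G = [sum_ij |p_i - p_j| / (2 n^2 pbar)] * n / (n - 1) with pbar = 1/n.
    0 = all isoforms equally expressed; 1 = one isoform carries everything
    (the n/(n-1) small-sample correction makes the single-isoform extreme
    exactly 1 for every n). NaN for an all-zero gene.
    """
    pv = _coerce(p)
    if pv.all_zero:
        return float("nan")
    n = pv.n
    s = np.sort(pv.p)
    # sum_ij |p_i - p_j| = 2 * sum_i (2i - n - 1) * p_(i), i = 1..n ascending
    i = np.arange(1, n + 1)
    pair_sum = 2.0 * float(((2 * i - n - 1) * s).sum())
    g = pair_sum / (2.0 * n)  # pbar = 1/n, so / (2 n^2 pbar) = / (2 n)
    return g * n / (n - 1)


def simpson_index(p) -> float:
    """Gini–Simpson diversity index, 1 - sum(p_i^2).

    The probability that two reads drawn at random come from different
    isoforms: 0 = one dominant isoform, maximum 1 - 1/n at uniformity.
    NaN for an all-zero gene.
    """
    pv = _coerce(p)
    if pv.all_zero:
        return float("nan")
    return float(1.0 - (pv.p**2).sum())


def inverse_simpson(p) -> float:
    """Inverse Simpson index, 1 / sum(p_i^2): effective isoform number.

    Ranges from 1 (single expressed isoform) to n (uniform expression).
    NaN for an all-zero gene.
    """
    pv = _coerce(p)
    if pv.all_zero:
        return float("nan")
    return float(1.0 / (pv.p**2).sum())


def metric_function(metric: str, normalized: bool = False):
    """Return f(expression_vector) -> float for a metric label.

    The returned callable always takes the raw (unnormalized) expression
    vector, so the scale-dependent Laplace entropy and the proportion-based
    metrics share one calling convention.
    """
    if metric == "naive":
        return lambda x: entropy_naive(proportions(x), normalized=normalized)
    if metric == "laplace":
        return lambda x: entropy_laplace(x, normalized=normalized)
    if metric == "gini":
        return lambda x: gini_index(proportions(x))
    if metric == "simpson":
        return lambda x: simpson_index(proportions(x))
    if metric == "invsimpson":
        return lambda x: inverse_simpson(proportions(x))
    raise SpliceDiversityError(
        f"unknown metric {metric!r}; valid metrics: "
        "('naive', 'laplace', 'gini', 'simpson', 'invsimpson')"
    )
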