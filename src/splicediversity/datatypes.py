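"""Core in-memory containers shared across the toolkit.

All tabular data rides on pandas; these thin dataclasses pin down the
orientation conventions (rows = transcripts or genes, columns = samples)
and carry the metadata that plain DataFrames would lose (expression unit,
transcript lengths, diversity metric name).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Expression units the toolkit accepts. TPM is recommended: metrics are
#: computed on within-gene proportions, and un-normalized read counts bias
#: proportions toward long isoforms.
VALID_UNITS = ("TPM", "counts", "RPKM", "FPKM", "other")

#: Diversity metric labels understood by the calculators.
VALID_METRICS = ("naive", "laplace", "gini", "simpson", "invsimpson")

#: Metrics with a meaningful [0, 1] normalization (entropies only; the
#: concentration indices are already bounded).
ENTROPY_METRICS = ("naive", "laplace")


class SpliceDiversityError(ValueError):
    """Base class for input-contract violations."""


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise SpliceDiversityError(f"duplicate {what}: {dups}")


@dataclass
class ExpressionTable:
    """Transcript-by-sample expression matrix.

    Rows are transcripts, columns are samples — fixed orientation, never
    auto-transposed. Values must be finite and non-negative; missing values
    are not permitted (quantifier outputs are complete).
    """

    values: pd.DataFrame
    unit: str = "TPM"
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise SpliceDiversityError(
                f"unknown unit {self.unit!r}; valid units: {VALID_UNITS}"
            )
        _check_unique(self.values.index, "transcript IDs")
        _check_unique(self.values.columns, "sample IDs")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise SpliceDiversityError("expression values must be numeric")
        if np.isnan(arr).any():
            rows, cols = np.nonzero(np.isnan(arr))
            raise SpliceDiversityError(
                "missing value at "
                f"({self.values.index[rows[0]]}, {self.values.columns[cols[0]]})"
            )
        if not np.isfinite(arr).all():
            raise SpliceDiversityError("expression values must be finite")
        if (arr < 0).any():
            rows, cols = np.nonzero(arr < 0)
            raise SpliceDiversityError(
                "negative expression value at "
                f"({self.values.index[rows[0]]}, {self.values.columns[cols[0]]})"
            )
        if self.lengths is not None:
            self.lengths = pd.Series(self.lengths)
            if not self.lengths.index.equals(self.values.index):
                self.lengths = self.lengths.reindex(self.values.index)
            if self.lengths.isna().any():
                raise SpliceDiversityError("a length is missing for some transcripts")
            if (self.lengths <= 0).any():
                bad = self.lengths.index[self.lengths <= 0].tolist()
                raise SpliceDiversityError(f"non-positive transcript lengths: {bad}")

    @property
    def transcript_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class TranscriptGeneMap:
    """Many-to-one transcript -> gene mapping (tx2gene)."""

    pairs: pd.Series  # index = transcript IDs, values = gene IDs

    def __post_init__(self) -> None:
        self.pairs = pd.Series(self.pairs)
        _check_unique(self.pairs.index, "transcripts in tx2gene")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TranscriptGeneMap":
        if frame.shape[1] < 2:
            raise SpliceDiversityError("tx2gene table needs two columns")
        return cls(pd.Series(frame.iloc[:, 1].values, index=frame.iloc[:, 0].values))

    def gene_of(self, transcript_id) -> str:
        return self.pairs[transcript_id]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class SampleGroups:
    """Assignment of each sample to one of exactly two condition labels.

    ``reference`` names the condition treated as group 1; by default the
    lexicographically smaller label, so results are deterministic.
    """

    assignment: pd.Series  # index = sample IDs, values = condition labels
    reference: str | None = None

    def __post_init__(self) -> None:
        self.assignment = pd.Series(self.assignment).astype(str)
        _check_unique(self.assignment.index, "samples in groups table")
        labels = sorted(self.assignment.unique())
        if len(labels) != 2:
            raise SpliceDiversityError(
                f"exactly two condition labels required, found {labels}"
            )
        if self.reference is None:
            self.reference = labels[0]
        elif self.reference not in labels:
            raise SpliceDiversityError(
                f"reference label {self.reference!r} not among conditions {labels}"
            )

    @property
    def labels(self) -> tuple[str, str]:
        """(group 1 label, group 2 label): reference first."""
        labels = sorted(self.assignment.unique())
        other = labels[1] if labels[0] == self.reference else labels[0]
        return (self.reference, other)

    def samples_in(self, label: str) -> list:
        return list(self.assignment.index[self.assignment == label])


@dataclass
class BootstrapSet:
    """Bootstrap expression replicates for one sample.

    ``replicates`` is a replicate-by-transcript DataFrame: each row is one
    bootstrap draw over the same ordered transcript set.
    """

    sample_id: str
    replicates: pd.DataFrame
    unit: str = "TPM"

    def __post_init__(self) -> None:
        if self.replicates.shape[0] < 2:
            raise SpliceDiversityError(
                f"at least 2 bootstrap replicates required, "
                f"got {self.replicates.shape[0]}"
            )
        _check_unique(self.replicates.columns, "transcripts in bootstrap replicates")
        arr = self.replicates.to_numpy()
        if np.isnan(arr).any() or (arr < 0).any():
            raise SpliceDiversityError("bootstrap values must be non-negative, no NA")

    @property
    def n_replicates(self) -> int:
        return self.replicates.shape[0]

    @property
    def transcript_ids(self) -> pd.Index:
        return self.replicates.columns


@dataclass
class DiversityMatrix:
    """Gene-by-sample diversity values with the metric recorded alongside.

    NA marks (gene, sample) cells where the metric is undefined: total gene
    expression of zero for every metric except the Laplace entropy, which is
    defined everywhere thanks to its pseudocount.
    """

    values: pd.DataFrame  # rows = genes, columns = samples, NaN allowed
    metric: str = "naive"
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.metric not in VALID_METRICS:
            raise SpliceDiversityError(
                f"unknown metric {self.metric!r}; valid metrics: {VALID_METRICS}"
            )
        _check_unique(self.values.index, "gene IDs")
        _check_unique(self.values.columns, "sample IDs")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class DifferentialConfig:
    """Settings for the two-group differential diversity step.

    Defaults encode the significance rule used throughout:
    |difference of central values| > 0.1 and BH-adjusted P < 0.05.
    """

    central: str = "mean"  # or "median"
    test: str = "wilcoxon"  # or "shuffle"
    n_permutations: int = 1000
    seed: int = 0
    min_samples_per_group: int = 3
    diff_threshold: float = 0.1
    adj_p_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.central not in ("mean", "median"):
            raise SpliceDiversityError("central must be 'mean' or 'median'")
        if self.test not in ("wilcoxon", "shuffle"):
            raise SpliceDiversityError("test must be 'wilcoxon' or 'shuffle'")
        if self.n_permutations < 1:
            raise SpliceDiversityError("n_permutations must be positive")
        if self.min_samples_per_group < 1:
            raise SpliceDiversityError("min_samples_per_group must be positive")
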