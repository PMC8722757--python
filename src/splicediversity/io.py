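"""Readers and writers for every external format the toolkit touches.

Expression matrices, tx2gene maps and sample-group tables travel as
delimited text (TSV by default). Per-sample quantifier outputs are read
from Salmon ``quant.sf`` and Kallisto ``abundance.tsv`` files; bootstrap
expression replicates from their plain-text exports, either one file per
replicate (Kallisto plaintext mode) or one row per replicate (Salmon's
TSV conversion). All quantifier parsing is header-name driven, never
column-position driven.

Missing values are forbidden in input expression tables (quantifier
outputs are complete); in result tables "NA" (case-insensitive) or an
empty cell denotes missing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    BootstrapSet,
    DiversityMatrix,
    ExpressionTable,
    SampleGroups,
    SpliceDiversityError,
    TranscriptGeneMap,
)

__all__ = [
    "read_expression_table",
    "read_salmon_quant",
    "read_kallisto_abundance",
    "read_bootstrap_replicates",
    "read_tx2gene",
    "read_sample_groups",
    "read_diversity_matrix",
    "counts_to_tpm",
    "table_counts_to_tpm",
    "bootstrap_counts_to_tpm",
    "write_results_table",
]

_NA_STRINGS = ["NA", "na", "Na", "nA", ""]


def _coerce_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    try:
        return df.apply(pd.to_numeric)
    except (ValueError, TypeError):
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                raise SpliceDiversityError(
                    f"{path}: non-numeric value {df[col][bad].iloc[0]!r} at "
                    f"({df.index[bad.to_numpy().nonzero()[0][0]]}, {col})"
                ) from None
        raise


def read_expression_table(
    path, delimiter: str = "\t", unit: str = "TPM"
) -> ExpressionTable:
    """Read a transcript-by-sample expression matrix from delimited text.

    First column holds transcript IDs, header row holds sample IDs; the
    body must be numeric and non-negative. Duplicate transcript IDs,
    ragged rows, negative or missing cells are hard errors.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    except pd.errors.ParserError as exc:
        raise SpliceDiversityError(f"{path}: ragged row — {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise SpliceDiversityError(f"{path}: empty file") from exc
    df = _coerce_numeric(df, path)
    df.index = df.index.astype(str)
    df.index.name = "transcript_id"
    return ExpressionTable(values=df, unit=unit)


def _read_quant_file(path, required: dict[str, str], delimiter: str = "\t"):
    """Read a quantifier output file, resolving columns by header name.

    ``required`` maps header names to roles ('id', 'value', 'length')."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter)
    except pd.errors.EmptyDataError as exc:
        raise SpliceDiversityError(f"{path}: empty file") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SpliceDiversityError(
            f"{path}: missing required column(s) {missing}; found "
            f"{list(df.columns)}"
        )
    cols = {role: df[name] for name, role in required.items()}
    ids = cols["id"].astype(str)
    if ids.duplicated().any():
        dups = ids[ids.duplicated()].unique().tolist()
        raise SpliceDiversityError(f"{path}: duplicate transcript IDs {dups}")
    return ids, cols


def read_salmon_quant(path, sample_id: str | None = None) -> ExpressionTable:
    """Read one Salmon ``quant.sf`` file into a single-sample table.

    TPM becomes the expression value; Length is kept as transcript
    lengths. The sample ID defaults to the directory holding ``quant.sf``
    (Salmon's per-sample output convention), else the file stem.
    """
    path = Path(path)
    ids, cols = _read_quant_file(
        path,
        {
            "Name": "id",
            "Length": "length",
            "EffectiveLength": "efflen",
            "TPM": "value",
            "NumReads": "reads",
        },
    )
    if sample_id is None:
        sample_id = path.parent.name if path.name == "quant.sf" else path.stem
    values = pd.DataFrame({sample_id: cols["value"].to_numpy(dtype=float)})
    values.index = pd.Index(ids, name="transcript_id")
    lengths = pd.Series(cols["length"].to_numpy(dtype=float), index=values.index)
    return ExpressionTable(values=values, unit="TPM", lengths=lengths)


def read_kallisto_abundance(path, sample_id: str | None = None) -> ExpressionTable:
    """Read one Kallisto ``abundance.tsv`` file into a single-sample table.

    ``tpm`` becomes the expression value; ``length`` is kept. Zero-count
    transcripts are retained. The sample ID defaults to the directory
    holding ``abundance.tsv``, else the file stem.
    """
    path = Path(path)
    ids, cols = _read_quant_file(
        path,
        {
            "target_id": "id",
            "length": "length",
            "eff_length": "efflen",
            "est_counts": "counts",
            "tpm": "value",
        },
    )
    if sample_id is None:
        sample_id = path.parent.name if path.name == "abundance.tsv" else path.stem
    values = pd.DataFrame({sample_id: cols["value"].to_numpy(dtype=float)})
    values.index = pd.Index(ids, name="transcript_id")
    lengths = pd.Series(cols["length"].to_numpy(dtype=float), index=values.index)
    return ExpressionTable(values=values, unit="TPM", lengths=lengths)


def _looks_like_header(fields: list[str]) -> bool:
    known = {
        "transcript",
        "transcript_id",
        "target_id",
        "tx",
        "gene",
        "gene_id",
        "sample",
        "sample_id",
        "condition",
        "group",
        "value",
    }
    return any(f.strip().lower() in known for f in fields)


def _read_two_columns(path, delimiter: str, what: str) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise SpliceDiversityError(f"{path}: empty {what} file")
    header = 0 if _looks_like_header(first.rstrip("\n").split(delimiter)) else None
    df = pd.read_csv(path, sep=delimiter, header=header, dtype=str)
    if df.shape[1] < 2:
        raise SpliceDiversityError(f"{path}: {what} table needs two columns")
    return df


def read_tx2gene(path, delimiter: str = "\t") -> TranscriptGeneMap:
    """Read a two-column transcript -> gene mapping (header optional)."""
    df = _read_two_columns(path, delimiter, "tx2gene")
    return TranscriptGeneMap.from_frame(df)


def read_sample_groups(
    path, delimiter: str = "\t", reference: str | None = None
) -> SampleGroups:
    """Read a two-column sample -> condition table (header optional)."""
    df = _read_two_columns(path, delimiter, "groups")
    assignment = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)
    return SampleGroups(assignment=assignment, reference=reference)


def read_bootstrap_replicates(
    path,
    layout: str = "auto",
    sample_id: str | None = None,
    unit: str = "TPM",
) -> BootstrapSet:
    """Read plain-text bootstrap expression replicates for one sample.

    Two dialects are supported and auto-detected by shape:

    * ``per-file`` — ``path`` is a directory with one file per replicate,
      each either a Kallisto-format abundance table or a two-column
      (transcript, value) table; files are taken in sorted order.
    * ``per-row`` — ``path`` is a single file whose header row lists the
      transcript IDs and each subsequent row is one replicate (the layout
      produced when converting Salmon's binary bootstraps to TSV; those
      carry estimated read counts — convert with
      :func:`bootstrap_counts_to_tpm` before computing diversity).

    Replicates with mismatched transcript sets are a hard error; at least
    two replicates are required.
    """
    path = Path(path)
    if layout == "auto":
        layout = "per-file" if path.is_dir() else "per-row"
    if layout not in ("per-file", "per-row"):
        raise SpliceDiversityError("layout must be 'auto', 'per-file' or 'per-row'")
    if sample_id is None:
        sample_id = path.stem if not path.is_dir() else path.name

    if layout == "per-file":
        files = sorted(p for p in path.iterdir() if p.is_file())
        if len(files) < 2:
            raise SpliceDiversityError(
                f"{path}: found {len(files)} replicate file(s), need >= 2"
            )
        rows = []
        ref_ids = None
        for f in files:
            with open(f) as fh:
                first = fh.readline().rstrip("\n").split("\t")
            if "target_id" in first:
                tab = read_kallisto_abundance(f)
                series = tab.values.iloc[:, 0]
            else:
                df = _read_two_columns(f, "\t", "bootstrap replicate")
                series = pd.Series(
                    pd.to_numeric(df.iloc[:, 1]).to_numpy(),
                    index=df.iloc[:, 0].astype(str).to_numpy(),
                )
            if ref_ids is None:
                ref_ids = series.index
            elif set(series.index) != set(ref_ids):
                raise SpliceDiversityError(
                    f"{f}: replicate transcript set differs from {files[0]}"
                )
            rows.append(series.reindex(ref_ids).to_numpy(dtype=float))
        replicates = pd.DataFrame(np.vstack(rows), columns=ref_ids)
    else:
        try:
            df = pd.read_csv(path, sep="\t")
        except pd.errors.EmptyDataError as exc:
            raise SpliceDiversityError(f"{path}: empty bootstrap file") from exc
        if df.shape[0] < 2:
            raise SpliceDiversityError(
                f"{path}: found {df.shape[0]} replicate row(s), need >= 2"
            )
        replicates = df.astype(float)
        replicates.columns = [str(c) for c in df.columns]

    return BootstrapSet(sample_id=sample_id, replicates=replicates, unit=unit)


def counts_to_tpm(counts, lengths) -> np.ndarray:
    """Convert read counts to TPM given transcript lengths (nt).

    TPM_i = (counts_i / lengths_i) / sum_j (counts_j / lengths_j) * 1e6.
    All-zero counts map to all-zero TPM. Any non-positive length is a hard
    error.
    """
    c = np.asarray(counts, dtype=float)
    l = np.asarray(lengths, dtype=float)
    if c.shape != l.shape:
        raise SpliceDiversityError("counts and lengths must have equal length")
    if (l <= 0).any() or np.isnan(l).any():
        raise SpliceDiversityError("all transcript lengths must be positive")
    if (c < 0).any():
        raise SpliceDiversityError("counts must be non-negative")
    rate = c / l
    total = rate.sum()
    if total == 0:
        return np.zeros_like(c)
    return rate / total * 1e6


def table_counts_to_tpm(expr: ExpressionTable) -> ExpressionTable:
    """Convert a counts ExpressionTable to TPM using its stored lengths."""
    if expr.lengths is None:
        raise SpliceDiversityError("transcript lengths are required for TPM conversion")
    tpm = {
        s: counts_to_tpm(expr.values[s].to_numpy(), expr.lengths.to_numpy())
        for s in expr.sample_ids
    }
    values = pd.DataFrame(tpm, index=expr.values.index)
    return ExpressionTable(values=values, unit="TPM", lengths=expr.lengths)


def bootstrap_counts_to_tpm(bs: BootstrapSet, lengths) -> BootstrapSet:
    """Convert count-valued bootstrap replicates to TPM, replicate-wise."""
    lengths = pd.Series(lengths).reindex(bs.transcript_ids)
    if lengths.isna().any():
        raise SpliceDiversityError("a length is missing for some transcripts")
    mat = np.vstack(
        [
            counts_to_tpm(row, lengths.to_numpy())
            for row in bs.replicates.to_numpy(dtype=float)
        ]
    )
    return BootstrapSet(
        sample_id=bs.sample_id,
        replicates=pd.DataFrame(mat, columns=bs.transcript_ids),
        unit="TPM",
    )


def write_results_table(table, path, delimiter: str = "\t") -> None:
    """Write a DiversityMatrix or a result DataFrame as delimited text.

    Missing values are serialized as the literal ``NA``. A DiversityMatrix
    additionally records its metric in a leading comment line
    (``# metric=naive normalized=true``) so the matrix round-trips through
    :func:`read_diversity_matrix`.
    """
    path = Path(path)
    if isinstance(table, DiversityMatrix):
        with open(path, "w") as fh:
            fh.write(
                f"# metric={table.metric} "
                f"normalized={'true' if table.normalized else 'false'}\n"
            )
            table.values.to_csv(
                fh, sep=delimiter, na_rep="NA", index_label="gene_id"
            )
    elif isinstance(table, pd.DataFrame):
        table.to_csv(path, sep=delimiter, na_rep="NA", index=False)
    else:
        raise SpliceDiversityError(
            f"cannot serialize object of type {type(table).__name__}"
        )


def read_diversity_matrix(path, delimiter: str = "\t") -> DiversityMatrix:
    """Read a diversity matrix written by :func:`write_results_table`."""
    path = Path(path)
    metric, normalized = "naive", False
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first.lstrip("#").split():
                key, _, val = token.partition("=")
                if key == "metric":
                    metric = val
                elif key == "normalized":
                    normalized = val.lower() == "true"
            body = fh
        else:
            fh.seek(0)
            body = fh
        df = pd.read_csv(
            body,
            sep=delimiter,
            index_col=0,
            na_values=_NA_STRINGS,
            keep_default_na=False,
        )
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return DiversityMatrix(values=df, metric=metric, normalized=normalized)
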