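"""Readers and writers for the package's external table formats.

All formats are plain tab-separated text with a header row, no quoting and
"." decimals:

* expression TSV — first column ``gene``, remaining columns are sample ids;
* annotation TSV — columns ``gene``, ``chromosome``, ``cytoband``, ``tss_bp``;
* metadata TSV — columns ``sample_id``, ``participant_tag``, ``condition``
  followed by free attribute columns (anatomical site, smoking, ...);
* GMT — one gene set per line: ``set_id<TAB>description<TAB>member...``;
* result TSV — written by :func:`write_result_table` with light numeric
  formatting (p/q values below 1e-3 in scientific notation).

Also provides metadata-driven sample subsetting and participant-tag
pairing of normal with tumor samples.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ANNOTATION_COLUMNS,
    CONDITIONS,
    METADATA_COLUMNS,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
)
from .errors import EmptySelectionError, FormatError, MissingFeatureError

log = logging.getLogger(__name__)

GENE_COLUMN = "gene"

#: Smallest p-value the paper-style tables print; smaller values are shown
#: as "<1.11e-16" by :func:`write_result_table` (the numeric value is kept
#: exact in memory).
P_PRINT_FLOOR = 1.11e-16


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read a gene-by-sample expression TSV.

    The header row carries sample ids; the first column (``gene``) carries
    feature ids. Raises :class:`FormatError` naming the offender on
    duplicate ids and giving row/column coordinates on negative or
    non-numeric cells.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene row {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample column {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at gene "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    neg = (numeric.to_numpy() < 0)
    if neg.any():
        r, c = np.argwhere(neg)[0]
        raise FormatError(
            f"{path}: negative value at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    numeric.index.name = GENE_COLUMN
    return ExpressionMatrix(numeric)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix as a TSV that round-trips bit-exactly."""
    df = matrix.data.copy()
    df.index.name = GENE_COLUMN
    df.to_csv(path, sep="\t", float_format=None)


# ---------------------------------------------------------------------------
# annotations and metadata


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation TSV (gene, chromosome, cytoband, tss_bp)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chromosome": str, "cytoband": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: annotation table missing columns {missing}")
    if df["gene"].duplicated().any():
        dup = df["gene"][df["gene"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate gene annotation {dup!r}")
    df["tss_bp"] = pd.to_numeric(df["tss_bp"], errors="raise").astype(np.int64)
    if (df["tss_bp"] < 1).any():
        bad = df.loc[df["tss_bp"] < 1, "gene"].iloc[0]
        raise FormatError(f"{path}: non-positive TSS for gene {bad!r}")
    return df


def write_annotation_table(annotations: pd.DataFrame, path: str | Path) -> None:
    annotations.to_csv(path, sep="\t", index=False)


def read_metadata_table(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata TSV; validates uniqueness and condition labels."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: metadata missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate sample_id {dup!r}")
    bad = set(df["condition"]) - set(CONDITIONS)
    if bad:
        raise FormatError(f"{path}: unknown condition labels {sorted(bad)}")
    return df


def write_metadata_table(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file.

    One set per line: ``set_id<TAB>description<TAB>member1<TAB>member2...``.
    Duplicate members within a line collapse to one (set semantics). Lines
    with fewer than three fields raise :class:`FormatError` with the line
    number.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            set_id, name, *members = fields
            members = [m for m in members if m]
            sets.append(GeneSet(set_id, name, frozenset(members)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT; members sorted for reproducible output."""
    with open(path, "w") as fh:
        for set_id in collection:
            s = collection[set_id]
            fh.write("\t".join([s.set_id, s.name, *sorted(s.members)]) + "\n")


# ---------------------------------------------------------------------------
# result tables


def _format_value(col: str, value) -> str:
    if isinstance(value, (float, np.floating)):
        if np.isnan(value):
            return "NA"
        if col in ("p", "q"):
            if 0 < value < P_PRINT_FLOOR:
                return f"<{P_PRINT_FLOOR:.2e}"
            if value < 1e-3:
                return f"{value:.6e}"
            return f"{value:.6f}"
        if col in ("r", "es", "min_deficit", "null_mean", "null_sd", "mu", "chrom_float", "cv", "score"):
            return f"{value:.6f}"
        return repr(float(value))
    return str(value)


def write_result_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a result DataFrame as a formatted TSV.

    Correlation-like columns are printed with six decimals; ``p``/``q``
    switch to scientific notation below 1e-3 and values below the
    double-precision complement floor print as ``<1.11e-16``.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, rows.columns)) + "\n")
        for _, row in rows.iterrows():
            fh.write("\t".join(_format_value(c, row[c]) for c in rows.columns) + "\n")


def read_result_table(path: str | Path) -> pd.DataFrame:
    """Read a result TSV back; ``<floor`` p-values parse to the floor."""

    def _parse(v: str):
        if isinstance(v, str) and v.startswith("<"):
            return float(v[1:])
        return v

    df = pd.read_csv(path, sep="\t")
    for col in df.columns:
        if df[col].dtype == object:
            parsed = df[col].map(_parse)
            try:
                df[col] = pd.to_numeric(parsed)
            except (ValueError, TypeError):
                df[col] = parsed
    return df


# ---------------------------------------------------------------------------
# sample subsetting and pairing


def subset_samples(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    predicate: dict[str, str],
) -> ExpressionMatrix:
    """Restrict a matrix to samples whose metadata match ``predicate``.

    ``predicate`` maps metadata column names to required values; all
    constraints must hold (logical AND). Every matrix sample must be
    present in the metadata. Raises :class:`EmptySelectionError` if no
    sample matches.
    """
    meta = metadata.set_index("sample_id")
    missing = [s for s in matrix.sample_ids if s not in meta.index]
    if missing:
        raise MissingFeatureError(f"samples absent from metadata: {missing[:5]}")
    for col in predicate:
        if col not in metadata.columns:
            raise MissingFeatureError(f"metadata has no column {col!r}")
    keep = [
        s
        for s in matrix.sample_ids
        if all(meta.at[s, col] == val for col, val in predicate.items())
    ]
    if not keep:
        raise EmptySelectionError(f"zero samples matched predicate {predicate}")
    log.info("subset_samples: %d of %d samples retained", len(keep), matrix.n_samples)
    return matrix.subset_samples(keep)


def participant_tag_from_sample_id(
    sample_id: str, delimiter: str = "-", n_fields: int = 3
) -> str:
    """Prefix of a sample id up to the Nth delimiter (TCGA-barcode-like).

    ``TCGA-CV-7100-01A`` -> ``TCGA-CV-7100`` with the defaults.
    """
    return delimiter.join(sample_id.split(delimiter)[:n_fields])


def match_normal_tumor_pairs(
    metadata: pd.DataFrame,
) -> tuple[list[tuple[str, str]], list[str]]:
    """Pair normal with tumor samples sharing a participant tag.

    A pair is formed for every participant tag carrying exactly one normal
    sample and at least one tumor sample; when several tumor samples exist
    the first in file order is chosen. Returns ``(pairs, unmatched_normals)``
    where unmatched normals (no tumor, or ambiguous duplicate normals) are
    reported rather than silently dropped. Pairs plus unmatched normals
    always partition the normal samples.
    """
    pairs: list[tuple[str, str]] = []
    unmatched: list[str] = []
    by_tag: dict[str, dict[str, list[str]]] = {}
    for _, row in metadata.iterrows():
        tag = row["participant_tag"]
        by_tag.setdefault(tag, {"normal": [], "tumor": []})
        by_tag[tag][row["condition"]].append(row["sample_id"])
    for tag, groups in by_tag.items():
        normals, tumors = groups["normal"], groups["tumor"]
        if len(normals) == 1 and tumors:
            pairs.append((normals[0], tumors[0]))
        else:
            unmatched.extend(normals)
    log.info(
        "match_normal_tumor_pairs: %d pairs, %d unmatched normals",
        len(pairs),
        len(unmatched),
    )
    return pairs, unmatched
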