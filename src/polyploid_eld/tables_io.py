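"""Tabular input/output with strict validation.

All artifacts the pipeline touches are plain UTF-8 tab-separated files:

* count tables: one row per gene/miRNA, one integer count column per library
  (roles ``A`` = maternal parent, ``B`` = paternal parent, ``C`` =
  allopolyploid), an optional ``length`` column (bp) for RPKM;
* miRNA->gene predicted-target pairs: two columns, optional header;
* feature->term annotations (GO/KEGG/TF family): 2-4 columns.

Lines starting with ``#`` are treated as comments.  Readers are strict: a
malformed row raises :class:`~polyploid_eld.errors.FormatError` naming the
offending column/id/line rather than silently dropping data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError

ROLES = ("A", "B", "C")


@dataclass
class ExpressionTable:
    """Raw counts for one feature type across the three libraries.

    Parameters
    ----------
    counts
        Non-negative integer DataFrame indexed by unique feature id with
        columns exactly ``["A", "B", "C"]``.
    library_sizes
        Total reads per library.  Defaults to the column sums, i.e. the
        table is assumed to contain every mapped read.
    lengths
        Optional per-feature length in bp, required for RPKM.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series | None = None
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(ROLES):
            raise FormatError(
                f"count columns must be {list(ROLES)}, got {list(self.counts.columns)}"
            )
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate feature id: {dup!r}")
        if not all(np.issubdtype(d, np.integer) for d in self.counts.dtypes):
            raise FormatError("counts must be integers")
        if (self.counts.to_numpy() < 0).any():
            bad = self.counts.index[(self.counts < 0).any(axis=1)][0]
            raise FormatError(f"negative count for feature {bad!r}")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(np.int64)
        else:
            self.library_sizes = pd.Series(self.library_sizes, dtype=np.int64).reindex(ROLES)
            if self.library_sizes.isna().any():
                raise ConfigurationError("library_sizes must cover roles A, B, C")
        if (self.library_sizes <= 0).any():
            raise ConfigurationError("library sizes must be positive")
        if self.lengths is not None:
            self.lengths = pd.Series(self.lengths).reindex(self.counts.index)
            if self.lengths.isna().any():
                missing = self.counts.index[self.lengths.isna()][0]
                raise FormatError(f"length missing for feature {missing!r}")
            if (self.lengths <= 0).any():
                raise FormatError("feature lengths must be positive")

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    def __len__(self) -> int:
        return len(self.counts)

    def equals(self, other: "ExpressionTable") -> bool:
        same_len = (self.lengths is None) == (other.lengths is None) and (
            self.lengths is None or self.lengths.astype(np.int64).equals(
                other.lengths.astype(np.int64))
        )
        return (
            self.counts.equals(other.counts)
            and self.library_sizes.equals(other.library_sizes)
            and same_len
        )


def read_counts(
    path,
    role_map: Mapping[str, str] | None = None,
    library_sizes: Mapping[str, int] | None = None,
) -> ExpressionTable:
    """Read a count TSV into an :class:`ExpressionTable`.

    ``role_map`` maps file column names to roles ``A``/``B``/``C``; by default
    the columns are expected to already be named by role.  A ``length`` column,
    when present, is carried along for RPKM.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    df = df.set_index(df.columns[0])
    if role_map:
        inverse = {}
        for col, role in role_map.items():
            if role not in ROLES:
                raise FormatError(f"unknown role {role!r} for column {col!r}")
            inverse[col] = role
        df = df.rename(columns=inverse)
    for role in ROLES:
        if role not in df.columns:
            raise FormatError(f"{path}: missing count column for role {role!r}")
    lengths = None
    if "length" in df.columns:
        lengths = pd.to_numeric(df["length"], errors="coerce")
        if lengths.isna().any():
            bad = df.index[lengths.isna()][0]
            raise FormatError(f"{path}: non-numeric length for feature {bad!r}")
    raw = df[list(ROLES)]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.index[numeric.isna().any(axis=1)][0]
        raise FormatError(f"{path}: non-numeric count for feature {bad!r}")
    if ((numeric % 1) != 0).any().any():
        bad = numeric.index[((numeric % 1) != 0).any(axis=1)][0]
        raise FormatError(f"{path}: non-integer count for feature {bad!r}")
    if numeric.index.has_duplicates:
        dup = numeric.index[numeric.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    sizes = pd.Series(library_sizes, dtype=np.int64) if library_sizes else None
    return ExpressionTable(numeric.astype(np.int64), library_sizes=sizes, lengths=lengths)


def write_counts(table: ExpressionTable, path) -> None:
    """Write an ExpressionTable to TSV (inverse of :func:`read_counts`)."""
    out = table.counts.copy()
    if table.lengths is not None:
        out["length"] = table.lengths.astype(np.int64)
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_target_pairs(path) -> pd.DataFrame:
    """Read miRNA->gene predicted target pairs.

    Two tab-separated columns (mirna_id, gene_id); an optional header line
    containing the literal words ``mirna`` and ``gene`` is skipped.  Pairs are
    de-duplicated preserving first-occurrence order.
    """
    rows: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
            if lineno == 1 and "mirna" in fields[0].lower() and "gene" in fields[1].lower():
                continue
            rows.append((fields[0], fields[1]))
    df = pd.DataFrame(rows, columns=["mirna_id", "gene_id"])
    return df.drop_duplicates(ignore_index=True)


def write_target_pairs(pairs: pd.DataFrame, path) -> None:
    pairs[["mirna_id", "gene_id"]].to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    """Read a feature->term annotation table.

    Columns: feature_id, term_id, then optional term_name and namespace.
    Duplicate (feature_id, term_id) rows are collapsed to one.
    """
    names = ["feature_id", "term_id", "term_name", "namespace"]
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or len(fields) > 4:
                raise FormatError(f"{path}:{lineno}: expected 2-4 fields, got {len(fields)}")
            if lineno == 1 and fields[0].lower() in {"feature_id", "feature", "gene_id"}:
                continue
            rows.append(fields + [""] * (4 - len(fields)))
    df = pd.DataFrame(rows, columns=names)
    return df.drop_duplicates(subset=["feature_id", "term_id"], ignore_index=True)


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_slim_map(path) -> pd.DataFrame:
    """Read a term -> (namespace, level-2 slim term) mapping table.

    Columns: term_id, namespace, slim_term (tab-separated, optional header).
    """
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
            if lineno == 1 and fields[0].lower() in {"term_id", "term"}:
                continue
            rows.append(fields)
    df = pd.DataFrame(rows, columns=["term_id", "namespace", "slim_term"])
    return df.drop_duplicates(subset=["term_id"], ignore_index=True)


def read_library_sizes(path) -> dict[str, int]:
    """Two-column TSV ``role<TAB>size`` overriding column-sum library sizes.

    Needed whenever the count table does not contain every mapped read
    (subset tables, simulations with a nominal sequencing depth): column
    totals then mis-state the sampling fraction and bias every proportion
    test by the libraries' composition difference.
    """
    sizes: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields")
            if fields[0].lower() in {"role", "library"}:
                continue
            if fields[0] not in ROLES:
                raise FormatError(f"{path}:{lineno}: unknown role {fields[0]!r}")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_library_sizes(sizes, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("role\tsize\n")
        for role in ROLES:
            fh.write(f"{role}\t{int(sizes[role])}\n")


def read_feature_list(path) -> list[str]:
    """One feature id per line (used for study/population sets)."""
    with open(path, encoding="utf-8") as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
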