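"""Domain types and file I/O for expression matrices, metadata, intervals and gene sets.

The expression matrix is the universal currency of the pipeline: a features x
samples table of non-negative abundances (counts, peak amplitudes, miRNA
copies ...).  Everything downstream -- noise removal, normalisation, QC,
differential expression, network inference -- consumes and produces this type.

Genomic coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``.  Gene identifiers are opaque strings; no identifier
conversion is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MatrixIOError",
    "ExpressionMatrix",
    "MetadataTable",
    "GenomicInterval",
    "GeneSet",
    "GeneSetCollection",
    "InteractionTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_metadata",
    "write_metadata",
    "read_gmt",
    "write_gmt",
    "read_bed",
    "write_bed",
    "read_interactions",
    "write_interactions",
]

#: allowed processing states of an expression matrix, in pipeline order
STATES = ("raw", "denoised", "normalised")


class MatrixIOError(ValueError):
    """Raised on malformed input files or invariant violations."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen[x] = 1
    if dups:
        raise MatrixIOError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class ExpressionMatrix:
    """Features x samples abundance matrix with a processing-state flag.

    Parameters
    ----------
    data
        DataFrame with feature identifiers as the index and sample
        identifiers as columns.  All values must be finite and >= 0.
    state
        One of ``raw`` (as loaded), ``denoised`` (noise-filtered, still
        un-normalised) or ``normalised``.
    modality_tag
        Label of the assay the rows come from, e.g. ``mRNA``, ``ChIP``,
        ``miRNA``.  Used to colour nodes in integrated networks.
    feature_modalities
        Optional per-feature modality labels; set by trans-integration when
        rows of several modalities are concatenated.
    """

    data: pd.DataFrame
    state: str = "raw"
    modality_tag: str = "mRNA"
    feature_modalities: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def feature_modality(self, feature_id: str) -> str:
        if self.feature_modalities is not None:
            return str(self.feature_modalities.loc[feature_id])
        return self.modality_tag

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise MatrixIOError("data must be a pandas DataFrame")
        if self.state not in STATES:
            raise MatrixIOError(f"unknown state {self.state!r}; expected one of {STATES}")
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        _check_unique(self.data.index, "feature ids")
        _check_unique(self.data.columns, "sample ids")
        if self.data.shape[1] < 2:
            raise MatrixIOError("expression matrix needs at least 2 samples")
        vals = self.data.to_numpy(dtype=float)
        bad = ~np.isfinite(vals) | (vals < 0)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise MatrixIOError(
                "negative or non-finite value at feature "
                f"{self.data.index[r]!r}, sample {self.data.columns[c]!r}: {vals[r, c]!r}"
            )
        if self.feature_modalities is not None:
            if not self.feature_modalities.index.equals(self.data.index):
                raise MatrixIOError("feature_modalities index must match feature ids")

    def with_data(self, data: pd.DataFrame, state: str | None = None) -> "ExpressionMatrix":
        """Return a copy holding ``data`` (and optionally a new state)."""
        fm = None
        if self.feature_modalities is not None:
            fm = self.feature_modalities.reindex(data.index)
        return ExpressionMatrix(
            data=data,
            state=self.state if state is None else state,
            modality_tag=self.modality_tag,
            feature_modalities=fm,
        )


@dataclass
class MetadataTable:
    """Per-sample experimental factors (condition, timepoint, batch ...)."""

    table: pd.DataFrame  # index = sample ids, columns = factor names

    def __post_init__(self) -> None:
        if not isinstance(self.table, pd.DataFrame):
            raise MatrixIOError("metadata must be a pandas DataFrame")
        self.table.index = self.table.index.astype(str)
        _check_unique(self.table.index, "sample ids")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def factors(self) -> list[str]:
        return list(self.table.columns)

    def harmonise(self, matrix: ExpressionMatrix) -> "MetadataTable":
        """Reorder rows to the matrix's canonical column order.

        The matrix column order is authoritative; a sample-set mismatch in
        either direction is an error listing the symmetric difference.
        """
        mine, theirs = set(self.sample_ids), set(matrix.sample_ids)
        if mine != theirs:
            missing = sorted(theirs - mine)
            extra = sorted(mine - theirs)
            raise MatrixIOError(
                f"metadata/matrix sample mismatch: missing from metadata {missing}, "
                f"absent from matrix {extra}"
            )
        return MetadataTable(self.table.loc[matrix.sample_ids].copy())

    def levels(self, factor: str) -> list[str]:
        if factor not in self.table.columns:
            raise MatrixIOError(f"unknown metadata factor {factor!r}; have {self.factors}")
        return sorted(self.table[factor].astype(str).unique())

    def samples_for(self, factor: str, level: str) -> list[str]:
        if factor not in self.table.columns:
            raise MatrixIOError(f"unknown metadata factor {factor!r}; have {self.factors}")
        mask = self.table[factor].astype(str) == str(level)
        return list(self.table.index[mask])


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise MatrixIOError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "unknown"):
            raise MatrixIOError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    """Named gene sets (an offline stand-in for GO/KEGG/Reactome services)."""

    terms: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique([t.term_id for t in self.terms], "term ids")
        for t in self.terms:
            if not t.members:
                raise MatrixIOError(f"gene set {t.term_id!r} is empty")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)


@dataclass
class InteractionTable:
    """External regulator->target interactions (e.g. curated miRNA targets)."""

    table: pd.DataFrame  # columns: regulator, target, source

    REQUIRED = ("regulator", "target", "source")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise MatrixIOError(f"interaction table missing column {col!r}")
        sub = self.table[list(self.REQUIRED)]
        if sub.isna().any().any() or (sub.astype(str) == "").any().any():
            raise MatrixIOError("interaction table contains missing fields")
        self.table = sub.astype(str).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def rows(self) -> Iterable[tuple[str, str, str]]:
        return self.table.itertuples(index=False, name=None)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_SEPS = {"tsv": "\t", "csv": ","}


def _infer_fmt(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _SEPS:
            raise MatrixIOError(f"unknown format {fmt!r}; expected tsv or csv")
        return fmt
    return "csv" if path.suffix.lower() == ".csv" else "tsv"


def read_expression_matrix(
    path: str | Path,
    fmt: str | None = None,
    state: str = "raw",
    modality_tag: str = "mRNA",
) -> ExpressionMatrix:
    """Read a features x samples matrix (first column = feature ids)."""
    path = Path(path)
    if not path.exists():
        raise MatrixIOError(f"no such file: {path}")
    sep = _SEPS[_infer_fmt(path, fmt)]
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    try:
        df = df.astype(float)
    except ValueError as e:
        raise MatrixIOError(f"non-numeric value in {path}: {e}") from e
    return ExpressionMatrix(df, state=state, modality_tag=modality_tag)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path, fmt: str | None = None) -> None:
    """Write to TSV/CSV with >= 17 significant digits (lossless round-trip)."""
    path = Path(path)
    sep = _SEPS[_infer_fmt(path, fmt)]
    m.data.to_csv(path, sep=sep, float_format="%.17g", index_label="feature")


def read_metadata(path: str | Path) -> MetadataTable:
    """Read a sample metadata CSV/TSV (first column = sample ids)."""
    path = Path(path)
    if not path.exists():
        raise MatrixIOError(f"no such file: {path}")
    sep = _SEPS[_infer_fmt(path, None)]
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    return MetadataTable(df)


def write_metadata(meta: MetadataTable, path: str | Path) -> None:
    sep = _SEPS[_infer_fmt(Path(path), None)]
    meta.table.to_csv(path, sep=sep, index_label="sample")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``id<TAB>name<TAB>member...``."""
    terms = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise MatrixIOError(f"{path}:{lineno}: GMT line needs id, name and >= 1 member")
            members = frozenset(p for p in parts[2:] if p)
            if not members:
                raise MatrixIOError(f"{path}:{lineno}: gene set {parts[0]!r} has no members")
            terms.append(GeneSet(parts[0], parts[1], members))
    return GeneSetCollection(terms)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in sets:
            fh.write("\t".join([t.term_id, t.term_name, *sorted(t.members)]) + "\n")


def read_bed(path: str | Path) -> list[tuple[str, GenomicInterval]]:
    """Read BED (3-6 columns) as ``(name, interval)`` pairs, 0-based half-open.

    The optional 5th column (score) is ignored here; peak amplitudes travel in
    bedGraph coverage files instead.  Unnamed intervals get ``chrom:start-end``.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise MatrixIOError(f"{path}:{lineno}: BED line needs >= 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise MatrixIOError(f"{path}:{lineno}: non-integer coordinates") from e
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "unknown"
            try:
                iv = GenomicInterval(chrom, start, end, strand)
            except MatrixIOError as e:
                raise MatrixIOError(f"{path}:{lineno}: {e}") from e
            name = parts[3] if len(parts) >= 4 and parts[3] not in ("", ".") else f"{chrom}:{start}-{end}"
            out.append((name, iv))
    return out


def write_bed(entries: Iterable[tuple[str, GenomicInterval]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, iv in entries:
            strand = iv.strand if iv.strand in ("+", "-") else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{strand}\n")


def read_interactions(path: str | Path) -> InteractionTable:
    """Read a 3-column TSV of (regulator, target, source), with or without header."""
    path = Path(path)
    if not path.exists():
        raise MatrixIOError(f"no such file: {path}")
    first = open(path).readline().rstrip("\n").split("\t")
    header = [c.lower() for c in first[:3]] == ["regulator", "target", "source"]
    df = pd.read_csv(path, sep="\t", header=0 if header else None, dtype=str)
    if not header:
        if df.shape[1] < 3:
            raise MatrixIOError(f"{path}: interaction table needs 3 columns")
        df = df.iloc[:, :3]
        df.columns = ["regulator", "target", "source"]
    else:
        df.columns = [c.lower() for c in df.columns]
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 1 + (1 if header else 0)
        raise MatrixIOError(f"{path}:{bad}: missing field in interaction table")
    return InteractionTable(df)


def write_interactions(tbl: InteractionTable, path: str | Path) -> None:
    tbl.table.to_csv(path, sep="\t", index=False)
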