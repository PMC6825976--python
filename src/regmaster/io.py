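"""Readers and writers for the on-disk formats.

Expression matrices travel as TSV (first column = gene id, header row =
sample ids) or GCT 1.2; regulons as GMT with an optional trailing ``+``/``-``
mode suffix on each member token; clinical tables as TSV with ``sample_id``,
``time``, ``event`` and free covariate columns.  All text is UTF-8,
tab-separated, and round-trips bit-exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("regmaster")

__all__ = [
    "ExpressionMatrix",
    "SignedGeneSet",
    "read_expression",
    "write_expression",
    "read_gene_sets",
    "write_gene_sets",
    "read_clinical",
    "write_clinical",
]

#: If the 99th percentile of a freshly loaded matrix exceeds this, the data
#: are assumed to be on the natural scale and are log2(x+1)-transformed.
LOG_TRANSFORM_P99 = 50.0


@dataclass
class ExpressionMatrix:
    """Log2 gene-by-sample expression with optional group labels."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    sample_groups: list[str] | None = None
    log_transformed_on_load: bool = False
    n_dropped_rows: int = 0

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for label, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValueError(f"duplicate {label} ids: {sorted(dupes)}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.sample_groups is not None:
            self.sample_groups = list(self.sample_groups)
            if len(self.sample_groups) != len(self.sample_ids):
                raise ValueError("sample_groups length mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.sample_ids)

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(genes, self.sample_ids, self.values[rows],
                                sample_groups=self.sample_groups)

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene)]


@dataclass
class SignedGeneSet:
    """Named gene set with a per-member mode of action (+1/-1)."""

    name: str
    members: dict[str, int] = field(default_factory=dict)
    description: str = ""

    def __len__(self) -> int:
        return len(self.members)


def _duplicates(ids: list[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in ids:
        (dup if x in seen else seen).add(x)
    return dup


# ---------------------------------------------------------------------------
# expression


def read_expression(path: str | Path, fmt: str = "tsv") -> ExpressionMatrix:
    """Load a gene-by-sample matrix from TSV or GCT 1.2.

    Rows containing any missing value are dropped (and counted on the
    returned object).  Matrices that look like natural-scale intensities
    (99th percentile above ``LOG_TRANSFORM_P99``) are log2(x+1)-transformed
    and the transformation is flagged and logged.
    """
    path = Path(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif fmt == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise ValueError(f"unsupported GCT version line {version!r}")
            dims = fh.readline().split("\t")
            n_rows, n_cols = int(dims[0]), int(dims[1])
            df = pd.read_csv(fh, sep="\t", index_col=0)
        df = df.drop(columns=df.columns[0])  # Description column
        if df.shape != (n_rows, n_cols):
            raise ValueError(
                f"GCT header declares {n_rows}x{n_cols} but body is "
                f"{df.shape[0]}x{df.shape[1]}"
            )
    else:
        raise ValueError(f"unknown format {fmt!r}")

    for c, col in enumerate(df.columns):
        if pd.api.types.is_numeric_dtype(df[col]):
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            r = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"non-numeric value {df.iat[r, c]!r} at gene "
                f"{df.index[r]!r}, sample {col!r}"
            )
        df[col] = coerced
    dupes = _duplicates(list(df.index.astype(str)))
    if dupes:
        raise ValueError(f"duplicate gene ids: {sorted(dupes)}")

    n_before = len(df)
    df = df.dropna(axis=0, how="any")
    n_dropped = n_before - len(df)
    if n_dropped:
        log.info("dropped %d rows with missing values from %s", n_dropped, path)

    values = df.to_numpy(dtype=float)
    transformed = False
    if values.size and np.percentile(values, 99) > LOG_TRANSFORM_P99:
        values = np.log2(values + 1.0)
        transformed = True
        log.info("applied log2(x+1) transform to %s (p99 > %g)", path,
                 LOG_TRANSFORM_P99)
    return ExpressionMatrix(
        list(df.index.astype(str)), list(df.columns.astype(str)), values,
        log_transformed_on_load=transformed, n_dropped_rows=n_dropped,
    )


def write_expression(expr: ExpressionMatrix, path: str | Path,
                     fmt: str = "tsv") -> None:
    path = Path(path)
    df = expr.to_frame()
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index_label="gene_id")
    elif fmt == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
            out = df.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="NAME")
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# gene sets (signed GMT)


def read_gene_sets(path: str | Path) -> list[SignedGeneSet]:
    """Parse a GMT file; a trailing ``+``/``-`` on a member token is its mode.

    Unsigned members default to +1.  Empty sets are skipped with a warning.
    """
    sets: list[SignedGeneSet] = []
    n_skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            name, desc, tokens = parts[0], parts[1] if len(parts) > 1 else "", parts[2:]
            members: dict[str, int] = {}
            for tok in tokens:
                if not tok:
                    continue
                if tok.endswith("+"):
                    members[tok[:-1]] = 1
                elif tok.endswith("-"):
                    members[tok[:-1]] = -1
                else:
                    members[tok] = 1
            if not members:
                n_skipped += 1
                continue
            sets.append(SignedGeneSet(name, members, desc))
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} empty gene set(s) in {path}",
                      stacklevel=2)
        log.info("skipped %d empty gene sets in %s", n_skipped, path)
    return sets


def write_gene_sets(sets: list[SignedGeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            tokens = [f"{g}{'+' if m >= 0 else '-'}" for g, m in s.members.items()]
            fh.write("\t".join([s.name, s.description, *tokens]) + "\n")


# ---------------------------------------------------------------------------
# clinical tables


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Clinical TSV: sample_id, time, event, then covariate columns."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in clinical table")
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event must be 0/1")
    return df


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
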