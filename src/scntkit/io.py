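"""Domain containers and file I/O for the analysis pipeline.

All expression values are FPKM (fragments per kilobase of exon model per
million mapped reads).  Group-level statistics are computed on the FPKM
scale and log-transformed afterwards with :func:`log2p1`; see
:func:`group_mean` for the aggregation-order convention.

File dialects
-------------
* Expression matrices: TSV, header row of sample ids, first column header
  fixed to ``gene_id``, '.' decimal, UTF-8, no quoting.
* Sample sheets: CSV with columns ``sample_id,group,stage,embryo_type,replicate``.
* Gene sets: standard GMT (name, description, then one gene per field).
* Regulons: TSV with columns ``condition,tf,target[,weight]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "SampleSheet",
    "GeneSet",
    "GeneSetCollection",
    "RegulonSet",
    "read_expression",
    "write_expression",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gmt",
    "write_gmt",
    "read_regulons",
    "write_regulons",
    "log2p1",
    "group_mean",
]


class FormatError(ValueError):
    """An input file violates the documented dialect or an invariant."""


def log2p1(x):
    """log2(x + 1) for non-negative FPKM values (scalar or array).

    The +1 pseudocount keeps zeros at zero and is the transform every
    downstream statistic (rescue classification, fold changes, activation
    scores, correlations) operates on.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("log2p1 requires non-negative input (FPKM scale)")
    out = np.log2(arr + 1.0)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class ExpressionMatrix:
    """FPKM expression values, genes x samples.

    ``data`` is a pandas DataFrame indexed by gene id with sample-id
    columns; values must be finite and non-negative.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        if df.shape[0] == 0:
            raise FormatError("no genes in expression matrix")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric expression values")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite value at gene {df.index[bad[0]]!r}, "
                f"sample {df.columns[bad[1]]!r}"
            )
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative FPKM at gene {df.index[bad[0]]!r}, "
                f"sample {df.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.data.index]
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            warnings.warn(
                f"{len(missing)} gene(s) absent from matrix dropped: "
                f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
            )
        if not present:
            raise ValueError(f"no requested genes found in matrix; missing {missing}")
        return ExpressionMatrix(self.data.loc[present])

    def log_values(self) -> pd.DataFrame:
        """Per-cell log2(FPKM+1) values."""
        return pd.DataFrame(
            log2p1(self.data.to_numpy()), index=self.data.index, columns=self.data.columns
        )


@dataclass(frozen=True)
class SampleSheet:
    """Sample annotations: group, developmental stage, embryo type, replicate."""

    data: pd.DataFrame

    REQUIRED = ("sample_id", "group", "stage", "embryo_type", "replicate")

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        reps = df["replicate"]
        if (reps.astype(int) < 1).any():
            raise FormatError("replicate numbers must be positive integers")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def groups(self) -> list[str]:
        return list(pd.unique(self.data["group"]))

    def samples_in_group(self, group: str) -> list[str]:
        sel = self.data.loc[self.data["group"] == group, "sample_id"]
        return list(sel)

    def samples_in_stage(self, stage: str, embryo_type: str | None = None) -> list[str]:
        mask = self.data["stage"] == stage
        if embryo_type is not None:
            mask &= self.data["embryo_type"] == embryo_type
        return list(self.data.loc[mask, "sample_id"])


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise FormatError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass(frozen=True)
class GeneSetCollection:
    """Ordered collection of named gene sets (e.g. the three transcription
    pathways: basal TFs, RNA polymerase, spliceosome)."""

    sets: tuple[GeneSet, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dup = next(n for n in names if names.count(n) > 1)
            raise FormatError(f"duplicate gene set name: {dup!r}")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets:
            out.update(s.genes)
        return out


@dataclass(frozen=True)
class RegulonSet:
    """Condition-labelled TF -> target edges with non-negative weights.

    ``edges`` columns: condition, tf, target, weight.  Self-edges
    (tf == target) are permitted but flagged with a warning.
    """

    edges: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.edges
        required = ["condition", "tf", "target", "weight"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"regulon table missing columns: {missing}")
        dup = df.duplicated(subset=["condition", "tf", "target"])
        if dup.any():
            row = df.loc[dup].iloc[0]
            raise FormatError(
                f"duplicate regulon edge: ({row['condition']}, {row['tf']}, {row['target']})"
            )
        if (df["weight"].to_numpy() < 0).any():
            raise FormatError("negative regulon edge weight")
        self_edges = df["tf"] == df["target"]
        if self_edges.any():
            warnings.warn(
                f"{int(self_edges.sum())} self-edge(s) (tf == target) in regulon set"
            )

    def conditions(self) -> list[str]:
        return list(pd.unique(self.edges["condition"]))

    def for_condition(self, condition: str) -> pd.DataFrame:
        if condition not in set(self.edges["condition"]):
            raise ValueError(f"unknown regulon condition: {condition!r}")
        return self.edges.loc[self.edges["condition"] == condition]

    def tfs(self, condition: str) -> list[str]:
        return list(pd.unique(self.for_condition(condition)["tf"]))

    def __len__(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# Readers / writers


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples FPKM matrix from TSV.

    First column must be ``gene_id``; remaining header fields are sample ids.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected gene_id column plus >=1 sample column")
    if df.columns[0] != "gene_id":
        raise FormatError(f"{path}: first column header must be 'gene_id', got {df.columns[0]!r}")
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no genes")
    body = df.iloc[:, 1:].copy()
    for col in body.columns:
        coerced = pd.to_numeric(body[col], errors="coerce")
        bad = coerced.isna() & body[col].notna()
        if bad.any():
            row = df.loc[bad, "gene_id"].iloc[0]
            raise FormatError(f"{path}: non-numeric value at gene {row!r}, sample {col!r}")
        if coerced.isna().any():
            row = df.loc[coerced.isna(), "gene_id"].iloc[0]
            raise FormatError(f"{path}: missing value at gene {row!r}, sample {col!r}")
        body[col] = coerced
    body.index = pd.Index(df["gene_id"], name="gene_id")
    try:
        return ExpressionMatrix(body)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, dtype={"sample_id": str, "group": str, "stage": str,
                                  "embryo_type": str})
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.data.to_csv(path, index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets from a GMT file (name, description, members...)."""
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                warnings.warn(
                    f"{path}:{lineno}: {len(genes) - len(deduped)} duplicate member(s) "
                    f"removed from set {name!r}"
                )
            sets.append(GeneSet(name, desc, tuple(deduped)))
    return GeneSetCollection(tuple(sets))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def read_regulons(path: str | Path) -> RegulonSet:
    """Read TF->target edges from TSV (condition, tf, target[, weight]).

    A missing weight column defaults every edge weight to 1.0.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"condition": str, "tf": str, "target": str})
    required = ["condition", "tf", "target"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: regulon table missing columns {missing}")
    if "weight" not in df.columns:
        df["weight"] = 1.0
    df["weight"] = pd.to_numeric(df["weight"], errors="raise").astype(float)
    try:
        return RegulonSet(df[["condition", "tf", "target", "weight"]])
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_regulons(regulons: RegulonSet, path: str | Path) -> None:
    regulons.edges.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Elementary transforms


def group_mean(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    group: str,
    *,
    log_first: bool = False,
) -> pd.Series:
    """Per-gene mean FPKM over a group's samples.

    Aggregation happens on the FPKM scale; the log2(+1) transform is applied
    afterwards by callers that need it.  ``log_first=True`` instead averages
    log2(FPKM+1) values and back-transforms, for workflows that prefer
    post-log replicate aggregation.
    """
    samples = [s for s in sheet.samples_in_group(group) if s in expr.data.columns]
    if not samples:
        raise ValueError(f"group {group!r} has no samples in the expression matrix")
    sub = expr.data[samples]
    if log_first:
        arr = 2.0 ** log2p1(sub.to_numpy()).mean(axis=1) - 1.0
        return pd.Series(arr, index=sub.index, name=group)
    return sub.mean(axis=1).rename(group)
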