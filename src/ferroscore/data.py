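"""Core domain containers and plain-text I/O.

All matrices in this package are oriented features x samples: genes (or gene
sets) in rows, samples in columns.  Expression values are expected on a log2
scale unless the matrix is tagged as raw counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "InputError",
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "CohortAnnotations",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_annotations",
    "write_annotations",
    "align",
]


class InputError(ValueError):
    """Raised when an input file or object violates a contract."""


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


@dataclass
class ExpressionMatrix:
    """A genes x samples numeric expression matrix.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene symbols (rows).
    sample_ids : list of str
        Unique sample identifiers (columns).
    values : ndarray, shape (n_genes, n_samples)
        Finite numeric expression values.
    scale_tag : {"log2", "counts"}
        Declared scale of ``values``.  Callers must state the scale
        explicitly; nothing in the pipeline guesses it.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale_tag: str = "log2"

    def __post_init__(self) -> None:
        self.gene_ids = [str(g).strip() for g in self.gene_ids]
        self.sample_ids = [str(s).strip() for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.scale_tag not in ("log2", "counts"):
            raise InputError(f"unknown scale_tag {self.scale_tag!r}")
        if self.values.ndim != 2:
            raise InputError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise InputError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InputError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise InputError("duplicate sample ids")
        if self.values.size == 0:
            raise InputError("empty expression matrix")
        if not np.all(np.isfinite(self.values)):
            raise InputError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, scale_tag: str = "log2") -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float), scale_tag)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            list(self.gene_ids), list(sample_ids), self.values[:, idx], self.scale_tag
        )


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(str(m).strip() for m in self.members))
        if not self.members:
            raise InputError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """An ordered collection of uniquely named gene sets."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise InputError(f"duplicate gene set names: {dupes}")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(s.name == name for s in self.sets)

    def subset(self, names: list[str]) -> "GeneSetCollection":
        return GeneSetCollection([self[n] for n in names])


@dataclass
class CohortAnnotations:
    """Per-sample annotations: group label, survival time, censoring event.

    ``table`` is indexed by sample id and carries at least ``group``,
    ``time`` (days, > 0) and ``event`` (0 censored / 1 death); any further
    columns are treated as clinical covariates.
    """

    table: pd.DataFrame

    REQUIRED = ("group", "time", "event")

    def __post_init__(self) -> None:
        t = self.table
        if not t.index.is_unique:
            raise InputError("duplicate sample ids in annotations")
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise InputError(f"annotations missing required columns: {missing}")
        ev = t["event"].to_numpy()
        if not np.isin(ev[~pd.isna(ev)], (0, 1)).all():
            raise InputError("event must be 0 (censored) or 1 (death)")
        tm = t["time"].to_numpy(dtype=float)
        if np.any(tm[~np.isnan(tm)] <= 0):
            raise InputError("survival times must be > 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def n_samples(self) -> int:
        return len(self.table)

    @property
    def group(self) -> pd.Series:
        return self.table["group"]

    @property
    def time(self) -> np.ndarray:
        return self.table["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.table["event"].to_numpy(dtype=int)

    def covariates(self) -> pd.DataFrame:
        extra = [c for c in self.table.columns if c not in self.REQUIRED]
        return self.table[extra]

    def subset(self, sample_ids: list[str]) -> "CohortAnnotations":
        return CohortAnnotations(self.table.loc[list(sample_ids)].copy())


def read_expression(path: str | Path, scale_tag: str = "log2") -> ExpressionMatrix:
    """Read a delimited genes x samples table (first column = gene ids).

    Duplicate gene rows are collapsed by arithmetic mean (with a logged
    warning).  Non-numeric cells or missing values are rejected rather than
    imputed.
    """
    try:
        frame = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise InputError(f"cannot parse expression table {path}: {exc}") from exc
    if frame.empty:
        raise InputError(f"empty expression matrix in {path}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any() and not frame.isna().to_numpy().any():
        bad = frame.columns[numeric.isna().any(axis=0)].tolist()
        raise InputError(f"non-numeric expression cells in columns {bad} of {path}")
    if numeric.isna().to_numpy().any():
        raise InputError(f"missing expression values in {path}; imputation is not supported")
    numeric.index = numeric.index.astype(str).str.strip()
    if numeric.index.duplicated().any():
        n_dup = int(numeric.index.duplicated().sum())
        logger.warning("collapsing %d duplicate gene rows by mean in %s", n_dup, path)
        numeric = numeric.groupby(level=0, sort=False).mean()
    return ExpressionMatrix.from_frame(numeric, scale_tag=scale_tag)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep=_sep_for(path), index_label="gene_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a standard GMT file: name <tab> description <tab> member...

    Blank member fields are dropped; a line with fewer than three fields or a
    duplicated set name is an error naming the offending line.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, description = fields[0].strip(), fields[1].strip()
            members = [m.strip() for m in fields[2:] if m.strip()]
            if not members:
                raise InputError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in seen:
                raise InputError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            seen.add(name)
            sets.append(GeneSet(name, description, frozenset(members)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            members = "\t".join(sorted(s.members))
            fh.write(f"{s.name}\t{s.description}\t{members}\n")


def read_annotations(path: str | Path) -> CohortAnnotations:
    """Read a sample annotation table (required: sample_id, group, time, event)."""
    frame = pd.read_csv(path, sep=_sep_for(path))
    if "sample_id" not in frame.columns:
        raise InputError(f"annotations file {path} lacks a sample_id column")
    frame["sample_id"] = frame["sample_id"].astype(str).str.strip()
    frame = frame.set_index("sample_id")
    return CohortAnnotations(frame)


def write_annotations(ann: CohortAnnotations, path: str | Path) -> None:
    ann.table.to_csv(path, sep=_sep_for(path), index_label="sample_id")


def align(
    expr: ExpressionMatrix, ann: CohortAnnotations
) -> tuple[ExpressionMatrix, CohortAnnotations]:
    """Restrict both objects to their shared samples, in expression order."""
    shared = [s for s in expr.sample_ids if s in set(ann.sample_ids)]
    if not shared:
        raise InputError("expression and annotations share no samples")
    dropped = (expr.n_samples - len(shared)) + (ann.n_samples - len(shared))
    if dropped:
        logger.info("align: dropped %d unshared samples", dropped)
    if shared == expr.sample_ids and shared == ann.sample_ids:
        return expr, ann
    return expr.subset_samples(shared), ann.subset(shared)
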