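"""Readers/writers for the delimited formats the tool touches, plus the pathway mask.

Expression matrices are delimited text (TSV by default, comma accepted) with
samples in rows and genes in columns; a flag accepts the transposed layout.
Survival tables are three columns (id, time, event). Pathway collections are
standard GMT: one pathway per line, tab-separated name, description, members.

Values are assumed already log-normalized; ``read_expression`` can optionally
apply log2(x+1) for raw counts, default off.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("pathsurv")


class DataError(ValueError):
    """Raised for malformed input files or inconsistent datasets."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ExpressionMatrix:
    """n x p matrix of log-normalized expression with sample/gene identifiers."""

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray  # (n, p) float64

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n, p = self.values.shape
        if n < 2:
            raise DataError(f"expression matrix needs at least 2 samples, got {n}")
        if p < 1:
            raise DataError("expression matrix needs at least 1 gene")
        if len(self.sample_ids) != n or len(self.gene_ids) != p:
            raise DataError("id lists do not match matrix shape")
        if len(set(self.sample_ids)) != n:
            raise DataError("duplicate sample ids")
        if len(set(self.gene_ids)) != p:
            raise DataError("duplicate gene ids")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise DataError(
                f"non-finite expression value at sample {self.sample_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.gene_ids.index(g) for g in gene_ids]
        return ExpressionMatrix(list(self.sample_ids), list(gene_ids), self.values[:, idx])


@dataclasses.dataclass
class SurvivalOutcome:
    """Right-censored outcomes: follow-up time and event indicator per sample."""

    sample_ids: list[str]
    time: np.ndarray  # (n,) float64, >= 0
    event: np.ndarray  # (n,) int, in {0, 1}

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=np.float64)
        self.event = np.asarray(self.event)
        if len(self.sample_ids) != len(self.time) or len(self.time) != len(self.event):
            raise DataError("survival columns have inconsistent lengths")
        if np.any(self.time < 0) or not np.all(np.isfinite(self.time)):
            bad = self.sample_ids[int(np.argmax((self.time < 0) | ~np.isfinite(self.time)))]
            raise DataError(f"negative or non-finite survival time for sample {bad!r}")
        if not np.all(np.isin(self.event, [0, 1])):
            bad = self.sample_ids[int(np.argmax(~np.isin(self.event, [0, 1])))]
            raise DataError(f"event indicator outside {{0,1}} for sample {bad!r}")
        self.event = self.event.astype(np.int64)

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx: np.ndarray) -> "SurvivalOutcome":
        ids = [self.sample_ids[i] for i in np.atleast_1d(idx)]
        return SurvivalOutcome(ids, self.time[idx], self.event[idx])


@dataclasses.dataclass
class CohortDataset:
    """Expression and survival for one cohort, in identical sample order."""

    expression: ExpressionMatrix
    survival: SurvivalOutcome

    def __post_init__(self) -> None:
        if self.expression.sample_ids != self.survival.sample_ids:
            raise DataError("expression and survival sample orders differ")

    @property
    def n_samples(self) -> int:
        return self.expression.n_samples

    def subset(self, idx: np.ndarray) -> "CohortDataset":
        idx = np.atleast_1d(idx)
        expr = ExpressionMatrix(
            [self.expression.sample_ids[i] for i in idx],
            list(self.expression.gene_ids),
            self.expression.values[idx],
        )
        return CohortDataset(expr, self.survival.subset(idx))


@dataclasses.dataclass
class PathwayCollection:
    """Named gene sets, in file order."""

    pathway_names: list[str]
    members: list[list[str]]

    def __post_init__(self) -> None:
        if len(self.pathway_names) < 1:
            raise DataError("need at least one pathway")
        if len(self.pathway_names) != len(self.members):
            raise DataError("pathway names and member lists differ in length")

    @property
    def n_pathways(self) -> int:
        return len(self.pathway_names)


@dataclasses.dataclass
class PathwayMask:
    """Binary q x p biadjacency matrix gating the sparse first layer.

    Row i has a 1 in column j iff gene j belongs to pathway i.  Every retained
    gene has at least one nonzero entry in its column.
    """

    matrix: np.ndarray  # (q, p) of {0,1}
    pathway_names: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        q, p = self.matrix.shape
        if len(self.pathway_names) != q or len(self.gene_ids) != p:
            raise DataError("mask labels do not match matrix shape")
        if not np.all(np.isin(self.matrix, [0.0, 1.0])):
            raise DataError("mask entries must be binary")

    @property
    def n_pathways(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        head = fh.readline()
    return "," if head.count(",") > head.count("\t") else "\t"


def read_expression(
    path: str | Path,
    orientation: str = "genes-in-columns",
    log2_transform: bool = False,
) -> ExpressionMatrix:
    """Load a delimited expression table.

    Parameters
    ----------
    path
        Delimited text with a header row and an id first column.
    orientation
        ``"genes-in-columns"`` (default: rows are samples) or
        ``"genes-in-rows"`` (transposed layout).
    log2_transform
        Apply log2(x+1); off by default since inputs are assumed already
        log-normalized.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        dup = next(h for h in header if header.count(h) > 1)
        raise DataError(f"{path}: duplicate column id {dup!r}")
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if orientation == "genes-in-rows":
        df = df.T
    elif orientation != "genes-in-columns":
        raise DataError(f"unknown orientation {orientation!r}")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise DataError(f"{path}: empty expression table")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = df.index[df[col].isna()][0]
        raise DataError(f"{path}: missing value at row {row!r}, column {col!r}")
    try:
        values = df.to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        bad = df.map(lambda v: isinstance(v, str))
        col = df.columns[bad.any()][0]
        row = df.index[bad[col]][0]
        raise DataError(f"{path}: non-numeric value at row {row!r}, column {col!r}") from exc
    if log2_transform:
        values = np.log2(values + 1.0)
    return ExpressionMatrix([str(s) for s in df.index], [str(g) for g in df.columns], values)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(expr.values, index=expr.sample_ids, columns=expr.gene_ids)
    df.to_csv(path, sep="\t", index_label="sample", float_format="%.17g")


def read_survival(path: str | Path) -> SurvivalOutcome:
    """Load a 3-column (id, time, event) delimited table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    if df.shape[0] == 0:
        raise DataError(f"{path}: no records")
    if df.shape[1] < 3:
        raise DataError(f"{path}: expected 3 columns (id, time, event), got {df.shape[1]}")
    ids = [str(s) for s in df.iloc[:, 0]]
    time = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy()
    event = pd.to_numeric(df.iloc[:, 2], errors="coerce").to_numpy()
    if np.any(np.isnan(time)) or np.any(np.isnan(event)):
        bad = ids[int(np.argmax(np.isnan(time) | np.isnan(event)))]
        raise DataError(f"{path}: non-numeric time/event for sample {bad!r}")
    return SurvivalOutcome(ids, time, event)


def write_survival(surv: SurvivalOutcome, path: str | Path) -> None:
    pd.DataFrame(
        {"sample": surv.sample_ids, "time": surv.time, "event": surv.event}
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gmt(path: str | Path) -> PathwayCollection:
    """Parse a GMT gene-set file, preserving file order."""
    path = Path(path)
    names: list[str] = []
    members: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(
                    f"{path}: line {lineno}: GMT needs >=3 tab-separated fields "
                    f"(name, description, members), got {len(fields)}"
                )
            names.append(fields[0])
            members.append([g for g in fields[2:] if g])
    if not names:
        raise DataError(f"{path}: no pathways found")
    return PathwayCollection(names, members)


def write_gmt(pathways: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in zip(pathways.pathway_names, pathways.members):
            fh.write("\t".join([name, "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# pathway mask
# ---------------------------------------------------------------------------

def build_pathway_mask(
    pathways: PathwayCollection,
    gene_ids: Sequence[str],
    unmapped_policy: str = "drop",
) -> PathwayMask:
    """Build the binary pathway x gene biadjacency matrix.

    Gene identifiers are matched exactly (case-sensitive).  Genes belonging to
    no retained pathway are dropped from the model input by default
    (``unmapped_policy="drop"``), since wiring them to every pathway node would
    defeat the sparsity the mask encodes; ``"catch-all"`` instead appends one
    pseudo-pathway row collecting them.  Pathways with no matching genes are
    removed.  The number of dropped genes is logged.
    """
    gene_ids = [str(g) for g in gene_ids]
    gene_index = {g: j for j, g in enumerate(gene_ids)}
    rows = []
    names = []
    for name, mem in zip(pathways.pathway_names, pathways.members):
        row = np.zeros(len(gene_ids))
        hits = [gene_index[g] for g in set(mem) if g in gene_index]
        if not hits:
            continue
        row[hits] = 1.0
        rows.append(row)
        names.append(name)
    if not rows:
        raise DataError("no gene-pathway overlap: mask would be all-zero")
    matrix = np.vstack(rows)
    mapped = matrix.sum(axis=0) > 0
    n_dropped = int((~mapped).sum())
    if unmapped_policy == "drop":
        if n_dropped:
            logger.info("dropping %d/%d genes in no retained pathway", n_dropped, len(gene_ids))
        kept = [g for g, m in zip(gene_ids, mapped) if m]
        matrix = matrix[:, mapped]
    elif unmapped_policy == "catch-all":
        if n_dropped:
            extra = np.zeros(len(gene_ids))
            extra[~mapped] = 1.0
            matrix = np.vstack([matrix, extra])
            names = names + ["UNMAPPED"]
            logger.info("catch-all pseudo-pathway for %d unmapped genes", n_dropped)
        kept = gene_ids
    else:
        raise DataError(f"unknown unmapped_policy {unmapped_policy!r}")
    return PathwayMask(matrix, names, list(kept))
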