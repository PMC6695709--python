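"""Reading and writing docking-score matrices and result tables.

The on-disk format for a score matrix is delimited text (CSV or TSV,
UTF-8, ``.`` decimal separator) with a mandatory header row::

    compound_id,label,<structure_id_1>,...,<structure_id_k>

``label`` is 1 for actives and 0 for inactives/decoys.  Score columns
hold raw docking scores where lower (more negative) means better
predicted binding.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ScoreMatrix",
    "RunConfig",
    "read_score_matrix",
    "write_score_matrix",
    "write_table",
    "load_config",
]


@dataclasses.dataclass(frozen=True)
class ScoreMatrix:
    """Compounds x protein-structures matrix of raw docking scores.

    Attributes
    ----------
    compound_ids : list of str
        Unique compound identifiers, one per row.
    labels : ndarray of int
        Binary activity labels (1 = active, 0 = inactive/decoy).
    structure_ids : list of str
        Unique protein-structure identifiers, one per column.
    scores : ndarray of float, shape (n_compounds, n_structures)
        Raw docking scores; lower = better.
    """

    compound_ids: list[str]
    labels: np.ndarray
    structure_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        n, k = self.scores.shape
        if len(self.compound_ids) != n or len(self.labels) != n:
            raise ValueError(
                f"row mismatch: {n} score rows, {len(self.compound_ids)} ids, "
                f"{len(self.labels)} labels"
            )
        if len(self.structure_ids) != k:
            raise ValueError(
                f"column mismatch: {k} score columns, "
                f"{len(self.structure_ids)} structure ids"
            )
        if k < 2:
            raise ValueError("a score matrix needs at least 2 structures")
        if len(set(self.compound_ids)) != n:
            seen: set[str] = set()
            dup = next(c for c in self.compound_ids if c in seen or seen.add(c))
            raise ValueError(f"duplicate compound_id {dup!r}")
        if len(set(self.structure_ids)) != k:
            raise ValueError("structure_ids must be unique")
        if not np.isin(self.labels, (0, 1)).all():
            bad = self.labels[~np.isin(self.labels, (0, 1))][0]
            raise ValueError(f"labels must be 0/1, found {bad}")
        if self.n_active == 0 or self.n_inactive == 0:
            raise ValueError("need at least 1 active and 1 inactive compound")
        if not np.isfinite(self.scores).all():
            i, j = np.argwhere(~np.isfinite(self.scores))[0]
            raise ValueError(
                f"non-finite score for compound {self.compound_ids[i]!r}, "
                f"structure {self.structure_ids[j]!r}"
            )

    @property
    def n_compounds(self) -> int:
        return self.scores.shape[0]

    @property
    def n_structures(self) -> int:
        return self.scores.shape[1]

    @property
    def n_active(self) -> int:
        return int(self.labels.sum())

    @property
    def n_inactive(self) -> int:
        return int((1 - self.labels).sum())

    def to_frame(self) -> pd.DataFrame:
        """Return the matrix as a DataFrame in the on-disk column layout."""
        df = pd.DataFrame(self.scores, columns=self.structure_ids)
        df.insert(0, "label", self.labels)
        df.insert(0, "compound_id", self.compound_ids)
        return df


@dataclasses.dataclass
class RunConfig:
    """Run-level configuration shared by the CLI subcommands."""

    seed: int = 42
    folds: int = 7
    alpha: float = 20.0
    null_mode: str = "auto"  # exact | monte_carlo | auto
    null_samples: int = 100_000

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(mapping) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**mapping)


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML (or flat key: value) file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return RunConfig.from_mapping(data)


def _sniff_sep(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        return {"csv": ",", "tsv": "\t"}.get(dialect, dialect)
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_score_matrix(path: str | Path, dialect: str | None = None) -> ScoreMatrix:
    """Read a docking-score matrix from delimited text.

    Parameters
    ----------
    path : path
        CSV/TSV file with header ``compound_id,label,<structure>...``.
    dialect : str, optional
        ``"csv"``, ``"tsv"``, or an explicit delimiter; inferred from
        the file suffix when omitted.

    Raises
    ------
    ValueError
        On duplicate compound ids, non-numeric score cells, labels
        outside {0, 1}, or an all-active / all-inactive label column.
    """
    path = Path(path)
    sep = _sniff_sep(path, dialect)
    df = pd.read_csv(path, sep=sep, dtype={0: str}, encoding="utf-8")
    if df.shape[1] < 4:
        raise ValueError(
            f"{path}: expected compound_id, label and >= 2 structure columns, "
            f"got columns {list(df.columns)}"
        )
    id_col, label_col = df.columns[0], df.columns[1]

    dup_mask = df[id_col].duplicated()
    if dup_mask.any():
        raise ValueError(
            f"{path}: duplicate compound_id {df.loc[dup_mask.idxmax(), id_col]!r}"
        )

    labels = pd.to_numeric(df[label_col], errors="coerce")
    bad = labels.isna() | ~labels.isin([0, 1])
    if bad.any():
        row = int(bad.idxmax())
        raise ValueError(
            f"{path}: row {row + 2}: label {df.loc[row, label_col]!r} "
            "does not parse to 0/1"
        )

    struct_cols = list(df.columns[2:])
    scores = np.empty((len(df), len(struct_cols)))
    for j, col in enumerate(struct_cols):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise ValueError(
                f"{path}: row {row + 2}, column {col!r}: "
                f"non-numeric score {df.loc[row, col]!r}"
            )
        scores[:, j] = vals.to_numpy()

    return ScoreMatrix(
        compound_ids=df[id_col].tolist(),
        labels=labels.to_numpy(dtype=int),
        structure_ids=[str(c) for c in struct_cols],
        scores=scores,
    )


def write_score_matrix(m: ScoreMatrix, path: str | Path, dialect: str | None = None) -> None:
    """Write a score matrix in the canonical on-disk layout."""
    path = Path(path)
    m.to_frame().to_csv(path, sep=_sniff_sep(path, dialect), index=False)


def write_table(rows: Sequence[dict] | pd.DataFrame, path: str | Path) -> None:
    """Write records as delimited text with a deterministic column order.

    Column order follows the first record (or the DataFrame); reading
    the file back reproduces the values exactly as formatted.  An empty
    record list yields a header-only file when columns are known,
    otherwise an empty file.
    """
    path = Path(path)
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(list(rows))
    df.to_csv(path, sep=_sniff_sep(path, None), index=False)
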