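"""Data-fusion rules for ensemble-docking consensus scoring.

Each compound docked against *n* protein structures yields per-structure
docking scores DS_1 ... DS_n (lower = better).  A fusion rule collapses
them into one consensus score per compound:

========  =======================================================
MIN       min(DS_1, ..., DS_n)
MAX       max(DS_1, ..., DS_n)
SUM       arithmetic mean
GEOM      geometric mean, computed on magnitudes with sign restored
HARM      harmonic mean, computed on magnitudes with sign restored
MED       median
EUC       Euclidean norm sqrt(sum DS_i^2), negated so lower = better
========  =======================================================

All rules are canonicalized to the *lower = better* orientation of the
raw scores.  For the all-negative docking scores this package targets,
a larger Euclidean norm means more-negative (better) scores, so the EUC
column is negated; GEOM and HARM are evaluated on magnitudes and the
common sign restored, since their textbook forms are undefined or
sign-ambiguous for negative inputs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import ScoreMatrix

__all__ = ["RULES", "FusedTable", "fuse_row", "fuse_matrix"]

#: The seven supported fusion rules, in canonical order.
RULES = ("MIN", "MAX", "SUM", "GEOM", "HARM", "MED", "EUC")

# Orientation of each canonical fused column: after canonicalization every
# rule is lower_better (EUC's raw norm is higher_better and gets negated).
ORIENTATION = {rule: "lower_better" for rule in RULES}


@dataclasses.dataclass(frozen=True)
class FusedTable:
    """Per-compound consensus scores, one column per fusion rule.

    ``values[i, r]`` is the canonical (lower = better) consensus score
    of compound *i* under rule ``rules[r]``.
    """

    compound_ids: list[str]
    rules: tuple[str, ...]
    values: np.ndarray
    orientation: dict[str, str]

    def column(self, rule: str) -> np.ndarray:
        return self.values[:, self.rules.index(rule)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.rules))
        df.insert(0, "compound_id", self.compound_ids)
        return df


def _validate_row(scores: np.ndarray, rule: str) -> None:
    if rule not in RULES:
        raise ValueError(f"unknown fusion rule {rule!r}; choose from {RULES}")
    if scores.ndim != 1 or scores.size < 2:
        raise ValueError("fusion needs a vector of at least 2 scores")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if rule in ("GEOM", "HARM"):
        if (scores == 0).any():
            raise ValueError(f"{rule} undefined for zero scores")
        if not ((scores > 0).all() or (scores < 0).all()):
            raise ValueError(f"{rule} undefined for mixed-sign scores")
    if rule == "EUC" and (scores >= 0).any():
        raise ValueError(
            "EUC canonicalization requires all-negative scores "
            "(lower = better convention)"
        )


def fuse_row(scores, rule: str) -> float:
    """Fuse one compound's per-structure scores with a single rule.

    Parameters
    ----------
    scores : array-like of float, length >= 2
        Per-structure docking scores of one compound (lower = better).
    rule : str
        One of :data:`RULES`.

    Returns
    -------
    float
        The canonical (lower = better) consensus score.
    """
    scores = np.asarray(scores, dtype=float)
    _validate_row(scores, rule)
    if rule == "MIN":
        return float(scores.min())
    if rule == "MAX":
        return float(scores.max())
    if rule == "SUM":
        return float(scores.mean())
    if rule == "MED":
        return float(np.median(scores))
    if rule == "GEOM":
        sign = 1.0 if scores[0] > 0 else -1.0
        return float(sign * np.exp(np.mean(np.log(np.abs(scores)))))
    if rule == "HARM":
        sign = 1.0 if scores[0] > 0 else -1.0
        return float(sign * scores.size / np.sum(1.0 / np.abs(scores)))
    # EUC: all-negative input guaranteed; negate the norm so lower = better
    return float(-np.sqrt(np.sum(scores**2)))


def fuse_matrix(m: ScoreMatrix, rules=RULES) -> FusedTable:
    """Apply fusion rules column-wise to a whole score matrix.

    Vectorized equivalent of calling :func:`fuse_row` per compound;
    compound order is preserved.
    """
    rules = tuple(rules)
    if not rules:
        raise ValueError("rules must be a nonempty subset of RULES")
    for rule in rules:
        if rule not in RULES:
            raise ValueError(f"unknown fusion rule {rule!r}; choose from {RULES}")

    s = m.scores
    needs_neg = {r for r in rules if r in ("GEOM", "HARM", "EUC")}
    if needs_neg and (s >= 0).any():
        i = int(np.argwhere((s >= 0).any(axis=1))[0, 0])
        raise ValueError(
            f"compound {m.compound_ids[i]!r}: rules {sorted(needs_neg)} require "
            "all-negative docking scores"
        )

    cols = {}
    for rule in rules:
        if rule == "MIN":
            cols[rule] = s.min(axis=1)
        elif rule == "MAX":
            cols[rule] = s.max(axis=1)
        elif rule == "SUM":
            cols[rule] = s.mean(axis=1)
        elif rule == "MED":
            cols[rule] = np.median(s, axis=1)
        elif rule == "GEOM":
            cols[rule] = -np.exp(np.mean(np.log(np.abs(s)), axis=1))
        elif rule == "HARM":
            cols[rule] = -s.shape[1] / np.sum(1.0 / np.abs(s), axis=1)
        else:  # EUC
            cols[rule] = -np.sqrt(np.sum(s**2, axis=1))

    values = np.column_stack([cols[r] for r in rules])
    return FusedTable(
        compound_ids=list(m.compound_ids),
        rules=rules,
        values=values,
        orientation={r: ORIENTATION[r] for r in rules},
    )
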