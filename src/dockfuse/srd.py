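"""Sum of ranking differences (SRD) with a random-ranking null.

SRD compares ranking methods (here: data-fusion rules and, optionally,
single-structure docking scores) against an ideal reference ranking.
Every column is rank transformed (rank 1 = best, average ranks on
ties) and the SRD of a method is the Manhattan distance between its
rank vector and the reference's, normalized to 0-100 by the maximum
attainable distance.  Smaller is better.

The reference is built with the *minimax* rule: the per-structure
scores are rank transformed column-wise, and the reference value of an
active compound is the minimum (best) of its per-structure ranks while
an inactive gets the maximum (worst) — the hypothetical ideal consensus
that scores every active as well as possible and every inactive as
badly as possible.

Two validation devices accompany the SRD values:

* a **randomization test** (CRRN): the distribution of SRD for a
  uniformly random permutation, computed exactly (enumeration for
  n <= 8, dynamic programming for n <= 12) or by seeded Monte Carlo;
  a method is better than random when its SRD falls below a low
  percentile (conventionally the 5th) of this null;
* **k-fold cross-validation** (default sevenfold): compounds are split
  into stratified random folds and the whole analysis (reference
  included) is recomputed on each leave-one-fold-out subset, giving a
  per-fold SRD distribution per method.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np
from scipy.stats import rankdata

from .fusion import FusedTable
from .io import ScoreMatrix

__all__ = [
    "ReferenceVector",
    "SRDNull",
    "SRDResult",
    "rank_transform",
    "build_reference",
    "srd_value",
    "srd_max",
    "null_distribution",
    "srd_analysis",
]

# full enumeration bound and DP bound for the exact null
_ENUM_MAX_N = 8
_EXACT_MAX_N = 12


def rank_transform(values, direction: str = "lower_better") -> np.ndarray:
    """Rank a vector so that the best value gets rank 1.

    Ties receive average (fractional) ranks, so the ranks always sum to
    n(n+1)/2.  ``direction`` declares which end is best.
    """
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    if direction == "lower_better":
        return rankdata(values, method="average")
    if direction == "higher_better":
        return rankdata(-values, method="average")
    raise ValueError(f"unknown direction {direction!r}")


@dataclasses.dataclass(frozen=True)
class ReferenceVector:
    """Ideal consensus ranking built from rank-transformed score columns."""

    values: np.ndarray
    construction: str = "minimax"


def build_reference(m: ScoreMatrix) -> ReferenceVector:
    """Minimax reference: best per-structure rank for actives, worst for inactives."""
    col_ranks = np.column_stack(
        [rank_transform(m.scores[:, j]) for j in range(m.n_structures)]
    )
    ref = np.where(
        m.labels == 1, col_ranks.min(axis=1), col_ranks.max(axis=1)
    )
    return ReferenceVector(values=ref)


def srd_value(method, ref) -> float:
    """Raw SRD: Manhattan distance between the two rank-transformed vectors."""
    method = np.asarray(method, dtype=float)
    ref_vals = ref.values if isinstance(ref, ReferenceVector) else np.asarray(ref, dtype=float)
    if method.shape != ref_vals.shape:
        raise ValueError(
            f"length mismatch: method {method.shape} vs reference {ref_vals.shape}"
        )
    return float(np.abs(rank_transform(method) - rank_transform(ref_vals)).sum())


def srd_max(n: int) -> int:
    """Maximum Manhattan distance between a permutation of 1..n and its reverse."""
    if n < 2:
        raise ValueError("srd_max needs n >= 2")
    return n * n // 2 if n % 2 == 0 else (n * n - 1) // 2


@dataclasses.dataclass(frozen=True)
class SRDNull:
    """Distribution of SRD between a random permutation and a fixed reference."""

    n: int
    values: np.ndarray  # achievable SRD values, ascending
    probs: np.ndarray   # matching probabilities, sum to 1
    mode: str           # "exact" or "monte_carlo"

    def as_dict(self) -> dict[float, float]:
        return {float(v): float(p) for v, p in zip(self.values, self.probs)}

    def cdf(self) -> np.ndarray:
        """Cumulative probabilities aligned with :attr:`values`."""
        return np.cumsum(self.probs)

    def percentile(self, q: float) -> float:
        """Smallest SRD value whose cumulative probability reaches q percent."""
        idx = int(np.searchsorted(self.cdf(), q / 100.0))
        idx = min(idx, len(self.values) - 1)
        return float(self.values[idx])

    def percentile_norm(self, q: float) -> float:
        """Same percentile on the 0-100 normalized scale."""
        return 100.0 * self.percentile(q) / srd_max(self.n)

    @property
    def mean(self) -> float:
        return float(np.sum(self.values * self.probs))


def _null_enumeration(n: int) -> tuple[np.ndarray, np.ndarray]:
    ref = np.arange(1, n + 1)
    counts: dict[int, int] = {}
    for perm in itertools.permutations(range(1, n + 1)):
        d = int(np.abs(np.asarray(perm) - ref).sum())
        counts[d] = counts.get(d, 0) + 1
    values = np.array(sorted(counts))
    probs = np.array([counts[v] for v in values], dtype=float) / math.factorial(n)
    return values, probs


def _null_dp(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of sum |pi(i) - i| via bitmask dynamic programming.

    State: the set of already-used ranks; the position being filled is the
    popcount of the mask.  Counts are exact integers.
    """
    dmax = srd_max(n)
    size = 1 << n
    # table[mask] = integer count array over distance
    table: list[np.ndarray | None] = [None] * size
    table[0] = np.zeros(dmax + 1, dtype=object)
    table[0][0] = 1
    order = sorted(range(size), key=lambda m: m.bit_count())
    for mask in order:
        cur = table[mask]
        if cur is None:
            continue
        i = mask.bit_count()  # next position (0-based)
        if i == n:
            continue
        nz = np.nonzero(cur)[0]
        for v in range(n):
            if mask & (1 << v):
                continue
            step = abs(v - i)
            nxt = mask | (1 << v)
            if table[nxt] is None:
                table[nxt] = np.zeros(dmax + 1, dtype=object)
            table[nxt][nz + step] += cur[nz]
        table[mask] = None  # free memory
    final = table[size - 1]
    values = np.nonzero(final)[0]
    total = math.factorial(n)
    probs = np.array([int(final[v]) / total for v in values], dtype=float)
    return values.astype(float), probs


def null_distribution(
    n: int,
    mode: str = "auto",
    n_samples: int = 100_000,
    seed: int = 0,
) -> SRDNull:
    """Distribution of SRD values of a uniformly random ranking.

    Parameters
    ----------
    n : int
        Number of ranked objects (compounds).
    mode : {"auto", "exact", "monte_carlo"}
        ``exact`` enumerates all n! permutations for n <= 8 and uses
        exact dynamic programming for n <= 12; larger n must use
        ``monte_carlo``.  ``auto`` picks exact when available.
    n_samples : int
        Number of seeded permutation draws in Monte-Carlo mode.
    seed : int
        Seed for the Monte-Carlo sampler.
    """
    if n < 2:
        raise ValueError("null distribution needs n >= 2")
    if mode == "auto":
        mode = "exact" if n <= _EXACT_MAX_N else "monte_carlo"
    if mode == "exact":
        if n > _EXACT_MAX_N:
            raise ValueError(
                f"exact null limited to n <= {_EXACT_MAX_N}; "
                "use mode='monte_carlo' for larger n"
            )
        values, probs = (
            _null_enumeration(n) if n <= _ENUM_MAX_N else _null_dp(n)
        )
        return SRDNull(n=n, values=values.astype(float), probs=probs, mode="exact")
    if mode != "monte_carlo":
        raise ValueError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed)
    ref = np.arange(1, n + 1)
    counts: dict[float, int] = {}
    batch = max(1, min(n_samples, 20_000_000 // max(n, 1)))
    remaining = n_samples
    while remaining > 0:
        b = min(batch, remaining)
        perms = np.tile(ref, (b, 1))
        rng.permuted(perms, axis=1, out=perms)
        dists = np.abs(perms - ref).sum(axis=1)
        vals, cnts = np.unique(dists, return_counts=True)
        for v, c in zip(vals, cnts):
            counts[float(v)] = counts.get(float(v), 0) + int(c)
        remaining -= b
    values = np.array(sorted(counts))
    probs = np.array([counts[v] for v in values], dtype=float) / n_samples
    return SRDNull(n=n, values=values, probs=probs, mode="monte_carlo")


@dataclasses.dataclass(frozen=True)
class SRDResult:
    """Full-data and cross-validated SRD values for a set of methods."""

    method_names: list[str]
    srd_raw: np.ndarray
    srd_norm: np.ndarray
    null: SRDNull
    cv_values: np.ndarray          # methods x folds, normalized 0-100
    folds: np.ndarray              # per-compound fold index
    n_compounds: int

    def significant_vs_random(self, q: float = 5.0) -> dict[str, bool]:
        """Whether each method's full-data SRD beats the null's q-th percentile."""
        cut = self.null.percentile_norm(q)
        return {
            name: bool(v < cut)
            for name, v in zip(self.method_names, self.srd_norm)
        }

    def to_frame(self):
        import pandas as pd

        rows = {
            "method": self.method_names,
            "srd_raw": self.srd_raw,
            "srd_norm": self.srd_norm,
        }
        for f in range(self.cv_values.shape[1]):
            rows[f"fold_{f + 1}"] = self.cv_values[:, f]
        return pd.DataFrame(rows)


def _standardize(col: np.ndarray) -> np.ndarray:
    sd = col.std()
    return (col - col.mean()) / sd if sd > 0 else col - col.mean()


def _method_columns(
    fused: FusedTable,
    m: ScoreMatrix,
    rows: np.ndarray,
    include_single_structures: bool,
) -> dict[str, np.ndarray]:
    """Standardized method columns restricted to ``rows``.

    Single-structure columns are rank transformed within the subset
    first (this removes per-structure score offsets), then all columns
    are z-scored; z-scoring is rank-invariant and kept for parity with
    the fused-score pipeline.
    """
    cols: dict[str, np.ndarray] = {}
    for rule in fused.rules:
        cols[rule] = _standardize(fused.column(rule)[rows])
    if include_single_structures:
        for j, sid in enumerate(m.structure_ids):
            cols[f"struct:{sid}"] = _standardize(
                rank_transform(m.scores[rows, j])
            )
    return cols


def _subset_matrix(m: ScoreMatrix, rows: np.ndarray) -> ScoreMatrix:
    return ScoreMatrix(
        compound_ids=[m.compound_ids[i] for i in rows],
        labels=m.labels[rows],
        structure_ids=list(m.structure_ids),
        scores=m.scores[rows],
    )


def srd_analysis(
    fused: FusedTable,
    m: ScoreMatrix,
    k_folds: int = 7,
    seed: int = 42,
    include_single_structures: bool = False,
    folds: np.ndarray | None = None,
    null_mode: str = "auto",
    null_samples: int = 100_000,
) -> SRDResult:
    """Run the complete SRD comparison of fusion rules on one dataset.

    The minimax reference is built on the full data and each method's
    normalized SRD computed against it; the same computation is then
    repeated on each leave-one-fold-out subset (reference rebuilt on the
    retained compounds) to give ``k_folds`` per-fold values per method.
    The random-ranking null for the full compound count is attached.

    Parameters
    ----------
    fused : FusedTable
        Canonical (lower = better) consensus scores, aligned with ``m``.
    m : ScoreMatrix
        The raw score matrix (used for the reference and, optionally,
        single-structure columns).
    k_folds : int
        Number of stratified cross-validation folds (default 7).
    seed : int
        Seed for fold assignment and the Monte-Carlo null.
    include_single_structures : bool
        Also score each rank-transformed single-structure column.
    folds : ndarray, optional
        Precomputed per-compound fold indices (overrides k_folds/seed),
        used to share folds with the enrichment-metric evaluation.
    """
    if fused.compound_ids != list(m.compound_ids):
        raise ValueError("fused table and score matrix are not aligned on compounds")
    n = m.n_compounds
    if folds is None:
        from .benchmark import make_folds

        if k_folds < 2 or k_folds > n:
            raise ValueError("k_folds must be in [2, n_compounds]")
        folds = make_folds(n, k_folds, m.labels, seed)
    else:
        folds = np.asarray(folds)
        k_folds = int(folds.max()) + 1

    all_rows = np.arange(n)
    cols = _method_columns(fused, m, all_rows, include_single_structures)
    names = list(cols)
    ref = build_reference(m)
    raw = np.array([srd_value(cols[c], ref) for c in names])
    norm = 100.0 * raw / srd_max(n)

    cv = np.empty((len(names), k_folds))
    for f in range(k_folds):
        keep = all_rows[folds != f]
        sub = _subset_matrix(m, keep)
        sub_cols = _method_columns(fused, m, keep, include_single_structures)
        sub_ref = build_reference(sub)
        smax = srd_max(len(keep))
        for i, c in enumerate(names):
            cv[i, f] = 100.0 * srd_value(sub_cols[c], sub_ref) / smax

    null = null_distribution(n, mode=null_mode, n_samples=null_samples, seed=seed)
    return SRDResult(
        method_names=names,
        srd_raw=raw,
        srd_norm=norm,
        null=null,
        cv_values=cv,
        folds=folds,
        n_compounds=n,
    )
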