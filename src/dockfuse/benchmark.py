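"""Orchestration of the full fusion-rule comparison.

For a labelled docking-score matrix this module fuses the per-structure
scores with every requested rule, evaluates each rule with AUC, average
precision, BEDROC and normalized SRD under stratified k-fold
cross-validation (default sevenfold), and tests whether the choice of
fusion rule matters with a one-way ANOVA (rule as the single factor
over per-fold metric values) followed by Tukey HSD post-hoc pairwise
comparisons at family level alpha = 0.05.

Per-fold enrichment metrics are computed on the *retained* (k-1)/k
subset so they share fold membership with the cross-validated SRD; a
flag switches to the held-out 1/k subset.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from . import metrics as em
from .fusion import RULES, fuse_matrix
from .io import ScoreMatrix
from .srd import srd_analysis

__all__ = [
    "MetricTable",
    "ComparisonSummary",
    "make_folds",
    "evaluate_all",
    "anova_tukey",
    "bubble_table",
]

METRICS = ("auc", "ap", "bedroc", "srd_norm")


def one_way_anova(groups) -> tuple[float, float]:
    """One-way ANOVA over per-fold metric groups: (F statistic, p-value)."""
    F, p = stats.f_oneway(*groups)
    return float(F), float(p)


def make_folds(n: int, k: int = 7, labels=None, seed: int = 42) -> np.ndarray:
    """Assign each of n compounds to one of k stratified random folds.

    Actives and inactives are shuffled separately and dealt round-robin,
    so every fold (and hence every retained complement) carries its
    share of actives.  Deterministic given the seed.
    """
    if k < 2 or k > n:
        raise ValueError("need 2 <= k <= n")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    if labels is None:
        labels = np.zeros(n, dtype=int)
    labels = np.asarray(labels)
    n_act = int((labels == 1).sum())
    if 0 < n_act < k:
        warnings.warn(
            f"only {n_act} actives for {k} folds; some folds will have no "
            "held-out active",
            stacklevel=2,
        )
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds


@dataclasses.dataclass(frozen=True)
class MetricTable:
    """Per (rule, fold) values of the four performance metrics."""

    data: pd.DataFrame  # columns: rule, fold, auc, ap, bedroc, srd_norm

    def __post_init__(self) -> None:
        required = {"rule", "fold", *METRICS}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"metric table missing columns {sorted(missing)}")
        if self.data.duplicated(["rule", "fold"]).any():
            raise ValueError("duplicate (rule, fold) rows")

    @property
    def rules(self) -> list[str]:
        return list(dict.fromkeys(self.data["rule"]))

    @property
    def n_folds(self) -> int:
        return self.data["fold"].nunique()

    def values(self, rule: str, metric: str) -> np.ndarray:
        sel = self.data[self.data["rule"] == rule].sort_values("fold")
        return sel[metric].to_numpy()

    def means(self) -> pd.DataFrame:
        return self.data.groupby("rule", sort=False)[list(METRICS)].mean()


def evaluate_all(
    m: ScoreMatrix,
    rules=RULES,
    k: int = 7,
    seed: int = 42,
    alpha: float = 20.0,
    include_single_structures: bool = False,
    held_out: bool = False,
    null_mode: str = "auto",
    null_samples: int = 100_000,
) -> tuple[MetricTable, "object"]:
    """Cross-validated AUC/AP/BEDROC/SRD for every fusion rule.

    Returns the metric table together with the :class:`~dockfuse.srd.SRDResult`
    (which carries the full-data SRD values and the random-ranking null).
    Pure function of its arguments: two calls with the same inputs give
    bit-identical results.
    """
    fused = fuse_matrix(m, rules)
    folds = make_folds(m.n_compounds, k, m.labels, seed)
    srd_res = srd_analysis(
        fused,
        m,
        seed=seed,
        include_single_structures=include_single_structures,
        folds=folds,
        null_mode=null_mode,
        null_samples=null_samples,
    )
    srd_idx = {name: i for i, name in enumerate(srd_res.method_names)}

    rows = []
    for f in range(k):
        sel = folds == f if held_out else folds != f
        labels = m.labels[sel]
        for rule in fused.rules:
            screen = em.RankedScreen(fused.column(rule)[sel], labels)
            rows.append(
                {
                    "rule": rule,
                    "fold": f,
                    "auc": em.auc(screen),
                    "ap": em.average_precision(screen),
                    "bedroc": em.bedroc(screen, alpha),
                    "srd_norm": srd_res.cv_values[srd_idx[rule], f],
                }
            )
        if include_single_structures:
            for j, sid in enumerate(m.structure_ids):
                screen = em.RankedScreen(m.scores[sel, j], labels)
                rows.append(
                    {
                        "rule": f"struct:{sid}",
                        "fold": f,
                        "auc": em.auc(screen),
                        "ap": em.average_precision(screen),
                        "bedroc": em.bedroc(screen, alpha),
                        "srd_norm": srd_res.cv_values[srd_idx[f"struct:{sid}"], f],
                    }
                )
    table = MetricTable(pd.DataFrame(rows).sort_values(["rule", "fold"], kind="stable").reset_index(drop=True))
    return table, srd_res


@dataclasses.dataclass(frozen=True)
class ComparisonSummary:
    """ANOVA + Tukey HSD comparison of the fusion rules, per metric."""

    means: pd.DataFrame      # rule x metric means
    sds: pd.DataFrame        # rule x metric standard deviations
    anova: pd.DataFrame      # metric, F, p, degenerate flag
    tukey: pd.DataFrame      # metric, rule_1, rule_2, meandiff, p_adj, significant

    def significant_pairs(self, metric: str) -> list[tuple[str, str]]:
        sel = self.tukey[(self.tukey["metric"] == metric) & self.tukey["significant"]]
        return list(zip(sel["rule_1"], sel["rule_2"]))


def anova_tukey(t: MetricTable, alpha_sig: float = 0.05) -> ComparisonSummary:
    """One-way ANOVA (rule as factor) and Tukey HSD per metric.

    A metric whose cells have zero within-group variance everywhere is
    flagged degenerate (F undefined) instead of raising.
    """
    rules = t.rules
    if len(rules) < 2 or t.n_folds < 2:
        raise ValueError("need at least 2 rules and 2 folds")

    anova_rows = []
    tukey_rows = []
    for metric in METRICS:
        groups = [t.values(r, metric) for r in rules]
        if all(np.ptp(g) == 0 for g in groups):
            anova_rows.append(
                {"metric": metric, "F": np.nan, "p": np.nan, "degenerate": True}
            )
            for r1, r2 in itertools.combinations(rules, 2):
                tukey_rows.append(
                    {
                        "metric": metric,
                        "rule_1": r1,
                        "rule_2": r2,
                        "meandiff": float(np.mean(t.values(r2, metric)) - np.mean(t.values(r1, metric))),
                        "p_adj": np.nan,
                        "significant": False,
                    }
                )
            continue
        F, p = one_way_anova(groups)
        anova_rows.append(
            {"metric": metric, "F": F, "p": p, "degenerate": False}
        )
        flat = np.concatenate(groups)
        labels = np.repeat(rules, [len(g) for g in groups])
        res = pairwise_tukeyhsd(flat, labels, alpha=alpha_sig)
        frame = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
        for _, row in frame.iterrows():
            tukey_rows.append(
                {
                    "metric": metric,
                    "rule_1": row["group1"],
                    "rule_2": row["group2"],
                    "meandiff": float(row["meandiff"]),
                    "p_adj": float(row["p-adj"]),
                    "significant": bool(row["reject"]),
                }
            )

    grouped = t.data.groupby("rule", sort=False)[list(METRICS)]
    return ComparisonSummary(
        means=grouped.mean(),
        sds=grouped.std(ddof=1),
        anova=pd.DataFrame(anova_rows),
        tukey=pd.DataFrame(tukey_rows),
    )


def bubble_table(t: MetricTable, drop: tuple[str, ...] = ()) -> pd.DataFrame:
    """Per-rule fold means arranged for the 4D bubble plot.

    One row per rule: mean AUC (x axis), mean AP (y axis), mean
    normalized SRD (bubble size, smaller = better) and mean BEDROC
    (color).  ``drop`` removes rules (e.g. MAX and the single-structure
    columns, which sit far from the fused cluster).
    """
    means = t.means().reset_index()
    if drop:
        means = means[~means["rule"].isin(drop)]
    return means.rename(
        columns={"auc": "x_auc", "ap": "y_ap", "srd_norm": "size_srd", "bedroc": "color_bedroc"}
    ).reset_index(drop=True)
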