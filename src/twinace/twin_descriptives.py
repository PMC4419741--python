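"""Phenotypic, cross-twin and cross-trait cross-twin correlations.

Cross-twin intraclass correlations (ICCs) are computed by double-entry
Pearson correlation: every complete pair enters in both twin orders, which
makes the estimate invariant to the arbitrary labelling of co-twins.
Confidence intervals use the Fisher z transform with the number of pairs
(not doubled entries) as the effective sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupCorrelation",
    "fisher_ci",
    "phenotypic_correlation",
    "cross_twin_icc",
    "cross_trait_cross_twin",
    "correlation_table",
]

GROUPS = ("MZM", "DZM", "MZF", "DZF")


@dataclass
class GroupCorrelation:
    group: str
    phenotype_a: str
    phenotype_b: str
    r: float
    ci_low: float
    ci_high: float
    n_pairs: int


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple:
    """Fisher z confidence interval for a correlation with n observations."""
    if n <= 3:
        return (-1.0, 1.0)
    r = float(np.clip(r, -0.999999, 0.999999))
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    return float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("correlation undefined: zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def phenotypic_correlation(
    selected: pd.DataFrame, pheno_a: str, pheno_b: str, level: float = 0.95
) -> GroupCorrelation:
    """Pearson correlation on a one-twin-per-pair table (pairwise complete)."""
    x = selected[pheno_a].to_numpy(dtype=float)
    y = selected[pheno_b].to_numpy(dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"need >= 3 complete rows for {pheno_a} x {pheno_b}; got {n}")
    r = _pearson(x[ok], y[ok])
    lo, hi = fisher_ci(r, n, level)
    return GroupCorrelation("all", pheno_a, pheno_b, r, lo, hi, n)


def _group_subset(records: pd.DataFrame, group: str) -> pd.DataFrame:
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    return records[(records["zygosity"] == group[:2]) & (records["sex"] == group[2])]


def cross_twin_icc(
    records: pd.DataFrame, group: str, phenotype: str, level: float = 0.95
) -> GroupCorrelation:
    """Cross-twin intraclass correlation by double-entry Pearson."""
    return cross_trait_cross_twin(records, group, phenotype, phenotype, level)


def cross_trait_cross_twin(
    records: pd.DataFrame,
    group: str,
    pheno_a: str,
    pheno_b: str,
    level: float = 0.95,
) -> GroupCorrelation:
    """Double-entry correlation of twin i's ``pheno_a`` with co-twin j's
    ``pheno_b`` (i != j), symmetric in twin order.

    With ``pheno_a == pheno_b`` this is the cross-twin ICC.  Each pair
    contributes its available orderings (pairwise-complete handling); the
    CI uses the number of distinct contributing pairs.
    """
    sub = _group_subset(records, group)
    a1 = sub[f"{pheno_a}_t1"].to_numpy(dtype=float)
    a2 = sub[f"{pheno_a}_t2"].to_numpy(dtype=float)
    b1 = sub[f"{pheno_b}_t1"].to_numpy(dtype=float)
    b2 = sub[f"{pheno_b}_t2"].to_numpy(dtype=float)
    e1 = ~(np.isnan(a1) | np.isnan(b2))  # twin1's a with twin2's b
    e2 = ~(np.isnan(a2) | np.isnan(b1))  # twin2's a with twin1's b
    x = np.concatenate([a1[e1], a2[e2]])
    y = np.concatenate([b2[e1], b1[e2]])
    n_pairs = int((e1 | e2).sum())
    if n_pairs < 3:
        raise ValueError(
            f"need >= 3 complete pairs in {group} for {pheno_a} x {pheno_b}; got {n_pairs}"
        )
    r = _pearson(x, y)
    lo, hi = fisher_ci(r, n_pairs, level)
    return GroupCorrelation(group, pheno_a, pheno_b, r, lo, hi, n_pairs)


def correlation_table(
    records: pd.DataFrame, phenotypes, level: float = 0.95
) -> pd.DataFrame:
    """Cross-twin ICCs and cross-trait cross-twin correlations per group."""
    rows = []
    phenotypes = list(phenotypes)
    for group in GROUPS:
        for i, pa in enumerate(phenotypes):
            for pb in phenotypes[i:]:
                try:
                    gc = cross_trait_cross_twin(records, group, pa, pb, level)
                except ValueError:
                    continue
                rows.append(
                    {
                        "group": group,
                        "phenotype_a": pa,
                        "phenotype_b": pb,
                        "kind": "ICC" if pa == pb else "cross-trait",
                        "r": gc.r,
                        "ci_low": gc.ci_low,
                        "ci_high": gc.ci_high,
                        "n_pairs": gc.n_pairs,
                    }
                )
    return pd.DataFrame(rows)
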