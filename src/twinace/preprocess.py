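"""Data preparation for twin analyses.

The chain mirrors standard behavioral-genetic practice: exclusion
filtering, natural-log transformation of positively skewed scales,
residualization of each scale on sex and age (ordinary least squares,
pooled over both twins), z-transformation, and random selection of one
twin per pair for phenotypic correlations.  Every applied step is
appended to a transforms log.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PhenotypeSpec",
    "apply_exclusions",
    "log_transform",
    "residualize",
    "zscore",
    "select_one_per_pair",
    "preprocess_dataset",
]

logger = logging.getLogger(__name__)

_SEX_CODE = {"M": 0.0, "F": 1.0}


@dataclass(frozen=True)
class PhenotypeSpec:
    """How one phenotype is prepared and where its extreme tail lies.

    ``extreme_tail`` is "high" for trait scales (difficulty = high scores)
    and "low" for ability scales (difficulty = low scores).
    """

    name: str
    log_transform: bool = False
    log_offset: float = 1.0
    extreme_tail: str = "high"
    max_score: float | None = None

    def __post_init__(self) -> None:
        if self.log_transform and self.log_offset <= 0.0:
            raise ValueError("log_offset must be > 0 when log_transform is set")
        if self.extreme_tail not in ("high", "low"):
            raise ValueError("extreme_tail must be 'high' or 'low'")


def apply_exclusions(records: pd.DataFrame, flags: Sequence[bool]) -> pd.DataFrame:
    """Drop flagged pairs (True = exclude); logs the removal count."""
    flags = np.asarray(flags, dtype=bool)
    if flags.shape[0] != len(records):
        raise ValueError(
            f"flags length {flags.shape[0]} does not match {len(records)} records"
        )
    n_removed = int(flags.sum())
    out = records.loc[~flags].reset_index(drop=True)
    logger.info("apply_exclusions: removed %d of %d pairs", n_removed, len(flags))
    if out.empty and len(records):
        warnings.warn("all pairs were excluded", stacklevel=2)
    return out


def log_transform(values, offset: float = 1.0) -> np.ndarray:
    """Natural log of (value + offset); missing values propagate."""
    arr = np.asarray(values, dtype=float)
    shifted = arr + offset
    bad = np.flatnonzero(~np.isnan(shifted) & (shifted <= 0.0))
    if bad.size:
        raise ValueError(
            f"log_transform: value + offset <= 0 at index {int(bad[0])} "
            f"(value={arr.flat[bad[0]]}, offset={offset})"
        )
    with np.errstate(invalid="ignore"):
        return np.log(shifted)


def residualize(values, sex, age) -> np.ndarray:
    """OLS residuals of score on a sex indicator and age.

    The fit pools all supplied individuals (both twins of every pair).
    Residuals have exactly zero sample correlation with both covariates.
    Missing scores or covariates yield missing residuals.  Constant
    covariates trigger a fall back to mean-centering with a warning.
    """
    y = np.asarray(values, dtype=float)
    sex = np.asarray([_SEX_CODE.get(s, s) for s in np.asarray(sex)], dtype=float)
    age = np.asarray(age, dtype=float)
    if not (y.shape == sex.shape == age.shape):
        raise ValueError("values, sex and age must have equal length")
    ok = ~(np.isnan(y) | np.isnan(sex) | np.isnan(age))
    if ok.sum() < 3:
        raise ValueError("residualize needs at least 3 complete (value, sex, age) triples")
    out = np.full_like(y, np.nan)
    if np.ptp(sex[ok]) == 0.0 and np.ptp(age[ok]) == 0.0:
        warnings.warn("both covariates constant; falling back to mean-centering", stacklevel=2)
        out[ok] = y[ok] - y[ok].mean()
        return out
    cols = [np.ones(ok.sum())]
    for cov in (sex[ok], age[ok]):
        if np.ptp(cov) > 0.0:
            cols.append(cov)
        else:
            warnings.warn("constant covariate dropped from residualization", stacklevel=2)
    design = np.column_stack(cols)
    fit = sm.OLS(y[ok], design).fit()
    out[ok] = fit.resid
    return out


def zscore(values) -> np.ndarray:
    """Standardize to mean 0, SD 1 (sample SD over non-missing entries)."""
    arr = np.asarray(values, dtype=float)
    ok = ~np.isnan(arr)
    if ok.sum() < 2:
        raise ValueError("zscore needs at least 2 non-missing values")
    sd = float(np.std(arr[ok], ddof=1))
    if sd == 0.0:
        raise ValueError("zscore: values have zero variance")
    out = np.full_like(arr, np.nan)
    out[ok] = (arr[ok] - arr[ok].mean()) / sd
    return out


def select_one_per_pair(records: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Randomly keep one twin per family (seed-reproducible).

    Returns one row per family with a single ``<pheno>`` column per
    phenotype (the selected twin's score) plus a ``twin`` column (1 or 2).
    """
    phenos = [c[:-3] for c in records.columns if c.endswith("_t1")]
    rng = np.random.default_rng(seed)
    pick = rng.integers(1, 3, size=len(records))
    out = records[["family_id", "zygosity", "sex", "age"]].copy()
    out["twin"] = pick
    for p in phenos:
        t1 = records[f"{p}_t1"].to_numpy(dtype=float)
        t2 = records[f"{p}_t2"].to_numpy(dtype=float)
        out[p] = np.where(pick == 1, t1, t2)
    return out.reset_index(drop=True)


def preprocess_dataset(
    records: pd.DataFrame,
    specs: Sequence[PhenotypeSpec],
    exclusion_flags: Sequence[bool] | None = None,
) -> tuple:
    """Full preparation chain: exclusions -> log -> residualize -> zscore.

    Transformations are applied to both twins' scores jointly (pooled
    residualization and pooled standardization), so co-twins stay on a
    common scale.  Returns ``(prepared_records, transforms_log)`` where the
    log is a list of human-readable step descriptions.
    """
    log: list = []
    out = records.copy()
    if exclusion_flags is not None:
        n0 = len(out)
        out = apply_exclusions(out, exclusion_flags)
        log.append(f"exclusions: removed {n0 - len(out)} of {n0} pairs")
    n = len(out)
    sex_pool = np.concatenate([out["sex"].to_numpy()] * 2)
    age_pool = np.concatenate([out["age"].to_numpy(dtype=float)] * 2)
    for spec in specs:
        cols = [f"{spec.name}_t1", f"{spec.name}_t2"]
        pooled = np.concatenate([out[cols[0]].to_numpy(float), out[cols[1]].to_numpy(float)])
        if spec.log_transform:
            pooled = log_transform(pooled, spec.log_offset)
            log.append(f"{spec.name}: log transform (offset={spec.log_offset})")
        pooled = residualize(pooled, sex_pool, age_pool)
        log.append(f"{spec.name}: residualized on sex and age (pooled OLS over both twins)")
        pooled = zscore(pooled)
        log.append(f"{spec.name}: z-transformed (mean 0, SD 1 over non-missing entries)")
        out[cols[0]] = pooled[:n]
        out[cols[1]] = pooled[n:]
    return out, log
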