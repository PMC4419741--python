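"""DeFries-Fulker (DF) extremes analysis.

Probands are individuals scoring in a declared tail of a z-scored
phenotype (high tail for trait scales, low tail for ability scales).
Scores are rescaled so the proband mean is 1 and the population mean 0;
the regression of co-twin scores on proband scores and the coefficient of
relatedness R (1 for MZ, 0.5 for DZ) then yields group heritability: the
zygosity coefficient equals twice the difference between the transformed
MZ and DZ co-twin means.  The bivariate form regresses co-twin scores on
a second (outcome) phenotype on the proband's selection score, giving the
genetic contribution to the cross-trait association at the extreme, and,
run in both directions, an extremes genetic correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ProbandSet",
    "DFRegressionResult",
    "ExtremesGeneticCorrelation",
    "select_probands",
    "df_transform",
    "transformed_cotwin_means",
    "univariate_df",
    "bivariate_df",
    "group_phenotypic_correlation",
    "extremes_genetic_correlation",
]

#: coefficient of relatedness by zygosity; this coding makes the zygosity
#: regression weight equal 2*(mu_MZ - mu_DZ) rather than the raw difference
RELATEDNESS = {"MZ": 1.0, "DZ": 0.5}

_SEX_CODE = {"M": 0.0, "F": 1.0}


@dataclass
class ProbandSet:
    """Extreme-scoring individuals on one (z-scored) selection phenotype."""

    selection_phenotype: str
    tail: str
    proportion: float
    ids: list  # (family_id, twin in {1, 2})
    threshold: float
    proband_mean: float
    population_mean: float
    n_by_zygosity: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class DFRegressionResult:
    """OLS estimates from a DF regression, with capping metadata."""

    selection_phenotype: str
    outcome_phenotype: str
    proband_coef: float  # beta1, partial regression on proband scores
    zygosity_coef: float  # beta2, the raw (group) heritability estimate
    intercept: float  # the regression constant
    covariate_coefs: dict
    mu_mz: float  # transformed MZ co-twin mean
    mu_dz: float  # transformed DZ co-twin mean
    capped_estimate: float
    cap_applied: bool
    n_probands: dict
    group_correlation: float | None = None
    ratio_to_group_correlation: float | None = None
    exceeds_group_correlation: bool | None = None


@dataclass
class ExtremesGeneticCorrelation:
    beta_xy: float
    beta_yx: float
    beta_x: float
    beta_y: float
    r_g: float
    clipped: bool
    valid: bool


def _long_scores(records: pd.DataFrame, phenotype: str) -> np.ndarray:
    cols = [f"{phenotype}_t1", f"{phenotype}_t2"]
    return np.concatenate([records[c].to_numpy(dtype=float) for c in cols])


def select_probands(
    records: pd.DataFrame, phenotype: str, tail: str, proportion: float
) -> ProbandSet:
    """Individuals beyond the empirical quantile in the declared tail.

    Either twin of a pair may qualify; ties at the threshold are included.
    The population mean is taken over all individuals with observed scores.
    """
    if not 0.0 < proportion <= 0.5:
        raise ValueError("proportion must be in (0, 0.5]")
    if tail not in ("high", "low"):
        raise ValueError("tail must be 'high' or 'low'")
    scores = _long_scores(records, phenotype)
    fam = np.concatenate([records["family_id"].to_numpy()] * 2)
    twin = np.concatenate([np.ones(len(records), int), np.full(len(records), 2)])
    zyg = np.concatenate([records["zygosity"].to_numpy()] * 2)
    ok = ~np.isnan(scores)
    if not ok.any():
        raise ValueError(f"no observed scores for {phenotype!r}")
    obs = scores[ok]
    if tail == "high":
        threshold = float(np.quantile(obs, 1.0 - proportion))
        sel = ok & (scores >= threshold)
    else:
        threshold = float(np.quantile(obs, proportion))
        sel = ok & (scores <= threshold)
    n = int(sel.sum())
    if n == 0:
        raise ValueError("no probands selected")
    if n < 10:
        warnings.warn(f"only {n} probands selected for {phenotype!r}", stacklevel=2)
    proband_mean = float(scores[sel].mean())
    population_mean = float(obs.mean())
    if abs(proband_mean - population_mean) < 0.05:
        warnings.warn(
            "proband mean is very close to the population mean; the DF "
            "transformation denominator is near zero",
            stacklevel=2,
        )
    counts = pd.Series(zyg[sel]).value_counts().to_dict()
    ids = list(zip(fam[sel].tolist(), twin[sel].tolist()))
    return ProbandSet(
        selection_phenotype=phenotype,
        tail=tail,
        proportion=proportion,
        ids=ids,
        threshold=threshold,
        proband_mean=proband_mean,
        population_mean=population_mean,
        n_by_zygosity={z: int(counts.get(z, 0)) for z in ("MZ", "DZ")},
    )


def df_transform(scores, proband_mean: float, population_mean: float) -> np.ndarray:
    """Rescale so the proband mean maps to 1 and the population mean to 0."""
    denom = proband_mean - population_mean
    if abs(denom) < 1e-12:
        raise ValueError("proband mean equals population mean; transform undefined")
    return (np.asarray(scores, dtype=float) - population_mean) / denom


def _proband_rows(
    probands: ProbandSet, records: pd.DataFrame, outcome: str, double_entry: bool = True
) -> pd.DataFrame:
    """One row per proband: proband selection score, co-twin outcome score."""
    sel = probands.selection_phenotype
    pr = pd.DataFrame(probands.ids, columns=["family_id", "twin"])
    if not double_entry:
        pr = pr.drop_duplicates("family_id")
    merged = pr.merge(records, on="family_id", how="left", validate="many_to_one")
    first = merged["twin"] == 1
    merged["proband_score"] = np.where(first, merged[f"{sel}_t1"], merged[f"{sel}_t2"])
    merged["cotwin_outcome"] = np.where(
        first, merged[f"{outcome}_t2"], merged[f"{outcome}_t1"]
    )
    cols = ["family_id", "twin", "zygosity", "sex", "age", "proband_score", "cotwin_outcome"]
    out = merged[cols]
    return out[~out["cotwin_outcome"].isna()].reset_index(drop=True)


def transformed_cotwin_means(
    probands: ProbandSet,
    records: pd.DataFrame,
    outcome_phenotype: str,
    outcome_scale: tuple | None = None,
    double_entry: bool = True,
) -> tuple:
    """Mean transformed co-twin outcome score by proband zygosity.

    ``outcome_scale`` is the (proband_mean, population_mean) pair defining
    the outcome's DF transformation; it defaults to the selection
    phenotype's own scale (the univariate case).  Concordant pairs are
    double-entered: each proband contributes one ordering.
    """
    if outcome_scale is None:
        outcome_scale = (probands.proband_mean, probands.population_mean)
    rows = _proband_rows(probands, records, outcome_phenotype, double_entry)
    out = {}
    for zyg in ("MZ", "DZ"):
        sub = rows[rows["zygosity"] == zyg]
        if sub.empty:
            raise ValueError(f"no {zyg} probands with observed co-twin outcome")
        out[zyg] = float(df_transform(sub["cotwin_outcome"], *outcome_scale).mean())
    return out["MZ"], out["DZ"]


def _df_regression(
    probands: ProbandSet,
    records: pd.DataFrame,
    outcome: str,
    outcome_scale: tuple,
    covariates: tuple,
    double_entry: bool,
) -> DFRegressionResult:
    sel_scale = (probands.proband_mean, probands.population_mean)
    rows = _proband_rows(probands, records, outcome, double_entry)
    if rows.empty:
        raise ValueError("no probands with observed co-twin outcome scores")
    c = df_transform(rows["cotwin_outcome"], *outcome_scale)
    p = df_transform(rows["proband_score"], *sel_scale)
    r = rows["zygosity"].map(RELATEDNESS).to_numpy(dtype=float)
    design = {"proband": p, "relatedness": r}
    for cov in covariates:
        if cov == "sex":
            design["sex"] = rows["sex"].map(_SEX_CODE).to_numpy(dtype=float)
        elif cov == "age":
            design["age"] = rows["age"].to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    X = sm.add_constant(pd.DataFrame(design), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear DF design matrix (a covariate may be constant)")
    fit = sm.OLS(c, X).fit()
    beta1 = float(fit.params["proband"])
    beta2 = float(fit.params["relatedness"])
    mu_mz, mu_dz = transformed_cotwin_means(
        probands, records, outcome, outcome_scale, double_entry
    )
    cap_applied = beta2 > mu_mz
    n_by_zyg = rows["zygosity"].value_counts().to_dict()
    return DFRegressionResult(
        selection_phenotype=probands.selection_phenotype,
        outcome_phenotype=outcome,
        proband_coef=beta1,
        zygosity_coef=beta2,
        intercept=float(fit.params["const"]),
        covariate_coefs={c_: float(fit.params[c_]) for c_ in covariates},
        mu_mz=mu_mz,
        mu_dz=mu_dz,
        capped_estimate=min(beta2, mu_mz),
        cap_applied=bool(cap_applied),
        n_probands={z: int(n_by_zyg.get(z, 0)) for z in ("MZ", "DZ")},
    )


def univariate_df(
    probands: ProbandSet,
    records: pd.DataFrame,
    covariates: tuple = ("sex", "age"),
    double_entry: bool = True,
) -> DFRegressionResult:
    """Univariate DF regression: co-twin score on proband score and relatedness.

    The zygosity coefficient estimates group heritability and is capped at
    the transformed MZ co-twin mean (an excess indicates non-additive
    genetic influences).
    """
    return _df_regression(
        probands,
        records,
        probands.selection_phenotype,
        (probands.proband_mean, probands.population_mean),
        covariates,
        double_entry,
    )


def bivariate_df(
    probands_x: ProbandSet,
    records: pd.DataFrame,
    outcome_y: str,
    y_probands: ProbandSet,
    covariates: tuple = ("sex", "age"),
    double_entry: bool = True,
) -> DFRegressionResult:
    """Bivariate DF regression: co-twin's outcome score on the proband's
    selection score and relatedness.

    The outcome is transformed on its own DF scale, taken from
    ``y_probands`` (the outcome phenotype's own selection at the same
    proportion).  The zygosity coefficient estimates the genetic
    contribution to the cross-trait association; its ratio to the
    phenotypic group correlation is the proportion of that correlation
    explained, and an excess over the group correlation flags possible
    non-additive influences.
    """
    if y_probands.selection_phenotype != outcome_y:
        raise ValueError("y_probands must come from selection on the outcome phenotype")
    result = _df_regression(
        probands_x,
        records,
        outcome_y,
        (y_probands.proband_mean, y_probands.population_mean),
        covariates,
        double_entry,
    )
    rho_g = group_phenotypic_correlation(probands_x, records, outcome_y)
    result.group_correlation = rho_g
    if abs(rho_g) > 1e-12:
        result.ratio_to_group_correlation = result.capped_estimate / rho_g
    result.exceeds_group_correlation = abs(result.capped_estimate) > abs(rho_g)
    return result


def group_phenotypic_correlation(
    probands_x: ProbandSet, records: pd.DataFrame, outcome_y: str
) -> float:
    """Mean proband z-score on the outcome over mean proband z on the
    selection phenotype."""
    pr = pd.DataFrame(probands_x.ids, columns=["family_id", "twin"])
    merged = pr.merge(records, on="family_id", how="left", validate="many_to_one")
    first = merged["twin"] == 1
    ys = np.where(first, merged[f"{outcome_y}_t1"], merged[f"{outcome_y}_t2"])
    mean_y = float(np.nanmean(ys.astype(float)))
    denom = probands_x.proband_mean
    if abs(denom) < 1e-12:
        raise ValueError("mean proband z-score on the selection phenotype is zero")
    return mean_y / denom


def extremes_genetic_correlation(
    beta_xy: float, beta_yx: float, beta_x: float, beta_y: float
) -> ExtremesGeneticCorrelation:
    """Extremes genetic correlation from the four DF heritability estimates.

    r_g = sign(beta_xy*beta_yx) * sqrt(|beta_xy*beta_yx| / (beta_x*beta_y)),
    clipped to [-1, 1] (flagged) and flagged invalid when the univariate
    group heritabilities are not both positive.
    """
    denom = beta_x * beta_y
    if denom <= 0.0:
        return ExtremesGeneticCorrelation(
            beta_xy, beta_yx, beta_x, beta_y, np.nan, clipped=False, valid=False
        )
    num = beta_xy * beta_yx
    raw = float(np.sign(num) * np.sqrt(abs(num) / denom))
    clipped = abs(raw) > 1.0
    return ExtremesGeneticCorrelation(
        beta_xy,
        beta_yx,
        beta_x,
        beta_y,
        float(np.clip(raw, -1.0, 1.0)),
        clipped=bool(clipped),
        valid=True,
    )
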