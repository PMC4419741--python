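"""Synthetic twin-pair cohorts with known biometric structure.

Generates same-sex MZ/DZ twin pairs whose phenotypes follow a multivariate
linear-Gaussian variance-component model: per-twin latent A/C/D/E factor
vectors with the standard cross-twin correlations (A: 1 in MZ, 0.5 in DZ;
C: 1 in both; D: 1 in MZ, 0.25 in DZ; E: 0), weighted by lower-triangular
path matrices that may differ between the sexes.  Optional monotone skew
transforms emulate count-like questionnaire scales, and
missing-completely-at-random dropout emulates partial completion of test
batteries.  Everything is reproducible from a single seed, with one
independent random stream per zygosity-sex cell.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from . import _reference
from .biometric_model import ALPHA, DELTA, GROUPS, SEXES, ZYGOSITIES, PathMatrices

__all__ = [
    "SkewSpec",
    "SimulationConfig",
    "TwinPairRecord",
    "simulate_twin_dataset",
    "write_dataset",
    "read_dataset",
    "iter_records",
    "paths_from_structure",
    "study_like_config",
    "two_trait_config",
]

logger = logging.getLogger(__name__)

_META_COLUMNS = ("family_id", "zygosity", "sex", "age")


@dataclass(frozen=True)
class SkewSpec:
    """Monotone transform applied to a phenotype after the linear stage.

    ``exponential`` maps a score y to exp(scale*y) (log-normal-like positive
    skew); ``ordinal`` bins scores at the given cut points into integer
    categories (count-like scales with a floor at 0).  Both preserve rank
    order.
    """

    kind: str = "none"
    scale: float = 1.0
    cut_points: tuple | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "exponential", "ordinal"):
            raise ValueError(f"unknown skew transform {self.kind!r}")
        if self.kind == "ordinal" and not self.cut_points:
            raise ValueError("ordinal transform requires cut_points")

    def apply(self, values: np.ndarray) -> np.ndarray:
        if self.kind == "none":
            return values
        if self.kind == "exponential":
            return np.exp(self.scale * values)
        out = np.digitize(values, np.asarray(self.cut_points, dtype=float)).astype(float)
        out[np.isnan(values)] = np.nan
        return out


@dataclass
class TwinPairRecord:
    """One family's paired observations (dataclass view of a dataset row)."""

    family_id: int
    zygosity: str
    sex: str
    age: float
    scores_twin1: dict
    scores_twin2: dict


@dataclass
class SimulationConfig:
    """True generating parameters for a synthetic twin cohort.

    ``true_paths`` maps sex ("M"/"F") to :class:`PathMatrices`; pass the
    same object for both sexes to generate without sex differences.
    ``n_pairs_per_group`` is an int (all four cells equal) or a mapping
    keyed by MZM/DZM/MZF/DZF.  ``missing_rate`` is a probability in [0, 1)
    per phenotype (scalar or mapping), applied independently per twin and
    independently of all latent factors (MCAR).
    """

    n_pairs_per_group: int | Mapping[str, int]
    true_paths: Mapping[str, PathMatrices]
    phenotype_names: Sequence[str]
    skew_transform: Mapping[str, SkewSpec] = field(default_factory=dict)
    missing_rate: float | Mapping[str, float] = 0.0
    age_range: tuple = (11.5, 13.5)
    age_effects: Sequence[float] | float = 0.0
    sex_effects: Sequence[float] | float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.phenotype_names = tuple(self.phenotype_names)
        k = len(self.phenotype_names)
        for group in GROUPS:
            if self.pairs_in_group(group) < 1:
                raise ValueError(f"n_pairs_per_group must be >= 1 (group {group})")
        for sex in SEXES:
            if sex not in self.true_paths:
                raise ValueError(f"true_paths missing sex {sex!r}")
            if self.true_paths[sex].k != k:
                raise ValueError("path matrices do not match phenotype count")
        for name in self.phenotype_names:
            rate = self.missing_for(name)
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"missing_rate for {name!r} must be in [0, 1)")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must be (min, max) with min < max")
        # the Cholesky parameterization keeps each component PSD, but guard
        # against degenerate inputs producing a singular joint covariance
        for sex in SEXES:
            for zyg in ZYGOSITIES:
                cov = _joint_covariance(self.true_paths[sex], zyg)
                eigmin = float(np.linalg.eigvalsh(cov).min())
                if eigmin < -1e-8:
                    raise ValueError(
                        f"implied covariance for {zyg}{sex} is not PSD "
                        f"(min eigenvalue {eigmin:.3g})"
                    )

    def pairs_in_group(self, group: str) -> int:
        if isinstance(self.n_pairs_per_group, Mapping):
            return int(self.n_pairs_per_group[group])
        return int(self.n_pairs_per_group)

    def missing_for(self, phenotype: str) -> float:
        if isinstance(self.missing_rate, Mapping):
            return float(self.missing_rate.get(phenotype, 0.0))
        return float(self.missing_rate)

    def _effects(self, which: str) -> np.ndarray:
        val = self.age_effects if which == "age" else self.sex_effects
        k = len(self.phenotype_names)
        arr = np.asarray(val, dtype=float)
        return np.full(k, float(arr)) if arr.ndim == 0 else arr


def _joint_covariance(pm: PathMatrices, zygosity: str) -> np.ndarray:
    covs = pm.component_covariances()
    k = pm.k
    zero = np.zeros((k, k))
    within = sum(covs.values(), zero.copy())
    cross = (
        ALPHA[zygosity] * covs.get("A", zero)
        + covs.get("C", zero)
        + DELTA[zygosity] * covs.get("D", zero)
    )
    return np.block([[within, cross], [cross.T, within]])


_SHARING = {"A": ALPHA, "C": {"MZ": 1.0, "DZ": 1.0}, "D": DELTA, "E": {"MZ": 0.0, "DZ": 0.0}}


def simulate_twin_dataset(config: SimulationConfig) -> pd.DataFrame:
    """Draw a twin-pair dataset under the configured generating model.

    Returns a DataFrame with columns ``family_id, zygosity, sex, age,
    <pheno>_t1, <pheno>_t2, ...``; missing scores are NaN.  The master seed
    is split into one independent stream per zygosity-sex cell, so each
    cell is reproducible in isolation.
    """
    streams = np.random.SeedSequence(config.seed).spawn(len(GROUPS))
    k = len(config.phenotype_names)
    age_eff = config._effects("age")
    sex_eff = config._effects("sex")
    frames = []
    family_id = 0
    for group, stream in zip(GROUPS, streams):
        zyg, sex = group[:2], group[2]
        rng = np.random.default_rng(stream)
        n = config.pairs_in_group(group)
        pm = config.true_paths[sex]
        age = rng.uniform(*config.age_range, size=n)
        sex_code = float(sex == "F")
        y1 = np.tile(pm.means, (n, 1)).astype(float)
        y2 = y1.copy()
        fixed = np.outer(age, age_eff) + sex_code * sex_eff
        y1 += fixed
        y2 += fixed
        for comp, path in pm.paths.items():
            share = _SHARING[comp][zyg]
            common = rng.standard_normal((n, k))
            u1 = rng.standard_normal((n, k))
            u2 = rng.standard_normal((n, k))
            f1 = np.sqrt(share) * common + np.sqrt(1.0 - share) * u1
            f2 = np.sqrt(share) * common + np.sqrt(1.0 - share) * u2
            y1 += f1 @ path.T
            y2 += f2 @ path.T
        data = {
            "family_id": np.arange(family_id, family_id + n),
            "zygosity": zyg,
            "sex": sex,
            "age": age,
        }
        family_id += n
        for pi, name in enumerate(config.phenotype_names):
            skew = config.skew_transform.get(name, SkewSpec())
            col1 = skew.apply(y1[:, pi].copy())
            col2 = skew.apply(y2[:, pi].copy())
            rate = config.missing_for(name)
            if rate > 0:
                col1[rng.random(n) < rate] = np.nan
                col2[rng.random(n) < rate] = np.nan
            data[f"{name}_t1"] = col1
            data[f"{name}_t2"] = col2
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)


def iter_records(records: pd.DataFrame) -> Iterator[TwinPairRecord]:
    """Row-wise dataclass view of a dataset frame."""
    phenos = [c[:-3] for c in records.columns if c.endswith("_t1")]
    for _, row in records.iterrows():
        yield TwinPairRecord(
            family_id=int(row["family_id"]),
            zygosity=str(row["zygosity"]),
            sex=str(row["sex"]),
            age=float(row["age"]),
            scores_twin1={p: row[f"{p}_t1"] for p in phenos},
            scores_twin2={p: row[f"{p}_t2"] for p in phenos},
        )


def write_dataset(records: pd.DataFrame, path) -> None:
    """Write the dataset as CSV (missing values as empty fields)."""
    records.to_csv(path, index=False, na_rep="")


def read_dataset(path) -> pd.DataFrame:
    """Read a twin dataset CSV, validating zygosity and sex codes.

    Malformed codes raise with the offending row number (0-based data row);
    an empty file returns an empty frame with a logged warning.
    """
    try:
        # round_trip parser: written floats (full repr precision) read back bit-exact
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        logger.warning("dataset file %s is empty; returning an empty collection", path)
        warnings.warn(f"dataset file {path} is empty", stacklevel=2)
        return pd.DataFrame(columns=list(_META_COLUMNS))
    missing_cols = [c for c in _META_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"dataset is missing required columns: {missing_cols}")
    bad_zyg = ~df["zygosity"].isin(ZYGOSITIES)
    if bad_zyg.any():
        row = int(np.flatnonzero(bad_zyg)[0])
        raise ValueError(f"row {row}: invalid zygosity {df['zygosity'].iloc[row]!r}")
    bad_sex = ~df["sex"].isin(SEXES)
    if bad_sex.any():
        row = int(np.flatnonzero(bad_sex)[0])
        raise ValueError(f"row {row}: invalid sex {df['sex'].iloc[row]!r}")
    return df


# ---------------------------------------------------------------------------
# building path matrices from standardized structures, and study presets
# ---------------------------------------------------------------------------


def paths_from_structure(
    proportions: Mapping[str, Sequence[float]],
    correlations: Mapping[str, np.ndarray],
    means: Sequence[float] | None = None,
) -> PathMatrices:
    """Path matrices from standardized variance proportions and etiological
    correlations (unit total phenotypic variance per trait).

    Each component covariance ``diag(sqrt(p)) @ R @ diag(sqrt(p))`` must be
    positive definite; a non-PSD input is rejected with a diagnostic.
    """
    names = list(proportions)
    k = len(next(iter(proportions.values())))
    paths = {}
    for comp in names:
        p = np.asarray(proportions[comp], dtype=float)
        corr = np.asarray(correlations.get(comp, np.eye(k)), dtype=float)
        cov = np.outer(np.sqrt(p), np.sqrt(p)) * corr
        try:
            paths[comp] = np.linalg.cholesky(cov + 1e-12 * np.eye(k))
        except np.linalg.LinAlgError as err:
            eigmin = float(np.linalg.eigvalsh(cov).min())
            raise ValueError(
                f"component {comp}: implied covariance is not positive definite "
                f"(min eigenvalue {eigmin:.3g}); adjust proportions/correlations"
            ) from err
    return PathMatrices(paths=paths, means=np.zeros(k) if means is None else means)


def _block_corr(k: int, first_vs_rest: float, within_rest: float) -> np.ndarray:
    """Correlation matrix: trait 0 vs the rest, and a common value among the rest."""
    corr = np.full((k, k), within_rest)
    corr[0, 1:] = first_vs_rest
    corr[1:, 0] = first_vs_rest
    np.fill_diagonal(corr, 1.0)
    return corr


def study_like_config(seed: int = 0, n_pairs_per_group=None) -> SimulationConfig:
    """Simulation preset mirroring the published study conditions.

    Five phenotypes (an autistic-trait scale plus four language tests),
    group sizes and per-sex standardized A/C/E proportions as published;
    a modest negative genetic correlation between traits and language
    (about -0.13), stronger negative shared-environment overlap, near-zero
    nonshared overlap, positive skew on the trait scale, and ~25%
    missingness on the language measures.
    """
    phenos = _reference.PHENOTYPES
    k = len(phenos)
    correlations = {
        "A": _block_corr(k, -0.13, 0.55),
        "C": _block_corr(k, -0.60, 0.65),
        "E": _block_corr(k, -0.05, 0.15),
    }
    true_paths = {}
    for sex in SEXES:
        a = np.asarray(_reference.VARIANCE_COMPONENTS[sex]["A"])
        c = np.asarray(_reference.VARIANCE_COMPONENTS[sex]["C"])
        props = {"A": a, "C": c, "E": 1.0 - a - c}
        true_paths[sex] = paths_from_structure(props, correlations)
    return SimulationConfig(
        n_pairs_per_group=n_pairs_per_group or dict(_reference.GROUP_N_PAIRS),
        true_paths=true_paths,
        phenotype_names=phenos,
        skew_transform={"traits": SkewSpec("exponential", scale=0.8)},
        missing_rate={p: 0.25 for p in phenos[1:]},
        age_range=(11.5, 13.5),
        age_effects=0.05,
        sex_effects=0.0,
        seed=seed,
    )


def two_trait_config(seed: int = 0, n_pairs_per_group: int = 500) -> SimulationConfig:
    """Small two-phenotype preset (trait scale + one language test), sexes equal."""
    props = {"A": (0.70, 0.30), "C": (0.05, 0.15), "E": (0.25, 0.55)}
    correlations = {
        "A": np.array([[1.0, -0.15], [-0.15, 1.0]]),
        "C": np.array([[1.0, -0.50], [-0.50, 1.0]]),
        "E": np.array([[1.0, -0.05], [-0.05, 1.0]]),
    }
    pm = paths_from_structure(props, correlations)
    return SimulationConfig(
        n_pairs_per_group=n_pairs_per_group,
        true_paths={"M": pm, "F": pm},
        phenotype_names=("traits", "vocabulary"),
        skew_transform={"traits": SkewSpec("exponential", scale=0.5)},
        missing_rate={"vocabulary": 0.2},
        age_range=(11.5, 13.5),
        age_effects=0.05,
        sex_effects=0.0,
        seed=seed,
    )
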