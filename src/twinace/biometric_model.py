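"""Variance-component (biometric) twin models.

Fits saturated and Cholesky-parameterized variance-component models to
same-sex twin-pair data by full-information maximum likelihood (FIML).
The phenotypic covariance of a set of ``k`` traits is decomposed into
additive genetic (A), shared-environmental (C), non-additive genetic (D)
and nonshared-environmental (E) components.  Each component covariance is
parameterized as the product of a lower-triangular path matrix with its
transpose (a Cholesky factorization), which keeps it positive
semi-definite by construction.  Cross-twin blocks scale A by the expected
genetic sharing (1 for MZ, 0.5 for DZ pairs) and D by 1 (MZ) or 0.25
(DZ); C is shared completely and E not at all.

Models may equate parameters across the sexes or allow them to differ in
magnitude (quantitative sex limitation).  Results are re-expressed as the
correlated-factors solution: standardized variance proportions per
phenotype plus etiological correlations (r_g, r_c, r_d, r_e) between
phenotypes, with profile-likelihood confidence intervals and a bivariate
decomposition of each phenotypic correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

__all__ = [
    "ALPHA",
    "DELTA",
    "GROUPS",
    "BiometricModelSpec",
    "PathMatrices",
    "MomentStructure",
    "FitResult",
    "ModelComparison",
    "StandardizedSolution",
    "ProfileCI",
    "implied_moments",
    "count_parameters",
    "neg2_log_likelihood",
    "fit_model",
    "fit_saturated",
    "likelihood_ratio_test",
    "aic",
    "correlated_factors",
    "bivariate_heritability",
    "confidence_intervals",
    "infer_phenotypes",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

ZYGOSITIES = ("MZ", "DZ")
SEXES = ("M", "F")
GROUPS = ("MZM", "DZM", "MZF", "DZF")

#: cross-twin sharing of additive genetic effects, by zygosity
ALPHA = {"MZ": 1.0, "DZ": 0.5}
#: cross-twin sharing of non-additive (dominance) genetic effects, by zygosity
DELTA = {"MZ": 1.0, "DZ": 0.25}

_COMP_ORDER = ("A", "C", "D", "E")


# ---------------------------------------------------------------------------
# specifications and parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BiometricModelSpec:
    """Which variance components are free, for how many phenotypes.

    ``components=None`` denotes the saturated model (free means and an
    unstructured covariance per group).  E must always be present in a
    structural model, and C and D cannot be estimated simultaneously
    because same-sex MZ/DZ pairs supply too few distinct covariance
    equations.
    """

    components: frozenset | None
    k: int
    sex_limitation: str = "equated"

    def __post_init__(self) -> None:
        if self.components is not None:
            comps = frozenset(self.components)
            object.__setattr__(self, "components", comps)
            unknown = comps - set(_COMP_ORDER)
            if unknown:
                raise ValueError(f"unknown components: {sorted(unknown)}")
            if "E" not in comps:
                raise ValueError("E must be included in every structural model")
            if "C" in comps and "D" in comps:
                raise ValueError("C and D cannot be estimated simultaneously")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.sex_limitation not in ("equated", "quantitative"):
            raise ValueError("sex_limitation must be 'equated' or 'quantitative'")

    @classmethod
    def from_name(cls, name: str, k: int, sex_limitation: str = "equated") -> "BiometricModelSpec":
        """Build a spec from a component string such as ``"ACE"`` or ``"saturated"``."""
        if name.lower() == "saturated":
            return cls(components=None, k=k, sex_limitation=sex_limitation)
        return cls(components=frozenset(name), k=k, sex_limitation=sex_limitation)

    @property
    def is_saturated(self) -> bool:
        return self.components is None

    @property
    def name(self) -> str:
        if self.is_saturated:
            return "saturated"
        return "".join(c for c in _COMP_ORDER if c in self.components)

    @property
    def ordered_components(self) -> tuple:
        if self.is_saturated:
            return ()
        return tuple(c for c in _COMP_ORDER if c in self.components)


def saturated_spec(k: int, sex_limitation: str = "quantitative") -> BiometricModelSpec:
    return BiometricModelSpec(components=None, k=k, sex_limitation=sex_limitation)


@dataclass
class PathMatrices:
    """Lower-triangular path matrices (one per component) plus phenotype means.

    The covariance attributable to component X with path matrix ``P`` is
    ``P @ P.T``.  Means are equated across co-twins and zygosity groups.
    """

    paths: dict
    means: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        k = self.means.shape[0]
        clean = {}
        for comp, mat in self.paths.items():
            m = np.asarray(mat, dtype=float)
            if m.shape != (k, k):
                raise ValueError(f"path matrix for {comp} must be {k}x{k}")
            if not np.allclose(np.triu(m, 1), 0.0):
                raise ValueError(f"path matrix for {comp} must be lower-triangular")
            clean[comp] = m
        self.paths = clean

    @property
    def k(self) -> int:
        return self.means.shape[0]

    def component_covariances(self) -> dict:
        return {comp: m @ m.T for comp, m in self.paths.items()}

    def phenotypic_covariance(self) -> np.ndarray:
        covs = self.component_covariances()
        return sum(covs.values(), np.zeros((self.k, self.k)))


@dataclass
class MomentStructure:
    """Implied mean vector (2k) and covariance (2k x 2k) for one twin group."""

    group: str
    mean: np.ndarray
    covariance: np.ndarray


def implied_moments(paths: PathMatrices, spec: BiometricModelSpec, group: str) -> MomentStructure:
    """Model-implied joint moments of the two co-twins' phenotype vectors.

    The within-twin block is A+C+D+E; the cross-twin block is
    ``alpha*A + C + delta*D`` with alpha/delta the zygosity sharing
    coefficients.  Both twins share the same within-twin block and mean.
    """
    if spec.is_saturated:
        raise ValueError("implied_moments applies to structural models only")
    zyg = group[:2]
    if zyg not in ZYGOSITIES:
        raise ValueError(f"unknown group {group!r}")
    covs = paths.component_covariances()
    extra = set(covs) - set(spec.ordered_components)
    if extra:
        raise ValueError(f"paths contain components {sorted(extra)} not in spec {spec.name}")
    k = paths.k
    zero = np.zeros((k, k))
    a = covs.get("A", zero)
    c = covs.get("C", zero)
    d = covs.get("D", zero)
    e = covs.get("E", zero)
    if "C" in covs and "D" in covs:
        raise ValueError("C and D cannot both be present")
    within = a + c + d + e
    cross = ALPHA[zyg] * a + c + DELTA[zyg] * d
    cov = np.block([[within, cross], [cross.T, within]])
    mean = np.concatenate([paths.means, paths.means])
    return MomentStructure(group=group, mean=mean, covariance=cov)


def count_parameters(spec: BiometricModelSpec) -> int:
    """Free-parameter count.

    Structural models: per sex set, one lower-triangular k x k matrix per
    component (k(k+1)/2 entries each) plus k means; doubled under
    quantitative sex limitation.  Saturated: per group, 2k means plus
    2k(2k+1)/2 covariances, with 4 groups (quantitative) or 2 zygosity
    groups (sexes equated).
    """
    k = spec.k
    if spec.is_saturated:
        n_groups = 4 if spec.sex_limitation == "quantitative" else 2
        per_group = 2 * k + (2 * k) * (2 * k + 1) // 2
        return n_groups * per_group
    n_sex = 2 if spec.sex_limitation == "quantitative" else 1
    tri = k * (k + 1) // 2
    return n_sex * (k + len(spec.ordered_components) * tri)


# ---------------------------------------------------------------------------
# data preparation and the FIML likelihood
# ---------------------------------------------------------------------------


def infer_phenotypes(records: pd.DataFrame) -> list:
    """Phenotype names from ``<name>_t1`` / ``<name>_t2`` column pairs, in order."""
    names = [c[:-3] for c in records.columns if c.endswith("_t1")]
    missing = [n for n in names if f"{n}_t2" not in records.columns]
    if missing:
        raise ValueError(f"phenotypes missing a _t2 column: {missing}")
    if not names:
        raise ValueError("no phenotype columns (expected <name>_t1 / <name>_t2)")
    return names


def _pair_matrix(records: pd.DataFrame, phenotypes: Sequence[str]) -> np.ndarray:
    cols = [f"{p}_t1" for p in phenotypes] + [f"{p}_t2" for p in phenotypes]
    return records[cols].to_numpy(dtype=float)


@dataclass
class _Prepared:
    """Per-group data grouped by missingness pattern for fast FIML."""

    items: list  # list of (observed column indices, data sub-matrix)
    n_pairs: int
    n_obs: int


def _prepare_matrix(y: np.ndarray) -> _Prepared:
    obs = ~np.isnan(y)
    keep = obs.any(axis=1)  # pairs with nothing observed contribute nothing
    y = y[keep]
    obs = obs[keep]
    items = []
    if len(y):
        patterns, inverse = np.unique(obs, axis=0, return_inverse=True)
        for ip, pat in enumerate(patterns):
            cols = np.flatnonzero(pat)
            rows = np.flatnonzero(inverse == ip)
            items.append((cols, np.ascontiguousarray(y[np.ix_(rows, cols)])))
    return _Prepared(items=items, n_pairs=len(y), n_obs=int(obs.sum()))


def _prepare_groups(
    records: pd.DataFrame, phenotypes: Sequence[str], by_sex: bool = True
) -> dict:
    out = {}
    for zyg in ZYGOSITIES:
        zmask = records["zygosity"] == zyg
        if by_sex:
            for sex in SEXES:
                sub = records[zmask & (records["sex"] == sex)]
                if len(sub):
                    out[zyg + sex] = _prepare_matrix(_pair_matrix(sub, phenotypes))
        else:
            sub = records[zmask]
            if len(sub):
                out[zyg] = _prepare_matrix(_pair_matrix(sub, phenotypes))
    if not out:
        raise ValueError("no twin pairs found in any zygosity group")
    return out


def _fiml(prep: _Prepared, mean: np.ndarray, cov: np.ndarray) -> float:
    """-2 log-likelihood of one group's pairs under Gaussian moments.

    Each pair contributes the log-density of its observed sub-vector
    (rows/columns of missing entries dropped).  Raises LinAlgError when an
    observed sub-matrix is not positive definite.
    """
    total = 0.0
    for cols, data in prep.items:
        sub = cov[np.ix_(cols, cols)]
        chol = np.linalg.cholesky(sub)
        dev = data - mean[cols]
        z = solve_triangular(chol, dev.T, lower=True, check_finite=False)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        total += data.shape[0] * (len(cols) * _LOG_2PI + logdet) + float((z * z).sum())
    return total


def _paths_for_sexes(paths) -> dict:
    if isinstance(paths, PathMatrices):
        return {"M": paths, "F": paths}
    out = dict(paths)
    for sex in SEXES:
        if sex not in out:
            raise ValueError(f"paths mapping missing sex {sex!r}")
    return out


def neg2_log_likelihood(
    paths,
    spec: BiometricModelSpec,
    records: pd.DataFrame,
    phenotypes: Sequence[str] | None = None,
) -> float:
    """FIML -2 log-likelihood over all zygosity-sex groups.

    ``paths`` is a single :class:`PathMatrices` (applied to both sexes) or a
    mapping ``{"M": ..., "F": ...}``.
    """
    phenotypes = list(phenotypes) if phenotypes is not None else infer_phenotypes(records)
    if len(phenotypes) != spec.k:
        raise ValueError(f"spec.k={spec.k} but {len(phenotypes)} phenotypes supplied")
    by_sex = _paths_for_sexes(paths)
    prepared = _prepare_groups(records, phenotypes, by_sex=True)
    total = 0.0
    for group, prep in prepared.items():
        mom = implied_moments(by_sex[group[2]], spec, group)
        try:
            total += _fiml(prep, mom.mean, mom.covariance)
        except np.linalg.LinAlgError as err:
            raise ValueError(
                f"implied covariance for group {group} is not positive definite "
                "on an observed sub-matrix; no regularization is applied"
            ) from err
    return total


# ---------------------------------------------------------------------------
# parameter packing, start values, fitting
# ---------------------------------------------------------------------------

_E_DIAG_FLOOR = 1e-6  # keeps implied covariance invertible at the boundary


class _Packer:
    """Flattens per-sex path matrices + means into one optimization vector."""

    def __init__(self, spec: BiometricModelSpec):
        self.spec = spec
        self.k = spec.k
        self.comps = spec.ordered_components
        self.sexsets = ("MF",) if spec.sex_limitation == "equated" else ("M", "F")
        self.tril_r, self.tril_c = np.tril_indices(self.k)
        self.n_tril = len(self.tril_r)
        self.block = self.k + len(self.comps) * self.n_tril
        self.n_params = self.block * len(self.sexsets)

    def unpack(self, theta: np.ndarray) -> dict:
        out = {}
        for si, sexset in enumerate(self.sexsets):
            off = si * self.block
            means = theta[off : off + self.k].copy()
            off += self.k
            paths = {}
            for comp in self.comps:
                mat = np.zeros((self.k, self.k))
                mat[self.tril_r, self.tril_c] = theta[off : off + self.n_tril]
                paths[comp] = mat
                off += self.n_tril
            pm = PathMatrices(paths=paths, means=means)
            if sexset == "MF":
                out["M"] = pm
                out["F"] = pm
            else:
                out[sexset] = pm
        return out

    def pack(self, by_sex: Mapping[str, PathMatrices]) -> np.ndarray:
        theta = np.empty(self.n_params)
        for si, sexset in enumerate(self.sexsets):
            pm = by_sex["M"] if sexset in ("MF", "M") else by_sex["F"]
            off = si * self.block
            theta[off : off + self.k] = pm.means
            off += self.k
            for comp in self.comps:
                theta[off : off + self.n_tril] = pm.paths[comp][self.tril_r, self.tril_c]
                off += self.n_tril
        return theta

    def bounds(self) -> list:
        # diagonal path entries constrained non-negative (sign convention);
        # E diagonals floored to keep the implied covariance invertible
        out = []
        diag = self.tril_r == self.tril_c
        for _ in self.sexsets:
            out.extend([(None, None)] * self.k)
            for comp in self.comps:
                lo = _E_DIAG_FLOOR if comp == "E" else 0.0
                out.extend([(lo, None) if d else (None, None) for d in diag])
        return out


def _psd_project(mat: np.ndarray, floor: float = 0.0) -> np.ndarray:
    mat = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(mat)
    vals = np.clip(vals, floor, None)
    return (vecs * vals) @ vecs.T


def _moment_summaries(records: pd.DataFrame, phenotypes: Sequence[str], sex: str | None):
    """Pairwise-complete within-twin covariance, MZ/DZ cross-twin covariance, means."""
    sub = records if sex is None else records[records["sex"] == sex]
    t1 = [f"{p}_t1" for p in phenotypes]
    t2 = [f"{p}_t2" for p in phenotypes]
    k = len(phenotypes)
    stacked = pd.DataFrame(
        np.vstack([sub[t1].to_numpy(float), sub[t2].to_numpy(float)]), columns=phenotypes
    )
    within = stacked.cov(min_periods=3).to_numpy()
    means = stacked.mean().to_numpy()
    within = np.where(np.isnan(within), 0.0, within)
    d = np.diag(within).copy()
    d[d <= 0] = 1.0
    within[np.diag_indices(k)] = d
    cross = {}
    for zyg in ZYGOSITIES:
        z = sub[sub["zygosity"] == zyg]
        de1 = np.vstack([z[t1].to_numpy(float), z[t2].to_numpy(float)])
        de2 = np.vstack([z[t2].to_numpy(float), z[t1].to_numpy(float)])
        both = pd.DataFrame(np.hstack([de1, de2]))
        full = both.cov(min_periods=3).to_numpy()
        blk = full[:k, k:]
        blk = np.where(np.isnan(blk), 0.0, blk)
        cross[zyg] = (blk + blk.T) / 2.0
    return within, cross["MZ"], cross["DZ"], np.where(np.isnan(means), 0.0, means)


def _mom_components(spec: BiometricModelSpec, within, c_mz, c_dz) -> dict:
    """Method-of-moments component covariance estimates used as start values."""
    comps = spec.ordered_components
    est = {}
    if comps == ("A", "C", "E"):
        est["A"] = 2.0 * (c_mz - c_dz)
        est["C"] = 2.0 * c_dz - c_mz
    elif comps == ("A", "D", "E"):
        est["A"] = 4.0 * c_dz - c_mz
        est["D"] = 2.0 * c_mz - 4.0 * c_dz
    elif comps == ("A", "E"):
        est["A"] = (c_mz + 2.0 * c_dz) / 2.0
    elif comps == ("C", "E"):
        est["C"] = (c_mz + c_dz) / 2.0
    elif comps == ("E",):
        pass
    else:  # pragma: no cover - spec validation precludes other sets
        raise ValueError(f"unsupported component set {comps}")
    non_e = sum(est.values(), np.zeros_like(within))
    est["E"] = within - non_e
    floor = 1e-3 * max(float(np.trace(within)) / spec.k, 1e-6)
    out = {}
    for comp, mat in est.items():
        f = floor if comp == "E" else 0.0
        out[comp] = np.linalg.cholesky(_psd_project(mat, floor=f) + floor * 1e-3 * np.eye(spec.k))
    return out


def _start_theta(spec: BiometricModelSpec, records, phenotypes, packer: _Packer) -> np.ndarray:
    by_sex = {}
    for sexset in packer.sexsets:
        sex = None if sexset == "MF" else sexset
        within, c_mz, c_dz, means = _moment_summaries(records, phenotypes, sex)
        paths = _mom_components(spec, within, c_mz, c_dz)
        pm = PathMatrices(paths=paths, means=means)
        if sexset == "MF":
            by_sex["M"] = pm
            by_sex["F"] = pm
        else:
            by_sex[sexset] = pm
    return packer.pack(by_sex)


@dataclass
class FitResult:
    """A fitted model: parameters, -2LL, and Mx-style degrees of freedom.

    ``df`` is the total number of observed data points (non-missing phenotype
    values over all included pairs) minus the number of free parameters.
    """

    spec: BiometricModelSpec
    phenotypes: tuple
    minus2LL: float
    n_parameters: int
    df: int
    n_obs_points: int
    converged: bool
    n_restarts_used: int = 0
    paths_by_sex: dict | None = None
    moments_by_group: dict | None = None

    @property
    def name(self) -> str:
        return self.spec.name


def _clip_to_bounds(theta: np.ndarray, bounds: list) -> np.ndarray:
    out = theta.copy()
    for i, (lo, hi) in enumerate(bounds):
        if lo is not None:
            out[i] = max(out[i], lo)
        if hi is not None:
            out[i] = min(out[i], hi)
    return out


def _make_objective(packer: _Packer, spec: BiometricModelSpec, prepared: dict) -> Callable:
    def fun(theta: np.ndarray) -> float:
        by_sex = packer.unpack(theta)
        total = 0.0
        for group, prep in prepared.items():
            mom = implied_moments(by_sex[group[2]], spec, group)
            try:
                total += _fiml(prep, mom.mean, mom.covariance)
            except np.linalg.LinAlgError:
                return 1e12
        return total

    return fun


def fit_model(
    spec: BiometricModelSpec,
    records: pd.DataFrame,
    *,
    phenotypes: Sequence[str] | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    maxiter: int = 2000,
) -> FitResult:
    """Fit a Cholesky structural model by FIML with multiple restarts.

    The first start is a method-of-moments solution (component covariances
    from MZ/DZ cross-twin covariance contrasts, projected to the nearest
    PSD matrix and Cholesky-factored); remaining restarts perturb it.
    The best of all converged runs is returned.
    """
    if spec.is_saturated:
        return fit_saturated(records, phenotypes=phenotypes, sex_limitation=spec.sex_limitation)
    phenotypes = tuple(phenotypes) if phenotypes is not None else tuple(infer_phenotypes(records))
    if len(phenotypes) != spec.k:
        raise ValueError(f"spec.k={spec.k} but {len(phenotypes)} phenotypes supplied")
    prepared = _prepare_groups(records, phenotypes, by_sex=True)
    if len(prepared) < 2:
        raise ValueError("need data in at least two zygosity-sex groups")
    packer = _Packer(spec)
    objective = _make_objective(packer, spec, prepared)
    theta0 = _clip_to_bounds(_start_theta(spec, records, phenotypes, packer), packer.bounds())
    rng = np.random.default_rng(seed)
    best = None
    tries = 0
    for attempt in range(max(1, n_restarts)):
        if attempt == 0:
            start = theta0
        else:
            jitter = rng.normal(0.0, 0.2 * (np.abs(theta0) + 0.1))
            start = _clip_to_bounds(theta0 + jitter, packer.bounds())
        res = optimize.minimize(
            objective,
            start,
            method="L-BFGS-B",
            bounds=packer.bounds(),
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7},
        )
        tries += 1
        if best is None or res.fun < best.fun:
            best = res
        # the moment start typically lands on the optimum; extra restarts
        # guard against ridge/boundary starts only
        if attempt >= 1 and best.fun < 1e11 and res.fun > best.fun - 1e-6:
            continue
    n_obs = sum(p.n_obs for p in prepared.values())
    n_par = count_parameters(spec)
    converged = bool(np.isfinite(best.fun) and best.fun < 1e11)
    return FitResult(
        spec=spec,
        phenotypes=phenotypes,
        minus2LL=float(best.fun),
        n_parameters=n_par,
        df=n_obs - n_par,
        n_obs_points=n_obs,
        converged=converged,
        n_restarts_used=tries,
        paths_by_sex=packer.unpack(best.x),
    )


def _fit_saturated_group(prep: _Prepared, y: np.ndarray, maxiter: int):
    """MLE mean/covariance for one group; closed form when data are complete."""
    dim = y.shape[1]
    complete = not np.isnan(y).any()
    if complete and len(y) > dim:
        mean = y.mean(axis=0)
        cov = np.cov(y, rowvar=False, ddof=0)
        return mean, cov, _fiml(prep, mean, cov)
    # FIML optimization over mean + Cholesky factor of the covariance
    frame = pd.DataFrame(y)
    cov0 = frame.cov(min_periods=2).to_numpy()
    cov0 = np.where(np.isnan(cov0), 0.0, cov0)
    scale = max(float(np.trace(cov0)) / dim, 1e-3)
    cov0 = _psd_project(cov0, floor=1e-3 * scale)
    chol0 = np.linalg.cholesky(cov0 + 1e-6 * scale * np.eye(dim))
    mean0 = np.nanmean(y, axis=0)
    mean0 = np.where(np.isnan(mean0), 0.0, mean0)
    tril_r, tril_c = np.tril_indices(dim)
    diag = tril_r == tril_c

    def unpack(theta):
        mean = theta[:dim]
        mat = np.zeros((dim, dim))
        mat[tril_r, tril_c] = theta[dim:]
        return mean, mat @ mat.T

    def fun(theta):
        mean, cov = unpack(theta)
        try:
            return _fiml(prep, mean, cov)
        except np.linalg.LinAlgError:
            return 1e12

    theta0 = np.concatenate([mean0, chol0[tril_r, tril_c]])
    bounds = [(None, None)] * dim + [(1e-8, None) if d else (None, None) for d in diag]
    res = optimize.minimize(
        fun,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7},
    )
    mean, cov = unpack(res.x)
    return mean, cov, float(res.fun)


def fit_saturated(
    records: pd.DataFrame,
    *,
    phenotypes: Sequence[str] | None = None,
    sex_limitation: str = "quantitative",
    maxiter: int = 2000,
) -> FitResult:
    """Saturated model: free means and unstructured covariance per group.

    Groups are the four zygosity-sex cells under ``quantitative`` sex
    limitation, or the two zygosity groups (sexes pooled) when ``equated``.
    With complete data the per-group MLE is the sample mean and the
    ML (1/n) covariance; with missing data the group is fitted by FIML.
    """
    phenotypes = tuple(phenotypes) if phenotypes is not None else tuple(infer_phenotypes(records))
    spec = saturated_spec(len(phenotypes), sex_limitation)
    by_sex = sex_limitation == "quantitative"
    prepared = _prepare_groups(records, phenotypes, by_sex=by_sex)
    total = 0.0
    moments = {}
    n_obs = 0
    for group, prep in prepared.items():
        mask = records["zygosity"] == group[:2]
        if by_sex:
            mask &= records["sex"] == group[2]
        y = _pair_matrix(records[mask], phenotypes)
        y = y[~np.isnan(y).all(axis=1)]
        mean, cov, m2ll = _fit_saturated_group(prep, y, maxiter)
        moments[group] = (mean, cov)
        total += m2ll
        n_obs += prep.n_obs
    n_par = count_parameters(spec)
    return FitResult(
        spec=spec,
        phenotypes=phenotypes,
        minus2LL=float(total),
        n_parameters=n_par,
        df=n_obs - n_par,
        n_obs_points=n_obs,
        converged=True,
        moments_by_group=moments,
    )


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------


def aic(delta_chi2: float, delta_df: int) -> float:
    """Akaike's criterion for a model-vs-comparison contrast: chi2 - 2*df."""
    if delta_df <= 0:
        raise ValueError("delta_df must be positive")
    return float(delta_chi2) - 2.0 * delta_df


@dataclass
class ModelComparison:
    model_name: str
    comparison_name: str
    delta_chi2: float
    delta_df: int
    p_value: float
    aic: float


def likelihood_ratio_test(sub: FitResult, full: FitResult, tol: float = 1e-4) -> ModelComparison:
    """Compare a nested sub-model with a fuller model.

    delta_chi2 is the rise in -2LL; its reference distribution is chi-square
    with delta_df = difference in parameter counts.
    """
    if not (sub.converged and full.converged):
        raise ValueError("both fits must have converged")
    delta_df = full.n_parameters - sub.n_parameters
    if delta_df <= 0:
        raise ValueError("sub-model must have fewer parameters than the full model")
    delta = sub.minus2LL - full.minus2LL
    if delta < -tol * max(1.0, abs(full.minus2LL)):
        raise ValueError(
            f"sub-model fits better than the full model (delta={delta:.6g}); refit advised"
        )
    delta = max(delta, 0.0)
    p = float(stats.chi2.sf(delta, delta_df)) if delta > 0 else 1.0
    return ModelComparison(
        model_name=sub.name,
        comparison_name=full.name,
        delta_chi2=float(delta),
        delta_df=int(delta_df),
        p_value=p,
        aic=aic(delta, delta_df),
    )


# ---------------------------------------------------------------------------
# correlated-factors standardization
# ---------------------------------------------------------------------------

_VAR_TOL = 1e-10


@dataclass
class SexSolution:
    """Standardized solution for one sex."""

    proportions: dict  # component -> length-k proportions of phenotypic variance
    correlations: dict  # component -> k x k etiological correlation (NaN if undefined)
    undefined: dict  # component -> bool, True when a component variance is ~0
    rph: np.ndarray  # model-implied phenotypic correlation matrix
    bivariate_shares: dict  # component -> k x k share of each rph
    phenotypic_covariance: np.ndarray


@dataclass
class StandardizedSolution:
    phenotypes: tuple
    sexes: dict  # "M"/"F" -> SexSolution

    def implied_covariance(self, sex: str) -> np.ndarray:
        return self.sexes[sex].phenotypic_covariance


def correlated_factors(fit: FitResult) -> StandardizedSolution:
    """Re-express a Cholesky fit as the correlated-factors solution.

    Per sex: standardized variance proportions (diagonals of each component
    covariance over total phenotypic variance) and etiological correlations
    ``r_comp[i,j] = Comp[i,j]/sqrt(Comp[i,i]*Comp[j,j])``.  Bivariate shares
    decompose each model-implied phenotypic correlation into component
    contributions ``Comp[i,j]/Sigma[i,j]``, which sum to one.
    """
    if not fit.converged:
        raise ValueError("cannot standardize a non-converged fit")
    if fit.paths_by_sex is None:
        raise ValueError("correlated_factors applies to structural fits only")
    sexes = {}
    for sex, pm in fit.paths_by_sex.items():
        covs = pm.component_covariances()
        sigma = pm.phenotypic_covariance()
        sd = np.sqrt(np.diag(sigma))
        rph = sigma / np.outer(sd, sd)
        proportions = {}
        correlations = {}
        undefined = {}
        shares = {}
        for comp, cc in covs.items():
            dv = np.diag(cc)
            proportions[comp] = dv / np.diag(sigma)
            bad = dv < _VAR_TOL
            undefined[comp] = bool(bad.any())
            dd = np.sqrt(np.where(bad, np.nan, dv))
            with np.errstate(invalid="ignore", divide="ignore"):
                correlations[comp] = cc / np.outer(dd, dd)
                np.fill_diagonal(correlations[comp], np.where(bad, np.nan, 1.0))
                shares[comp] = np.where(np.abs(sigma) > _VAR_TOL, cc / sigma, np.nan)
        sexes[sex] = SexSolution(
            proportions=proportions,
            correlations=correlations,
            undefined=undefined,
            rph=rph,
            bivariate_shares=shares,
            phenotypic_covariance=sigma,
        )
    return StandardizedSolution(phenotypes=fit.phenotypes, sexes=sexes)


def bivariate_heritability(
    solution: StandardizedSolution, pheno_pair, sex: str = "M", tol: float = 1e-8
) -> dict:
    """Decompose one phenotypic correlation into component shares.

    The A share is ``(sqrt(A1) * r_g * sqrt(A2)) / r_ph`` with A1, A2 the
    standardized A proportions; C/D/E shares are analogous.  The shares sum
    to one when r_ph is the model-implied correlation (it is, here).
    """
    names = list(solution.phenotypes)
    i = names.index(pheno_pair[0]) if isinstance(pheno_pair[0], str) else int(pheno_pair[0])
    j = names.index(pheno_pair[1]) if isinstance(pheno_pair[1], str) else int(pheno_pair[1])
    sol = solution.sexes[sex]
    rph = sol.rph[i, j]
    if abs(rph) < tol:
        raise ValueError(
            f"model-implied r_ph between {pheno_pair} is {rph:.2g}; shares are undefined"
        )
    out = {}
    for comp, props in sol.proportions.items():
        r = sol.correlations[comp][i, j]
        if np.isnan(r):
            # a zero-variance component contributes nothing to the covariance
            out[comp] = 0.0
        else:
            out[comp] = float(np.sqrt(props[i]) * r * np.sqrt(props[j]) / rph)
    return out


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals
# ---------------------------------------------------------------------------


@dataclass
class ProfileCI:
    estimate: float
    low: float
    high: float
    level: float
    low_at_boundary: bool = False
    high_at_boundary: bool = False


def _quantity_extractor(packer: _Packer, kind: str, comp: str, sex: str, i: int, j: int | None):
    def extract(theta: np.ndarray) -> float:
        pm = packer.unpack(theta)[sex]
        covs = pm.component_covariances()
        sigma = sum(covs.values(), np.zeros((packer.k, packer.k)))
        cc = covs[comp]
        if kind == "proportion":
            return float(cc[i, i] / sigma[i, i])
        if kind == "correlation":
            denom = np.sqrt(cc[i, i] * cc[j, j])
            return float(cc[i, j] / denom) if denom > _VAR_TOL else np.nan
        raise ValueError(kind)

    return extract


def _profile_value(objective, extract, bounds, target_value, start):
    cons = [{"type": "eq", "fun": lambda th: extract(th) - target_value}]
    res = optimize.minimize(
        objective,
        start,
        method="SLSQP",
        bounds=bounds,
        constraints=cons,
        options={"maxiter": 300, "ftol": 1e-9},
    )
    return float(res.fun), res.x


def _profile_bound(objective, extract, bounds, theta_hat, f_hat, v_hat, edge, crit):
    """Walk the profile from the MLE toward ``edge``; bisect the crossing."""
    if abs(edge - v_hat) < 1e-9:
        return v_hat, True
    fracs = (0.25, 0.5, 0.75, 0.9, 1.0)
    prev_t, prev_f, start = v_hat, 0.0, theta_hat
    for frac in fracs:
        t = v_hat + frac * (edge - v_hat)
        f, x = _profile_value(objective, extract, bounds, t, start)
        rise = f - f_hat
        if rise >= crit:
            lo_t, hi_t = prev_t, t
            lo_f, hi_f = prev_f, rise
            for _ in range(20):
                mid = 0.5 * (lo_t + hi_t)
                fm, x = _profile_value(objective, extract, bounds, mid, start)
                rm = fm - f_hat
                if rm >= crit:
                    hi_t, hi_f = mid, rm
                else:
                    lo_t, lo_f = mid, rm
                    start = x
                if abs(hi_t - lo_t) < 5e-4 * max(abs(edge - v_hat), 1e-3):
                    break
            return 0.5 * (lo_t + hi_t), False
        prev_t, prev_f, start = t, rise, x
    return edge, True  # profile never crossed: bound stuck at the parameter edge


def confidence_intervals(
    fit: FitResult,
    records: pd.DataFrame,
    quantities: Sequence[tuple] | None = None,
    level: float = 0.95,
) -> dict:
    """Profile-likelihood CIs for standardized quantities of a Cholesky fit.

    ``quantities`` is a list of tuples ``("proportion", comp, sex, i)`` or
    ``("correlation", comp, sex, i, j)``; by default all variance proportions
    are profiled.  Each bound is where the re-optimized -2LL (with the
    quantity fixed) rises by the chi-square(1) quantile; bounds that never
    cross within the parameter space are flagged as boundary-stuck (common
    for C proportions near 0).
    """
    if fit.paths_by_sex is None:
        raise ValueError("confidence_intervals applies to structural fits only")
    spec = fit.spec
    packer = _Packer(spec)
    prepared = _prepare_groups(records, fit.phenotypes, by_sex=True)
    objective = _make_objective(packer, spec, prepared)
    theta_hat = packer.pack(fit.paths_by_sex)
    f_hat = objective(theta_hat)
    crit = float(stats.chi2.ppf(level, 1))
    if quantities is None:
        quantities = [
            ("proportion", comp, sex, i)
            for sex in (packer.sexsets if spec.sex_limitation == "quantitative" else ("M",))
            for comp in spec.ordered_components
            for i in range(spec.k)
        ]
    out = {}
    for q in quantities:
        kind, comp, sex = q[0], q[1], q[2]
        i = q[3]
        j = q[4] if kind == "correlation" else None
        use_sex = sex if sex in ("M", "F") else "M"
        extract = _quantity_extractor(packer, kind, comp, use_sex, i, j)
        v_hat = extract(theta_hat)
        lo_edge, hi_edge = (0.0, 1.0) if kind == "proportion" else (-1.0, 1.0)
        low, low_b = _profile_bound(
            objective, extract, packer.bounds(), theta_hat, f_hat, v_hat, lo_edge, crit
        )
        high, high_b = _profile_bound(
            objective, extract, packer.bounds(), theta_hat, f_hat, v_hat, hi_edge, crit
        )
        out[q] = ProfileCI(
            estimate=v_hat,
            low=min(low, v_hat),
            high=max(high, v_hat),
            level=level,
            low_at_boundary=low_b,
            high_at_boundary=high_b,
        )
    return out
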