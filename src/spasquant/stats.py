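"""Random-intercept linear mixed model with cluster-robust inference.

The design observations (per-image SPAS counts, peak b0 values, sizes)
are correlated within a cross-section.  A random intercept per cluster,
``y = X beta + u_g + e`` with ``u_g ~ N(0, sigma_b^2)`` and
``e ~ N(0, sigma_e^2)``, induces a compound-symmetry covariance (equal
intra-cluster correlation).  Variance components are estimated by REML,
profiled to a one-dimensional search over the ratio
``lambda = sigma_b^2 / sigma_e^2`` with the fixed effects solved by
generalized least squares at each candidate.  Fixed-effect inference
uses the empirical (cluster-robust sandwich) covariance with a
``G/(G-1)`` correction and a standard-normal reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure and clustering for :func:`fit_lmm`.

    ``categorical`` terms are dummy-coded against a reference level
    (first level by default, overridable via ``reference_levels``);
    ``continuous`` terms enter as-is; ``interactions`` pairs a
    categorical with a continuous term (e.g. mode x compression).
    """

    response: str
    group: str
    categorical: tuple[str, ...] = ()
    continuous: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()
    reference_levels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        declared = set(self.categorical) | set(self.continuous)
        for cat, cont in self.interactions:
            if cat not in self.categorical or cont not in self.continuous:
                raise ValueError(
                    f"interaction ({cat}, {cont}) must reference declared "
                    f"main effects; declared: {sorted(declared)}")


def design_matrix(data: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Dummy-coded design matrix with intercept; returns (X, names)."""
    cols: list[np.ndarray] = [np.ones(len(data))]
    names = ["Intercept"]
    level_cols: dict[str, list[tuple[str, np.ndarray]]] = {}
    for term in spec.categorical:
        levels = list(pd.unique(data[term]))
        ref = spec.reference_levels.get(term, sorted(map(str, levels))[0])
        levels = sorted(map(str, levels))
        if str(ref) not in levels:
            raise ValueError(f"reference level {ref!r} not found in {term!r}")
        level_cols[term] = []
        for lev in levels:
            if lev == str(ref):
                continue
            ind = (data[term].astype(str) == lev).to_numpy(float)
            cols.append(ind)
            names.append(f"{term}[{lev}]")
            level_cols[term].append((lev, ind))
    for term in spec.continuous:
        cols.append(data[term].to_numpy(float))
        names.append(term)
    for cat, cont in spec.interactions:
        x = data[cont].to_numpy(float)
        for lev, ind in level_cols[cat]:
            cols.append(ind * x)
            names.append(f"{cat}[{lev}]:{cont}")
    X = np.column_stack(cols)
    return X, names


@dataclass
class LMMResult:
    names: list[str]
    beta: np.ndarray
    se_model: np.ndarray
    se_empirical: np.ndarray
    var_between: float
    var_residual: float
    ci95: np.ndarray          # (p, 2) from empirical SEs
    p_values: np.ndarray      # Wald, normal reference, empirical SEs
    n_obs: int
    n_groups: int
    converged: bool

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.beta, "se_model": self.se_model,
            "se_empirical": self.se_empirical,
            "ci_low": self.ci95[:, 0], "ci_high": self.ci95[:, 1],
            "p_value": self.p_values,
        }, index=self.names)

    def to_dict(self) -> dict:
        return dict(
            names=self.names, beta=self.beta.tolist(),
            se_model=self.se_model.tolist(),
            se_empirical=self.se_empirical.tolist(),
            var_between=self.var_between, var_residual=self.var_residual,
            ci95=self.ci95.tolist(), p_values=self.p_values.tolist(),
            n_obs=self.n_obs, n_groups=self.n_groups, converged=self.converged,
        )


def _gls_pieces(Xg, yg, lam):
    """Per-group GLS building blocks for V = I + lam * J (unit scale)."""
    XtX = np.zeros((Xg[0].shape[1],) * 2)
    Xty = np.zeros(Xg[0].shape[1])
    for X, y in zip(Xg, yg):
        n = len(y)
        w = lam / (1.0 + lam * n)
        Xs, ys = X.sum(axis=0), y.sum()
        XtX += X.T @ X - w * np.outer(Xs, Xs)
        Xty += X.T @ y - w * Xs * ys
    return XtX, Xty


def _reml_neg_loglik(log_lam, Xg, yg, n, p):
    lam = math.exp(log_lam)
    XtX, Xty = _gls_pieces(Xg, yg, lam)
    beta = np.linalg.solve(XtX, Xty)
    rss = 0.0
    logdet_v = 0.0
    for X, y in zip(Xg, yg):
        r = y - X @ beta
        ng = len(y)
        w = lam / (1.0 + lam * ng)
        rss += r @ r - w * r.sum() ** 2
        logdet_v += math.log1p(lam * ng)
    sigma_e2 = rss / (n - p)
    sign, logdet_x = np.linalg.slogdet(XtX)
    if sign <= 0:
        return np.inf
    return 0.5 * ((n - p) * math.log(sigma_e2) + logdet_v + logdet_x)


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> LMMResult:
    """REML fit of the random-intercept model with sandwich inference."""
    if data[spec.group].nunique() < 2:
        raise ValueError("need at least 2 groups")
    X, names = design_matrix(data, spec)
    y = data[spec.response].to_numpy(float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient after dummy coding")
    groups = data[spec.group].to_numpy()
    uniq = pd.unique(groups)
    Xg = [X[groups == g] for g in uniq]
    yg = [y[groups == g] for g in uniq]
    G = len(uniq)

    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(math.log(1e-8), math.log(1e6)),
        args=(Xg, yg, n, p), method="bounded",
        options={"xatol": 1e-8},
    )
    converged = bool(res.success)
    lam = math.exp(res.x)
    # boundary: no detectable between-group variance
    ll_zero = _reml_neg_loglik(math.log(1e-12), Xg, yg, n, p)
    if ll_zero <= res.fun:
        lam = 0.0

    XtX, Xty = _gls_pieces(Xg, yg, lam)
    beta = np.linalg.solve(XtX, Xty)
    rss = 0.0
    for Xb, yb in zip(Xg, yg):
        r = yb - Xb @ beta
        ng = len(yb)
        w = lam / (1.0 + lam * ng)
        rss += r @ r - w * r.sum() ** 2
    sigma_e2 = max(rss / (n - p), 0.0)
    sigma_b2 = lam * sigma_e2

    # XtX is in unit-residual scale: Cov_model(beta) = sigma_e2 * XtX^-1
    cov_model = sigma_e2 * np.linalg.inv(XtX)
    meat = np.zeros((p, p))
    for Xb, yb in zip(Xg, yg):
        r = yb - Xb @ beta
        ng = len(yb)
        w = lam / (1.0 + lam * ng)
        # X' V^-1 r with V = I + lam J (unit scale); sigma_e2 cancels in the sandwich
        xvr = Xb.T @ r - w * Xb.sum(axis=0) * r.sum()
        meat += np.outer(xvr, xvr)
    inv_XtX = np.linalg.inv(XtX)
    cov_emp = inv_XtX @ meat @ inv_XtX * (G / (G - 1.0))

    se_model = np.sqrt(np.maximum(np.diag(cov_model), 0.0))
    se_emp = np.sqrt(np.maximum(np.diag(cov_emp), 0.0))
    z = sps.norm.ppf(0.975)
    ci95 = np.column_stack([beta - z * se_emp, beta + z * se_emp])
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se_emp > 0, beta / se_emp, np.inf)
    p_values = np.clip(2.0 * sps.norm.sf(np.abs(zstat)), np.finfo(float).tiny, 1.0)

    return LMMResult(
        names=names, beta=beta, se_model=se_model, se_empirical=se_emp,
        var_between=float(sigma_b2), var_residual=float(sigma_e2),
        ci95=ci95, p_values=p_values, n_obs=n, n_groups=G,
        converged=converged,
    )


@dataclass
class SlopeContrast:
    """Difference between per-mode slopes: the interaction coefficient."""

    difference: float
    ci95: tuple[float, float]
    p_value: float
    term: str


def slope_contrast(result: LMMResult, interaction_term: str) -> SlopeContrast:
    """Extract an interaction coefficient as a slope-difference contrast.

    For a model with ``mode x compression`` interaction the coefficient
    is (non-reference mode slope) minus (reference mode slope).
    """
    if interaction_term not in result.names:
        raise ValueError(
            f"term {interaction_term!r} not in model; available: {result.names}")
    i = result.names.index(interaction_term)
    return SlopeContrast(
        difference=float(result.beta[i]),
        ci95=(float(result.ci95[i, 0]), float(result.ci95[i, 1])),
        p_value=float(result.p_values[i]),
        term=interaction_term,
    )


def group_regression_lines(
    data: pd.DataFrame, x: str, y: str, group_by: str
) -> pd.DataFrame:
    """Descriptive per-group OLS lines; one row per group."""
    rows = []
    for g, grp in data.groupby(group_by, sort=False):
        xs = grp[x].to_numpy(float)
        ys = grp[y].to_numpy(float)
        if np.unique(xs).size < 2:
            raise ValueError(f"group {g!r} has degenerate x values")
        slope, intercept = np.polyfit(xs, ys, 1)
        rows.append({group_by: g, "slope": slope, "intercept": intercept,
                     "n": len(grp)})
    return pd.DataFrame(rows)
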