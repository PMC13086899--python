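"""Phylogenetic generalized least squares and allometric indices.

The allometric model is the power law y = a * x**b, fitted on the log
scale as log y = log a + b log x with residuals whose covariance is
proportional to the tree matrix C (Brownian motion; no additional
branch-length transformation).  Estimation is exact GLS via Cholesky
whitening:

    beta = (X'C^-1 X)^-1 X'C^-1 y
    sigma2 = RSS_C / (n - p),   cov(beta) = sigma2 (X'C^-1 X)^-1

R^2 compares the C-weighted residual sum of squares with that of the
intercept-only GLS model; hypothesis tests on coefficients are Wald
chi-squared tests of linear constraints R beta = r.

Two summary indices describe how a neuropil scales against the
reference volume:

* slope index  si = b - b0, with b0 the isometric null (1 for a
  volume-on-volume regression); si < 0 means shallower-than-isometric
  scaling.
* grade-shift index  gsi = a1/a2 - 1, the intercept ratio between two
  ecological groups at a common slope; it is only meaningful when the
  group slopes are statistically indistinguishable, and is flagged
  invalid otherwise.

Both are invariant to the logarithm base (natural logs are used
internally).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cholesky, solve_triangular

from .tree import PhyloCovariance

__all__ = [
    "PGLSFit",
    "GradeShiftResult",
    "pgls_fit",
    "wald_chi2",
    "slope_index",
    "grade_shift",
    "leverage_screen",
    "two_factor_pgls",
    "isometry_report",
    "grade_shift_report",
    "ConfoundedFactorsError",
]

INCLUSION_R2 = 0.6  # adjusted-R^2 threshold for reporting scaling indices


class ConfoundedFactorsError(ValueError):
    """Design matrix is rank deficient (factors perfectly confounded)."""


@dataclass
class PGLSFit:
    """One fitted phylogenetic regression."""

    response: str
    predictors: list[str]
    params: pd.Series
    cov_params: pd.DataFrame
    sigma2: float
    n: int
    df_resid: int
    resid_raw: pd.Series
    resid_whitened: pd.Series
    r2: float
    r2_adj: float
    species: list[str]

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)


def _prepare(y: pd.Series, X: pd.DataFrame, C: PhyloCovariance,
             ridge: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    common = [s for s in C.species if s in y.index and s in X.index]
    yv = y.reindex(common)
    Xv = X.reindex(common)
    ok = yv.notna() & Xv.notna().all(axis=1)
    species = [s for s, keep in zip(common, ok) if keep]
    Cm = C.submatrix(species).matrix
    if ridge:
        Cm = Cm + ridge * np.eye(len(species))
    return yv[ok].to_numpy(float), Xv[ok].to_numpy(float), Cm, species


def pgls_fit(
    y: pd.Series,
    X: pd.DataFrame,
    C: PhyloCovariance,
    ridge: float = 0.0,
    ml_sigma2: bool = False,
) -> PGLSFit:
    """Fit a GLS regression with tree-structured residual covariance.

    ``y`` and the columns of ``X`` (which must include any intercept
    column explicitly) are aligned on species; rows with missing values
    are dropped pairwise and C is restricted to the remaining species.
    ``ridge`` adds epsilon*I to C for near-singular trees (default 0:
    singular C is an error).  ``ml_sigma2`` switches the residual
    variance denominator from n - p to n for cross-checks against
    ML-based software.
    """
    yv, Xv, Cm, species = _prepare(y, X, C, ridge)
    n, p = Xv.shape
    if n <= p:
        raise ValueError(f"n={n} species but {p} coefficients: insufficient data")
    try:
        L = cholesky(Cm, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular phylogenetic covariance; consider ridge > 0"
        ) from exc
    yw = solve_triangular(L, yv, lower=True)
    Xw = solve_triangular(L, Xv, lower=True)
    xtx = Xw.T @ Xw
    rank = np.linalg.matrix_rank(Xw)
    if rank < p:
        raise ConfoundedFactorsError(
            f"design matrix has rank {rank} < {p}; predictors are confounded"
        )
    beta = np.linalg.solve(xtx, Xw.T @ yw)
    resid = yv - Xv @ beta
    resid_w = yw - Xw @ beta
    rss = float(resid_w @ resid_w)
    sigma2 = rss / (n if ml_sigma2 else n - p)
    cov = sigma2 * np.linalg.inv(xtx)
    # C-weighted total SS around the GLS phylogenetic mean
    onew = solve_triangular(L, np.ones(n), lower=True)
    mu = float(onew @ yw) / float(onew @ onew)
    tss = float((yw - mu * onew) @ (yw - mu * onew))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else np.nan)
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p) if np.isfinite(r2) else np.nan
    cols = list(X.columns)
    return PGLSFit(
        response=y.name or "y",
        predictors=cols,
        params=pd.Series(beta, index=cols),
        cov_params=pd.DataFrame(cov, index=cols, columns=cols),
        sigma2=sigma2,
        n=n,
        df_resid=n - p,
        resid_raw=pd.Series(resid, index=species),
        resid_whitened=pd.Series(resid_w, index=species),
        r2=r2,
        r2_adj=r2_adj,
        species=species,
    )


def wald_chi2(fit: PGLSFit, R, r=0.0) -> tuple[float, int, float]:
    """Wald chi-squared test of the linear hypothesis R beta = r.

    ``R`` may be a constraint matrix, a single row, or a coefficient
    name (tested against ``r``).  Returns (chi2, df, p).
    """
    if isinstance(R, str):
        row = np.zeros(len(fit.params))
        row[list(fit.params.index).index(R)] = 1.0
        R = row
    R = np.atleast_2d(np.asarray(R, dtype=float))
    r = np.atleast_1d(np.asarray(r, dtype=float))
    if r.size == 1 and R.shape[0] > 1:
        r = np.repeat(r, R.shape[0])
    if np.linalg.matrix_rank(R) < R.shape[0]:
        raise ValueError("constraint matrix R is rank deficient")
    diff = R @ fit.params.to_numpy() - r
    mid = R @ fit.cov_params.to_numpy() @ R.T
    try:
        chi2 = float(diff @ np.linalg.solve(mid, diff))
    except np.linalg.LinAlgError:
        # degenerate (e.g. perfect fit, zero coefficient covariance):
        # a constraint that is exactly met still has chi2 = 0
        chi2 = float(diff @ np.linalg.pinv(mid) @ diff)
    df = R.shape[0]
    return chi2, df, float(stats.chi2.sf(chi2, df))


def slope_index(fit: PGLSFit, b0: float = 1.0, slope_name: str = "log_x") -> dict:
    """Slope index si = b - b0 with its Wald test against isometry."""
    b = float(fit.params[slope_name])
    chi2, df, p = wald_chi2(fit, slope_name, b0)
    return {
        "b": b,
        "se_b": float(fit.se[slope_name]),
        "si": b - b0,
        "chi2_b": chi2,
        "df": df,
        "p_b": p,
    }


@dataclass
class GradeShiftResult:
    """Grade-shift analysis of one neuropil between two ecological groups."""

    neuropil: str
    group1: str
    group2: str
    n: int
    slopes: dict[str, float]
    slope_diff_chi2: float
    slope_diff_p: float
    slopes_differ: bool
    common_slope: float | None
    gsi: float | None
    gsi_chi2: float | None
    gsi_p: float | None
    r2_adj: float
    include: bool
    gsi_valid: bool
    fit: PGLSFit = field(repr=False)


def _group_dummy(groups: pd.Series, group1: str) -> pd.Series:
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"grouping must be binary, got levels {levels}")
    if group1 not in levels:
        raise ValueError(f"group1={group1!r} not among levels {levels}")
    return (groups == group1).astype(float)


def grade_shift(
    y: pd.Series,
    x: pd.Series,
    groups: pd.Series,
    C: PhyloCovariance,
    group1: str,
    alpha: float = 0.05,
    include_r2: float = INCLUSION_R2,
    label: str = "",
) -> GradeShiftResult:
    """Two-step grade-shift analysis on log-scale data.

    Step 1 fits the interaction model
    ``y = log a_g + b_g * x`` and tests b1 = b2; if the slopes differ
    significantly only the slope difference is reported and the
    grade-shift index is marked invalid.  Step 2 (slopes homogeneous)
    refits with a common slope and reports gsi = a1/a2 - 1 with its
    Wald test on the intercept contrast.  ``y`` and ``x`` must already
    be on the log scale; ``group1`` names the numerator group.
    """
    g = _group_dummy(groups, group1)
    common = y.dropna().index.intersection(x.dropna().index).intersection(g.index)
    sizes = g.reindex(common).value_counts()
    if sizes.min() < 3 or len(sizes) < 2:
        raise ValueError(f"each group needs >= 3 species, got {sizes.to_dict()}")
    group2 = next(l for l in sorted(groups.dropna().unique()) if l != group1)

    X_int = pd.DataFrame(
        {"intercept": 1.0, "group": g, "log_x": x, "group_x": g * x}
    )
    fit_int = pgls_fit(y, X_int, C)
    chi2_s, _, p_s = wald_chi2(fit_int, "group_x", 0.0)
    b2 = float(fit_int.params["log_x"])
    slopes = {group2: b2, group1: b2 + float(fit_int.params["group_x"])}
    differ = p_s < alpha

    if differ:
        fit, common_slope = fit_int, None
        gsi = gsi_chi2 = gsi_p = None
    else:
        X_com = pd.DataFrame({"intercept": 1.0, "group": g, "log_x": x})
        fit = pgls_fit(y, X_com, C)
        common_slope = float(fit.params["log_x"])
        gsi = float(np.exp(fit.params["group"]) - 1.0)
        gsi_chi2, _, gsi_p = wald_chi2(fit, "group", 0.0)

    include = bool(fit.r2_adj > include_r2)
    return GradeShiftResult(
        neuropil=label or (y.name or ""),
        group1=group1,
        group2=group2,
        n=fit.n,
        slopes=slopes,
        slope_diff_chi2=chi2_s,
        slope_diff_p=p_s,
        slopes_differ=differ,
        common_slope=common_slope,
        gsi=gsi,
        gsi_chi2=gsi_chi2,
        gsi_p=gsi_p,
        r2_adj=fit.r2_adj,
        include=include,
        gsi_valid=bool((not differ) and include),
        fit=fit,
    )


def leverage_screen(fit: PGLSFit, n_sd: float = 2.0) -> pd.DataFrame:
    """Flag species with disproportionate influence on a regression.

    Each species' absolute whitened residual is normalized to the sum
    of all absolute whitened residuals; species above the mean plus
    ``n_sd`` standard deviations of these normalized values are
    flagged.  An all-zero residual vector yields zero statistics and no
    flags.
    """
    a = fit.resid_whitened.abs()
    total = a.sum()
    stat = a / total if total > 0 else a * 0.0
    cut = stat.mean() + n_sd * stat.std(ddof=1)
    return pd.DataFrame({"leverage": stat, "flagged": stat > cut})


def two_factor_pgls(
    y: pd.Series,
    x: pd.Series,
    activity: pd.Series,
    migration: pd.Series,
    C: PhyloCovariance,
    alpha: float = 0.05,
) -> tuple[PGLSFit, pd.DataFrame]:
    """Robustness model with both ecological factors on intercept and slope.

    Fits ``y = intercept + activity + migration + (b + activity + migration) * x``
    and Wald-tests each factor's intercept and slope term.  Perfectly
    confounded factors raise :class:`ConfoundedFactorsError` rather
    than being silently dropped.
    """
    act = _group_dummy(activity, "diurnal")
    mig = _group_dummy(migration, "migratory")
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "activity": act,
            "migration": mig,
            "log_x": x,
            "activity_x": act * x,
            "migration_x": mig * x,
        }
    )
    fit = pgls_fit(y, X, C)
    rows = []
    for term in ["activity", "migration", "activity_x", "migration_x"]:
        chi2, df, p = wald_chi2(fit, term, 0.0)
        rows.append({"term": term, "chi2": chi2, "df": df, "p": p,
                     "significant": p < alpha})
    return fit, pd.DataFrame(rows).set_index("term")


# --------------------------------------------------------------- reports


def isometry_report(
    traits: pd.DataFrame,
    reference: pd.Series,
    C: PhyloCovariance,
    b0: float = 1.0,
    alpha: float = 0.05,
    include_r2: float = INCLUSION_R2,
) -> pd.DataFrame:
    """Slope-index table: each neuropil's log mean volume vs log reference.

    ``traits`` holds raw species-mean volumes (species x neuropil);
    species missing a neuropil are dropped for that row only.
    """
    logx = np.log(reference)
    logx.name = "log_x"
    rows = []
    for col in traits.columns:
        y = np.log(traits[col].dropna())
        y.name = col
        X = pd.DataFrame({"intercept": 1.0, "log_x": logx})
        fit = pgls_fit(y, X, C)
        si = slope_index(fit, b0=b0)
        rows.append(
            {
                "neuropil": col,
                "n": fit.n,
                **si,
                "r2": fit.r2,
                "r2_adj": fit.r2_adj,
                "include": fit.r2_adj > include_r2,
                "significant": si["p_b"] < alpha,
            }
        )
    return pd.DataFrame(rows).set_index("neuropil")


def grade_shift_report(
    traits: pd.DataFrame,
    reference: pd.Series,
    groups: pd.Series,
    C: PhyloCovariance,
    group1: str,
    alpha: float = 0.05,
    include_r2: float = INCLUSION_R2,
    on_error: str = "raise",
) -> pd.DataFrame:
    """Grade-shift table across neuropils for one binary ecological factor.

    ``on_error="skip"`` records neuropils that cannot be analysed (for
    example a group left with fewer than 3 species after exclusions) as
    all-missing rows with the error message instead of raising.
    """
    logx = np.log(reference)
    rows = []
    for col in traits.columns:
        y = np.log(traits[col].dropna())
        y.name = col
        try:
            res = grade_shift(y, logx, groups, C, group1=group1, alpha=alpha,
                              include_r2=include_r2, label=col)
        except (ValueError, np.linalg.LinAlgError) as exc:
            if on_error != "skip":
                raise
            rows.append({"neuropil": col, "n": int(y.notna().sum()),
                         "note": str(exc)})
            continue
        rows.append(
            {
                "neuropil": col,
                "n": res.n,
                "slope_" + res.group1: res.slopes[res.group1],
                "slope_" + res.group2: res.slopes[res.group2],
                "slope_diff_chi2": res.slope_diff_chi2,
                "slope_diff_p": res.slope_diff_p,
                "slopes_differ": res.slopes_differ,
                "common_slope": res.common_slope,
                "gsi": res.gsi,
                "gsi_chi2": res.gsi_chi2,
                "gsi_p": res.gsi_p,
                "r2_adj": res.r2_adj,
                "include": res.include,
                "gsi_valid": res.gsi_valid,
            }
        )
    return pd.DataFrame(rows).set_index("neuropil")
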