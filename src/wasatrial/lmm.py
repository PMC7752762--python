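"""Random-intercept linear mixed models with Satterthwaite inference.

The longitudinal model for each body-composition measure is

    change_it = group_g(i) + month_t + (group x month)_gt
                + b1 * baseline_weight_i + b2 * baseline_bodyfat_i
                + u_i + e_it,

with ``change`` the change from baseline (kg), ``u_i ~ N(0, sigma2_subject)``
a participant random intercept and ``e_it ~ N(0, sigma2_residual)`` visit
noise.  Estimation is REML, profiled over the variance ratio
``lambda = sigma2_subject / sigma2_residual`` (a one-dimensional search, so
convergence is robust and fast).  The asymptotic covariance of the variance
components comes from the numerically differentiated REML information
matrix, which is what the Satterthwaite approximation for denominator
degrees of freedom consumes:

    df(c) = 2 * [var(c'beta)]^2 / Var[var(c'beta)],

with the denominator by the delta method (gradient of ``c' vcov(beta) c``
with respect to the variance components, propagated through their
covariance).  Multi-row hypotheses use the eigen-decomposition approach:
decompose ``L vcov(beta) L'``, apply single-contrast Satterthwaite to each
eigen-contrast, and combine the per-contrast dfs into a single denominator
df via nu = 2*E/(E - q) with E = sum nu_m/(nu_m - 2) over nu_m > 2.

Mixed models use every available visit, so inference is valid when
post-baseline missingness is at random given arm, sex and observed history.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

GROUP_LEVELS = ("HLC-F", "HLC-M", "HLF-F", "HLF-M")

#: The four pairwise diet-sex comparisons of interest, as (label, plus, minus).
PAIRWISE_COMPARISONS = (
    ("HLC vs HLF, women", "HLC-F", "HLF-F"),
    ("HLC vs HLF, men", "HLC-M", "HLF-M"),
    ("Men vs women, HLC", "HLC-M", "HLC-F"),
    ("Men vs women, HLF", "HLF-M", "HLF-F"),
)

_LAMBDA_LOG_BOUNDS = (-14.0, 14.0)
_RATIO_TOL = 1e-10


@dataclass
class ModelSpec:
    """What to model: measure, analysis months, and optional extra covariate."""

    measure: str = "weight"
    months: tuple[int, ...] | None = None  # default: (3, 6, 12) weight, (6, 12) DEXA
    extra_covariates: tuple[str, ...] = ()
    analysis_set: str = "dexa"  # "dexa": complete-case on baseline body fat;
    # "all": mean-impute baseline body fat to keep every weighed participant

    def resolved_months(self) -> tuple[int, ...]:
        if self.months is not None:
            return tuple(self.months)
        return (3, 6, 12) if self.measure == "weight" else (6, 12)


@dataclass
class LMMFit:
    """A fitted random-intercept model plus everything inference needs."""

    beta: pd.Series
    vcov_beta: np.ndarray
    sigma2_subject: float
    sigma2_residual: float
    vcov_theta: np.ndarray  # covariance of (sigma2_subject, sigma2_residual)
    n_obs: int
    n_subjects: int
    rank: int
    converged: bool
    log_reml: float
    # internal state for Satterthwaite recomputation at perturbed theta
    _X: np.ndarray = field(repr=False, default=None)
    _group_sizes: np.ndarray = field(repr=False, default=None)
    _group_starts: np.ndarray = field(repr=False, default=None)
    _theta_free: tuple[bool, bool] = (True, True)
    design_info: dict = field(default_factory=dict)

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.sigma2_subject, self.sigma2_residual])


@dataclass
class ContrastResult:
    label: str
    estimate: float
    se: float
    df: float
    t: float
    p: float
    ci_low: float
    ci_high: float


@dataclass
class OmnibusResult:
    F: float
    df1: int
    df2: float
    p: float


# ---------------------------------------------------------------------------
# core REML machinery (single random intercept)
# ---------------------------------------------------------------------------


def _group_structure(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sort order, block start indices and block sizes for the grouping factor."""
    order = np.argsort(groups, kind="stable")
    sorted_g = groups[order]
    starts = np.r_[0, np.flatnonzero(sorted_g[1:] != sorted_g[:-1]) + 1]
    sizes = np.diff(np.r_[starts, len(groups)])
    return order, starts, sizes


def _weighted_normal_eqs(
    X: np.ndarray, y: np.ndarray, starts: np.ndarray, sizes: np.ndarray, lam: float
):
    """Return (X'WX, X'Wy, y'Wy) where W = sigma2_residual * V^-1.

    With V = sigma2_e (I + lam Z Z') and a single random intercept,
    W = I - lam/(1 + lam n_i) * J within each subject block.
    """
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    if lam > 0:
        Sx = np.add.reduceat(X, starts, axis=0)  # per-subject column sums
        Sy = np.add.reduceat(y, starts)
        c = lam / (1.0 + lam * sizes)
        XtX = XtX - (Sx * c[:, None]).T @ Sx
        Xty = Xty - Sx.T @ (c * Sy)
        yty = yty - float(c @ (Sy**2))
    return XtX, Xty, yty


def _profiled_neg2_reml(
    lam: float, X: np.ndarray, y: np.ndarray, starts: np.ndarray, sizes: np.ndarray
):
    """-2 * restricted log-likelihood with beta and sigma2_e profiled out."""
    n, p = X.shape
    XtWX, XtWy, ytWy = _weighted_normal_eqs(X, y, starts, sizes, lam)
    try:
        Lchol = np.linalg.cholesky(XtWX)
    except np.linalg.LinAlgError:
        return np.inf, None, None, None
    beta = np.linalg.solve(XtWX, XtWy)
    rss_w = max(ytWy - float(XtWy @ beta), 1e-300)
    sigma2_e = rss_w / (n - p)
    # -2logL_R = (n-p) log(2 pi s2) + log|I + lam ZZ'| + log|X'WX| + (n-p),
    # using |V| = s2^n |I + lam ZZ'| and X'V^-1 X = X'WX / s2.
    m2 = (
        (n - p) * np.log(2.0 * np.pi * sigma2_e)
        + float(np.sum(np.log1p(lam * sizes)))
        + 2.0 * float(np.sum(np.log(np.diag(Lchol))))
        + (n - p)
    )
    return m2, beta, sigma2_e, XtWX


def _neg2_reml_at_theta(
    theta: np.ndarray, X: np.ndarray, y: np.ndarray, starts: np.ndarray, sizes: np.ndarray
) -> float:
    """-2 restricted log-likelihood at explicit (sigma2_subject, sigma2_residual)."""
    s2_u, s2_e = float(theta[0]), float(theta[1])
    if s2_e <= 0 or s2_u < 0:
        return np.inf
    n, p = X.shape
    lam = s2_u / s2_e
    XtWX, XtWy, ytWy = _weighted_normal_eqs(X, y, starts, sizes, lam)
    try:
        Lchol = np.linalg.cholesky(XtWX)
    except np.linalg.LinAlgError:
        return np.inf
    beta = np.linalg.solve(XtWX, XtWy)
    rss_w = max(ytWy - float(XtWy @ beta), 1e-300)
    logdet_V = n * np.log(s2_e) + float(np.sum(np.log1p(lam * sizes)))
    logdet_XtVinvX = 2.0 * float(np.sum(np.log(np.diag(Lchol)))) - p * np.log(s2_e)
    return (n - p) * np.log(2.0 * np.pi) + logdet_V + logdet_XtVinvX + rss_w / s2_e


def fit_random_intercept(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    colnames: list[str] | None = None,
    constrain_subject_var_zero: bool = False,
) -> LMMFit:
    """REML fit of ``y = X beta + Z u + e`` with one random intercept per group.

    The restricted likelihood is profiled down to the variance ratio and
    optimized by bounded scalar search; results are invariant to row order.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    n, p = X.shape
    if n != len(y) or n != len(groups):
        raise ValueError("y, X and groups must have matching lengths")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError("design matrix is rank deficient; drop collinear columns first")
    order, starts, sizes = _group_structure(groups)
    Xs, ys = X[order], y[order]

    if constrain_subject_var_zero:
        lam_hat, converged = 0.0, True
    else:
        obj = lambda u: _profiled_neg2_reml(np.exp(u), Xs, ys, starts, sizes)[0]
        res = optimize.minimize_scalar(
            obj, bounds=_LAMBDA_LOG_BOUNDS, method="bounded", options={"xatol": 1e-10}
        )
        lam_hat = float(np.exp(res.x))
        # boundary check: a ratio this small is numerically zero
        if (
            _profiled_neg2_reml(0.0, Xs, ys, starts, sizes)[0] <= res.fun + 1e-10
            or lam_hat < _RATIO_TOL
        ):
            lam_hat = 0.0
        converged = bool(res.success)

    m2, beta, sigma2_e, XtWX = _profiled_neg2_reml(lam_hat, Xs, ys, starts, sizes)
    sigma2_u = lam_hat * sigma2_e
    k = len(sizes)
    degenerate = lam_hat >= 0.5 * np.exp(_LAMBDA_LOG_BOUNDS[1]) and k > p
    if degenerate:
        # within-subject residual variance is numerically zero: the restricted
        # likelihood is unbounded in lambda.  In that limit lambda * rss_w
        # tends to the between-subject residual sum of squares, whose proper
        # denominator is n_subjects - p, not n_obs - p.
        logger.warning("zero residual variance detected; subject variance from between-subject fit")
        scale = (n - p) / (k - p)
        sigma2_u *= scale
        vcov_beta = sigma2_e * scale * lam_hat * np.linalg.inv(XtWX * lam_hat)
        sigma2_e = 0.0
    else:
        vcov_beta = sigma2_e * np.linalg.inv(XtWX)
    if sigma2_e > 0:
        theta = np.array([sigma2_u, sigma2_e])
        free = (not constrain_subject_var_zero and sigma2_u > 0, True)
        try:
            vcov_theta = _vcov_theta(theta, free, Xs, ys, starts, sizes)
        except np.linalg.LinAlgError:
            logger.warning("REML information singular; variance-component covariance unavailable")
            free = (False, False)
            vcov_theta = np.zeros((2, 2))
    else:
        free = (False, False)
        vcov_theta = np.zeros((2, 2))

    names = colnames if colnames is not None else [f"x{j}" for j in range(p)]
    return LMMFit(
        beta=pd.Series(beta, index=names),
        vcov_beta=vcov_beta,
        sigma2_subject=sigma2_u,
        sigma2_residual=sigma2_e,
        vcov_theta=vcov_theta,
        n_obs=n,
        n_subjects=len(sizes),
        rank=rank,
        converged=converged,
        log_reml=-0.5 * m2,
        _X=Xs,
        _group_sizes=sizes,
        _group_starts=starts,
        _theta_free=free,
    )


def _vcov_theta(theta, free, X, y, starts, sizes) -> np.ndarray:
    """Asymptotic covariance of the free variance components.

    Inverse of the observed REML information, with the information matrix
    obtained by central finite differences of -2 log L_R / 2.  Components on
    the boundary (subject variance estimated at 0) are held fixed; their
    rows/columns of the returned matrix are zero.
    """
    idx_free = [i for i, f in enumerate(free) if f]
    k = len(idx_free)
    out = np.zeros((2, 2))
    if k == 0:
        return out
    f0 = _neg2_reml_at_theta(theta, X, y, starts, sizes)

    def f(t_free):
        t = theta.copy()
        t[idx_free] = t_free
        return _neg2_reml_at_theta(t, X, y, starts, sizes)

    t0 = theta[idx_free]
    h = 1e-4 * np.maximum(np.abs(t0), 1e-3 * theta[1])
    H = np.zeros((k, k))
    for a in range(k):
        ea = np.zeros(k)
        ea[a] = h[a]
        H[a, a] = (f(t0 + ea) - 2.0 * f0 + f(t0 - ea)) / h[a] ** 2
        for b in range(a + 1, k):
            eb = np.zeros(k)
            eb[b] = h[b]
            H[a, b] = H[b, a] = (
                f(t0 + ea + eb) - f(t0 + ea - eb) - f(t0 - ea + eb) + f(t0 - ea - eb)
            ) / (4.0 * h[a] * h[b])
    info = 0.5 * H  # observed information of the restricted log-likelihood
    try:
        cov_free = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "singular REML information matrix for variance components "
            f"(free components: {idx_free})"
        )
    for a, ia in enumerate(idx_free):
        for b, ib in enumerate(idx_free):
            out[ia, ib] = cov_free[a, b]
    return out


def _var_contrast_at_theta(fit: LMMFit, c: np.ndarray, theta: np.ndarray) -> float:
    """c' vcov(beta | theta) c recomputed at arbitrary variance components."""
    s2_u, s2_e = float(theta[0]), float(theta[1])
    lam = max(s2_u, 0.0) / s2_e
    XtWX, _, _ = _weighted_normal_eqs(
        fit._X, np.zeros(fit.n_obs), fit._group_starts, fit._group_sizes, lam
    )
    return s2_e * float(c @ np.linalg.solve(XtWX, c))


def satterthwaite_df(fit: LMMFit, contrast: np.ndarray) -> float:
    """Satterthwaite denominator df for a single contrast of fixed effects."""
    if not fit.converged:
        raise RuntimeError("cannot compute Satterthwaite df for a non-converged fit")
    c = np.asarray(contrast, dtype=float)
    if c.shape != (len(fit.beta),):
        raise ValueError("contrast vector not conformable with fixed effects")
    theta = fit.theta
    var_c = float(c @ fit.vcov_beta @ c)
    # delta-method gradient of var_c wrt the free variance components
    grad = np.zeros(2)
    for j, is_free in enumerate(fit._theta_free):
        if not is_free:
            continue
        h = 1e-5 * max(theta[j], 1e-3 * theta[1])
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        grad[j] = (
            _var_contrast_at_theta(fit, c, tp) - _var_contrast_at_theta(fit, c, tm)
        ) / (2.0 * h)
    denom = float(grad @ fit.vcov_theta @ grad)
    resid_df = fit.n_obs - fit.rank
    if denom <= 0 or not np.isfinite(denom):
        return float(resid_df)
    df = 2.0 * var_c**2 / denom
    return float(min(df, resid_df))


def contrast_test(fit: LMMFit, contrast: np.ndarray, label: str = "") -> ContrastResult:
    """t-test of ``c' beta = 0`` with Satterthwaite df and a 95% CI."""
    c = np.asarray(contrast, dtype=float)
    est = float(c @ fit.beta.to_numpy())
    se = float(np.sqrt(c @ fit.vcov_beta @ c))
    df = satterthwaite_df(fit, c)
    t = est / se
    p = 2.0 * stats.t.sf(abs(t), df)
    half = stats.t.ppf(0.975, df) * se
    return ContrastResult(label, est, se, df, t, float(p), est - half, est + half)


def multi_contrast_test(fit: LMMFit, L: np.ndarray) -> OmnibusResult:
    """F-test of ``L beta = 0`` with eigen-combined Satterthwaite df2."""
    L = np.atleast_2d(np.asarray(L, dtype=float))
    q = np.linalg.matrix_rank(L)
    if q < L.shape[0]:
        raise ValueError("hypothesis matrix L is rank deficient")
    beta = fit.beta.to_numpy()
    M = L @ fit.vcov_beta @ L.T
    Lb = L @ beta
    F = float(Lb @ np.linalg.solve(M, Lb)) / q

    eigval, eigvec = np.linalg.eigh(M)
    Ltilde = eigvec.T @ L  # rows: independent eigen-contrasts
    nus = np.array([satterthwaite_df(fit, Ltilde[m]) for m in range(L.shape[0])])
    usable = nus > 2.0
    if usable.any():
        E = float(np.sum(nus[usable] / (nus[usable] - 2.0)))
        df2 = 2.0 * E / (E - q) if E > q else float(fit.n_obs - fit.rank)
    else:
        df2 = float(fit.n_obs - fit.rank)
    p = float(stats.f.sf(F, q, df2))
    return OmnibusResult(F=F, df1=int(q), df2=df2, p=p)


# ---------------------------------------------------------------------------
# trial-specific model assembly
# ---------------------------------------------------------------------------


def build_change_data(
    outcomes: pd.DataFrame,
    participants: pd.DataFrame,
    spec: ModelSpec,
    wasa_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Long change-from-baseline analysis table for one measure.

    Excludes participants without a baseline value for the measure, and —
    under the default complete-case analysis set — those missing baseline
    body-fat percentage (it is a model covariate).  Exclusion counts are
    logged.
    """
    months = spec.resolved_months()
    meas = outcomes[outcomes["measure"] == spec.measure]
    wide = meas.pivot_table(index="participant_id", columns="month", values="value_kg")
    if 0 not in wide.columns:
        raise ValueError(f"no baseline records for measure {spec.measure!r}")
    has_base = wide[0].notna()
    logger.info(
        "%s: %d participant(s) lack a baseline value and are excluded",
        spec.measure,
        int((~has_base).sum()),
    )
    wide = wide[has_base]

    rows = []
    for month in months:
        if month not in wide.columns:
            continue
        change = wide[month] - wide[0]
        change = change.dropna()
        rows.append(
            pd.DataFrame(
                {"participant_id": change.index, "month": month, "change_kg": change.to_numpy()}
            )
        )
    data = pd.concat(rows, ignore_index=True)
    part = participants[
        ["participant_id", "diet", "sex", "baseline_weight_kg", "baseline_bodyfat_pct"]
    ]
    data = data.merge(part, on="participant_id", how="inner")
    data["group"] = data["diet"] + "-" + data["sex"]

    if spec.analysis_set == "all":
        mean_bf = data["baseline_bodyfat_pct"].mean()
        data["baseline_bodyfat_pct"] = data["baseline_bodyfat_pct"].fillna(mean_bf)
    else:
        n_drop = data["baseline_bodyfat_pct"].isna().sum()
        if n_drop:
            logger.info(
                "%s: %d row(s) dropped for missing baseline body-fat %%", spec.measure, int(n_drop)
            )
        data = data[data["baseline_bodyfat_pct"].notna()]
    data = data[data["baseline_weight_kg"].notna()]

    if wasa_table is not None and "wasa" in spec.extra_covariates:
        wasa_map = wasa_table.set_index("participant_id")["wasa"]
        data["wasa"] = wasa_map.reindex(data["participant_id"]).to_numpy()
        data = data[data["wasa"].notna()]
    return data.reset_index(drop=True)


def build_design(data: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str], dict]:
    """Treatment-coded design: intercept, group, month, group x month, covariates.

    Baseline covariates are mean-centered (contrast estimates are unaffected;
    conditioning improves and the intercept becomes the reference-cell mean
    at average covariates).
    """
    months = sorted(data["month"].unique())
    ref_month = months[0]
    cols, names = [np.ones(len(data))], ["Intercept"]
    for g in GROUP_LEVELS[1:]:
        cols.append((data["group"] == g).to_numpy(float))
        names.append(f"group[{g}]")
    for m in months[1:]:
        cols.append((data["month"] == m).to_numpy(float))
        names.append(f"month[{m}]")
    for g in GROUP_LEVELS[1:]:
        for m in months[1:]:
            cols.append(((data["group"] == g) & (data["month"] == m)).to_numpy(float))
            names.append(f"group[{g}]:month[{m}]")
    covs = ["baseline_weight_kg", "baseline_bodyfat_pct", *spec.extra_covariates]
    dropped = []
    for cov in covs:
        x = data[cov].to_numpy(float)
        if np.std(x) == 0:
            logger.warning("covariate %s is constant; dropped as collinear", cov)
            dropped.append(cov)
            continue
        cols.append(x - x.mean())
        names.append(cov)
    X = np.column_stack(cols)
    info = {"months": months, "ref_month": ref_month, "dropped_covariates": dropped}
    return X, names, info


def fit_lmm(
    outcomes: pd.DataFrame,
    participants: pd.DataFrame,
    spec: ModelSpec | None = None,
    wasa_table: pd.DataFrame | None = None,
    constrain_subject_var_zero: bool = False,
) -> LMMFit:
    """Fit the longitudinal change model for one measure."""
    spec = spec or ModelSpec()
    data = build_change_data(outcomes, participants, spec, wasa_table)
    n_groups = data["group"].nunique()
    if n_groups < 2:
        raise ValueError(f"need at least 2 diet-sex groups, found {n_groups}")
    X, names, info = build_design(data, spec)
    fit = fit_random_intercept(
        data["change_kg"].to_numpy(),
        X,
        data["participant_id"].to_numpy(),
        colnames=names,
        constrain_subject_var_zero=constrain_subject_var_zero,
    )
    fit.design_info = {**info, "spec": spec, "n_rows": len(data)}
    return fit


def _cell_row(fit: LMMFit, group: str, month: int) -> np.ndarray:
    """Design row for (group, month) at mean covariates (centered: zeros)."""
    names = list(fit.beta.index)
    x = np.zeros(len(names))
    x[names.index("Intercept")] = 1.0
    gname = f"group[{group}]"
    if gname in names:
        x[names.index(gname)] = 1.0
    mname = f"month[{month}]"
    if mname in names:
        x[names.index(mname)] = 1.0
    iname = f"group[{group}]:month[{month}]"
    if iname in names:
        x[names.index(iname)] = 1.0
    return x


def pairwise_12mo_contrasts(fit: LMMFit, month: int = 12) -> list[ContrastResult]:
    """The four labeled pairwise comparisons of adjusted month-12 changes.

    No multiplicity adjustment is applied.
    """
    results = []
    for label, plus, minus in PAIRWISE_COMPARISONS:
        c = _cell_row(fit, plus, month) - _cell_row(fit, minus, month)
        results.append(contrast_test(fit, c, label=label))
    return results


def omnibus_group_test(fit: LMMFit, month: int = 12) -> OmnibusResult:
    """Rank-3 F-test that all four groups' adjusted month-12 changes are equal."""
    ref = GROUP_LEVELS[0]
    L = np.vstack(
        [_cell_row(fit, g, month) - _cell_row(fit, ref, month) for g in GROUP_LEVELS[1:]]
    )
    return multi_contrast_test(fit, L)


def contrasts_frame(results: list[ContrastResult], measure: str) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "measure": measure,
                "estimate": r.estimate,
                "se": r.se,
                "df": r.df,
                "t": r.t,
                "p": r.p,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
            }
            for r in results
        ]
    )
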