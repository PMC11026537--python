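"""Statistical models for depth comparisons and severe-bleaching drivers.

Three layers:

* ``two_sample_t`` — two-sample t-tests (pooled or Welch-Satterthwaite df)
  with a 95% CI on the mean difference, used for the 10 m vs 17 m
  comparisons of maximum AHS and MDTF.
* ``fit_lmm`` / ``type2_wald_tests`` / ``marginal_means`` — a linear mixed
  model of percent severely bleached per site x depth x size-class cell with
  fixed effects depth + AHS + size class + size:AHS and a random site
  intercept, fit by REML (statsmodels MixedLM).  Per-term Type II Wald F
  tests use Satterthwaite denominator degrees of freedom computed from the
  REML profile; estimated marginal means come with Tukey-adjusted pairwise
  contrasts (studentized-range distribution).
* ``fit_glmm_binomial`` — the colony-level analogue: a logit-link binomial
  mixed model with the same fixed and random structure, fit by maximum
  likelihood with per-site adaptive Gauss-Hermite quadrature, plus a
  qualitative-agreement report against the LMM.

The continuous AHS covariate is mean-centered by default so the size main
effects and marginal means are evaluated at the observed mean heat stress.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats
from scipy.special import expit, logsumexp
import statsmodels.api as sm

logger = logging.getLogger("reefstress.inference")

SIZE_LEVELS = ("small", "mid", "large")

#: Convergence tolerance on the -2*REML criterion.
REML_TOL = 1e-8

#: Gauss-Hermite nodes for the GLMM integral (adaptive, per site).
GLMM_QUAD_POINTS = 15


# ---------------------------------------------------------------------------
# Two-sample t-test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    df: float
    p_value: float
    ci95_low: float
    ci95_high: float
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    df_method: str

    @property
    def mean_difference(self) -> float:
        return self.mean1 - self.mean2


def group_summary(values) -> tuple[float, float, int]:
    """(mean, SD with ddof=1, n) of a sample."""
    x = np.asarray(values, dtype=float)
    return float(x.mean()), float(x.std(ddof=1)), int(x.size)


def two_sample_t(group1, group2, df_method: str = "pooled") -> TTestResult:
    """Two-sided two-sample t-test with a 95% CI on mean1 - mean2.

    ``df_method="pooled"`` uses the pooled-variance statistic and df
    n1+n2-2 (the classical Student test); ``"welch-satterthwaite"`` uses
    unpooled variances with the Welch-Satterthwaite df.  With equal group
    sizes the two t statistics coincide and only df (hence p and CI) differ.
    """
    m1, s1, n1 = group_summary(group1)
    m2, s2, n2 = group_summary(group2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations")
    if s1 == 0.0 and s2 == 0.0 and m1 == m2:
        raise ValueError("t undefined: zero variance in both groups with equal means")
    if df_method == "pooled":
        sp2 = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    elif df_method == "welch-satterthwaite":
        v1, v2 = s1 ** 2 / n1, s2 ** 2 / n2
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    else:
        raise ValueError(f"unknown df_method {df_method!r}")
    diff = m1 - m2
    t = diff / se
    p = 2 * stats.t.sf(abs(t), df)
    half = stats.t.ppf(0.975, df) * se
    return TTestResult(t_statistic=float(t), df=float(df), p_value=float(p),
                       ci95_low=float(diff - half), ci95_high=float(diff + half),
                       mean1=m1, sd1=s1, n1=n1, mean2=m2, sd2=s2, n2=n2,
                       df_method=df_method)


# ---------------------------------------------------------------------------
# Shared fixed-effects design
# ---------------------------------------------------------------------------

@dataclass
class Design:
    """Fixed-effects design shared by the LMM and GLMM.

    Columns (treatment coding): Intercept, depth[T.17], ahs_c,
    size[T.mid], size[T.large], size[T.mid]:ahs_c, size[T.large]:ahs_c.
    ``terms`` maps term name -> column indices.
    """

    X: np.ndarray
    names: list[str]
    terms: dict[str, list[int]]
    ahs_center: float
    site_codes: np.ndarray
    site_labels: list[str]


def build_design(df: pd.DataFrame, ahs_col: str = "max_ahs_c_weeks",
                 center_ahs: bool = True,
                 ahs_center: float | None = None) -> Design:
    """Build the depth + AHS + size + size:AHS design with a site grouping.

    Size class is an ordered factor (small < mid < large) with treatment
    coding, reference = small, so coefficients are level-vs-small
    differences, matching how pairwise contrasts are reported.
    """
    need = {"site", "depth_m", "size_class", ahs_col}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"design needs columns {sorted(missing)}")
    depth = df["depth_m"].astype(float)
    if not depth.isin([10.0, 17.0]).all():
        raise ValueError("depth_m must be 10 or 17")
    size = pd.Categorical(df["size_class"], categories=SIZE_LEVELS, ordered=True)
    if size.isna().any():
        raise ValueError("size_class must be one of " + "/".join(SIZE_LEVELS))
    ahs = df[ahs_col].astype(float).to_numpy()
    if ahs_center is None:
        # summed in sorted order so the center is row-permutation invariant
        center = float(np.sort(ahs).mean()) if center_ahs else 0.0
    else:
        center = float(ahs_center)
    ahs_c = ahs - center
    d17 = (depth == 17.0).to_numpy(dtype=float)
    mid = (size == "mid").astype(float)
    large = (size == "large").astype(float)
    X = np.column_stack([
        np.ones(len(df)), d17, ahs_c, mid, large, mid * ahs_c, large * ahs_c,
    ])
    names = ["Intercept", "depth[T.17]", "ahs_c", "size[T.mid]",
             "size[T.large]", "size[T.mid]:ahs_c", "size[T.large]:ahs_c"]
    terms = {"depth": [1], "ahs": [2], "size": [3, 4], "size:ahs": [5, 6]}
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by checking rank drop per column
        aliased = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                aliased.append(names[j])
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    sites = df["site"].astype(str)
    labels = sorted(sites.unique())
    codes = sites.map({s: i for i, s in enumerate(labels)}).to_numpy()
    return Design(X=X, names=names, terms=terms, ahs_center=center,
                  site_codes=codes, site_labels=labels)


def type2_contrast(design: Design, term: str) -> np.ndarray:
    """Type II hypothesis matrix L for a term in the full-model parameters.

    The Type II test of a term adjusts for every other term except its
    higher-order relatives (terms containing it).  The rows select the
    term's coefficients plus the projection correction
    ``(X2' Q1 X2)^{-1} X2' Q1 X3`` on the relatives' columns, where Q1
    projects out the non-relative terms; on balanced orthogonal designs the
    correction vanishes and Type II reduces to selecting the coefficients.
    """
    if term not in design.terms:
        raise ValueError(f"unknown term {term!r}")
    factors = set(term.split(":"))
    cols2 = design.terms[term]
    cols3: list[int] = []
    cols1: list[int] = [0]
    for other, cols in design.terms.items():
        if other == term:
            continue
        ofac = set(other.split(":"))
        if factors < ofac:
            cols3.extend(cols)
        else:
            cols1.extend(cols)
    X = design.X
    X1, X2 = X[:, cols1], X[:, cols2]
    q = len(cols2)
    L = np.zeros((q, X.shape[1]))
    L[np.arange(q), cols2] = 1.0
    if cols3:
        X3 = X[:, cols3]
        Q1 = np.eye(len(X)) - X1 @ np.linalg.pinv(X1)
        B = np.linalg.pinv(X2.T @ Q1 @ X2) @ (X2.T @ Q1 @ X3)
        L[:, cols3] = B
    return L


# ---------------------------------------------------------------------------
# Linear mixed model (REML, random site intercept)
# ---------------------------------------------------------------------------

@dataclass
class LMMResult:
    """Fitted random-intercept LMM with its REML variance profile.

    ``params``/``cov_beta`` are the GLS fixed effects and their covariance
    at the REML variance estimates ``(tau2, sigma2)`` (site and residual
    variance).  ``theta_cov`` is the asymptotic covariance of the variance
    components from the observed REML information, used by the Satterthwaite
    approximation.
    """

    params: np.ndarray
    names: list[str]
    cov_beta: np.ndarray
    tau2: float
    sigma2: float
    theta_cov: np.ndarray
    design: Design
    y: np.ndarray
    reml_neg2: float
    converged: bool
    boundary: bool
    n_sites: int
    metadata: dict = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def residual_df(self) -> float:
        return float(self.n_obs - len(self.params))

    def coef_table(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov_beta))
        return pd.DataFrame({"estimate": self.params, "se": se},
                            index=self.names)

    def to_dict(self) -> dict:
        return {
            "fixed_effects": {n: {"estimate": float(b), "se": float(s)}
                              for n, b, s in zip(self.names, self.params,
                                                 np.sqrt(np.diag(self.cov_beta)))},
            "variance_components": {"site": self.tau2, "residual": self.sigma2},
            "converged": self.converged,
            "boundary_site_variance": self.boundary,
            "metadata": self.metadata,
        }


def _site_indicator(codes: np.ndarray) -> np.ndarray:
    n_sites = int(codes.max()) + 1
    Z = np.zeros((len(codes), n_sites))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


def _reml_neg2(theta: np.ndarray, y: np.ndarray, X: np.ndarray,
               Z: np.ndarray) -> float:
    """-2 x restricted log-likelihood at variance components theta=(tau2, sigma2)."""
    tau2, sigma2 = float(theta[0]), float(theta[1])
    if sigma2 <= 0:
        return np.inf
    tau2 = max(tau2, 0.0)
    V = sigma2 * np.eye(len(y)) + tau2 * (Z @ Z.T)
    sign, logdet_v = np.linalg.slogdet(V)
    if sign <= 0:
        return np.inf
    Vi = np.linalg.inv(V)
    XtVi = X.T @ Vi
    A = XtVi @ X
    sign2, logdet_a = np.linalg.slogdet(A)
    if sign2 <= 0:
        return np.inf
    beta = np.linalg.solve(A, XtVi @ y)
    r = y - X @ beta
    return float(logdet_v + logdet_a + r @ Vi @ r)


def _gls(y, X, Z, tau2, sigma2):
    V = max(sigma2, 1e-12) * np.eye(len(y)) + max(tau2, 0.0) * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    C = np.linalg.inv(X.T @ Vi @ X)
    beta = C @ X.T @ Vi @ y
    return beta, C


def _num_hessian(f, x0: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian with per-coordinate relative steps."""
    x0 = np.asarray(x0, dtype=float)
    k = len(x0)
    h = rel_step * np.maximum(np.abs(x0), 1e-3)
    H = np.zeros((k, k))
    f0 = f(x0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x0 + ei + ej) - f(x0 + ei - ej)
                    - f(x0 - ei + ej) + f(x0 - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


def _profile_reml(y: np.ndarray, X: np.ndarray, Z: np.ndarray):
    """Exact 1-D REML profile over the variance ratio gamma = tau2/sigma2.

    With V = sigma2 (I + gamma ZZ'), sigma2 profiles out in closed form
    (sigma2_hat = r'W^{-1}r / (n - p)), leaving a deterministic bounded
    scalar minimisation that is invariant to row order.
    """
    n, p = X.shape
    ZZt = Z @ Z.T
    eye = np.eye(n)

    def profiled(gamma: float) -> float:
        W = eye + gamma * ZZt
        sign, logdet_w = np.linalg.slogdet(W)
        Wi = np.linalg.inv(W)
        A = X.T @ Wi @ X
        sign2, logdet_a = np.linalg.slogdet(A)
        if sign <= 0 or sign2 <= 0:
            return np.inf
        beta = np.linalg.solve(A, X.T @ Wi @ y)
        r = y - X @ beta
        quad = r @ Wi @ r
        if quad <= 0:
            return -np.inf  # exact fit; caller handles sigma2 -> 0
        sigma2 = quad / (n - p)
        return float((n - p) * np.log(sigma2) + logdet_w + logdet_a + (n - p))

    res = optimize.minimize_scalar(profiled, bounds=(0.0, 1e7),
                                   method="bounded",
                                   options={"xatol": 1e-12})
    gamma = float(res.x)
    if profiled(0.0) <= res.fun + REML_TOL:
        gamma = 0.0
    W = eye + gamma * ZZt
    Wi = np.linalg.inv(W)
    A = X.T @ Wi @ X
    beta = np.linalg.solve(A, X.T @ Wi @ y)
    r = y - X @ beta
    sigma2 = float(max(r @ Wi @ r, 0.0) / (n - p))
    return gamma * sigma2, sigma2, bool(res.success)


def fit_lmm(table: pd.DataFrame, response: str = "pct_severe",
            ahs_col: str = "max_ahs_c_weeks", center_ahs: bool = True,
            ahs_center: float | None = None) -> LMMResult:
    """Fit the percent-severe LMM by REML with a random site intercept.

    Rows with a missing response (empty survey cells) are dropped.  The
    variance components come from an exact 1-D REML profile over the
    site-to-residual variance ratio, so the profile used by the
    Satterthwaite df is precisely the one the estimates optimise and the fit
    is deterministic (row-order invariant).  A site variance estimated at
    the zero boundary is reported explicitly (``boundary=True``) rather than
    hidden.
    """
    df = table.loc[table[response].notna()].reset_index(drop=True)
    design = build_design(df, ahs_col=ahs_col, center_ahs=center_ahs,
                          ahs_center=ahs_center)
    y = df[response].astype(float).to_numpy()
    X, codes = design.X, design.site_codes
    n_sites = len(design.site_labels)
    if n_sites < 2:
        raise ValueError("need at least two sites for a site random effect")
    if len(y) < X.shape[1] + 2:
        raise ValueError("too few cells to identify the fixed effects")
    # canonical row order: makes every downstream float operation, and hence
    # the fit, exactly invariant to the input table's row order
    order = np.lexsort((y, *X.T[::-1], codes))
    X, y, codes = X[order], y[order], codes[order]
    design.X, design.site_codes = X, codes
    Z = _site_indicator(codes)

    crit = lambda th: _reml_neg2(th, y, X, Z)
    tau2, sigma2, converged = _profile_reml(y, X, Z)
    sigma2 = max(sigma2, 0.0)
    boundary = tau2 < 1e-8 * max(sigma2, 1.0)
    if not converged:
        raise RuntimeError("REML profile optimisation did not converge")
    res_fun = crit(np.array([tau2, max(sigma2, 1e-300)]))

    beta, C = _gls(y, X, Z, tau2, sigma2)
    if boundary:
        # one-parameter profile in sigma2; tau2 pinned at its boundary
        H = _num_hessian(lambda t: crit(np.array([0.0, t[0]])),
                         np.array([sigma2]))
        theta_cov = np.zeros((2, 2))
        theta_cov[1, 1] = 2.0 / H[0, 0] if H[0, 0] > 0 else 0.0
        logger.info("LMM: site variance at the zero boundary")
    else:
        H = _num_hessian(crit, np.array([tau2, sigma2]))
        try:
            theta_cov = 2.0 * np.linalg.inv(H)
        except np.linalg.LinAlgError:
            theta_cov = np.zeros((2, 2))
    return LMMResult(
        params=beta, names=design.names, cov_beta=C, tau2=tau2, sigma2=sigma2,
        theta_cov=theta_cov, design=design, y=y,
        reml_neg2=float(res_fun), converged=converged, boundary=boundary,
        n_sites=n_sites,
        metadata={"estimation": "REML", "optimizer": "MixedLM + Nelder-Mead polish",
                  "reml_tol": REML_TOL, "ahs_center": design.ahs_center,
                  "response": response},
    )


# ---------------------------------------------------------------------------
# Satterthwaite denominator degrees of freedom
# ---------------------------------------------------------------------------

def _satterthwaite_df_1d(model: LMMResult, ell: np.ndarray) -> float:
    """Satterthwaite df for the scalar contrast ell' beta.

    df = 2 g^2 / (grad g' . Var(theta) . grad g) with
    g(theta) = ell' C(theta) ell, gradients by central differences on the
    variance-component scale.
    """
    y, X = model.y, model.design.X
    Z = _site_indicator(model.design.site_codes)
    theta = np.array([model.tau2, model.sigma2])

    def g(th):
        _, C = _gls(y, X, Z, max(th[0], 0.0), max(th[1], 1e-12))
        return float(ell @ C @ ell)

    h = 1e-4 * np.maximum(np.abs(theta), 1e-3)
    grad = np.zeros(2)
    for i in range(2):
        e = np.zeros(2); e[i] = h[i]
        lo = theta - e
        if lo[0] < 0:  # one-sided at the tau2 >= 0 boundary
            grad[i] = (g(theta + e) - g(theta)) / h[i]
        else:
            grad[i] = (g(theta + e) - g(lo)) / (2 * h[i])
    denom = float(grad @ model.theta_cov @ grad)
    g0 = g(theta)
    if denom <= 0 or not np.isfinite(denom) or g0 <= 0:
        return model.residual_df
    df = 2.0 * g0 ** 2 / denom
    return float(np.clip(df, 1.0, 1e6))


def _satterthwaite_df_multi(model: LMMResult, L: np.ndarray) -> float:
    """Multi-row Satterthwaite denominator df (eigen-decomposition method).

    Decompose L C L' = P D P', get a per-eigendirection 1-df Satterthwaite
    df, and combine: den = 2E/(E - q) with E = sum nu_i/(nu_i - 2).
    """
    C = model.cov_beta
    M = L @ C @ L.T
    q = L.shape[0]
    if q == 1:
        return _satterthwaite_df_1d(model, L[0])
    evals, P = np.linalg.eigh(M)
    keep = evals > 1e-12 * evals.max()
    rows = (P.T @ L)[keep]
    nus = np.array([_satterthwaite_df_1d(model, r) for r in rows])
    usable = nus > 2.0
    if not usable.any():
        return model.residual_df
    E = float(np.sum(nus[usable] / (nus[usable] - 2.0)))
    q_eff = int(usable.sum())
    if E <= q_eff:
        return model.residual_df
    return float(np.clip(2.0 * E / (E - q_eff), 1.0, 1e6))


def type2_wald_tests(model: LMMResult,
                     df_method: str = "satterthwaite") -> pd.DataFrame:
    """Per-term Type II Wald F tests (with the asymptotic chi-square dual).

    Each term is tested after all other terms except its higher-order
    relatives.  Denominator df: ``satterthwaite`` (default) or ``residual``;
    ``kenward-roger`` is recognised but not implemented.  The chi-square
    column is the asymptotic Wald statistic F x num_df with its chi-square
    p-value, reported alongside because both scales appear in the field.
    """
    if df_method == "kenward-roger":
        raise NotImplementedError(
            "Kenward-Roger df are not implemented; use 'satterthwaite'")
    if df_method not in ("satterthwaite", "residual"):
        raise ValueError(f"unknown df_method {df_method!r}")
    rows = []
    for term in model.design.terms:
        L = type2_contrast(model.design, term)
        q = L.shape[0]
        Lb = L @ model.params
        M = L @ model.cov_beta @ L.T
        F = float(Lb @ np.linalg.solve(M, Lb) / q)
        if df_method == "residual":
            den = model.residual_df
        else:
            den = _satterthwaite_df_multi(model, L)
        chi2 = q * F
        rows.append({
            "term": term, "F": F, "num_df": q, "den_df": den,
            "p_value": float(stats.f.sf(F, q, den)),
            "chi2": chi2, "chi2_p": float(stats.chi2.sf(chi2, q)),
            "df_method": df_method,
        })
    return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# Estimated marginal means with Tukey contrasts
# ---------------------------------------------------------------------------

@dataclass
class MarginalMeansResult:
    factor: str
    means: pd.DataFrame
    contrasts: pd.DataFrame
    at: str
    scale: str = "response"


def _emm_rows(design: Design, factor: str) -> dict[str, np.ndarray]:
    """Design row per factor level, averaging the other factor's levels
    with equal weights and holding centered AHS at 0 (the observed mean)."""
    def row(depth17: float, size: str) -> np.ndarray:
        mid = 1.0 if size == "mid" else 0.0
        large = 1.0 if size == "large" else 0.0
        return np.array([1.0, depth17, 0.0, mid, large, 0.0, 0.0])

    if factor == "size_class":
        return {s: np.mean([row(0.0, s), row(1.0, s)], axis=0)
                for s in SIZE_LEVELS}
    if factor == "depth":
        return {lbl: np.mean([row(d, s) for s in SIZE_LEVELS], axis=0)
                for lbl, d in (("10", 0.0), ("17", 1.0))}
    raise ValueError(f"factor must be 'size_class' or 'depth', got {factor!r}")


def marginal_means(model: LMMResult, factor: str = "size_class",
                   df_method: str = "satterthwaite") -> MarginalMeansResult:
    """Model-adjusted means per factor level with Tukey-adjusted contrasts.

    Levels of the other factor are averaged with equal weights and the AHS
    covariate is held at its observed mean (because the model is linear in
    AHS, evaluating at the mean and averaging over the observed values give
    identical means).  Pairwise p-values use the studentized-range (Tukey)
    adjustment at the contrast's Satterthwaite df; with k levels there are
    k(k-1)/2 contrasts.
    """
    rows = _emm_rows(model.design, factor)
    k = len(rows)
    mean_rows = []
    for level, x in rows.items():
        est = float(x @ model.params)
        se = float(np.sqrt(x @ model.cov_beta @ x))
        df = (_satterthwaite_df_1d(model, x) if df_method == "satterthwaite"
              else model.residual_df)
        mean_rows.append({"level": level, "emmean": est, "se": se, "df": df})
    means = pd.DataFrame(mean_rows).set_index("level")

    levels = list(rows)
    crows = []
    for i in range(k):
        for j in range(i + 1, k):
            ell = rows[levels[i]] - rows[levels[j]]
            est = float(ell @ model.params)
            se = float(np.sqrt(ell @ model.cov_beta @ ell))
            df = (_satterthwaite_df_1d(model, ell)
                  if df_method == "satterthwaite" else model.residual_df)
            t = est / se
            p_unadj = float(2 * stats.t.sf(abs(t), df))
            p_tukey = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df))
            crows.append({
                "contrast": f"{levels[i]} - {levels[j]}",
                "estimate": est, "se": se, "df": df, "t": t,
                "p_unadjusted": p_unadj,
                "p_tukey": min(max(p_tukey, p_unadj), 1.0),
            })
    contrasts = pd.DataFrame(crows).set_index("contrast")
    return MarginalMeansResult(factor=factor, means=means, contrasts=contrasts,
                               at="mean_ahs")


# ---------------------------------------------------------------------------
# Binomial GLMM (logit link, random site intercept, adaptive GHQ)
# ---------------------------------------------------------------------------

@dataclass
class GLMMResult:
    """ML fit of the colony-level binomial mixed model."""

    params: np.ndarray
    names: list[str]
    cov_beta: np.ndarray
    site_sd: float
    design: Design
    loglik: float
    converged: bool
    n_obs: int
    metadata: dict = field(default_factory=dict)

    def coef_table(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov_beta))
        z = self.params / se
        return pd.DataFrame({
            "estimate": self.params, "se": se, "z": z,
            "p_value": 2 * stats.norm.sf(np.abs(z)),
        }, index=self.names)

    def to_dict(self) -> dict:
        return {
            "fixed_effects": {n: {"estimate": float(b), "se": float(s)}
                              for n, b, s in zip(self.names, self.params,
                                                 np.sqrt(np.diag(self.cov_beta)))},
            "site_sd": self.site_sd,
            "loglik": self.loglik,
            "converged": self.converged,
            "metadata": self.metadata,
        }


def _aggregate_binomial(design: Design, severe: np.ndarray):
    """Collapse colonies with identical covariate rows into binomial counts.

    Colonies in the same site x depth x size cell share a linear predictor,
    so the likelihood only needs per-unique-row (successes, trials); this
    makes the fit cost independent of colony count.
    """
    df = pd.DataFrame(design.X)
    df["__site"] = design.site_codes
    df["__y"] = severe.astype(float)
    grouped = df.groupby([*range(design.X.shape[1]), "__site"], sort=True)
    agg = grouped["__y"].agg(["sum", "size"]).reset_index()
    Xa = agg[list(range(design.X.shape[1]))].to_numpy(dtype=float)
    return Xa, agg["__site"].to_numpy(int), agg["sum"].to_numpy(), agg["size"].to_numpy()


def _site_loglik_agq(eta, k, n, sigma, nodes, weights):
    """log of the integrated binomial likelihood of one site's counts.

    Adaptive Gauss-Hermite quadrature: the integrand exp(h(u)) with
    h(u) = sum_i [k_i (eta_i+u) - n_i log(1+e^{eta_i+u})] + log N(u; 0, sigma^2)
    is re-centered at its mode with the Laplace curvature as scale.
    """
    # Newton for the mode
    u = 0.0
    for _ in range(50):
        p = expit(eta + u)
        g = float(np.sum(k - n * p)) - u / sigma ** 2
        hess = -float(np.sum(n * p * (1 - p))) - 1.0 / sigma ** 2
        step = g / hess
        u -= step
        if abs(step) < 1e-10:
            break
    p = expit(eta + u)
    hess = -float(np.sum(n * p * (1 - p))) - 1.0 / sigma ** 2
    s = 1.0 / np.sqrt(-hess)
    pts = u + np.sqrt(2.0) * s * nodes
    lin = eta[:, None] + pts[None, :]
    h_vals = (np.sum(k[:, None] * lin - n[:, None] * np.logaddexp(0.0, lin), axis=0)
              - 0.5 * pts ** 2 / sigma ** 2
              - 0.5 * np.log(2 * np.pi * sigma ** 2))
    log_terms = h_vals + nodes ** 2 + np.log(weights)
    return float(np.log(np.sqrt(2.0) * s) + logsumexp(log_terms))


def fit_glmm_binomial(records: pd.DataFrame, response: str = "severe",
                      ahs_col: str = "max_ahs_c_weeks",
                      center_ahs: bool = True,
                      ahs_center: float | None = None,
                      quad_points: int = GLMM_QUAD_POINTS) -> GLMMResult:
    """Logit-link binomial mixed model on per-colony severe indicators.

    Same fixed effects and random site intercept as the LMM; maximum
    likelihood with per-site adaptive Gauss-Hermite quadrature (the nAGQ
    approach).  The response column may be 0/1 per colony; if absent it is
    derived from pct_bleached + pct_dead >= 75.  Errors on a single outcome
    class and on (quasi-)complete separation.
    """
    df = records.copy()
    if response not in df.columns:
        from .survey_processing import classify_severe
        df[response] = classify_severe(df["pct_bleached"].to_numpy(),
                                       df["pct_dead"].to_numpy())
    y = df[response].astype(float).to_numpy()
    if y.min() == y.max():
        raise ValueError("single outcome class: every colony has the same severity")
    design = build_design(df, ahs_col=ahs_col, center_ahs=center_ahs,
                          ahs_center=ahs_center)
    if len(design.site_labels) < 2:
        raise ValueError("need at least two sites for a site random effect")
    Xa, site_a, k_a, n_a = _aggregate_binomial(design, y)
    n_sites = len(design.site_labels)
    nodes, weights = hermgauss(quad_points)
    p_fix = design.X.shape[1]

    def nll(theta):
        beta, log_sd = theta[:p_fix], theta[p_fix]
        sigma = np.exp(np.clip(log_sd, -8.0, 4.0))
        eta = Xa @ beta
        total = 0.0
        for s in range(n_sites):
            m = site_a == s
            total += _site_loglik_agq(eta[m], k_a[m], n_a[m], sigma,
                                      nodes, weights)
        return -total

    try:
        glm_start = sm.GLM(np.column_stack([k_a, n_a - k_a]), Xa,
                           family=sm.families.Binomial()).fit()
        beta0 = np.clip(glm_start.params, -10.0, 10.0)
    except Exception:  # e.g. perfect separation in the fixed-effects start
        beta0 = np.zeros(p_fix)
    x0 = np.concatenate([beta0, [np.log(0.3)]])
    res = optimize.minimize(nll, x0, method="BFGS",
                            options={"gtol": 1e-6, "maxiter": 500})
    if not res.success:  # one polish pass; BFGS on numerical grads can stall
        res = optimize.minimize(nll, res.x, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-8,
                                         "maxiter": 5000})
    beta = res.x[:p_fix]
    if np.abs(beta).max() > 15.0:
        worst = design.names[int(np.abs(beta).argmax())]
        raise RuntimeError(
            f"apparent complete separation: coefficient for {worst} diverged")
    H = _num_hessian(nll, res.x, rel_step=1e-4)
    try:
        cov_beta = np.linalg.inv(H)[:p_fix, :p_fix]
    except np.linalg.LinAlgError:
        cov_beta = np.linalg.pinv(H)[:p_fix, :p_fix]
    if np.any(np.diag(cov_beta) <= 0):
        # flat log-sd direction (site SD at ~0): condition on it and use the
        # fixed-effects block alone, which is the GLM information
        try:
            cov_beta = np.linalg.inv(H[:p_fix, :p_fix])
        except np.linalg.LinAlgError as err:
            raise RuntimeError("singular information matrix in GLMM fit") from err
    if np.any(np.diag(cov_beta) <= 0):
        raise RuntimeError("non-positive coefficient variance in GLMM fit")
    sigma = float(np.exp(res.x[p_fix]))
    return GLMMResult(
        params=beta, names=design.names, cov_beta=cov_beta, site_sd=sigma,
        design=design, loglik=float(-res.fun), converged=bool(res.success),
        n_obs=len(y),
        metadata={"estimation": "ML (adaptive Gauss-Hermite, "
                                f"{quad_points} nodes)",
                  "ahs_center": design.ahs_center},
    )


def glmm_wald_tests(model: GLMMResult) -> pd.DataFrame:
    """Per-term Type II Wald chi-square tests for the GLMM."""
    rows = []
    for term in model.design.terms:
        L = type2_contrast(model.design, term)
        q = L.shape[0]
        Lb = L @ model.params
        M = L @ model.cov_beta @ L.T
        chi2 = float(Lb @ np.linalg.solve(M, Lb))
        rows.append({"term": term, "chi2": chi2, "df": q,
                     "p_value": float(stats.chi2.sf(chi2, q))})
    return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# LMM / GLMM qualitative agreement
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    """Sign and significance concordance between the LMM and GLMM paths.

    ``sign_agreement`` is computed over all non-intercept coefficients;
    ``resolved_sign_agreement`` restricts to coefficients that at least one
    path distinguishes from zero at ``alpha`` (the sign of a coefficient
    neither model can resolve is sampling noise, not a qualitative
    disagreement).
    """

    effects: pd.DataFrame
    terms: pd.DataFrame
    sign_agreement: float
    resolved_sign_agreement: float
    significance_agreement: float
    alpha: float

    @property
    def agree(self) -> bool:
        return (self.resolved_sign_agreement == 1.0
                and self.significance_agreement == 1.0)


def qualitative_agreement(lmm: LMMResult, glmm: GLMMResult,
                          alpha: float = 0.05,
                          lmm_df_method: str = "satterthwaite") -> AgreementReport:
    """Compare effect signs and per-term significance across model paths.

    The LMM works on the percent scale and the GLMM on the logit scale, so
    magnitudes are not comparable but signs and test outcomes are; the
    report records, per non-intercept coefficient, whether the signs match
    and whether either path resolves it from zero, and per model term
    whether Type II significance at ``alpha`` matches.
    """
    names = [n for n in lmm.names if n != "Intercept"]
    idx = [lmm.names.index(n) for n in names]
    lmm_se = np.sqrt(np.diag(lmm.cov_beta))[idx]
    glmm_se = np.sqrt(np.diag(glmm.cov_beta))[idx]
    zcrit = stats.norm.ppf(1 - alpha / 2)
    eff = pd.DataFrame({
        "lmm_estimate": lmm.params[idx],
        "glmm_estimate": glmm.params[idx],
    }, index=names)
    eff["sign_match"] = np.sign(eff["lmm_estimate"]) == np.sign(eff["glmm_estimate"])
    eff["resolved"] = (np.abs(eff["lmm_estimate"] / lmm_se) > zcrit) | \
                      (np.abs(eff["glmm_estimate"] / glmm_se) > zcrit)
    lmm_tests = type2_wald_tests(lmm, df_method=lmm_df_method)
    glmm_tests = glmm_wald_tests(glmm)
    terms = pd.DataFrame({
        "lmm_p": lmm_tests["p_value"],
        "glmm_p": glmm_tests["p_value"],
    })
    terms["significance_match"] = (terms["lmm_p"] < alpha) == (terms["glmm_p"] < alpha)
    resolved = eff.loc[eff["resolved"], "sign_match"]
    return AgreementReport(
        effects=eff, terms=terms,
        sign_agreement=float(eff["sign_match"].mean()),
        resolved_sign_agreement=float(resolved.mean()) if len(resolved) else 1.0,
        significance_agreement=float(terms["significance_match"].mean()),
        alpha=alpha,
    )
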