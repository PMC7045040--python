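"""Constrained pooled estimation of the seasonal-AR habit model.

The model ladder
----------------
* **M1** — multilevel: fixed seasonal-AR + weekday structure with random
  coefficients (intercept, lag 1, lag 7) and level-2 gender/age terms.
* **M2** — fixed (pooled) model: intercept, lags {1, 2, 7, ..., 56},
  six weekday dummies (Sunday reference), with the substantive
  constraints below.
* **M3** — M2 without the weekday dummies.
* **M0** — the zero-covariance null of the same variable set (baseline
  for incremental fit indices).

Constraints (each independently toggleable):

1. *Order*: the non-seasonal chain b_1 >= b_2 >= 0 and the seasonal
   chain b_7 >= b_14 >= ... >= b_56 >= 0 — the longer ago, the weaker
   the effect, and all effects non-negative.
2. *Equal variances* of all lagged predictors (they are lags of one and
   the same variable).
3. *Covariances by distance*: Cov(lag_j, lag_k) depends only on the day
   distance |j - k| (a Toeplitz-by-distance structure).

Estimation is Gaussian maximum likelihood of the joint mean and
covariance structure of (response, lags), with the weekday dummies as
fixed regressors.  The joint likelihood factorises exactly into the
conditional regression block (order-constrained least squares, solved
as a bounded least-squares problem on the non-negative increment
reparameterisation of each coefficient chain) and the marginal
covariance block of the lags (structured ML, quasi-Newton on the
discrepancy log|Sigma| + tr(S Sigma^-1)).  With every constraint
disabled the solution coincides with ordinary least squares and the
sample covariance matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .transform import LagDesign, LagSpec

__all__ = [
    "ConstraintSpec",
    "ModelSpec",
    "FitResult",
    "FitIndices",
    "model_m0",
    "model_m1",
    "model_m2",
    "model_m3",
    "fit_pooled",
    "fit_multilevel",
    "fit_indices",
    "nested_chi2_test",
]


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConstraintSpec:
    order_nonseasonal: bool = True
    order_seasonal: bool = True
    equal_variances: bool = True
    covariances_by_distance: bool = True

    @classmethod
    def none(cls) -> "ConstraintSpec":
        return cls(False, False, False, False)

    @property
    def any_covariance(self) -> bool:
        return self.equal_variances or self.covariances_by_distance


@dataclass(frozen=True)
class ModelSpec:
    name: str = "M2"
    lag_spec: LagSpec = field(default_factory=LagSpec)
    include_lags: bool = True
    include_weekday: bool = True
    constraints: ConstraintSpec = field(default_factory=ConstraintSpec)
    random_effects: tuple[str, ...] = ()
    level2: tuple[str, ...] = ()
    baseline: bool = False

    def terms(self) -> frozenset:
        out = {"intercept"}
        if self.include_lags and not self.baseline:
            out |= {f"lag_{k}" for k in self.lag_spec.lags}
        if self.include_weekday and not self.baseline:
            out |= {"d_mon", "d_tue", "d_wed", "d_thu", "d_fri", "d_sat"}
        out |= set(self.level2) if not self.baseline else set()
        return frozenset(out)


def model_m2(lag_spec: LagSpec | None = None, constraints: ConstraintSpec | None = None) -> ModelSpec:
    """The accepted fixed model: lags + weekday dummies, all constraints on."""
    return ModelSpec(
        name="M2",
        lag_spec=lag_spec or LagSpec(),
        constraints=constraints or ConstraintSpec(),
    )


def model_m3(lag_spec: LagSpec | None = None, constraints: ConstraintSpec | None = None) -> ModelSpec:
    """M2 without the day-of-week terms (intercept + lags only)."""
    return replace(model_m2(lag_spec, constraints), name="M3", include_weekday=False)


def model_m0(lag_spec: LagSpec | None = None) -> ModelSpec:
    """Zero-covariance null of the M2 variable set."""
    return ModelSpec(name="M0", lag_spec=lag_spec or LagSpec(), baseline=True)


def model_m1(lag_spec: LagSpec | None = None) -> ModelSpec:
    """The full multilevel hypothesis: random intercept and random
    slopes for lags 1 and 7, plus level-2 gender and age terms."""
    return replace(
        model_m2(lag_spec),
        name="M1",
        random_effects=("intercept", "lag_1", "lag_7"),
        level2=("gender", "age"),
    )


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitIndices:
    chi2: float
    df: int
    pvalue: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    cfi: float
    tli: float
    srmr: float

    def as_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "df": self.df,
            "p": self.pvalue,
            "rmsea": self.rmsea,
            "rmsea_ci": list(self.rmsea_ci),
            "cfi": self.cfi,
            "tli": self.tli,
            "srmr": self.srmr,
        }


@dataclass
class FitResult:
    model: str
    params: pd.DataFrame  # index term; estimate, se, t, p, std, one_sided
    loglik: float
    loglik_saturated: float
    n: int
    n_free_params: int
    n_moments: int
    indices: FitIndices | None
    aic: float
    r2: float
    converged: bool
    terms: frozenset
    row_key: int
    residuals: pd.DataFrame | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def chi2(self) -> float:
        return self.indices.chi2 if self.indices else float("nan")

    @property
    def df(self) -> int:
        return self.indices.df if self.indices else 0

    def coef(self, term: str) -> float:
        return float(self.params.loc[term, "estimate"])

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params.reset_index().to_dict(orient="records"),
            "loglik": self.loglik,
            "n": self.n,
            "n_free_params": self.n_free_params,
            "indices": self.indices.as_dict() if self.indices else None,
            "aic": self.aic,
            "r2": self.r2,
            "converged": self.converged,
            "diagnostics": {
                k: v for k, v in self.diagnostics.items() if np.isscalar(v) or isinstance(v, (list, str, bool, dict))
            },
        }


class RankDeficientDesignError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Mean block: order-constrained least squares
# ---------------------------------------------------------------------------


def _chain_matrix(m: int) -> np.ndarray:
    """b = C e with e >= 0 enforcing b_1 >= b_2 >= ... >= b_m >= 0.

    e_i is the increment between consecutive chain members, e_m the
    floor above zero: b_i = sum_{j>=i} e_j.
    """
    return np.triu(np.ones((m, m)))


def _design_matrices(design: LagDesign, spec: ModelSpec, subjects: pd.DataFrame | None):
    """Assemble (y, fixed part W + names, lag part X + names)."""
    frame = design.frame
    y = design.response()
    w_cols: list[np.ndarray] = [np.ones(len(frame))]
    w_names = ["intercept"]
    if spec.include_weekday and not spec.baseline:
        for c in design.dummy_columns:
            w_cols.append(frame[c].to_numpy(float))
            w_names.append(c)
    if spec.level2 and not spec.baseline:
        if subjects is None:
            raise ValueError("level-2 terms requested but no subject table supplied")
        for c in spec.level2:
            v = frame["subject_id"].map(subjects[c])
            if c == "gender":
                v = (v.astype(str).str.upper().str[0] == "M").astype(float)
            w_cols.append(v.to_numpy(float))
            w_names.append(c)
    W = np.column_stack(w_cols)
    if spec.include_lags and not spec.baseline:
        X = design.lag_matrix()
        x_names = design.lag_columns
    else:
        X = np.empty((len(frame), 0))
        x_names = []
    return y, W, w_names, X, x_names


def _constrained_regression(y, W, X, lag_spec: LagSpec, cons: ConstraintSpec):
    """Order-constrained Gaussian ML of the regression block.

    Returns (gamma, b, fitted, psi_ml, active_constraints).
    """
    n = len(y)
    lags = list(lag_spec.lags) if X.shape[1] else []
    ns = [k for k in lags if k in lag_spec.nonseasonal]
    se = [k for k in lags if k not in lag_spec.nonseasonal]
    order = ns + se  # chain order: each chain descending in coefficient
    perm = [lags.index(k) for k in order]
    Xo = X[:, perm] if X.shape[1] else X

    blocks = []
    lb = []
    if X.shape[1]:
        if cons.order_nonseasonal and ns:
            blocks.append(_chain_matrix(len(ns)))
            lb += [0.0] * len(ns)
        else:
            blocks.append(np.eye(len(ns)))
            lb += [-np.inf] * len(ns)
        if cons.order_seasonal and se:
            blocks.append(_chain_matrix(len(se)))
            lb += [0.0] * len(se)
        else:
            blocks.append(np.eye(len(se)))
            lb += [-np.inf] * len(se)
    if blocks:
        C = np.block(
            [
                [blocks[0], np.zeros((blocks[0].shape[0], blocks[1].shape[1]))],
                [np.zeros((blocks[1].shape[0], blocks[0].shape[1])), blocks[1]],
            ]
        )
    else:
        C = np.empty((0, 0))

    A = np.column_stack([W, Xo @ C]) if C.size else W
    if np.linalg.matrix_rank(A) < A.shape[1]:
        # name the collinear columns for the error message
        _, R = np.linalg.qr(A)
        bad = [int(i) for i in np.where(np.abs(np.diag(R)) < 1e-10)[0]]
        raise RankDeficientDesignError(f"rank-deficient design; collinear columns at {bad}")
    bounds_lo = np.concatenate([np.full(W.shape[1], -np.inf), np.array(lb)])
    if np.all(np.isinf(bounds_lo)):
        theta, *_ = np.linalg.lstsq(A, y, rcond=None)
    else:
        res = optimize.lsq_linear(A, y, bounds=(bounds_lo, np.full(A.shape[1], np.inf)), method="bvls")
        theta = res.x
    gamma = theta[: W.shape[1]]
    e = theta[W.shape[1] :]
    b_ordered = C @ e if C.size else np.empty(0)
    # undo the chain permutation
    b = np.empty_like(b_ordered)
    for i, k in enumerate(order):
        b[lags.index(k)] = b_ordered[i]
    fitted = A @ theta
    resid = y - fitted
    psi = float(resid @ resid) / n
    active = [f"e[{i}]" for i, v in enumerate(e) if np.isfinite(lb[i] if i < len(lb) else -np.inf) and v < 1e-10]
    return gamma, b, fitted, resid, psi, active


# ---------------------------------------------------------------------------
# Covariance block: structured ML for the lag block
# ---------------------------------------------------------------------------


def _covariance_classes(lags: list[int], cons: ConstraintSpec):
    """Map each unique (i <= j) entry of the lag covariance matrix to a
    parameter class index; returns (classes matrix, n_params, kinds)."""
    q = len(lags)
    classes = -np.ones((q, q), dtype=int)
    kinds: list[str] = []
    if cons.equal_variances:
        v_idx = {None: 0}
        kinds.append("var")
        for i in range(q):
            classes[i, i] = 0
    else:
        for i in range(q):
            classes[i, i] = len(kinds)
            kinds.append(f"var_{lags[i]}")
    dist_map: dict[int, int] = {}
    for i in range(q):
        for j in range(i + 1, q):
            if cons.covariances_by_distance:
                d = abs(lags[i] - lags[j])
                if d not in dist_map:
                    dist_map[d] = len(kinds)
                    kinds.append(f"cov_d{d}")
                c = dist_map[d]
            else:
                c = len(kinds)
                kinds.append(f"cov_{lags[i]}_{lags[j]}")
            classes[i, j] = classes[j, i] = c
    return classes, len(kinds), kinds


def _sigma_from_theta(theta, classes):
    return theta[classes]


def _fit_structured_cov(S: np.ndarray, lags: list[int], cons: ConstraintSpec):
    """Minimise log|Sigma| + tr(S Sigma^-1) over the structured classes."""
    classes, n_par, kinds = _covariance_classes(lags, cons)
    q = S.shape[0]
    # start: class means of the sample covariance (the LS projection)
    theta0 = np.zeros(n_par)
    counts = np.zeros(n_par)
    for i in range(q):
        for j in range(q):
            theta0[classes[i, j]] += S[i, j]
            counts[classes[i, j]] += 1
    theta0 /= counts

    def f_and_grad(theta):
        Sigma = _sigma_from_theta(theta, classes)
        try:
            L = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError:
            w, V = np.linalg.eigh(Sigma)
            v = V[:, 0]
            grad = np.zeros(n_par)
            outer = np.outer(v, v)
            for c in range(n_par):
                grad[c] = -1e3 * outer[classes == c].sum()
            return 1e6 + 1e3 * max(0.0, -float(w[0])), grad
        Sinv = np.linalg.inv(Sigma)
        f = 2.0 * float(np.log(np.diag(L)).sum()) + float(np.sum(Sinv * S))
        G = Sinv - Sinv @ S @ Sinv  # dF/dSigma
        grad = np.zeros(n_par)
        for c in range(n_par):
            grad[c] = G[classes == c].sum()
        return f, grad

    res = optimize.minimize(
        f_and_grad, theta0, jac=True, method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
    )
    Sigma = _sigma_from_theta(res.x, classes)
    return Sigma, n_par, kinds, res


def _gauss_cov_loglik(S: np.ndarray, Sigma: np.ndarray, n: int) -> float:
    """Log-likelihood of n iid draws with sample (ML) covariance S and
    sample means exactly at the fitted means, under covariance Sigma."""
    q = S.shape[0]
    if q == 0:
        return 0.0
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return -np.inf
    return -0.5 * n * (q * np.log(2 * np.pi) + logdet + float(np.trace(np.linalg.solve(Sigma, S))))


# ---------------------------------------------------------------------------
# Fit indices
# ---------------------------------------------------------------------------


def _rmsea_ci(chi2: float, df: int, n: int, level: float = 0.90) -> tuple[float, float]:
    """Noncentral-chi2 inversion CI for RMSEA."""
    if df <= 0 or not np.isfinite(chi2):
        return (float("nan"), float("nan"))
    alpha = (1.0 - level) / 2.0

    def lam_for(prob):
        # find lambda with ncx2.cdf(chi2, df, lam) == prob
        f = lambda lam: stats.ncx2.cdf(chi2, df, lam) - prob
        if f(0.0) < 0:
            return 0.0
        hi = max(chi2, 1.0)
        while f(hi) > 0:
            hi *= 2.0
            if hi > 1e8:
                return hi
        return optimize.brentq(f, 0.0, hi, xtol=1e-8)

    lo = lam_for(1.0 - alpha)
    hi = lam_for(alpha)
    return (float(np.sqrt(lo / (df * n))), float(np.sqrt(hi / (df * n))))


def _incremental_indices(chi2, df, chi2_b, df_b):
    d = max(chi2 - df, 0.0)
    d_b = max(chi2_b - df_b, 0.0)
    cfi = 1.0 - d / max(d_b, d, np.finfo(float).tiny)
    if df > 0 and df_b > 0 and chi2_b / df_b > 1.0:
        tli = ((chi2_b / df_b) - (chi2 / df)) / ((chi2_b / df_b) - 1.0)
    else:
        tli = float("nan")
    return cfi, tli


def _srmr(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Root mean squared standardised residual over the unique moments."""
    d = np.sqrt(np.diag(S))
    scale = np.outer(d, d)
    R = (S - Sigma) / scale
    iu = np.triu_indices_from(R)
    return float(np.sqrt(np.mean(R[iu] ** 2)))


def fit_indices(
    result: "FitResult", loglik_saturated: float, baseline: "FitResult"
) -> FitIndices:
    """Recompute the overall fit indices of ``result`` against a
    saturated log-likelihood and a zero-covariance baseline fit.

    chi2 = 2(ll_sat - ll_model); df = observed moments - free
    parameters; RMSEA = sqrt(max(0, chi2 - df) / (df n)) with its 90%
    CI from the noncentral-chi2 inversion; CFI/TLI from model and
    baseline (chi2, df); SRMR from the stored moment residuals.
    """
    chi2 = 2.0 * (loglik_saturated - result.loglik)
    df = result.n_moments - result.n_free_params
    if df == 0 and abs(chi2) < 1e-6:
        # saturated boundary: perfect fit by construction
        return FitIndices(
            chi2=0.0, df=0, pvalue=float("nan"), rmsea=0.0, rmsea_ci=(0.0, 0.0),
            cfi=1.0, tli=float("nan"), srmr=float(result.diagnostics.get("srmr", 0.0)),
        )
    if df <= 0:
        raise ValueError("df <= 0: fit indices undefined")
    chi2_b = 2.0 * (loglik_saturated - baseline.loglik)
    df_b = baseline.n_moments - baseline.n_free_params
    cfi, tli = _incremental_indices(chi2, df, chi2_b, df_b)
    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * result.n)))
    srmr = result.diagnostics.get("srmr", float("nan"))
    return FitIndices(
        chi2=float(chi2),
        df=int(df),
        pvalue=float(stats.chi2.sf(chi2, df)) if chi2 >= 0 else float("nan"),
        rmsea=rmsea,
        rmsea_ci=_rmsea_ci(chi2, df, result.n),
        cfi=float(cfi),
        tli=float(tli),
        srmr=float(srmr),
    )


# ---------------------------------------------------------------------------
# Pooled (fixed) fit
# ---------------------------------------------------------------------------


def _row_key(frame: pd.DataFrame) -> int:
    return int(
        pd.util.hash_pandas_object(
            frame[["subject_id", "t"]].astype(str).agg("|".join, axis=1)
        ).sum()
        % (2**63)
    )


def _saturated_loglik(design: LagDesign, subjects, level2: tuple[str, ...]):
    """Unconstrained regression on the full term set + free covariance."""
    spec = ModelSpec(
        name="saturated",
        lag_spec=design.lag_spec,
        constraints=ConstraintSpec.none(),
        level2=level2,
    )
    y, W, w_names, X, x_names = _design_matrices(design, spec, subjects)
    A = np.column_stack([W, X])
    theta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ theta
    n = len(y)
    psi = float(resid @ resid) / n
    ll_cond = -0.5 * n * (np.log(2 * np.pi * psi) + 1.0)
    Xc = X - X.mean(axis=0)
    S = (Xc.T @ Xc) / n
    ll_x = _gauss_cov_loglik(S, S, n)
    return ll_cond + ll_x, S


def fit_pooled(
    design: LagDesign, spec: ModelSpec | None = None, subjects: pd.DataFrame | None = None
) -> FitResult:
    """Fit a fixed (no random effects) model of the ladder by Gaussian ML.

    Coefficient chains are estimated under the non-negative-increment
    reparameterisation of the order constraints; the lag covariance
    block under the equal-variance / distance-Toeplitz structure.
    Standard errors come from the observed information of the
    unconstrained parameterisation evaluated at the constrained
    solution (delta method through the invertible chain map); p-values
    are one-sided for sign-constrained lag terms, two-sided otherwise.
    """
    if spec is None:
        spec = model_m2()
    if spec.random_effects:
        raise ValueError("fit_pooled handles fixed models; use fit_multilevel")
    frame = design.frame
    n = len(frame)
    y, W, w_names, X, x_names = _design_matrices(design, spec, subjects)
    n_terms = W.shape[1] + X.shape[1]
    if n <= n_terms:
        raise ValueError("design has fewer rows than free parameters")

    cons = spec.constraints if not spec.baseline else ConstraintSpec.none()
    if spec.baseline:
        gamma = np.array([y.mean()])
        b = np.empty(0)
        fitted = np.full(n, y.mean())
        resid = y - fitted
        psi = float(resid @ resid) / n
        active: list[str] = []
    else:
        gamma, b, fitted, resid, psi, active = _constrained_regression(
            y, W, X, spec.lag_spec, cons
        )
    ll_cond = -0.5 * n * (np.log(2 * np.pi * psi) + 1.0)

    # covariance block over the full lag set (shared across the ladder)
    full_lags = list(design.lag_spec.lags)
    Xfull = design.lag_matrix()
    Xc = Xfull - Xfull.mean(axis=0)
    S = (Xc.T @ Xc) / n
    cov_diag: dict = {}
    if spec.baseline:
        Sigma = np.diag(np.diag(S))
        n_cov_par = len(full_lags)
        kinds = [f"var_{k}" for k in full_lags]
    elif cons.any_covariance:
        Sigma, n_cov_par, kinds, cov_res = _fit_structured_cov(S, full_lags, cons)
        cov_diag = {"cov_converged": bool(cov_res.success), "cov_message": str(cov_res.message)}
    else:
        Sigma = S.copy()
        n_cov_par = len(full_lags) * (len(full_lags) + 1) // 2
        kinds = []
    ll_x = _gauss_cov_loglik(S, Sigma, n)
    loglik = ll_cond + ll_x

    # ---- parameter table --------------------------------------------------
    if spec.baseline:
        M = np.ones((n, 1))
        names = ["intercept"]
        est = gamma
    else:
        M = np.column_stack([W, X])
        names = w_names + x_names
        est = np.concatenate([gamma, b])
    XtX = M.T @ M
    cov_est = psi * np.linalg.pinv(XtX)
    se = np.sqrt(np.maximum(np.diag(cov_est), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, est / se, np.nan)
    sd_y = float(np.std(y))
    rows = []
    for i, name in enumerate(names):
        sd_x = float(np.std(M[:, i]))
        std = est[i] * sd_x / sd_y if sd_y > 0 else np.nan
        one_sided = name.startswith("lag_") and (
            (cons.order_nonseasonal and int(name[4:]) in spec.lag_spec.nonseasonal)
            or (cons.order_seasonal and int(name[4:]) not in spec.lag_spec.nonseasonal)
        )
        if np.isnan(tval[i]):
            p = np.nan
        elif one_sided:
            p = float(stats.norm.sf(tval[i]))
        else:
            p = float(2 * stats.norm.sf(abs(tval[i])))
        rows.append((name, est[i], se[i], tval[i], p, std, one_sided))
    params = pd.DataFrame(
        rows, columns=["term", "estimate", "se", "t", "p", "std", "one_sided"]
    ).set_index("term")

    # ---- moment bookkeeping ----------------------------------------------
    q = len(full_lags)
    qz = q + 1
    n_l2 = len(spec.level2) if not spec.baseline else 0
    n_moments = qz * (qz + 1) // 2 + qz + 6 + n_l2
    if spec.baseline:
        n_free = 2 + 2 * q  # means + variances, everything uncorrelated
    else:
        n_free = len(names) + 1 + q + n_cov_par  # mean part + psi + mu_x + cov block
    # implied moments on the dummy-partialled scale for SRMR
    if spec.baseline:
        y_tilde = y - y.mean()
        implied_xy = np.zeros(q)
        implied_yy = psi
    else:
        y_tilde = resid + (X @ b if X.shape[1] else 0.0)
        y_tilde = y_tilde - y_tilde.mean()
        b_full = np.zeros(q)
        for i, nm in enumerate(x_names):
            b_full[full_lags.index(int(nm[4:]))] = b[i]
        implied_xy = Sigma @ b_full
        implied_yy = float(b_full @ Sigma @ b_full) + psi
    S_z = np.empty((qz, qz))
    S_z[1:, 1:] = (Xc.T @ Xc) / n
    S_z[0, 0] = float(y_tilde @ y_tilde) / n
    S_z[0, 1:] = S_z[1:, 0] = (Xc.T @ y_tilde) / n
    Sigma_z = np.empty((qz, qz))
    Sigma_z[1:, 1:] = Sigma
    Sigma_z[0, 0] = implied_yy
    Sigma_z[0, 1:] = Sigma_z[1:, 0] = implied_xy
    srmr = _srmr(S_z, Sigma_z)

    ll_sat, _ = _saturated_loglik(design, subjects, spec.level2)

    diagnostics = {
        "active_constraints": active,
        "psi": psi,
        "srmr": srmr,
        "cov_param_kinds": kinds,
        **cov_diag,
    }
    resid_frame = frame[["subject_id", "t", "weekday"]].copy()
    resid_frame["value"] = resid
    result = FitResult(
        model=spec.name,
        params=params,
        loglik=float(loglik),
        loglik_saturated=float(ll_sat),
        n=n,
        n_free_params=n_free,
        n_moments=n_moments,
        indices=None,
        aic=float(-2 * loglik + 2 * n_free),
        r2=float(1.0 - psi / max(np.var(y), np.finfo(float).tiny)),
        converged=bool(cov_diag.get("cov_converged", True)),
        terms=spec.terms(),
        row_key=_row_key(frame),
        residuals=resid_frame,
        diagnostics=diagnostics,
    )
    if spec.baseline:
        chi2_b = 2.0 * (ll_sat - loglik)
        df_b = n_moments - n_free
        result.indices = FitIndices(
            chi2=float(chi2_b),
            df=int(df_b),
            pvalue=float(stats.chi2.sf(chi2_b, df_b)),
            rmsea=float(np.sqrt(max(chi2_b - df_b, 0.0) / (df_b * n))),
            rmsea_ci=_rmsea_ci(chi2_b, df_b, n),
            cfi=0.0,
            tli=0.0,
            srmr=float(srmr),
        )
    else:
        baseline = fit_pooled(design, model_m0(design.lag_spec), subjects=None)
        try:
            result.indices = fit_indices(result, ll_sat, baseline)
        except ValueError:
            # e.g. inequality-only models: df = 0 but chi2 > 0
            result.indices = None
            result.diagnostics["indices_note"] = "undefined (df <= 0)"
    return result


# ---------------------------------------------------------------------------
# Multilevel fit
# ---------------------------------------------------------------------------


def fit_multilevel(
    design: LagDesign, spec: ModelSpec | None = None, subjects: pd.DataFrame | None = None,
    maxiter: int = 500,
) -> FitResult:
    """Random-coefficient (mixed) Gaussian model, estimated by ML.

    Returns a FitResult whose ``converged`` flag and boundary-variance
    diagnostics make non-convergence a reportable outcome rather than
    an exception; a zero or boundary random-effect variance is flagged
    as "degenerate — collapses to fixed model".
    """
    import statsmodels.api as sm

    if spec is None:
        spec = model_m1()
    if not spec.random_effects:
        raise ValueError("spec has no random effects; use fit_pooled")
    if design.frame["subject_id"].nunique() < 2:
        raise ValueError("multilevel fit requires at least 2 subjects")
    y, W, w_names, X, x_names = _design_matrices(design, spec, subjects)
    exog = np.column_stack([W, X])
    names = w_names + x_names
    re_cols = []
    re_names = []
    for r in spec.random_effects:
        if r == "intercept":
            re_cols.append(np.ones(len(y)))
        else:
            re_cols.append(X[:, x_names.index(r)])
        re_names.append(r)
    exog_re = np.column_stack(re_cols)
    groups = design.frame["subject_id"].to_numpy()

    best = None
    attempts = []
    for method in ("lbfgs", "bfgs", "cg"):  # multi-start via distinct optimisers
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(y, exog, groups=groups, exog_re=exog_re)
                res = model.fit(reml=False, maxiter=maxiter, method=method)
            attempts.append((method, bool(res.converged), float(res.llf)))

            def _rank(r):
                # a non-finite llf is a degenerate optimiser exit, never preferred
                return (np.isfinite(r.llf), bool(r.converged), r.llf if np.isfinite(r.llf) else -np.inf)

            if best is None or _rank(res) > _rank(best[1]):
                best = (method, res)
        except Exception as exc:  # singular random-effects covariance etc.
            attempts.append((method, False, str(exc)))
    if best is None:
        raise RuntimeError(f"all multilevel optimisers failed: {attempts}")
    res = best[1]
    k_fix = exog.shape[1]
    fe = np.asarray(res.fe_params)
    se = np.asarray(res.bse[:k_fix])
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, fe / se, np.nan)
    pvals = 2 * stats.norm.sf(np.abs(tval))
    sd_y = float(np.std(y))
    rows = []
    for i, name in enumerate(names):
        sd_x = float(np.std(exog[:, i]))
        rows.append((name, fe[i], se[i], tval[i], pvals[i], fe[i] * sd_x / sd_y, False))
    params = pd.DataFrame(
        rows, columns=["term", "estimate", "se", "t", "p", "std", "one_sided"]
    ).set_index("term")
    re_var = np.diag(np.asarray(res.cov_re))
    scale = float(res.scale)
    boundary = [re_names[i] for i, v in enumerate(re_var) if v < 1e-3 * scale]
    n_re_par = exog_re.shape[1] * (exog_re.shape[1] + 1) // 2
    n_free = k_fix + 1 + n_re_par
    loglik = float(res.llf)
    resid_frame = design.frame[["subject_id", "t", "weekday"]].copy()
    resid_frame["value"] = y - exog @ fe
    return FitResult(
        model=spec.name,
        params=params,
        loglik=loglik,
        loglik_saturated=float("nan"),
        n=len(y),
        n_free_params=n_free,
        n_moments=0,
        indices=None,
        aic=float(-2 * loglik + 2 * n_free),
        r2=float(1.0 - scale / max(np.var(y), np.finfo(float).tiny)),
        converged=bool(res.converged),
        terms=spec.terms(),
        row_key=_row_key(design.frame),
        residuals=resid_frame,
        diagnostics={
            "optimizer": best[0],
            "attempts": [list(map(str, a)) for a in attempts],
            "random_effect_variances": dict(zip(re_names, re_var.tolist())),
            "residual_variance": scale,
            "boundary_random_effects": boundary,
            "degenerate": "collapses to fixed model" if len(boundary) == len(re_names) else "",
        },
    )


# ---------------------------------------------------------------------------
# Nested comparison
# ---------------------------------------------------------------------------


def nested_chi2_test(restricted: FitResult, full: FitResult) -> tuple[float, int, float]:
    """Chi-square difference test for nested fits on identical rows.

    Returns (delta_chi2, delta_df, p).  Refuses non-nested term sets
    and mismatched analysis rows.
    """
    if restricted.row_key != full.row_key or restricted.n != full.n:
        raise ValueError("nested comparison requires identical analysis rows")
    if not restricted.terms <= full.terms:
        raise ValueError(
            f"models are not nested: {sorted(restricted.terms - full.terms)} "
            "appear only in the restricted model"
        )
    d_chi2 = restricted.chi2 - full.chi2
    d_df = restricted.df - full.df
    if d_df == 0:
        return (float(d_chi2), 0, 1.0)
    p = float(stats.chi2.sf(max(d_chi2, 0.0), d_df))
    return (float(d_chi2), int(d_df), p)
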