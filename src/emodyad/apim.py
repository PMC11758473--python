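"""Bivariate actor-partner interdependence model (APIM) estimation.

Each dyad contributes two outcomes (adolescent symptom, caregiver
symptom), both regressed on the same six dyad-level terms: each member's
mean emotion, emodiversity, and their product (interaction), for one
valence.  With every path free the model is just identified, so
complete-data maximum likelihood coincides with per-equation least
squares; partially missing outcomes are handled by full-information
maximum likelihood (FIML) — a dyad missing one outcome contributes the
univariate marginal of the observed outcome.  Standard errors are
sandwich (robust) estimates built from per-dyad score vectors, valid
under non-normal residuals; coefficients are also reported standardized
(beta = b * SD(x) / SD(y)) with delta-rule standard errors.

Estimation details: the observed-data log-likelihood is maximized by
BFGS on an unconstrained parameterization (regression coefficients,
log residual SDs, atanh residual correlation) with analytic gradients
and least-squares starting values; complete data short-circuits to the
exact closed form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

PREDICTORS = ("a_mean", "a_div", "a_mean_x_div", "c_mean", "c_div", "c_mean_x_div")
XNAMES = ("intercept",) + PREDICTORS
OUTCOMES = ("y_adol", "y_cg")
PRODUCTS = {"a_mean_x_div": ("a_mean", "a_div"),
            "c_mean_x_div": ("c_mean", "c_div")}

PATH_LABELS = {
    "a_mean": "{role} mean {valence} emotion".format,
    "a_div": "{role} {valence} emodiversity".format,
}


@dataclass
class ApimSpec:
    """Which model to build: emotion valence x symptom outcome."""

    valence: str = "negative"
    symptom: str = "anxious"
    grouping: str | None = None

    def __post_init__(self) -> None:
        if self.valence not in ("negative", "positive"):
            raise ValueError(f"unknown valence {self.valence!r}")
        if self.symptom not in ("anxious", "depressive"):
            raise ValueError(f"unknown symptom {self.symptom!r}")


@dataclass
class DesignMatrix:
    dyad_ids: list[str]
    X: np.ndarray                  # n x 7, intercept first, centered predictors
    xnames: tuple[str, ...]
    Y: np.ndarray                  # n x 2, NaN = missing outcome
    ynames: tuple[str, ...]
    centers: dict[str, float]
    groups: np.ndarray | None = None
    spec: ApimSpec | None = None

    @property
    def n(self) -> int:
        return len(self.dyad_ids)

    def xcol(self, name: str) -> np.ndarray:
        return self.X[:, self.xnames.index(name)]

    def subset(self, mask: np.ndarray) -> "DesignMatrix":
        return DesignMatrix(
            [d for d, m in zip(self.dyad_ids, mask) if m],
            self.X[mask], self.xnames, self.Y[mask], self.ynames,
            self.centers, None if self.groups is None else self.groups[mask],
            self.spec)

    def exog_correlations(self) -> pd.DataFrame:
        cols = self.X[:, 1:]
        return pd.DataFrame(np.corrcoef(cols, rowvar=False),
                            index=self.xnames[1:], columns=self.xnames[1:])


@dataclass
class ApimFit:
    """Point estimates and (once filled) robust inference for one APIM."""

    xnames: tuple[str, ...]
    ynames: tuple[str, ...]
    B: np.ndarray                  # p x 2 coefficients
    Sigma: np.ndarray              # 2 x 2 residual covariance
    loglik: float
    n: int
    converged: bool
    n_complete: int
    cov_robust: np.ndarray | None = None    # over theta = (b1, b2, s11, s22, s12)
    cov_classical: np.ndarray | None = None
    sd_x: dict[str, float] = field(default_factory=dict)
    sd_y: dict[str, float] = field(default_factory=dict)
    exog_corr: pd.DataFrame | None = None

    @property
    def p(self) -> int:
        return len(self.xnames)

    def coef(self, outcome: str, xname: str) -> float:
        return float(self.B[self.xnames.index(xname), self.ynames.index(outcome)])

    def param_index(self, outcome: str, xname: str) -> int:
        return self.ynames.index(outcome) * self.p + self.xnames.index(xname)

    def se_b(self, outcome: str, xname: str) -> float:
        if self.cov_robust is None:
            raise ValueError("robust covariance not computed; call robust_se first")
        i = self.param_index(outcome, xname)
        return float(np.sqrt(self.cov_robust[i, i]))

    @property
    def residual_correlation(self) -> float:
        return float(self.Sigma[0, 1] / np.sqrt(self.Sigma[0, 0] * self.Sigma[1, 1]))

    def summary_table(self, level: float = 0.95) -> pd.DataFrame:
        """Standardized path table: beta, robust SE, z, p, CI per path."""
        zcrit = stats.norm.ppf(0.5 + level / 2)
        rows = []
        for outcome in self.ynames:
            for xname in self.xnames:
                if xname == "intercept":
                    continue
                b = self.coef(outcome, xname)
                se = self.se_b(outcome, xname)
                scale = self.sd_x[xname] / self.sd_y[outcome]
                beta, se_beta = b * scale, se * scale
                z = b / se if se > 0 else np.nan
                rows.append({
                    "outcome": outcome, "path": xname, "b": b,
                    "beta": beta, "se_beta": se_beta, "z": z,
                    "p": 2 * stats.norm.sf(abs(z)),
                    "ci_low": beta - zcrit * se_beta,
                    "ci_high": beta + zcrit * se_beta,
                })
        return pd.DataFrame(rows)


class FitError(RuntimeError):
    pass


def build_design(summaries: pd.DataFrame, baselines: pd.DataFrame,
                 spec: ApimSpec, center: bool = True) -> DesignMatrix:
    """Assemble the per-dyad design for one valence x symptom model.

    Mean-emotion and emodiversity columns are grand-mean centered and
    the interaction columns are products of the centered factors;
    outcomes keep their original scale and missingness.  Dyads with any
    missing predictor (e.g. undefined emodiversity) are dropped with a
    warning; dyads missing both outcomes are dropped as uninformative.
    """
    mean_col = f"mean_{spec.valence[:3]}"
    gini_col = f"gini_{spec.valence[:3]}"
    sym_col = f"{spec.symptom}_mean"

    s = summaries.pivot(index="dyad_id", columns="role",
                        values=[mean_col, gini_col])
    b = baselines.pivot(index="dyad_id", columns="role", values=sym_col)
    merged = pd.DataFrame({
        "a_mean_raw": s[(mean_col, "adolescent")],
        "a_div_raw": s[(gini_col, "adolescent")],
        "c_mean_raw": s[(mean_col, "caregiver")],
        "c_div_raw": s[(gini_col, "caregiver")],
        "y_adol": b.get("adolescent"),
        "y_cg": b.get("caregiver"),
    })
    if spec.grouping is not None:
        g = baselines[baselines["role"] == "adolescent"].set_index("dyad_id")[spec.grouping]
        merged["group"] = g

    pred_cols = ["a_mean_raw", "a_div_raw", "c_mean_raw", "c_div_raw"]
    bad = merged[pred_cols].isna().any(axis=1)
    no_outcome = merged[["y_adol", "y_cg"]].isna().all(axis=1)
    if bad.any():
        logger.warning("dropping %d dyads with missing predictors: %s",
                       bad.sum(), ", ".join(merged.index[bad]))
    if (no_outcome & ~bad).any():
        logger.warning("dropping %d dyads with both outcomes missing",
                       (no_outcome & ~bad).sum())
    merged = merged[~bad & ~no_outcome]
    if merged.empty:
        raise FitError("no analyzable dyads")

    centers = {c[:-4]: (float(merged[c].mean()) if center else 0.0)
               for c in pred_cols}
    xc = {name: merged[f"{name}_raw"].to_numpy() - centers[name]
          for name in ("a_mean", "a_div", "c_mean", "c_div")}
    cols = {
        "intercept": np.ones(len(merged)),
        "a_mean": xc["a_mean"], "a_div": xc["a_div"],
        "a_mean_x_div": xc["a_mean"] * xc["a_div"],
        "c_mean": xc["c_mean"], "c_div": xc["c_div"],
        "c_mean_x_div": xc["c_mean"] * xc["c_div"],
    }
    X = np.column_stack([cols[name] for name in XNAMES])
    sds = X[:, 1:].std(axis=0, ddof=1)
    if np.any(sds == 0):
        flat = [n for n, s_ in zip(XNAMES[1:], sds) if s_ == 0]
        raise FitError(f"constant predictor column(s): {flat}")
    Y = merged[["y_adol", "y_cg"]].to_numpy(dtype=float)
    groups = merged["group"].to_numpy() if "group" in merged else None
    return DesignMatrix(list(merged.index), X, XNAMES, Y, OUTCOMES,
                        centers, groups, spec)


# ---------------------------------------------------------------------------
# likelihood machinery (natural parameterization theta = b1, b2, s11, s22, s12)

def _split(theta: np.ndarray, p: int):
    return theta[:p], theta[p:2 * p], theta[2 * p], theta[2 * p + 1], theta[2 * p + 2]


def _case_scores(theta: np.ndarray, X: np.ndarray, Y: np.ndarray
                 ) -> tuple[float, np.ndarray]:
    """Observed-data log-likelihood and per-case score matrix (n x dim)."""
    n, p = X.shape
    b1, b2, s11, s22, s12 = _split(theta, p)
    dim = 2 * p + 3
    scores = np.zeros((n, dim))
    ll = 0.0
    obs1, obs2 = ~np.isnan(Y[:, 0]), ~np.isnan(Y[:, 1])

    both = obs1 & obs2
    if both.any():
        det = s11 * s22 - s12 ** 2
        if det <= 0 or s11 <= 0 or s22 <= 0:
            return -np.inf, scores
        W = np.array([[s22, -s12], [-s12, s11]]) / det
        Xb, Yb = X[both], Y[both]
        E = Yb - Xb @ np.column_stack([b1, b2])
        q = np.einsum("ij,jk,ik->i", E, W, E)
        ll += float(-E.shape[0] * (np.log(2 * np.pi) + 0.5 * np.log(det)) - 0.5 * q.sum())
        WE = E @ W                       # n x 2
        scores[both, :p] = Xb * WE[:, [0]]
        scores[both, p:2 * p] = Xb * WE[:, [1]]
        # dll/dSigma = 0.5 * (W e e' W - W)
        s_mat = 0.5 * (WE[:, :, None] * WE[:, None, :] - W[None])
        scores[both, 2 * p] = s_mat[:, 0, 0]
        scores[both, 2 * p + 1] = s_mat[:, 1, 1]
        scores[both, 2 * p + 2] = 2.0 * s_mat[:, 0, 1]

    for k, (only, bk, s_kk, bslice, sidx) in enumerate([
            (obs1 & ~obs2, b1, s11, slice(0, p), 2 * p),
            (obs2 & ~obs1, b2, s22, slice(p, 2 * p), 2 * p + 1)]):
        if only.any():
            if s_kk <= 0:
                return -np.inf, scores
            Xo, yo = X[only], Y[only, k]
            e = yo - Xo @ bk
            ll += float(-0.5 * only.sum() * np.log(2 * np.pi * s_kk)
                        - 0.5 * (e ** 2).sum() / s_kk)
            scores[only, bslice] = Xo * (e / s_kk)[:, None]
            scores[only, sidx] = 0.5 * (e ** 2 / s_kk ** 2 - 1.0 / s_kk)

    return ll, scores


def _to_natural(phi: np.ndarray, p: int) -> np.ndarray:
    theta = phi.copy()
    a, c, r = phi[2 * p], phi[2 * p + 1], phi[2 * p + 2]
    s11, s22 = np.exp(2 * a), np.exp(2 * c)
    theta[2 * p] = s11
    theta[2 * p + 1] = s22
    theta[2 * p + 2] = np.tanh(r) * np.exp(a + c)
    return theta


def _neg_ll_and_grad(phi: np.ndarray, X: np.ndarray, Y: np.ndarray):
    p = X.shape[1]
    theta = _to_natural(phi, p)
    ll, scores = _case_scores(theta, X, Y)
    if not np.isfinite(ll):
        return np.inf, np.zeros_like(phi)
    g = scores.sum(axis=0)
    s11, s22, s12 = theta[2 * p], theta[2 * p + 1], theta[2 * p + 2]
    r = phi[2 * p + 2]
    g_phi = g.copy()
    g_phi[2 * p] = g[2 * p] * 2 * s11 + g[2 * p + 2] * s12
    g_phi[2 * p + 1] = g[2 * p + 1] * 2 * s22 + g[2 * p + 2] * s12
    g_phi[2 * p + 2] = g[2 * p + 2] * np.sqrt(s11 * s22) * (1 - np.tanh(r) ** 2)
    return -ll, -g_phi


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    mask = ~np.isnan(y)
    coef, *_ = np.linalg.lstsq(X[mask], y[mask], rcond=None)
    return coef


def fit_apim(design: DesignMatrix, min_n: int = 20) -> ApimFit:
    """FIML point estimates for the just-identified bivariate path model."""
    X, Y = design.X, design.Y
    n, p = X.shape
    if n < min_n:
        raise FitError(f"need at least {min_n} dyads, got {n}")
    if np.linalg.matrix_rank(X) < p:
        corr = np.corrcoef(X[:, 1:], rowvar=False)
        pairs = [(design.xnames[1 + i], design.xnames[1 + j])
                 for i in range(corr.shape[0]) for j in range(i)
                 if abs(corr[i, j]) > 0.999]
        raise FitError(f"rank-deficient design; collinear columns: {pairs}")

    complete = ~np.isnan(Y).any(axis=1)
    if complete.all():
        B = np.column_stack([_ols(X, Y[:, 0]), _ols(X, Y[:, 1])])
        E = Y - X @ B
        Sigma = E.T @ E / n
        theta = np.concatenate([B[:, 0], B[:, 1],
                                [Sigma[0, 0], Sigma[1, 1], Sigma[0, 1]]])
        ll, _ = _case_scores(theta, X, Y)
        fit = ApimFit(design.xnames, design.ynames, B, Sigma, ll, n, True, n)
    else:
        b1, b2 = _ols(X, Y[:, 0]), _ols(X, Y[:, 1])
        if complete.sum() >= p + 2:
            Ec = Y[complete] - X[complete] @ np.column_stack([b1, b2])
            S0 = Ec.T @ Ec / complete.sum()
        else:
            v1 = np.nanvar(Y[:, 0] - X @ b1)
            v2 = np.nanvar(Y[:, 1] - X @ b2)
            S0 = np.diag([v1, v2])
        rho0 = np.clip(S0[0, 1] / np.sqrt(S0[0, 0] * S0[1, 1]), -0.95, 0.95)
        phi0 = np.concatenate([
            b1, b2,
            [0.5 * np.log(max(S0[0, 0], 1e-8)), 0.5 * np.log(max(S0[1, 1], 1e-8)),
             np.arctanh(rho0)]])
        res = optimize.minimize(_neg_ll_and_grad, phi0, args=(X, Y), jac=True,
                                method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 2000})
        # convergence judged on the average per-dyad gradient so the
        # criterion does not tighten with sample size
        gnorm = float(np.max(np.abs(res.jac))) / n
        if gnorm > 1e-5:
            raise FitError(f"FIML did not converge: per-case gradient {gnorm:.2e}")
        converged = gnorm < 1e-7
        if not converged:
            logger.warning("FIML per-case gradient %.2e above tolerance", gnorm)
        theta = _to_natural(res.x, p)
        B = np.column_stack([theta[:p], theta[p:2 * p]])
        Sigma = np.array([[theta[2 * p], theta[2 * p + 2]],
                          [theta[2 * p + 2], theta[2 * p + 1]]])
        ll, _ = _case_scores(theta, X, Y)
        fit = ApimFit(design.xnames, design.ynames, B, Sigma, ll, n,
                      converged, int(complete.sum()))

    fit.exog_corr = design.exog_correlations()
    return fit


def _theta_of(fit: ApimFit) -> np.ndarray:
    return np.concatenate([fit.B[:, 0], fit.B[:, 1],
                           [fit.Sigma[0, 0], fit.Sigma[1, 1], fit.Sigma[0, 1]]])


def _total_score(theta: np.ndarray, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    _, scores = _case_scores(theta, X, Y)
    return scores.sum(axis=0)


def robust_se(fit: ApimFit, design: DesignMatrix,
              small_sample_factor: bool = True) -> ApimFit:
    """Fill sandwich (and classical) covariance of the natural parameters.

    V = A^-1 B A^-1 / n with A the average negative Hessian (central
    differences of the analytic score) and B the average outer product
    of per-dyad scores, scaled by n/(n-1) by default.
    """
    X, Y = design.X, design.Y
    n = X.shape[0]
    theta = _theta_of(fit)
    _, scores = _case_scores(theta, X, Y)
    Bmat = scores.T @ scores / n

    dim = len(theta)
    H = np.zeros((dim, dim))
    for j in range(dim):
        h = 1e-6 * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        H[:, j] = (_total_score(tp, X, Y) - _total_score(tm, X, Y)) / (2 * h)
    H = 0.5 * (H + H.T)
    A = -H / n
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular Hessian in sandwich covariance") from exc
    V = Ainv @ Bmat @ Ainv.T / n
    if small_sample_factor:
        V *= n / (n - 1)
    fit.cov_robust = V
    fit.cov_classical = Ainv / n
    return fit


def standardize(fit: ApimFit, design: DesignMatrix) -> ApimFit:
    """Record the sample SDs used to put paths on the standardized scale."""
    for i, name in enumerate(fit.xnames):
        fit.sd_x[name] = float(design.X[:, i].std(ddof=1)) if name != "intercept" else 0.0
    for k, name in enumerate(fit.ynames):
        y = design.Y[:, k]
        sd = float(np.nanstd(y, ddof=1))
        if sd == 0:
            raise FitError(f"zero-variance outcome {name}")
        fit.sd_y[name] = sd
    return fit


@dataclass
class GroupedFits:
    fits: dict[str, ApimFit]
    excluded_groups: dict[str, int]


def fit_multigroup(design: DesignMatrix, groups: np.ndarray | None = None,
                   min_group_n: int = 10) -> GroupedFits:
    """Independent APIM fits per stratum; undersized strata are reported."""
    labels = design.groups if groups is None else np.asarray(groups)
    if labels is None:
        raise ValueError("no grouping labels available")
    fits: dict[str, ApimFit] = {}
    excluded: dict[str, int] = {}
    for label in pd.unique(labels):
        mask = labels == label
        n_g = int(mask.sum())
        if n_g < min_group_n:
            excluded[str(label)] = n_g
            logger.info("group %r excluded (n=%d < %d)", label, n_g, min_group_n)
            continue
        sub = design.subset(mask)
        fit = fit_apim(sub, min_n=min(20, min_group_n))
        robust_se(fit, sub)
        standardize(fit, sub)
        fits[str(label)] = fit
    if not fits:
        raise FitError("all groups below the minimum size")
    return GroupedFits(fits, excluded)
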